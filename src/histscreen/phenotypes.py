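"""Analytics over the ordinal phenotype-severity matrix and the two
follow-up screens (chromosome-loss instability, heterochromatin
silencing).

The severity matrix grades each mutant under each stress condition on an
ordinal 0-4 scale (0 = no phenotype, 4 = strongest).  Conditions group
into four stress classes — DNA damage, microtubule destabilization,
temperature, other — and a mutant's "phenotype class count" is the
number of distinct classes in which it shows any phenotype (labels I-IV
for counts 1-4).

Chromosome loss: the rate per generation is estimated as half-sectored
colonies / total colonies (first-division loss of a marked chromosome);
a mutant is called unstable when its rate exceeds wild type by strictly
more than fourfold.

Silencing: reporter-expression scores (higher = more expression = less
silencing) are compared to wild type per locus.  Telomeric locus calls:
LTS (loss of telomere silencing), ITS (increased telomere silencing), or
WT; rDNA locus calls: LRS (loss of rDNA silencing) or WT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

STRESS_CLASSES = ("DNA_damage", "microtubule", "temperature", "other")
SEVERITY_MIN, SEVERITY_MAX = 0, 4
CLASS_LABELS = {0: "", 1: "I", 2: "II", 3: "III", 4: "IV"}

TELOMERE_CALLS = ("WT", "LTS", "ITS")
RDNA_CALLS = ("WT", "LRS")


class PhenotypeError(ValueError):
    pass


def load_severity_matrix(path: str | Path) -> pd.DataFrame:
    """Mutant x condition severity TSV (first column = mutant id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_severity_matrix(df)


def validate_severity_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    vals = matrix.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.all(vals == np.round(vals)):
            raise PhenotypeError("severities must be integers")
        matrix = matrix.astype(int)
        vals = matrix.to_numpy()
    if vals.size and (vals.min() < SEVERITY_MIN or vals.max() > SEVERITY_MAX):
        raise PhenotypeError(
            f"severities must lie in [{SEVERITY_MIN}, {SEVERITY_MAX}]"
        )
    return matrix


def load_class_map(path: str | Path) -> dict[str, str]:
    """Condition -> stress-class TSV (columns: condition, class)."""
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df["condition"], df["class"]))
    bad = set(mapping.values()) - set(STRESS_CLASSES)
    if bad:
        raise PhenotypeError(f"unknown stress classes: {sorted(bad)}")
    return mapping


def residue_severity(matrix: pd.DataFrame, catalog) -> pd.DataFrame:
    """Per-(histone, residue, condition) severity: the max over all
    mutants touching that residue."""
    rows = []
    for mutant_id, sev in matrix.iterrows():
        m = catalog.by_id.get(mutant_id)
        if m is None:
            raise PhenotypeError(f"mutant {mutant_id!r} absent from catalog")
        for res in m.residues:
            rows.append((m.histone, res, *sev.to_numpy()))
    tall = pd.DataFrame(rows, columns=["histone", "residue", *matrix.columns])
    return tall.groupby(["histone", "residue"]).max()


def count_phenotype_classes(matrix: pd.DataFrame,
                            class_map: dict[str, str]) -> pd.Series:
    """Distinct stress classes (0-4) in which each mutant has severity >= 1."""
    unmapped = set(matrix.columns) - set(class_map)
    if unmapped:
        raise PhenotypeError(f"conditions without a stress class: {sorted(unmapped)}")
    counts = pd.Series(0, index=matrix.index, dtype=int)
    for cls in STRESS_CLASSES:
        cols = [c for c in matrix.columns if class_map[c] == cls]
        if cols:
            counts += (matrix[cols].max(axis=1) >= 1).astype(int)
    return counts


def class_label(count: int) -> str:
    """Roman presentation label (I-IV) for class counts 1-4; '' for 0."""
    try:
        return CLASS_LABELS[count]
    except KeyError:
        raise PhenotypeError(f"class count {count} outside 0-4") from None


def fraction_with_phenotype(matrix: pd.DataFrame) -> tuple[int, int, float]:
    """(mutants with any phenotype, all mutants, fraction)."""
    if matrix.empty:
        raise PhenotypeError("empty severity matrix")
    num = int((matrix.max(axis=1) >= 1).sum())
    den = int(matrix.shape[0])
    return num, den, num / den


def subset_relation(set_a: set, set_b: set) -> tuple[str, tuple[int, int, int]]:
    """Exact set relation plus Venn counts (A only, B only, both)."""
    a, b = set(set_a), set(set_b)
    both = a & b
    counts = (len(a - b), len(b - a), len(both))
    if a == b:
        rel = "equal"
    elif a <= b:
        rel = "A_subset_B"
    elif b <= a:
        rel = "B_subset_A"
    elif both:
        rel = "overlap"
    else:
        rel = "disjoint"
    return rel, counts


def conservation_compare(scores: pd.Series,
                         class_counts: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conservation-score summaries per phenotype-class group.

    Returns (group summary with mean/SEM/n, pairwise two-sided
    Mann-Whitney U P-values with significance stars).  Groups with n < 2
    have SEM flagged as NaN.
    """
    shared = scores.index.intersection(class_counts.index)
    if shared.empty:
        raise PhenotypeError("scores and class counts share no mutants")
    s = scores.loc[shared].astype(float)
    g = class_counts.loc[shared].astype(int)
    groups = {k: s[g == k].to_numpy() for k in sorted(g.unique())}
    summary = pd.DataFrame(
        {
            "group": list(groups),
            "label": [class_label(k) for k in groups],
            "n": [len(v) for v in groups.values()],
            "mean": [float(np.mean(v)) for v in groups.values()],
            "sem": [float(stats.sem(v)) if len(v) >= 2 else float("nan")
                    for v in groups.values()],
        }
    )
    rows = []
    keys = list(groups)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            res = stats.mannwhitneyu(groups[ka], groups[kb],
                                     alternative="two-sided")
            p = float(res.pvalue)
            stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            rows.append((ka, kb, p, stars))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value", "stars"])
    return summary, pairwise


# ---------------------------------------------------------------------------
# Chromosome loss


def chromosome_loss_rate(half_sectored: int, total: int) -> float:
    """Loss rate per generation = half-sectored colonies / total colonies."""
    if total <= 0:
        raise PhenotypeError("total colonies must be positive")
    if not 0 <= half_sectored <= total:
        raise PhenotypeError("half_sectored must lie in [0, total]")
    return half_sectored / total


def call_unstable(rate_mutant: float, rate_wt: float,
                  fold_cut: float = 4.0) -> tuple[bool, float]:
    """Unstable iff rate exceeds wild type strictly more than fold_cut-fold."""
    if rate_wt <= 0:
        raise PhenotypeError("wild-type rate must be positive (fold undefined)")
    fold = rate_mutant / rate_wt
    return fold > fold_cut, fold


@dataclass
class ChromosomeLossRecord:
    strain_id: str
    total_colonies: int
    half_sectored: int
    rate_per_generation: float
    fold_vs_wt: float
    unstable: bool


def analyze_chromosome_loss(table: pd.DataFrame, wt_id: str = "WT",
                            fold_cut: float = 4.0) -> pd.DataFrame:
    """Per-strain loss rates and instability calls from colony counts.

    ``table`` needs columns strain_id, total_colonies, half_sectored and
    must contain the wild-type row.
    """
    if wt_id not in set(table["strain_id"]):
        raise PhenotypeError(f"wild-type strain {wt_id!r} missing from table")
    rates = {
        row.strain_id: chromosome_loss_rate(int(row.half_sectored),
                                            int(row.total_colonies))
        for row in table.itertuples()
    }
    wt_rate = rates[wt_id]
    records = []
    for row in table.itertuples():
        unstable, fold = call_unstable(rates[row.strain_id], wt_rate, fold_cut)
        records.append(
            ChromosomeLossRecord(row.strain_id, int(row.total_colonies),
                                 int(row.half_sectored), rates[row.strain_id],
                                 fold, unstable)
        )
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# Silencing


def call_silencing(score_mutant: float, score_wt: float, locus: str,
                   delta_cut: float = 1.0) -> str:
    """Categorical silencing call for one locus.

    Scores are reporter expression (higher = less silencing).  Telomere:
    above WT by more than delta_cut -> LTS; below by more -> ITS; else
    WT.  rDNA: above WT by more than delta_cut -> LRS; else WT.
    """
    delta = score_mutant - score_wt
    if locus == "telomere":
        if delta > delta_cut:
            return "LTS"
        if -delta > delta_cut:
            return "ITS"
        return "WT"
    if locus == "rdna":
        return "LRS" if delta > delta_cut else "WT"
    raise PhenotypeError(f"unknown locus {locus!r} (expected telomere/rdna)")


def analyze_silencing(table: pd.DataFrame, delta_cut: float = 1.0) -> pd.DataFrame:
    """Per-mutant telomere/rDNA silencing calls from reporter scores.

    ``table`` needs columns mutant_id, locus (telomere/rdna), score, and a
    WT row per locus.
    """
    calls: dict[str, dict[str, str]] = {}
    for locus, grp in table.groupby("locus"):
        scores = grp.set_index("mutant_id")["score"]
        if "WT" not in scores.index:
            raise PhenotypeError(f"no WT reference score for locus {locus!r}")
        wt = float(scores["WT"])
        for mid, sc in scores.items():
            if mid == "WT":
                continue
            calls.setdefault(mid, {"telomere": "WT", "rdna": "WT"})[locus] = (
                call_silencing(float(sc), wt, locus, delta_cut)
            )
    out = pd.DataFrame(
        [(mid, d["telomere"], d["rdna"]) for mid, d in sorted(calls.items())],
        columns=["mutant_id", "telomere", "rdna"],
    )
    return out
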