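"""Depletion statistics: calling drug-sensitive mutants from count tables.

For each mutant the treated and control arms are compared as a 2x2 table
(mutant reads vs rest-of-library reads) with a two-sided Fisher exact
test; effect size is the normalized log2 ratio of proportions.  A mutant
is called sensitive when, in a replicate, log2 ratio < -1, P < 0.01 and
Benjamini-Hochberg q < 0.01 — all strict inequalities.  A Holm
family-wise-error-adjusted P is also reported but does not gate the call.
Replicates are analyzed independently and their candidate sets
intersected.

Library sizes are per-sample *assigned* read totals (column sums of the
count matrix), so unassigned reads never distort proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class Thresholds:
    """Sensitivity-call cutoffs; all three criteria are strict."""

    log2_cut: float = -1.0
    p_cut: float = 0.01
    q_cut: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cut < 1.0 and 0.0 < self.q_cut < 1.0):
            raise ValueError("p_cut and q_cut must lie in (0, 1)")
        if not np.isfinite(self.log2_cut):
            raise ValueError("log2_cut must be finite")


def log2_ratio(t: float, c: float, T: float, C: float,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2( ((t+pc)/T) / ((c+pc)/C) ); NaN when undefined (t=c=0, pc=0)."""
    if T <= 0 or C <= 0:
        raise ValueError("library sizes must be positive")
    if t < 0 or c < 0 or pseudocount < 0:
        raise ValueError("counts and pseudocount must be non-negative")
    num = (t + pseudocount) / T
    den = (c + pseudocount) / C
    if num == 0 and den == 0:
        return float("nan")
    if den == 0:
        return float("inf")
    if num == 0:
        return float("-inf")
    return float(np.log2(num / den))


def depletion_test(t: int, c: int, T: int, C: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[t, T-t], [c, C-c]]."""
    _check_margins(t, c, T, C)
    _, p = stats.fisher_exact([[t, T - t], [c, C - c]], alternative="two-sided")
    return float(min(p, 1.0))


def _check_margins(t, c, T, C) -> None:
    if T <= 0 or C <= 0:
        raise ValueError("degenerate margins: T and C must be positive")
    if not (0 <= t <= T and 0 <= c <= C):
        raise ValueError("counts must satisfy 0 <= t <= T and 0 <= c <= C")


# Relative slack when comparing pmf values for two-sided tail collection,
# matching the conventional Fisher-test treatment of ties.
_PMF_REL_TOL = 1e-7


def depletion_test_many(t: np.ndarray, c: np.ndarray, T: int, C: int) -> np.ndarray:
    """Vectorised two-sided Fisher exact P-values for shared library sizes.

    For each mutant the null is hypergeometric: conditioned on s = t + c
    reads for the mutant, the treated count follows Hypergeom(N=T+C,
    K=T, n=s).  The two-sided P sums the probabilities of all outcomes no
    more likely than the observed one.
    """
    t = np.asarray(t, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    if t.shape != c.shape:
        raise ValueError("t and c must have the same shape")
    if t.size and (int(t.min()) < 0 or int(c.min()) < 0):
        raise ValueError("negative counts")
    if t.size and (int(t.max()) > T or int(c.max()) > C):
        raise ValueError("counts exceed library sizes")
    _check_margins(0, 0, T, C)

    N = T + C
    p_out = np.ones(t.shape, dtype=float)
    s_all = t + c
    for s in np.unique(s_all):
        sel = np.flatnonzero(s_all == s)
        lo = max(0, s - C)
        hi = min(T, s)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, N, T, s)
        obs = pmf[t[sel] - lo]
        # sum of pmf over outcomes with pmf <= observed (with tie slack)
        p = (pmf[None, :] <= obs[:, None] * (1 + _PMF_REL_TOL)) @ pmf
        p_out[sel] = np.minimum(p, 1.0)
    return p_out


def adjust_fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    _check_probs(p)
    return multipletests(p, method="fdr_bh")[1]


def adjust_fwer_holm(p_values) -> np.ndarray:
    """Holm step-down FWER-adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    _check_probs(p)
    return multipletests(p, method="holm")[1]


def _check_probs(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")


def classify_sensitive(results: pd.DataFrame,
                       thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Flag sensitive mutants by the strict triple rule.

    Requires columns log2_ratio, p_value, q_value_fdr; returns a copy
    with a boolean ``sensitive`` column.
    """
    th = thresholds or Thresholds()
    out = results.copy()
    out["sensitive"] = (
        (out["log2_ratio"] < th.log2_cut)
        & (out["p_value"] < th.p_cut)
        & (out["q_value_fdr"] < th.q_cut)
    )
    return out


def test_replicate(counts: pd.DataFrame, treated_col: str, control_col: str,
                   thresholds: Thresholds | None = None,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Full depletion analysis of one treated/control sample pair."""
    t = counts[treated_col].to_numpy()
    c = counts[control_col].to_numpy()
    T = int(t.sum())
    C = int(c.sum())
    lr = np.array([log2_ratio(ti, ci, T, C, pseudocount) for ti, ci in zip(t, c)])
    p = depletion_test_many(t, c, T, C)
    res = pd.DataFrame(
        {
            "mutant_id": counts.index,
            "log2_ratio": lr,
            "p_value": p,
            "q_value_fdr": adjust_fdr_bh(p),
            "p_fwer": adjust_fwer_holm(p),
        }
    )
    return classify_sensitive(res, thresholds)


def run_differential(counts: pd.DataFrame, design: pd.DataFrame,
                     thresholds: Thresholds | None = None,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT
                     ) -> dict[int, pd.DataFrame]:
    """Per-replicate depletion results keyed by replicate number.

    ``design`` needs columns sample_id, condition (treated/control), and
    replicate; each replicate must contribute exactly one sample per
    condition.
    """
    out: dict[int, pd.DataFrame] = {}
    for rep, grp in design.groupby("replicate"):
        by_cond = grp.set_index("condition")["sample_id"]
        if sorted(by_cond.index) != ["control", "treated"]:
            raise ValueError(
                f"replicate {rep} must have exactly one treated and one "
                f"control sample, got {list(grp['condition'])}"
            )
        out[int(rep)] = test_replicate(
            counts, by_cond["treated"], by_cond["control"], thresholds, pseudocount
        )
    return out


def replicate_concordance(res1: pd.DataFrame, res2: pd.DataFrame) -> dict:
    """Agreement between two replicate analyses.

    Pearson correlation of log2 ratios (over mutants finite in both) plus
    candidate-set overlap; downstream analyses use the intersection.
    """
    u1 = set(res1["mutant_id"])
    u2 = set(res2["mutant_id"])
    shared = u1 & u2
    if not shared:
        raise ValueError("replicates share no mutants")
    a = res1.set_index("mutant_id").loc[sorted(shared)]
    b = res2.set_index("mutant_id").loc[sorted(shared)]
    finite = np.isfinite(a["log2_ratio"]) & np.isfinite(b["log2_ratio"])
    if finite.sum() >= 2:
        r = float(stats.pearsonr(a.loc[finite, "log2_ratio"],
                                 b.loc[finite, "log2_ratio"])[0])
    else:
        r = float("nan")
    cand1 = set(a.index[a["sensitive"]])
    cand2 = set(b.index[b["sensitive"]])
    inter = cand1 & cand2
    union = cand1 | cand2
    return {
        "pearson_r": r,
        "candidates_rep1": cand1,
        "candidates_rep2": cand2,
        "intersection": inter,
        "union": union,
        "jaccard": (len(inter) / len(union)) if union else 1.0,
    }
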