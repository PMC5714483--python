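"""Map per-residue phenotype annotations onto the nucleosome structure
and test whether phenotype residues cluster spatially.

The nucleosome crystal structure contains two copies of each histone
chain; a residue key (histone, residue number) therefore maps to one or
two Calpha coordinates.  Distances between residues use the minimum over
symmetric copies, so a residue pair close in either nucleosome half
counts as close.

The clustering statistic is the mean pairwise Calpha distance of a query
residue set; its null distribution comes from same-size residue sets
drawn uniformly without replacement with the same per-histone
composition as the query, so chain-specific geometry cannot masquerade
as clustering.  The permutation P-value uses the add-one estimator
p = (1 + #{null <= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

SEVERITY_BANDS = {1: "low", 2: "low", 3: "high", 4: "high"}


class StructureError(ValueError):
    pass


def parse_structure(pdb_path: str | Path,
                    chain_map: dict[str, str]) -> pd.DataFrame:
    """One Calpha coordinate per mapped residue of the histone chains.

    Chains absent from ``chain_map`` (e.g. DNA) are skipped silently;
    mapped residues lacking a Calpha are skipped with a warning.
    Alternate locations resolve to the highest-occupancy conformer, then
    first listed.
    """
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("nucleosome", str(pdb_path))[0]
    rows = []
    for chain in model:
        histone = chain_map.get(chain.id)
        if histone is None:
            continue
        for residue in chain:
            if residue.id[0].strip():
                continue  # heteroatoms / waters
            if "CA" not in residue:
                logger.warning(
                    "chain %s residue %s has no CA atom; skipped",
                    chain.id, residue.id[1],
                )
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                # Bio.PDB's selected child is the highest-occupancy altloc
                atom = atom.selected_child
            x, y, z = (float(v) for v in atom.coord)
            rows.append((chain.id, histone, int(residue.id[1]), x, y, z))
    return pd.DataFrame(rows, columns=["chain", "histone", "residue", "x", "y", "z"])


def load_chain_map(path: str | Path) -> dict[str, str]:
    """Chain -> histone TSV (columns: chain, histone)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["chain"], df["histone"]))


def map_annotations(annotations: pd.DataFrame,
                    coordinates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join residue severities onto structure coordinates.

    ``annotations`` needs columns histone, residue, severity (1-4).
    Returns (attribute table with a two-tier severity band — "low" for
    severities 1-2, "high" for 3-4 — one row per chain instance; report
    of annotated residues with no coordinate).
    """
    attr_rows = []
    unmapped = []
    coord_key = coordinates.set_index(["histone", "residue"])
    for row in annotations.itertuples():
        sev = int(row.severity)
        if sev < 1 or sev > 4:
            raise StructureError(f"severity {sev} outside 1-4 for "
                                 f"{row.histone} {row.residue}")
        key = (row.histone, int(row.residue))
        try:
            hits = coord_key.loc[[key]]
        except KeyError:
            unmapped.append((row.histone, int(row.residue), sev))
            continue
        for hit in hits.itertuples():
            attr_rows.append((hit.chain, int(row.residue), row.histone, sev,
                              SEVERITY_BANDS[sev]))
    attr = pd.DataFrame(attr_rows,
                        columns=["chain", "residue", "histone", "severity", "band"])
    report = pd.DataFrame(unmapped, columns=["histone", "residue", "severity"])
    return attr, report


def write_attribute_file(attr: pd.DataFrame, path: str | Path,
                         value_col: str = "severity") -> None:
    """Plain per-residue attribute text (chain, residue, value) for
    molecular viewers."""
    lines = [f"# residue attribute: {value_col}"]
    for row in attr.itertuples():
        lines.append(f"{row.chain}\t{row.residue}\t{getattr(row, value_col)}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ClusterTestResult:
    """Permutation test of spatial clustering on the structure."""

    observed_stat: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    seed: int | None


class _ResidueGeometry:
    """Residue-level coordinates with symmetric-copy minimum distances."""

    def __init__(self, coordinates: pd.DataFrame):
        self.positions: dict[tuple[str, int], np.ndarray] = {}
        for (histone, residue), grp in coordinates.groupby(["histone", "residue"]):
            self.positions[(histone, int(residue))] = grp[["x", "y", "z"]].to_numpy()

    def residues_of(self, histone: str) -> list[tuple[str, int]]:
        return sorted(k for k in self.positions if k[0] == histone)

    def distance(self, a: tuple[str, int], b: tuple[str, int]) -> float:
        pa, pb = self.positions[a], self.positions[b]
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        return float(d.min())

    def mean_pairwise(self, keys: list[tuple[str, int]]) -> float:
        dists = [self.distance(a, b) for a, b in itertools.combinations(keys, 2)]
        return float(np.mean(dists))


def spatial_clustering_test(
    query: list[tuple[str, int]],
    coordinates: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    exhaustive: bool = False,
    max_exhaustive: int = 500_000,
) -> ClusterTestResult:
    """Is the query residue set more spatially compact than chance?

    Null sets preserve the query's per-histone composition and are drawn
    uniformly without replacement from each histone's resolved residues.
    With ``exhaustive=True`` every same-composition set is enumerated and
    p = #{stat <= observed} / #sets (the query itself is in the
    enumeration, so p >= 1/#sets).
    """
    if len(query) < 2:
        raise StructureError("query must contain at least two residues")
    geom = _ResidueGeometry(coordinates)
    missing = [q for q in query if (q[0], int(q[1])) not in geom.positions]
    if missing:
        raise StructureError(f"query residues without coordinates: {missing}")
    query = [(h, int(r)) for h, r in query]
    if len(set(query)) != len(query):
        raise StructureError("query contains duplicate residues")

    by_histone: dict[str, int] = {}
    for h, _ in query:
        by_histone[h] = by_histone.get(h, 0) + 1
    pools = {h: geom.residues_of(h) for h in by_histone}
    for h, k in by_histone.items():
        if k > len(pools[h]):
            raise StructureError(f"query needs {k} residues of {h}, structure "
                                 f"resolves only {len(pools[h])}")

    observed = geom.mean_pairwise(query)

    if exhaustive:
        n_sets = math.prod(math.comb(len(pools[h]), k)
                           for h, k in by_histone.items())
        if n_sets > max_exhaustive:
            raise StructureError(
                f"exhaustive enumeration needs {n_sets} sets (cap {max_exhaustive})"
            )
        stats_null = []
        per_histone = [
            list(itertools.combinations(pools[h], by_histone[h]))
            for h in by_histone
        ]
        for combo in itertools.product(*per_histone):
            keys = [k for part in combo for k in part]
            stats_null.append(geom.mean_pairwise(keys))
        null = np.array(stats_null)
        p = float((null <= observed + 1e-12).sum() / null.size)
        return ClusterTestResult(observed, float(null.mean()), float(null.std()),
                                 p, int(null.size), None)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        keys: list[tuple[str, int]] = []
        for h, k in by_histone.items():
            pool = pools[h]
            picks = rng.choice(len(pool), size=k, replace=False)
            keys.extend(pool[j] for j in picks)
        null[i] = geom.mean_pairwise(keys)
    hits = int((null <= observed + 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return ClusterTestResult(observed, float(null.mean()), float(null.std()),
                             float(p), n_permutations, seed)
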