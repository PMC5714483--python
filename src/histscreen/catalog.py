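"""Domain types and validated I/O for the histone-mutant catalog.

The screen's strain library attaches two strain-specific DNA barcodes
("uptag" / "downtag", in the tradition of the yeast deletion collection)
to every histone H2A/H2B allele.  Pooled samples are distinguished by a
5-nt sample index engineered so that any two indices differ at >= 2
positions, which makes a single sequencing error detectable (though not
correctable).  This module holds the shared record types -- mutants,
sample indices, and the amplicon layout -- together with strict loaders
for their tab-separated exchange formats.
"""

from __future__ import annotations

import dataclasses
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

DNA_ALPHABET = frozenset("ACGT")
HISTONES = ("H2A", "H2B", "H3", "H4")

INDEX_LENGTH = 5          # sample index is always a 5-mer
MIN_INDEX_DISTANCE = 2    # any two indices differ at >= 2 positions

#: Common annealing sequences flanking every TAG in the amplicon; defaults
#: follow the deletion-collection uptag primer pair (U1/U2).
DEFAULT_UPSTREAM_FLANK = "GATGTCCACGAGGTCTCT"
DEFAULT_DOWNSTREAM_FLANK = "CGTACGCTGCAGGTCGAC"
DEFAULT_TAG_LENGTH = 20


class CatalogError(ValueError):
    """Raised when a catalog, index table, or layout violates an invariant."""


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise CatalogError(
            f"{what} {seq!r} contains non-ACGT characters: {sorted(bad)}"
        )


_POINT_RE = re.compile(r"^[A-Z](\d+(?:,\d+)*)[A-Z]$")
_DEL_RE = re.compile(r"^del(\d+)(?:-(\d+))?$")


def parse_allele_residues(allele: str) -> tuple[int, ...]:
    """Residue positions (1-based) affected by an allele string.

    Supported forms: point substitutions ("K34E"), compound substitutions
    with comma-joined positions ("K6,11,16Q"), and deletions ("del29-36",
    "del12").
    """
    m = _DEL_RE.match(allele)
    if m:
        start = int(m.group(1))
        stop = int(m.group(2)) if m.group(2) else start
        if stop < start:
            raise CatalogError(f"deletion allele {allele!r} has stop < start")
        return tuple(range(start, stop + 1))
    m = _POINT_RE.match(allele)
    if m:
        return tuple(int(p) for p in m.group(1).split(","))
    raise CatalogError(f"cannot parse residues from allele {allele!r}")


@dataclass(frozen=True)
class Mutant:
    """One barcoded histone allele in the library."""

    id: str
    histone: str
    allele: str
    residues: tuple[int, ...]
    uptag: str
    downtag: str

    def __post_init__(self) -> None:
        if self.histone not in HISTONES:
            raise CatalogError(
                f"mutant {self.id!r}: histone {self.histone!r} not in {HISTONES}"
            )
        _check_dna(self.uptag, f"mutant {self.id!r} uptag")
        _check_dna(self.downtag, f"mutant {self.id!r} downtag")
        if not self.residues:
            raise CatalogError(f"mutant {self.id!r}: residues must be non-empty")
        if any(r < 1 for r in self.residues):
            raise CatalogError(f"mutant {self.id!r}: residues must be >= 1")


@dataclass(frozen=True)
class SampleIndex:
    """A 5-nt sample index with its experimental-design annotation."""

    sample_id: str
    index_seq: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        _check_dna(self.index_seq, f"sample {self.sample_id!r} index")
        if len(self.index_seq) != INDEX_LENGTH:
            raise CatalogError(
                f"sample {self.sample_id!r}: index {self.index_seq!r} is not "
                f"{INDEX_LENGTH} nt"
            )
        if self.condition not in ("treated", "control"):
            raise CatalogError(
                f"sample {self.sample_id!r}: condition must be treated/control"
            )
        if self.replicate < 1:
            raise CatalogError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class AmpliconLayout:
    """Structure of a sequenced barcode amplicon read.

    Read 1 (by default) carries the sample index at ``index_offset``,
    followed by ``upstream_flank``, the TAG, and ``downstream_flank``.
    """

    upstream_flank: str = DEFAULT_UPSTREAM_FLANK
    downstream_flank: str = DEFAULT_DOWNSTREAM_FLANK
    tag_length: int = DEFAULT_TAG_LENGTH
    index_offset: int = 0
    tag_read: int = 1

    def __post_init__(self) -> None:
        if not self.upstream_flank or not self.downstream_flank:
            raise CatalogError("amplicon flanks must be non-empty")
        _check_dna(self.upstream_flank, "upstream flank")
        _check_dna(self.downstream_flank, "downstream flank")
        if self.tag_length < 1:
            raise CatalogError("tag_length must be positive")
        if self.index_offset < 0:
            raise CatalogError("index_offset must be >= 0")
        if self.tag_read not in (1, 2):
            raise CatalogError("tag_read must be 1 or 2")

    @property
    def read_length(self) -> int:
        """Minimal read length spanning index, flanks, and TAG."""
        return (
            self.index_offset
            + INDEX_LENGTH
            + len(self.upstream_flank)
            + self.tag_length
            + len(self.downstream_flank)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmpliconLayout":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


class MutantCatalog:
    """Validated collection of mutants with unique ids and barcodes."""

    def __init__(self, mutants: Sequence[Mutant]):
        self.mutants: tuple[Mutant, ...] = tuple(mutants)
        self.by_id: dict[str, Mutant] = {}
        self.by_tag: dict[str, tuple[str, str]] = {}  # tag -> (mutant id, up/down)
        dup_ids: dict[str, list[str]] = {}
        dup_tags: dict[str, list[str]] = {}
        for m in self.mutants:
            if m.id in self.by_id:
                dup_ids.setdefault(m.id, [self.by_id[m.id].id]).append(m.id)
            self.by_id[m.id] = m
            for tag, which in ((m.uptag, "up"), (m.downtag, "down")):
                if tag in self.by_tag:
                    other = self.by_tag[tag][0]
                    dup_tags.setdefault(tag, [other]).append(m.id)
                else:
                    self.by_tag[tag] = (m.id, which)
        if dup_ids:
            raise CatalogError(f"duplicate mutant ids: {sorted(dup_ids)}")
        if dup_tags:
            details = "; ".join(
                f"tag {t} shared by mutants {ids}" for t, ids in sorted(dup_tags.items())
            )
            raise CatalogError(f"duplicate barcodes: {details}")
        lengths = {len(t) for t in self.by_tag}
        if len(lengths) > 1:
            raise CatalogError(f"TAGs have mixed lengths: {sorted(lengths)}")
        self._min_tag_distance: int | None = None

    def __len__(self) -> int:
        return len(self.mutants)

    def __iter__(self):
        return iter(self.mutants)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.mutants]

    @property
    def tag_length(self) -> int:
        return len(self.mutants[0].uptag) if self.mutants else 0

    def min_tag_distance(self) -> int:
        """Minimum pairwise Hamming distance over all up+down TAGs (cached)."""
        if self._min_tag_distance is None:
            tags = list(self.by_tag)
            self._min_tag_distance = (
                min_pairwise_hamming(tags) if len(tags) >= 2 else self.tag_length
            )
        return self._min_tag_distance


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise CatalogError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def min_pairwise_hamming(seqs: Sequence[str]) -> int:
    """Minimum Hamming distance over all unordered pairs of sequences.

    Vectorised over blocks so that catalog-sized inputs (~1000 tags of
    20 nt) stay fast.
    """
    if len(seqs) < 2:
        raise CatalogError("need at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise CatalogError("sequences must have equal length")
    enc = _encode(seqs)
    best = enc.shape[1]
    block = 256
    for i in range(0, len(seqs), block):
        chunk = enc[i : i + block]
        rest = enc[i:]
        # d[r, c] = Hamming(seq[i+r], seq[i+c]); keep strictly-later pairs only
        d = (chunk[:, None, :] != rest[None, :, :]).sum(axis=2)
        for r in range(chunk.shape[0]):
            later = d[r, r + 1 :]
            if later.size:
                best = min(best, int(later.min()))
        if best == 0:
            return 0
    return best


@dataclass
class IndexSetReport:
    """Outcome of validating a sample-index set."""

    valid: bool
    violations: list[tuple[str, str, int]] = field(default_factory=list)
    bad_lengths: list[str] = field(default_factory=list)


def validate_index_set(indices: Sequence[SampleIndex | str]) -> IndexSetReport:
    """Check that all indices are 5-mers with pairwise Hamming >= 2.

    Violations are reported, not raised.
    """
    if not indices:
        raise CatalogError("empty index set")
    seqs = [i.index_seq if isinstance(i, SampleIndex) else i for i in indices]
    report = IndexSetReport(valid=True)
    for s in seqs:
        if len(s) != INDEX_LENGTH:
            report.bad_lengths.append(s)
            report.valid = False
    ok = [s for s in seqs if len(s) == INDEX_LENGTH]
    for a, b in itertools.combinations(ok, 2):
        d = hamming(a, b)
        if d < MIN_INDEX_DISTANCE:
            report.violations.append((a, b, d))
            report.valid = False
    return report


# ---------------------------------------------------------------------------
# Tabular I/O

CATALOG_COLUMNS = ("id", "histone", "allele", "residues", "uptag", "downtag")
INDEX_COLUMNS = ("sample_id", "index_seq", "condition", "replicate")


def load_catalog(path: str | Path) -> MutantCatalog:
    """Read a mutant catalog from TSV (columns: id, histone, allele,
    residues, uptag, downtag; residues comma-joined integers)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogError(f"catalog {path} missing columns: {sorted(missing)}")
    mutants = [
        Mutant(
            id=row.id,
            histone=row.histone,
            allele=row.allele,
            residues=tuple(int(r) for r in str(row.residues).split(",")),
            uptag=row.uptag,
            downtag=row.downtag,
        )
        for row in df.itertuples()
    ]
    return MutantCatalog(mutants)


def save_catalog(catalog: MutantCatalog, path: str | Path) -> None:
    lines = ["\t".join(CATALOG_COLUMNS)]
    for m in catalog:
        lines.append(
            "\t".join(
                (
                    m.id,
                    m.histone,
                    m.allele,
                    ",".join(str(r) for r in m.residues),
                    m.uptag,
                    m.downtag,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_indices(path: str | Path) -> list[SampleIndex]:
    """Read a sample-index table from TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "index_seq": str,
                                            "condition": str, "replicate": int})
    missing = set(INDEX_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogError(f"index table {path} missing columns: {sorted(missing)}")
    return [
        SampleIndex(row.sample_id, row.index_seq, row.condition, int(row.replicate))
        for row in df.itertuples()
    ]


def save_indices(indices: Iterable[SampleIndex], path: str | Path) -> None:
    lines = ["\t".join(INDEX_COLUMNS)]
    for s in indices:
        lines.append(f"{s.sample_id}\t{s.index_seq}\t{s.condition}\t{s.replicate}")
    Path(path).write_text("\n".join(lines) + "\n")
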