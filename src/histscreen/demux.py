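"""Demultiplex paired barcode-amplicon FASTQ and build the count table.

Every read pair ends up in exactly one place: a (mutant, sample) cell of
the count matrix, or one of four unassigned counters (bad_index,
bad_flank, unknown_tag, ambiguous_tag).  That conservation — assigned +
unassigned = total pairs — is asserted after every run.

Policy choices: sample indices are matched exactly (the pairwise
distance-2 design makes single errors detectable, not correctable);
flanks are matched exactly; TAG matching may tolerate one mismatch, but
only when the catalog's minimum pairwise TAG distance is >= 3, which
guarantees a 1-error read has a unique nearest TAG.  Only read 1 is used
for counting by default (it carries index + TAG); read 2 is checked for
pairing.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .catalog import (
    AmpliconLayout,
    CatalogError,
    INDEX_LENGTH,
    MutantCatalog,
    SampleIndex,
    validate_index_set,
)

BAD_INDEX = "bad_index"
BAD_FLANK = "bad_flank"
UNKNOWN_TAG = "unknown_tag"
AMBIGUOUS_TAG = "ambiguous_tag"
UNASSIGNED_KINDS = (BAD_INDEX, BAD_FLANK, UNKNOWN_TAG, AMBIGUOUS_TAG)


class FastqFormatError(ValueError):
    """Raised for truncated or malformed FASTQ input."""


@dataclass
class CountTable:
    """Sample x mutant counts plus the unassigned-read ledger.

    ``matrix`` has mutants as rows and samples as columns.  ``unassigned``
    is indexed by sample plus a ``(none)`` row for reads whose index
    matched no sample (which therefore cannot be attributed).
    """

    matrix: pd.DataFrame
    unassigned: pd.DataFrame
    total_pairs: int

    NO_SAMPLE = "(none)"

    def validate(self) -> None:
        if (self.matrix.to_numpy() < 0).any() or (self.unassigned.to_numpy() < 0).any():
            raise ValueError("negative counts in count table")
        assigned = int(self.matrix.to_numpy().sum())
        lost = int(self.unassigned.to_numpy().sum())
        if assigned + lost != self.total_pairs:
            raise ValueError(
                f"read conservation violated: {assigned} assigned + {lost} "
                f"unassigned != {self.total_pairs} total pairs"
            )

    def save(self, counts_path: str | Path, ledger_path: str | Path) -> None:
        self.matrix.to_csv(counts_path, sep="\t")
        self.unassigned.to_csv(ledger_path, sep="\t")


def demultiplex(read_seq: str, index_to_sample: dict[str, str],
                index_offset: int = 0) -> str | None:
    """Assign a read to a sample by exact 5-mer index match, else None."""
    idx = read_seq[index_offset : index_offset + INDEX_LENGTH]
    if len(idx) < INDEX_LENGTH:
        return None
    return index_to_sample.get(idx)


def extract_tag(read_seq: str, layout: AmpliconLayout) -> str | None:
    """Pull the TAG out of a read by exact flank anchoring, else None.

    The upstream flank must occur exactly once; the downstream flank must
    follow the TAG exactly.
    """
    up = layout.upstream_flank
    pos = read_seq.find(up)
    if pos < 0:
        return None
    if read_seq.find(up, pos + 1) >= 0:
        return None  # ambiguous anchoring
    start = pos + len(up)
    tag = read_seq[start : start + layout.tag_length]
    if len(tag) < layout.tag_length:
        return None
    if not read_seq.startswith(layout.downstream_flank, start + layout.tag_length):
        return None
    return tag


class TagMatcher:
    """Match observed TAGs to the catalog at 0 or 1 mismatches.

    One mismatch is only permitted when the catalog's minimum pairwise TAG
    distance is >= 3: then any read within Hamming 1 of a catalog TAG is
    within 1 of that TAG alone, so the match is provably unambiguous.
    """

    def __init__(self, catalog: MutantCatalog, max_mismatch: int = 0):
        if max_mismatch not in (0, 1):
            raise CatalogError("max_mismatch must be 0 or 1")
        if max_mismatch == 1 and catalog.min_tag_distance() < 3:
            raise CatalogError(
                f"1-mismatch TAG matching requires catalog minimum pairwise "
                f"distance >= 3 (got {catalog.min_tag_distance()})"
            )
        self.catalog = catalog
        self.max_mismatch = max_mismatch
        self._tags = list(catalog.by_tag)
        self._enc = (
            np.frombuffer("".join(self._tags).encode(), dtype=np.uint8)
            .reshape(len(self._tags), -1)
            if self._tags
            else np.empty((0, catalog.tag_length), dtype=np.uint8)
        )
        self._cache: dict[str, str] = {}

    def match(self, tag: str) -> str:
        """Return a mutant id, UNKNOWN_TAG, or AMBIGUOUS_TAG."""
        hit = self.catalog.by_tag.get(tag)
        if hit is not None:
            return hit[0]
        if self.max_mismatch == 0:
            return UNKNOWN_TAG
        cached = self._cache.get(tag)
        if cached is not None:
            return cached
        if len(tag) != self._enc.shape[1]:
            return UNKNOWN_TAG
        q = np.frombuffer(tag.encode(), dtype=np.uint8)
        d = (self._enc != q).sum(axis=1)
        within = np.flatnonzero(d <= 1)
        if within.size == 0:
            result = UNKNOWN_TAG
        elif within.size == 1:
            result = self.catalog.by_tag[self._tags[within[0]]][0]
        else:
            # unreachable when min distance >= 3, kept as a safety net
            result = AMBIGUOUS_TAG
        self._cache[tag] = result
        return result


def match_tag(tag: str, catalog: MutantCatalog, max_mismatch: int = 0) -> str:
    """One-shot TAG lookup (see :class:`TagMatcher`)."""
    return TagMatcher(catalog, max_mismatch).match(tag)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    n = 0
    with _open_text(path) as fh:
        try:
            for rec in FastqGeneralIterator(fh):
                n += 1
                yield rec
        except ValueError as exc:
            raise FastqFormatError(
                f"{path}: malformed/truncated FASTQ after record {n}: {exc}"
            ) from exc


def build_count_table(
    r1_path: str | Path,
    catalog: MutantCatalog,
    indices: list[SampleIndex],
    layout: AmpliconLayout,
    max_mismatch: int = 0,
    r2_path: str | Path | None = None,
) -> CountTable:
    """Stream FASTQ into a validated CountTable.

    Each read pair increments exactly one matrix cell or one unassigned
    counter; the conservation invariant is asserted before returning.
    When ``r2_path`` is given the two files must pair record-for-record.
    """
    report = validate_index_set(indices)
    if not report.valid:
        raise CatalogError(f"invalid index set: {report.violations or report.bad_lengths}")
    index_to_sample = {s.index_seq: s.sample_id for s in indices}
    matcher = TagMatcher(catalog, max_mismatch)

    sample_ids = [s.sample_id for s in indices]
    mut_pos = {mid: i for i, mid in enumerate(catalog.ids)}
    samp_pos = {sid: j for j, sid in enumerate(sample_ids)}
    matrix = np.zeros((len(catalog), len(sample_ids)), dtype=np.int64)
    ledger_rows = sample_ids + [CountTable.NO_SAMPLE]
    ledger = np.zeros((len(ledger_rows), len(UNASSIGNED_KINDS)), dtype=np.int64)
    kind_pos = {k: j for j, k in enumerate(UNASSIGNED_KINDS)}

    reads1 = _fastq_records(r1_path)
    reads2 = _fastq_records(r2_path) if r2_path is not None else None

    total = 0
    offset = layout.index_offset
    for rec1 in reads1:
        if reads2 is not None:
            rec2 = next(reads2, None)
            if rec2 is None:
                raise FastqFormatError(
                    f"{r2_path}: ran out of mates at read pair {total + 1}"
                )
        total += 1
        seq1 = rec1[1]
        sample = demultiplex(seq1, index_to_sample, offset)
        if sample is None:
            ledger[-1, kind_pos[BAD_INDEX]] += 1
            continue
        row = samp_pos[sample]
        tag = extract_tag(seq1, layout)
        if tag is None:
            ledger[row, kind_pos[BAD_FLANK]] += 1
            continue
        hit = matcher.match(tag)
        if hit == UNKNOWN_TAG:
            ledger[row, kind_pos[UNKNOWN_TAG]] += 1
        elif hit == AMBIGUOUS_TAG:
            ledger[row, kind_pos[AMBIGUOUS_TAG]] += 1
        else:
            matrix[mut_pos[hit], row] += 1
    if reads2 is not None and next(reads2, None) is not None:
        raise FastqFormatError(f"{r1_path}: ran out of reads before {r2_path}")

    table = CountTable(
        matrix=pd.DataFrame(matrix, index=pd.Index(catalog.ids, name="id"),
                            columns=sample_ids),
        unassigned=pd.DataFrame(ledger, index=pd.Index(ledger_rows, name="sample"),
                                columns=list(UNASSIGNED_KINDS)),
        total_pairs=total,
    )
    table.validate()
    return table
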