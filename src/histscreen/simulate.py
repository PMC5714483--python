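"""Synthetic bar-seq experiment generator.

Emulates the pooled-growth fitness screen: a barcoded histone-mutant pool
is split into an untreated control arm and a genotoxin-treated arm
(methyl methanesulfonate in the motivating screen), each arm is sampled
by amplicon sequencing of the strain TAGs, and depleted mutants reveal
drug sensitivity.  The generator produces a mutant catalog, a sample
index set, ground-truth log2 fitness effects, multinomial count vectors,
and paired-end FASTQ reads, all bit-reproducible under a fixed seed.

Model in brief: baseline pool abundances are lognormal and normalized to
proportions p_c; the treated arm's proportions are p_t ∝ p_c · 2^e for a
per-mutant log2 effect e (0 for unaffected mutants, negative for
depleted ones); each sample's counts are one multinomial draw of the
configured sequencing depth.  Sequencing noise is i.i.d. per-base
substitution at a configurable rate; qualities are constant.
"""

from __future__ import annotations

import dataclasses
import gzip
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    AmpliconLayout,
    CatalogError,
    INDEX_LENGTH,
    Mutant,
    MutantCatalog,
    SampleIndex,
    validate_index_set,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: TAG sets are generated at pairwise Hamming >= 3 so that 1-mismatch
#: matching can never be ambiguous.
MIN_TAG_DISTANCE = 3

# Residue spans of the S. cerevisiae histones (mature protein numbering).
_HISTONE_LENGTHS = {"H2A": 132, "H2B": 130}
_AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic screen.

    Defaults mirror the screen being emulated: 570 scored mutants, two
    conditions x two replicates, and 95,000 read pairs per sample.
    """

    n_mutants: int = 570
    tag_length: int = 20
    n_samples: int = 4                      # treated/control x replicates
    read_pairs_per_sample: int = 95_000
    depleted_fraction: float = 0.1
    effect_log2_mean: float = -2.0
    effect_log2_sd: float = 0.5
    abundance_lognormal_sd: float = 0.5
    seq_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")
        if self.n_samples < 2 or self.n_samples % 2:
            raise ValueError("n_samples must be an even number >= 2")
        if self.read_pairs_per_sample < 1:
            raise ValueError("read_pairs_per_sample must be >= 1")
        if not 0.0 <= self.depleted_fraction <= 1.0:
            raise ValueError("depleted_fraction must be in [0, 1]")
        if not 0.0 <= self.seq_error_rate <= 0.1:
            raise ValueError("seq_error_rate must be in [0, 0.1]")
        if self.abundance_lognormal_sd < 0:
            raise ValueError("abundance_lognormal_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# Index and TAG design


def _distance2_codewords() -> list[str]:
    """All 5-mers whose base-4 digit sum is 0 mod 4.

    A single substitution always changes the digit sum, so any two
    codewords differ at >= 2 positions (a classical parity code); this
    yields 4^4 = 256 usable sample indices.
    """
    words = []
    for digits in itertools.product(range(4), repeat=INDEX_LENGTH - 1):
        parity = (-sum(digits)) % 4
        full = digits + (parity,)
        words.append("".join("ACGT"[d] for d in full))
    return words


def generate_index_set(n: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` sample indices with pairwise Hamming distance >= 2."""
    pool = _distance2_codewords()
    if n > len(pool):
        raise CatalogError(
            f"cannot design {n} length-{INDEX_LENGTH} indices at pairwise "
            f"distance >= 2 (maximum {len(pool)})"
        )
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in chosen]


def generate_tags(n: int, length: int, rng: np.random.Generator,
                  min_distance: int = MIN_TAG_DISTANCE,
                  max_rounds: int = 200) -> list[str]:
    """Random DNA TAGs with pairwise Hamming distance >= ``min_distance``.

    Random 20-mers are almost surely far apart; offending sequences are
    redrawn until the whole set satisfies the distance floor.
    """
    enc = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    for _ in range(max_rounds):
        bad = np.zeros(n, dtype=bool)
        block = 256
        for i in range(0, n, block):
            d = (enc[i : i + block, None, :] != enc[None, :, :]).sum(axis=2)
            close = d < min_distance
            for r in range(close.shape[0]):
                close[r, i + r] = False  # self
            rows = close.any(axis=1)
            bad[i : i + block] |= rows
        if not bad.any():
            return ["".join("ACGT"[b] for b in row) for row in enc]
        enc[bad] = rng.integers(0, 4, size=(int(bad.sum()), length), dtype=np.uint8)
    raise CatalogError(
        f"failed to design {n} TAGs of length {length} at distance >= {min_distance}"
    )


def generate_catalog(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[MutantCatalog, list[SampleIndex]]:
    """Random mutant catalog plus a valid sample-index set.

    Alleles alternate between H2A and H2B and are mostly point
    substitutions, with a sprinkling of short tail deletions so that
    allele-parsing paths are exercised.
    """
    tags = generate_tags(2 * config.n_mutants, config.tag_length, rng)
    mutants = []
    seen_ids: set[str] = set()
    for k in range(config.n_mutants):
        histone = "H2A" if k % 2 == 0 else "H2B"
        length = _HISTONE_LENGTHS[histone]
        if rng.random() < 0.05:
            start = int(rng.integers(1, length - 8))
            stop = start + int(rng.integers(3, 8))
            allele = f"del{start}-{stop}"
            residues = tuple(range(start, stop + 1))
        else:
            pos = int(rng.integers(1, length + 1))
            ref, alt = rng.choice(list(_AMINO_ACIDS), size=2, replace=False)
            allele = f"{ref}{pos}{alt}"
            residues = (pos,)
        base_id = f"{histone}_{allele}"
        mid = base_id
        suffix = 2
        while mid in seen_ids:
            mid = f"{base_id}_{suffix}"
            suffix += 1
        seen_ids.add(mid)
        mutants.append(
            Mutant(mid, histone, allele, residues, tags[2 * k], tags[2 * k + 1])
        )
    catalog = MutantCatalog(mutants)

    n_rep = config.n_samples // 2
    seqs = generate_index_set(config.n_samples, rng)
    indices = []
    for r in range(n_rep):
        indices.append(SampleIndex(f"control_{r + 1}", seqs[2 * r], "control", r + 1))
        indices.append(SampleIndex(f"treated_{r + 1}", seqs[2 * r + 1], "treated", r + 1))
    assert validate_index_set(indices).valid
    return catalog, indices


# ---------------------------------------------------------------------------
# Ground truth and counts


def generate_truth(
    catalog: MutantCatalog, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ground-truth log2 fitness effects: 0 for unaffected mutants and a
    strictly negative normal draw for the depleted fraction."""
    n = len(catalog)
    n_dep = int(round(config.depleted_fraction * n))
    depleted_idx = rng.choice(n, size=n_dep, replace=False)
    effects = np.zeros(n)
    for i in depleted_idx:
        e = rng.normal(config.effect_log2_mean, config.effect_log2_sd)
        while e >= 0:  # effects of depleted mutants are strictly negative
            e = rng.normal(config.effect_log2_mean, config.effect_log2_sd)
        effects[i] = e
    return pd.DataFrame(
        {
            "id": catalog.ids,
            "true_log2_effect": effects,
            "is_depleted": effects < 0,
        }
    )


def treated_proportions(baseline: np.ndarray, log2_effects: np.ndarray) -> np.ndarray:
    """Renormalized treated-arm proportions: p_t ∝ p_c · 2^effect."""
    w = np.asarray(baseline, dtype=float) * np.exp2(log2_effects)
    return w / w.sum()


def simulate_counts(
    catalog: MutantCatalog,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial count table (mutants x samples) plus the design table.

    One baseline abundance vector describes the shared pool; every sample
    is an independent multinomial draw of the configured depth from its
    arm's proportion vector.
    """
    if len(catalog) == 0:
        raise CatalogError("cannot simulate counts for an empty catalog")
    if set(truth["id"]) != set(catalog.ids):
        raise CatalogError("truth table does not cover the catalog")
    effects = truth.set_index("id").loc[catalog.ids, "true_log2_effect"].to_numpy()

    baseline = rng.lognormal(0.0, config.abundance_lognormal_sd, size=len(catalog))
    p_ctrl = baseline / baseline.sum()
    p_trt = treated_proportions(baseline, effects)

    n_rep = config.n_samples // 2
    counts: dict[str, np.ndarray] = {}
    design_rows = []
    for r in range(1, n_rep + 1):
        counts[f"control_{r}"] = rng.multinomial(config.read_pairs_per_sample, p_ctrl)
        counts[f"treated_{r}"] = rng.multinomial(config.read_pairs_per_sample, p_trt)
        design_rows.append((f"control_{r}", "control", r))
        design_rows.append((f"treated_{r}", "treated", r))
    count_df = pd.DataFrame(counts, index=pd.Index(catalog.ids, name="id"))
    design = pd.DataFrame(design_rows, columns=["sample_id", "condition", "replicate"])
    return count_df, design


# ---------------------------------------------------------------------------
# FASTQ emission


def _apply_errors(enc: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate``, never to the original base."""
    if rate <= 0 or enc.size == 0:
        return enc
    mask = rng.random(enc.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return enc
    # shift by 1-3 positions in ACGT so the substituted base always differs
    orig = enc[mask]
    code = np.searchsorted(_BASES, orig)
    shift = rng.integers(1, 4, size=n_err)
    enc[mask] = _BASES[(code + shift) % 4]
    return enc


def _encode_read(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class FastqPair(NamedTuple):
    r1: Path
    r2: Path


def emit_fastq(
    catalog: MutantCatalog,
    counts: pd.DataFrame,
    indices: list[SampleIndex],
    layout: AmpliconLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    outdir: str | Path,
) -> dict[str, FastqPair]:
    """Write per-sample gzip FASTQ pairs realizing a count table.

    Read 1: [pad][5-nt index][upstream flank][uptag][downstream flank];
    read 2 carries the partner downtag in the same layout.  Per-base
    substitution errors at ``config.seq_error_rate``; constant Q40
    qualities.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample = {s.sample_id: s for s in indices}
    missing = set(counts.columns) - set(by_sample)
    if missing:
        raise CatalogError(f"no sample index for samples: {sorted(missing)}")

    pad = "T" * layout.index_offset
    read_len = layout.read_length
    paths: dict[str, FastqPair] = {}
    order = {mid: i for i, mid in enumerate(catalog.ids)}

    for sample_id in counts.columns:
        idx_seq = by_sample[sample_id].index_seq
        templates_r1 = np.empty((len(catalog), read_len), dtype=np.uint8)
        templates_r2 = np.empty_like(templates_r1)
        for m in catalog:
            r1 = f"{pad}{idx_seq}{layout.upstream_flank}{m.uptag}{layout.downstream_flank}"
            r2 = f"{pad}{idx_seq}{layout.upstream_flank}{m.downtag}{layout.downstream_flank}"
            templates_r1[order[m.id]] = _encode_read(r1)
            templates_r2[order[m.id]] = _encode_read(r2)

        col = counts[sample_id].reindex(catalog.ids).to_numpy()
        mutant_of_read = np.repeat(np.arange(len(catalog)), col)
        rng.shuffle(mutant_of_read)
        reads1 = _apply_errors(templates_r1[mutant_of_read].copy(),
                               config.seq_error_rate, rng)
        reads2 = _apply_errors(templates_r2[mutant_of_read].copy(),
                               config.seq_error_rate, rng)

        qual = "I" * read_len
        p1 = outdir / f"{sample_id}_R1.fastq.gz"
        p2 = outdir / f"{sample_id}_R2.fastq.gz"
        for path, reads, mate in ((p1, reads1, 1), (p2, reads2, 2)):
            with gzip.open(path, "wt") as fh:
                for i in range(reads.shape[0]):
                    seq = reads[i].tobytes().decode()
                    fh.write(f"@{sample_id}:{i}/{mate}\n{seq}\n+\n{qual}\n")
        paths[sample_id] = FastqPair(p1, p2)
    return paths


# ---------------------------------------------------------------------------
# One-call experiment


class SimulatedExperiment(NamedTuple):
    catalog: MutantCatalog
    indices: list[SampleIndex]
    layout: AmpliconLayout
    truth: pd.DataFrame
    counts: pd.DataFrame
    design: pd.DataFrame
    fastq: dict[str, FastqPair] | None


def simulate_experiment(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    layout: AmpliconLayout | None = None,
    emit_reads: bool = True,
) -> SimulatedExperiment:
    """Generate catalog, truth, counts, and (optionally) FASTQ in one call.

    All randomness derives from ``config.seed``; identical configs give
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    layout = layout or AmpliconLayout(tag_length=config.tag_length)
    if layout.tag_length != config.tag_length:
        raise CatalogError("layout tag_length disagrees with config tag_length")
    catalog, indices = generate_catalog(config, rng)
    truth = generate_truth(catalog, config, rng)
    counts, design = simulate_counts(catalog, truth, config, rng)
    fastq = None
    if outdir is not None and emit_reads:
        fastq = emit_fastq(catalog, counts, indices, layout, config, rng, outdir)
    if outdir is not None:
        outdir = Path(outdir)
        from .catalog import save_catalog, save_indices

        save_catalog(catalog, outdir / "catalog.tsv")
        save_indices(indices, outdir / "indices.tsv")
        layout.to_yaml(outdir / "layout.yaml")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        counts.to_csv(outdir / "true_counts.tsv", sep="\t")
        design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    return SimulatedExperiment(catalog, indices, layout, truth, counts, design, fastq)
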