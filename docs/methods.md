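# Methods

## The experiment being modeled

A pooled library of barcoded histone H2A/H2B point, compound, and
tail-deletion mutants is grown as one culture, split into an untreated
control arm and a genotoxin-treated arm, and the post-treatment
composition of each arm is measured by amplicon sequencing of the
strain-specific TAG barcodes. Mutants whose relative abundance drops in
the treated arm are sensitive to the stress. Around this core sit three
lower-throughput screens over the same library: an ordinal
phenotype-severity matrix from serial-dilution spotting under many
stresses, a chromosome-loss assay from colony sectoring, and a
heterochromatin-silencing reporter assay — plus mapping of the affected
residues onto the nucleosome crystal structure.

## Simulation model

The generator produces, from one seed, every artifact the pipeline
consumes.

**Amplicon.** Read 1 is `[index][upstream flank][uptag][downstream
flank]`; read 2 carries the partner downtag in the same layout. The
default flanks are the classic deletion-collection common-primer pair
(18 nt each) and the default TAG length is 20 nt, the historical length
of yeast-collection barcodes; both are configurable in the layout. Only
read 1 is used for counting; read 2 is verified for pairing.

**Sample indices.** 5-nt indices must differ pairwise at ≥ 2 positions.
They are drawn from the parity code {5-mers whose base-4 digit sum ≡ 0
mod 4}: a single substitution always changes the digit sum, giving
minimum distance 2 and a capacity of 4⁴ = 256 indices — comfortably
above the 96 samples a multiplexed run carries.

**TAGs.** Random 20-mers, redrawn until the whole set (up- and downtags
pooled) has pairwise Hamming distance ≥ 3. Random 20-mers are almost
surely far apart, so rejection is rare; the floor of 3 is what licenses
optional 1-mismatch TAG matching downstream (a read one error away from
a TAG is then provably nearest to that TAG alone).

**Abundances and counts.** Baseline pool proportions are lognormal
(σ = 0.5 by default) and normalized. The treated arm multiplies each
mutant's proportion by 2^e for its log2 fitness effect e and
renormalizes; each sample is one multinomial draw of 95,000 read pairs
(the per-sample depth of the motivating screen). The default dispersion
models a deliberately equal-pooled library: σ = 0.5 gives a ~10-fold
95% abundance range, typical of hand-pooled collections, and keeps even
the rarest of 570 mutants at a countable depth (~100 reads/sample). A
heavier tail (σ = 1) would starve the bottom of the pool to ~15
reads/sample, below what any exact test can call at q < 0.01 — a
regime the screen's equal-pooling protocol is designed to avoid.

**Effects.** A configurable fraction (default 10%) of mutants is
depleted with effects drawn from N(−2, 0.5) truncated to negative
values; all other mutants have effect exactly 0. Depletion acts once
between the arms (a single multiplicative 2^e), abstracting exposure
plus outgrowth; per-generation growth is not modeled separately. With
the strict log2 < −1 call threshold, ~3–4% of depleted mutants draw
effects too mild to be callable even at infinite depth; the recovery
targets account for this.

**Sequencing noise.** I.i.d. per-base substitutions (default 0.5%,
a conservative figure for older short-read chemistry), never to the
same base; no indels (fixed-layout amplicons) and no PCR jackpot or
chimera modeling. Quality strings are constant Q40 and nothing
downstream is quality-aware.

What the generator does *not* emulate — index hopping, PCR bias, depth
variation between samples, overdispersion beyond multinomial — means
passing tests demonstrate correctness of the analysis under the stated
model, not robustness to every artifact of real sequencing runs.

## Counting policies

Index matching is exact: at pairwise distance 2, a 1-error index can be
equidistant to two valid indices, so correction would trade correctness
for yield. Flank matching is exact and the upstream flank must occur
exactly once in the read. TAG matching tolerates one mismatch only when
the catalog-wide minimum TAG distance is ≥ 3 (checked at matcher
construction). Every read pair increments exactly one count cell or one
of four unassigned counters (bad_index, bad_flank, unknown_tag,
ambiguous_tag); the identity assigned + unassigned = total is asserted
after every run, not assumed.

## Depletion statistics

Per mutant and replicate, the 2×2 table [[t, T−t], [c, C−c]] (mutant vs
rest-of-library reads, treated vs control) is tested with a two-sided
Fisher exact test. The test family is a package choice: an exact
conditional test needs no dispersion estimate, which matters because the
design has no replicate structure within an arm. Implementation: the
pipeline path vectorises the hypergeometric tail sum grouped by s = t+c
(outcomes no more likely than the observed one, with the conventional
1 + 1e−7 relative tie slack); the scalar entry point delegates to
`scipy.stats.fisher_exact`, and the two are cross-checked against each
other and against exact integer enumeration in the tests.

Library sizes T, C are per-sample *assigned* totals so unassigned reads
cannot distort proportions. Log2 ratios use a 0.5 pseudocount (finite at
t = 0, ranking-preserving, configurable). Multiplicity control is
Benjamini–Hochberg for FDR and Holm for FWER; the sensitivity rule gates
on P and BH q only (log2 < −1, P < 0.01, q < 0.01, all strict), with the
Holm column reported for reference. Replicates are analyzed
independently and candidate sets intersected, which empirically drives
the false-discovery proportion of the intersection to ~0 while keeping
sensitivity above 0.9 at the default study conditions.

## Phenotype analytics

Severities are integers 0–4; 0 encodes "no phenotype" rather than a
missing value so matrix algebra is total. Residue-level severity is the
max over all mutants touching the residue (deletion alleles touch their
whole range). A mutant's phenotype-class count is the number of distinct
stress classes (DNA damage, microtubule, temperature, other) with any
phenotype; Roman labels I–IV are presentation only, and class-count-0
mutants are excluded from "mutants with phenotypes" summaries.
Conservation scores are consumed precomputed (e.g., ConSurf output) and
compared between class groups with a two-sided Mann–Whitney U — a rank
test, since conservation scores have no reason to be normal — with
mean ± SEM summaries and stars at 0.05/0.01.

Chromosome-loss rate per generation is half-sectored colonies / total
colonies (the first-division loss estimator of the standard sectoring
assay); instability requires strictly more than fourfold over wild type.
Silencing calls compare reporter-expression scores to wild type per
locus with a symmetric threshold: telomere scores above WT by more than
δ are LTS, below by more are ITS; rDNA only derepresses (LRS) — an
"increased rDNA silencing" category is not part of the call space.
Digitising colony color into scores is out of scope; callers supply
them.

## Structure mapping and clustering

Cα coordinates are read from PDB via Bio.PDB with altlocs resolved to
highest occupancy then first listed; DNA and unmapped chains are
skipped. The nucleosome holds two copies of each histone, so a residue
key (histone, number) can map to two coordinates; inter-residue
distances take the minimum over copies, so proximity in either
nucleosome half counts (which copy the original figures color is
unknowable, and the minimum is the symmetric convention).

The clustering statistic is the mean pairwise Cα distance of the query
set — the simplest statistic that formalizes a visual "these residues
cluster" claim. The null preserves the query's per-histone composition
and draws residues uniformly without replacement from each histone's
resolved residues; p = (1 + #{null ≤ observed}) / (1 + permutations),
which is exactly super-uniform under the null. An exhaustive mode
enumerates every composition-matched set (used against a brute-force
oracle on an 8-residue toy structure in the tests).

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical configs give byte-identical catalogs, counts, and FASTQ.
- Degenerate inputs: empty p-vectors return empty arrays; log2(0/0) with
  zero pseudocount returns NaN (flagged, not raised); zero-margin 2×2
  tables and zero-colony totals raise.
- Tie handling in the two-sided exact test uses the conventional
  relative slack (1 + 1e−7) when comparing outcome probabilities; the
  acceptance oracle mirrors the same convention in exact integer
  arithmetic, so agreement is required to 1e−9 relative, not merely to
  the slack width.
- Test problem sizes: end-to-end checks run at the full study scale
  (570 mutants, 4 × 95,000 pairs); calibration and recovery properties
  average 10–50 seeded simulations at counts level (the FASTQ layer is
  exercised separately by the round-trip tests, so re-emitting reads in
  every statistical replicate would add cost without information).

## Known limitations

- The exact test conditions on per-mutant totals and assumes multinomial
  sampling; real bar-seq data are overdispersed by PCR and growth noise,
  so on real data the P-values are anti-conservative and a dispersion
  model (negative binomial across replicates) would be the upgrade path.
- The severity matrix and conservation scores are inputs; the package
  does not grade spot assays or compute conservation.
- The silencing δ threshold is a free parameter with no published
  quantitative anchor; calls are only as meaningful as the supplied
  scores.
- Chromosome-loss rates are plain binomial point estimates; no
  confidence intervals are attached to the fourfold rule.
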