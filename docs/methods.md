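# Methods

This note documents the models, rules and numerical choices behind
`floralnet`, in the order the pipeline applies them, followed by the
synthetic-data model and its limits.

## Detection-call filtering

Array processing software emits a Present/Marginal/Absent call per
cell. Two filters are provided, matching the two analysis tracks:

- `discard_all_absent`: remove genes called `A` at every stage; feeds
  the differential/clustering track.
- `require_one_present`: keep genes with at least one `P`; feeds the
  co-expression track, which needs more confidently detected profiles.

`M` is treated literally as neither absent nor present: an all-`M` gene
survives the first filter and fails the second. The second filter's
output is always a subset of the first's.

## Fold-change selection and normalization

A gene is differential when its max/min signal ratio across the eight
stages reaches 4 (boundary inclusive). The ratio is computed on raw
signal after flooring at 1.0 intensity unit — arrays can report
near-zero intensities whose ratios are noise; the floor is configurable
and applied before, never after, the ratio. Normalization divides each
signal by the gene's across-stage mean and takes log2, giving
dimensionless mean-ratio profiles whose `mean_s 2^x = 1` identity is
asserted to 1e-9 in the tests; the transform is exactly invariant to
per-gene rescaling.

Per-stage up/down counts compare each stage to a baseline — stage 1 by
default, or the preceding stage — at a 1 log2-unit (twofold) call
threshold. No single convention for such counts exists; both baseline
and threshold are explicit config parameters rather than constants.

## Pattern clustering

k-means with Pearson-correlation distance `d = 1 − r`, which groups
genes by trajectory shape independent of amplitude. Details that
matter:

- Centroids are arithmetic means of member rows (closed-form update;
  the behaviour of MeV-style correlation k-means), not medoids.
- Initialization is k-means++ D² sampling under the correlation
  distance; plain random-row (Forgy) starts frequently miss one of
  several near-parallel shape groups and converge to a visibly worse
  objective.
- Ten restarts with seeds `seed..seed+9`; the run with the lowest
  within-cluster distance sum wins, ties to the lowest seed. Everything
  is deterministic given (matrix, k, seed, restarts).
- Empty clusters are repaired by reassigning the point farthest from
  its current centroid; non-singleton donor clusters only.
- Zero-variance genes are a hard error, not silently dropped — they
  have no defined correlation, and the fold-change pre-selection makes
  them impossible in the intended flow.
- A zero-variance *centroid* (possible transiently) is given
  correlation 0, i.e. distance 1, to every profile.

Cluster trend summaries tag each centroid as early-dip, rise-fall,
late-rise, drift-up or drift-down: an interior extremum counts as a
dip/peak when the profile recovers by ≥ 20% of the centroid's range on
both sides; a rise is "late" when one step carries ≥ 50% of the range
and lands at stage 3 or later. These are reporting heuristics only;
nothing downstream consumes the tags.

## GO enrichment

The urn model: background of N genes, K carrying the term, a set of n
showing k carriers; p = P(X ≥ k) under Hypergeometric(N, K, n),
evaluated through the scipy survival function (log-space internally;
agreement with exact integer enumeration is verified to 1e-12 over
every population N ≤ 30). Flags use the raw p ≤ 0.01 threshold with no
multiple-testing correction — the convention of the classical
array-era analyses this package implements; Benjamini–Hochberg
q-values are reported in the same records for modern use but never
alter the flags. The background
defaults to every gene on the array, including unannotated genes (they
are draws without the term) and including genes removed by the
detection filter; both choices are configurable.

## Homolog filtering and contig classification

Per query, the top hit is the maximal bitscore, with ties broken by
smaller e-value then lexicographic subject id — bitscore because it is
database-size independent; the cascade is total so input order can
never matter. The filter is `evalue < 1e-5` (strict) ∧ `identity ≥ 80`
∧ `coverage ≥ 50` (inclusive), with coverage = aligned query span of
the top hit over query length — single-HSP, no merging. Twelve-column
BLAST tabular lacks query length, so a two-column lengths sidecar is
required; coordinates stay 1-based inclusive, and `s_start > s_end`
records a minus-strand subject alignment. Cross-assembly
classification calls a contig *common* when its best hit into the other
assembly reaches `e ≤ 1e-10` (inclusive), independently per direction,
so the two common sets can differ in size.

## Mutual-Rank co-expression network

PCC is computed on the normalized log2 mean-ratio profiles (a raw-scale
option exists behind `pcc_scale`). For each ordered pair, `R(a→b)` is
the position of b in a's partner list sorted by descending PCC, self
excluded, best partner = 1; tied PCCs receive the mean of their tied
positions, which keeps MR well-defined and permutation-invariant.
`MR = sqrt(R(a→b)·R(b→a))` is symmetric, ≥ 1, and 1 exactly for
reciprocal top partners. The network is *seeded*: only pairs touching a
core flowering gene are considered (core–core pairs included), kept at
MR ≤ 50 and classed bold (≤ 5), normal (≤ 30), thin (≤ 50).

Function modules are connected components of the MR ≤ 30 subgraph with
singletons discarded, ids assigned by descending size then smallest
member — no single standard module algorithm exists for seeded MR
networks, so the choice is isolated behind one interface with
Clauset–Newman–Moore greedy modularity as the alternative. Module GO profiles report the
percentage of members carrying each term to two decimals; a module is
flower-flagged when a flower-development term is among its top three
terms (or above an explicit percentage floor if one is given).

Recruitment: a non-core node with ≥ 1 core partner at MR ≤ 30 and
PCC ≥ 0.8 (both inclusive) that itself carries a flower-development GO
term. Relaxing either threshold recruits a superset.

## qPCR

Comparative-Ct with amplification efficiency fixed at 2 and no
efficiency correction: replicates are averaged on the Ct scale, ΔCt
subtracts the reference gene (actin) per sample, ΔΔCt subtracts the
calibrator sample (stage S1 by default — the choice is a config
parameter, as no universal convention exists), RQ = 2^−ΔΔCt. Two exact
identities are asserted: the calibrator's RQ is 1, and adding a
constant to every Ct of one sample changes nothing (reference
cancellation). Concordance with the array is the Pearson r of log2 RQ
against the normalized array profile.

## Synthetic data model

The generator emulates the pipeline's substrate with planted truth; its
defaults are the package's study conditions.

- **Signals**: `signal = 2^(μ + ε)`, ε ~ N(0, σ) on log2 — additive
  Gaussian on the log scale, hence multiplicative on signal, matching
  ratio-based microarray fold changes. Default σ = 0.25; the signal
  base is 2^8 ≈ 256 intensity units.
- **Archetypes**: nine fixed mean profiles (constants in code, so
  fixtures are stable): early dips bottoming at S2/S3/S4/S6, step rises
  at S4/S5, a rise-then-fall, and two slow drifts. All spans are ≥ 2.2
  log2 units, comfortably above the fourfold criterion, and the shapes
  are mutually distinguishable under correlation distance — by
  construction the nine-archetype fixture is recoverable by the
  clustering module at ARI ≥ 0.9, which is the fixture's contract with
  the test suite. Default 100 genes per archetype (scaled down
  proportionally for smaller `n_genes`).
- **Cores and partners**: each of 10 core genes gets an individual
  random log-profile (sd 1.5 across stages) — deliberately *not* an
  archetype, so a core's strongest correlates are its own planted
  partners rather than a 100-gene archetype block; each core gets 5
  partners = scaled (×U(0.6, 1.4)), shifted (+U(−1, 1)) copies of the
  core profile with smaller noise (σ = 0.1). Partner–core PCC is ≈ 1
  (exactly 1 at zero noise), and partner MR to the core lands ≤ 5.
- **GO labels**: the first 3 cores are the flower module; they and
  their partners carry the flower-development term GO:0009908. All
  other genes draw 1–2 generic terms, plus the flower term at a 2%
  background rate — nonzero so recruitment precision is measured
  against realistic annotation noise, small so the planted module, not
  that noise, dominates the default fixture.
- **Absent genes and calls**: 2% of genes are all-`A` (carved from the
  unstructured background block, never from cores or partners); all
  other calls are `P`, with `M` at a configurable rate defaulting to 0
  since no convention for generating marginal calls exists.
- **BLAST tables**: exactly `round(fraction_pass × n_queries)` queries
  receive a hit passing all three homolog thresholds (coverage spans
  are ceiled so rounding can never push a planted pass below the cut);
  each failing query violates exactly one randomly chosen threshold.
- **Ct tables**: a gene's Ct is a base cycle minus the array's
  normalized log2 value plus N(0, 0.3) biological noise and N(0, 0.05)
  replicate noise; the reference gene is flat, so 2^−ΔΔCt recovers the
  array profile up to that noise.

Every generator is bit-deterministic under its seed.

### What the generator does not emulate

Probe-level intensities and scanner artifacts, probe→gene
summarization, between-array normalization, correlated (batch or
spatially structured) noise, realistic GO term co-occurrence, partial
detection-call patterns tied to signal level, or 454 read/assembly
error. Passing tests therefore demonstrate that the *rules and
numerics* of the pipeline behave as specified and that planted
structure of realistic magnitude is recovered — not that the pipeline's
thresholds are optimal for any particular real dataset.

## Problem sizes and other fixed choices

Test and demo datasets use 1,000 genes × 8 stages (900 for the pure
clustering fixture), 20–50-gene matrices for Mutual-Rank oracle
comparisons (100 trials), all populations N ≤ 30 for exhaustive
hypergeometric enumeration, 200 permutations for the enrichment null,
and 300 trials for qPCR concordance simulation — sizes at which the
planted effects are neither trivial nor marginal and every oracle can
be exhaustive or near-exhaustive. The pipeline itself is O(n²) in genes
only in the PCC/MR step and comfortably handles tens of thousands of
genes.

Known limitations: the module-extraction step is a stand-in for an
undocumented original algorithm; Figure-style per-stage up/down counts
depend on an unspecified baseline convention and are therefore
configurable; the hypergeometric test is upper-tail only (no
depletion); GO terms are flat sets with no DAG propagation; coverage
uses a single HSP. These are deliberate scope edges, not oversights.
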