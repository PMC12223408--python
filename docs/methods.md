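# Methods

`bogforam` implements the desk half of a low-diversity 18S rRNA amplicon
survey of freshwater foraminifera: calling OTUs from merged reads,
curating the OTU-by-sample count table, and analysing the resulting
communities with phylogeny-aware statistics. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## The curation cascade

Raw OTU tables from environmental amplicon runs mix signal with several
artifact classes; the cascade in `bogforam.curation` addresses them in a
fixed order, and every removal or zeroing is logged in a replayable
`CurationReport`.

1. **Unrarefied filtering to a fixpoint.** Samples with fewer than
   `min_sample_reads` (default 500) total reads are treated as failed
   libraries; OTUs with fewer than `min_otu_reads` (default 100) total
   reads or present in fewer than `min_otu_occurrence` (default 2)
   samples are treated as irreproducible noise. Because removing OTUs can
   push further samples under the floor (and vice versa), passes repeat
   until nothing changes. The output provably satisfies all three
   thresholds simultaneously, and the filter is idempotent.
2. **Flagged removals.** Contaminant OTUs and samples identified outside
   the pipeline (phylogenetic placement near marine lineages, BLAST) are
   supplied as ID lists, never inferred; unknown IDs are logged as no-ops.
3. **Re-check.** A full fixpoint pass re-establishes the unrarefied
   thresholds after the flagged removals.
4. **Rarefaction.** Each sample with more than `rarefaction_depth`
   (default 10,000) reads is drawn down to exactly that depth *without
   replacement* (multivariate hypergeometric); shallower samples keep all
   their reads. Each sample gets an independent generator sub-seeded from
   the master seed and a CRC-32 of the sample ID, so results are
   reproducible and independent of column order.
5. **Index-switching correction.** Multiplexed sequencing misassigns a
   small fraction of reads between samples ("tag jumping"), producing
   spurious low-count cells. Row totals are computed once on the rarefied
   table; rows above `big_otu_total` (default 1000) reads have occupied
   cells below `big_otu_cell_floor` (default 20) zeroed, remaining rows
   have cells at `small_otu_cell_floor` (default 1) zeroed. A row totalling
   exactly 1000 falls under the conservative second rule. The rationale:
   an abundant OTU sheds enough stray reads to seed multi-read ghost
   cells, a rare OTU only single-read ones.
6. **Final filter.** OTUs must end with strictly more than
   `final_min_otu_reads` (default 20) rarefied reads.

The 500-read sample floor applies to unrarefied counts only: a sample
whose total falls below it merely through rarefaction or zeroing is
retained (a ~700-read library that passed the failure check is a valid,
if shallow, observation).

## OTU calling

The calling stage is deliberately simple and fully deterministic:
dereplication (counts aggregated per sample; ties broken lexicographically),
then single-linkage seed-growth clustering at Levenshtein radius `d = 1`
— the most abundant unassigned sequence seeds a cluster and the frontier
absorbs any unassigned sequence within distance `d` of any member, so
mutation chains A–B–C merge even when the endpoints are far apart. The
result equals the connected components of the distance-≤d graph with
abundance-maximal seeds, which is what the test oracle checks.

Three filters follow. Single-read OTUs are dropped. A two-parent
breakpoint test flags chimeras: a seed is chimeric if two clusters at
least twice as abundant explain it as a prefix of one and a suffix of the
other at ≥99% identity per segment (each segment ≥20% of the length),
while neither parent alone matches at ≥99% over the full length. Segment
comparison is positional (ungapped) when lengths agree, as
template-switching chimeras preserve position; the gapped global identity
is the fallback. Finally, seeds less than 65% globally identical to the
most abundant seed are removed as off-target amplicons; the boundary is
strict (0.65 is kept).

Global identity is matches / alignment columns (gap columns included) in
a global alignment scored match +1, mismatch 0, gap −1. Among co-optimal
alignments the one with the most matches defines the value — this makes
the identity deterministic and equal to the maximum identity achievable
at optimal score. It is computed by a single max-plus dynamic program over
a packed (score, matches) objective, validated against exhaustive
alignment enumeration on short strings. Plain edit distances are computed
with `edlib`.

## Community analysis

**Weighted UniFrac** between samples A and B is
`Σ_i b_i |p_i(A) − p_i(B)|` over branches `i`, with `b_i` the branch
length and `p_i(X)` the fraction of X's reads on leaves below the branch;
the normalized variant (default) divides by `Σ_i b_i (p_i(A) + p_i(B))`,
bounding values to [0, 1]. The implementation accumulates per-branch
profiles in one postorder pass. Tree leaves absent from the table carry
zero weight everywhere, so "pruning extra leaves" is a mathematical
no-op; table OTUs missing from the tree are an error, never silently
dropped. Raw weighted UniFrac is a metric and is invariant to scaling any
sample's counts by a positive constant; both properties are asserted in
tests, and the values are cross-checked against scikit-bio.

**PCoA** is classical scaling: Gower double-centering of −½ d²,
symmetric eigendecomposition, coordinates = eigenvectors ×
√eigenvalue. Because UniFrac matrices need not be Euclidean, negative
eigenvalues can occur; they are reported but excluded from the
coordinates and from the percent-variance denominator (no
Cailliez/Lingoes correction). Axis signs are fixed by making the
largest-magnitude loading positive, so runs are bit-reproducible.

**Abundance classes** follow read-share cutoffs per sample: a nonzero
presence is *rare* below 25%, *intermediate* from 25% to 75% inclusive,
and *dominant* above 75%. The endpoints are assigned to the middle class,
matching the strict "less than"/"more than" wording of the outer classes.

**Occupancy.** Detection is ≥1 read after full curation. An OTU seen in
exactly one location is *specific*, otherwise *shared*; per-location OTU
richness is reported alongside.

## The synthetic-community generator

`simulate_dataset` emulates the statistical structure of the motivating
survey design — it is the test bed for every downstream stage, with a
ground-truth ledger (`SimTruth`) recording exactly what was injected.

- **Scale:** 34 samples across 4 locations (three field-like, one
  greenhouse-like), 60 freshwater + 6 marine-contaminant OTUs.
- **Abundances:** log-normal with σ = 2.5, chosen so the median top-OTU
  share across seeds is ≈ one third of all reads — the dominance regime
  the pipeline is designed for — while staying within 10–60% in ≥ 80% of
  seeds.
- **Habitat structure:** 80% of freshwater OTUs are restricted to a
  single location (reads structurally zero elsewhere); assignment is
  round-robin so every location receives specific OTUs.
- **Depths:** log-uniform over 10^2.85–10^5.47 (≈708–295,000 reads),
  spanning three orders of magnitude so rarefaction does real work; a
  12% fraction of failed libraries is drawn uniformly on [50, 499] reads
  so the 500-read floor is exercised on both sides.
- **Contaminants:** each marine OTU is seeded into a random subset of
  samples, emulating cross-study lab contamination.
- **Index switching:** each read independently moves to a uniformly
  random *other* sample with probability `switch_rate`, and every
  transfer is recorded. The uniform-destination model is intentionally
  simple; real index hopping lands reads roughly in proportion to library
  size, so a uniform model over-delivers strays to small libraries. The
  default rate of 2 × 10⁻⁵ is calibrated to give small libraries the same
  expected stray load (well under one read) as proportional hopping at
  the ~0.1% rates reported for Illumina platforms. Reads are conserved
  exactly: clean table + recorded moves = corrupted table.
- **Sequences:** a random root sequence evolves down a random-join tree
  under a single-rate, equal-frequency substitution model
  (p_change = ¾(1 − e^(−4/3·r·t))); branch lengths are exponential with
  mean 0.02 substitutions/site, keeping pairwise divergence in the 5–30%
  band typical within a clade-level 18S survey (and safely beyond the
  d = 1 clustering radius). Chimeras are prefix+suffix joins of two leaf
  sequences with the breakpoint in the middle 60%.

**What passing tests do and do not show.** The generator has no
quality-score errors, no PCR point errors, no indel variation within an
OTU, no chimeras of more than two parents, and its switching model is
uniform rather than depth-proportional. Tests on it demonstrate that the
algorithms implement their definitions and recover exactly the injected
artifact classes; they do not certify performance on real libraries,
where dereplication noise and model misspecification add failure modes
this pipeline does not attempt to model.

## Problem sizes and determinism

All simulations used in the test suite and the acceptance script run at
the survey's own scale (≤ ~70 OTUs, ~34 samples, ≤ ~300k reads/sample) or
smaller; oracle comparisons use instances small enough for brute force
(≤50 sequences, ≤10 leaves, ≤6 samples). Every stochastic component is
driven by an explicit seed: `SimConfig.seed` fixes the generator,
`rarefy` sub-seeds per sample, and the pipeline driver derives per-stage
seeds from one master seed, so identical configurations yield
byte-identical artifacts.

## Known limitations

- The chimera test assumes two parents and positional segment alignment;
  heavily gapped chimeras would need an alignment-based breakpoint scan.
- The 65% divergence filter compares full sequences; amplicons that are
  genuine short fragments of the target region would need a
  fragment-aware identity before this filter is applied to them.
- PCoA reports negative eigenvalues but offers no correction; strongly
  non-Euclidean distance matrices shift percent-variance values between
  the normalized and raw UniFrac variants.
- `occupancy_summary` treats a single post-curation read as a detection;
  with deeper sequencing a prevalence threshold may be preferable.
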