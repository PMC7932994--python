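# Methods

## Data model

A repertoire is a clones × samples matrix of unique-UMI counts. Clone
identity is the CDR3 amino-acid sequence alone: reads whose CDR3
nucleotide sequences differ but translate identically belong to one
clone. A configuration flag (`key_includes_vj` in read processing,
`use_vj` on `CloneKey.identity`) adds the V/J calls to the identity for
users who prefer the stricter convention; the default follows the
amino-acid clustering rule because identical CDR3s with different V genes
cannot be distinguished reliably on short amplicons. Clonal frequencies
are always computed from unique-UMI counts, never read counts, since UMI
counting removes PCR amplification bias. Library size is defined as the
exact column sum, so frequencies per sample always total 1.

## Read processing

* **Pair merging.** Best ungapped 3′ overlap of the pair (R2
  reverse-complemented), scored as matches − mismatches over every
  overlap length ≥ `min_overlap` (default 30 nt), accepted when the
  mismatch fraction is ≤ `max_mismatch_frac` (default 0.1). Disagreeing
  bases resolve to the higher-Phred base and the merged quality is the
  elementwise maximum. An unmergeable pair is a *result* (dropped and
  counted in the attrition report), not an error. A full dynamic-programming
  assembler is unnecessary at amplicon scale, where the true overlap is
  long and indel-free.
* **Demultiplexing.** The leading 8-nt MID is matched against the sample
  table allowing `max_mid_mismatch` (default 1) mismatches; the table is
  rejected up front unless MIDs are mutually ≥ 2·max+1 apart, which makes
  every rescue unique. Unassignable reads go to an `undetermined` bin.
* **V/J assignment.** Each reference segment is aligned semi-globally to
  the read (reference end-to-end, free read overhangs) with match +1,
  mismatch −1, gap open −2, extend −1, via Biopython's PairwiseAligner.
  The best-scoring V and J are accepted when the score reaches
  `min_score_frac` (default 0.6) of the reference length — random 300-mers
  essentially never reach this — and the conserved anchor codon (V Cys,
  J Phe/Trp) is mapped through the alignment onto read coordinates.
  Alignments are cached per distinct read sequence, so PCR duplicates are
  free.
* **CDR3 extraction.** Default convention is the IMGT junction: V-anchor
  Cys codon through J-anchor codon inclusive; a flag switches to
  anchor-exclusive. A read is rejected when the anchors are out of order,
  the interval is not a codon multiple, any base in it has Phred < 30
  (`min_phred`), or the translation contains a stop.
* **UMI counting.** Within a sample, a UMI observed with two different
  clones is a collision; it is awarded to the clone with more reads, ties
  to the lexicographically smaller CDR3, and logged. This policy is a
  package choice — published pipelines rarely document theirs — and is
  deterministic. Optional single-linkage collapse of UMIs within Hamming
  distance 1 (off by default) absorbs sequencing errors in the UMI itself;
  with a 0.1% per-base substitution rate and collapse enabled, recovered
  totals stay within 2% of truth on the bundled simulation.
* Coordinates are 0-based half-open internally; only exported
  human-readable reports are 1-based.

## Size distribution

Each library is downsized to a common depth by multivariate
hypergeometric sampling (without replacement; upsampling refuses). The
default depth of 25,000 UMIs makes a singleton clone a clonal frequency
of 0.004%. Classes partition observed clones: **rare** is structural
(count == 1) so the same specification works at any depth; **small** is
below 0.1%; **medium** is 0.1% ≤ c.f. < 0.5% (left-closed); **large** is
c.f. ≥ 0.5%. Class fractions are UMI-mass fractions (share of the
repertoire occupied), not clone-number fractions, and sum to 1 per
sample. Timepoint comparisons use fixed-effects ANOVA on the raw
fractions (untransformed — the replicate SDs here are small relative to
the means, so a variance-stabilizing transform would not change
conclusions) with pairwise t-tests Bonferroni-multiplied by the number of
pairs and capped at 1. Degenerate inputs follow explicit rules: no
between-group signal gives F = 0, p = 1; signal with zero within-group
variance gives an undefined p and a flag.

## Trajectory clustering

Clones enter the clustering when nonzero in at least `min_replicates`
(default 2) of a timepoint's replicates at **one or more** timepoints
(`mode="any"`). The phrase "present at each time point" is genuinely
ambiguous; requiring presence at *every* timepoint (`mode="every"`,
provided) would exclude genuine expanders absent before stimulation, so
the permissive reading is the default and the decision is logged.
Counts are averaged over replicates per timepoint and each clone's
trajectory is Z-scored (ddof = 1). The feature vector is the full
autoscaled trajectory; under Z-scoring this differs from "changes from
day 0" only by a per-clone constant, which cancels in squared Euclidean
distances up to a shared offset. Constant trajectories cannot be scaled
and become zero rows (with a warning) rather than being dropped, keeping
cluster membership a partition of the filtered set.

k-means uses Lloyd iterations with `restarts` (default 25) random
initializations, deterministic given the seed, k defaulting to 10 with
the elbow curve reported. The elbow SSE curve is made non-increasing in k
by construction: each k's restart pool is augmented with a warm start
built from the previous best centroids plus the farthest data point,
whose assignment step already attains an SSE no larger than the previous
optimum. The suggested k maximizes perpendicular distance to the chord
joining the curve's endpoints; it is a suggestion only and the configured
k always wins. Cluster impact at a timepoint is the summed
replicate-averaged frequency of the member clones, ×100.

## Differential expansion

The two-group contrast follows the replicated count-model workflow
standard in expression analysis, implemented here in full:

1. **TMM normalization.** Reference sample = the one whose 75th-percentile
   scaled count is closest to the mean of those. Per sample, log2
   abundance ratios (M) and average abundances (A) against the reference
   are computed over doubly-nonzero clones, the extreme 30% of M and 5% of
   A are trimmed by rank, and the factor is 2^(precision-weighted mean of
   the surviving M), with delta-method weights; factors are rescaled to
   geometric mean 1. Fewer than two usable clones gives factor 1 with a
   warning. The implementation agrees with the Bioconductor reference to
   ~1e-8 on shared fixtures.
2. **Quantile adjustment.** Counts are mapped to a common effective
   library size (geometric mean) by matched NB quantiles, approximated as
   the average of a tail-matched normal and gamma map; non-finite gamma
   values fall back to the (linear) normal map and results are clipped at
   zero.
3. **Dispersion.** The common dispersion φ maximizes the conditional
   log-likelihood given per-group totals, summed over clones, on
   φ ∈ [1e-6, 10] (bounded scalar optimization on log φ, with the
   quantile adjustment re-done at the updated φ twice). A flat likelihood
   (e.g. no overdispersion information) returns the lower bound with a
   warning; absent replication is an error directing the user to set φ
   manually. Tagwise values maximize each clone's conditional
   log-likelihood plus `prior_weight` (default 10) times the average
   per-clone log-likelihood, evaluated on an 81-point log grid that always
   contains the common estimate — so infinite prior weight recovers the
   common value exactly and zero prior weight the per-clone ML.
4. **Exact test.** Group sums of the adjusted counts (rounded to
   integers) are conditioned on their total; the conditional law is
   beta-binomial with sizes n_A/φ and n_B/φ, binomial(n_A/(n_A+n_B)) in
   the φ→0 limit. The two-sided p sums the probabilities of all
   partitions no more probable than the observed one, with the customary
   1+1e-7 relative tie tolerance, capped at 1. This is the "small-p"
   two-sided convention — identical to the exact binomial two-sided test
   in the Poisson limit (verified to < 1e-10 for every total ≤ 200) and to
   the reference implementation's small-p variant (< 1e-6 on shared
   fixtures). Exact summation is affordable because totals at repertoire
   depth are bounded.
5. **Multiplicity and labels.** BH step-up within each contrast
   separately (day 0 vs 3, vs 5, vs 10 are separate families). Labels use
   strict inequalities exactly as stated: over if log2FC > log2 1.5 and
   adjusted p < 0.05, under if log2FC < −log2 1.5 and adjusted p < 0.05,
   else not-differential; the "fold change below −1.5" phrasing is read as
   the standard signed-fold-change convention (ratio < 1/1.5). Clones
   absent from a contrast's universe are Not Detected (ND). Fold changes
   are computed on TMM-normalized abundances with a prior count of 0.5
   per group so low-abundance clones get finite values; the reported
   abundance axis is log2 UCPM (UMI counts per million).
6. **Reporting.** Cross-tables between an expansion and a representation
   contrast are 4×4 (over/not/under/ND each axis) with integer row
   percentages rounded half away from zero; condition overlaps are
   exclusive Venn-region counts.

No independent low-count filter is applied before testing: the clone
universe of a contrast is every clone with ≥ 1 UMI in either group.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at the study's conditions: ~10³–10⁵ clones with heavy-tailed baseline
frequencies (lognormal(0, 1) weights by default; Pareto available), four
timepoints (days 0/3/5/10) × 3 replicates, 25,000 expected UMIs per
library, a 5% responder minority following named archetypes
(transient-early/mid, late-expander ×32, early-plus-late ×16, decliner),
NB replicate noise with dispersion φ = 0.05, and a sorted fraction in
which activated clones (80% of expanders) are enriched 20-fold in odds.
Expected frequencies at each timepoint are baseline × archetype
multiplier, renormalized; replicate counts are NB with mean depth ×
frequency (multinomial of exact size `depth` when φ = 0). Read emission
lays the amplicon out as 8-nt MID + 9-nt UMI + V–CDR3–J template, with
the CDR3 reverse-translated through a fixed codon table (lexicographically
smallest codon per amino acid) so emission is deterministic; per-UMI
duplication, substitution errors and Phred strings are configurable. UMIs
are drawn unique within a sample by default so the zero-error round trip
is exact.

What the generator does **not** emulate — and what passing tests
therefore cannot certify about real data: primer sequence biases and
V-gene amplification efficiency differences, indels and chimeric reads,
UMI collisions across molecules of the same clone at saturating depth,
carrier-RNA effects, cross-sample index hopping, and any deviation of
real replicate noise from the NB family. Results on real repertoires
additionally depend on the upstream aligner's reference completeness,
which the bundled toy V/J panel does not represent.

## Problem sizes and determinism

Defaults were chosen so the full test suite and the acceptance script
each complete in a few minutes on one CPU: stochastic properties
(calibration, recovery, dispersion) average 20 seeds of 2,000-clone
repertoires at depth 25,000; the read round-trip uses a 40-clone,
4-sample repertoire with duplication up to 4. Every stochastic routine
takes an explicit seed or `numpy` Generator and is bit-reproducible given
it; the CLI `run` records config hash, seed and package version in a
manifest and skips stages whose inputs are unchanged.

## Known limitations

* β-chain only; no D-gene calling, allele-level genotyping or paired-chain
  handling; no nucleotide-level clonotype model.
* The exact test covers a single two-group contrast; multi-factor designs
  would need a GLM/quasi-likelihood route that is out of scope.
* TMM assumes most clones are non-differential between samples; a culture
  in which expanders dominate the library violates this and normalization
  then absorbs part of the composition shift (visible as a shared offset
  in fold changes, not as sign errors at the 1.5-fold gate in the bundled
  conditions).
* The elbow suggestion is a geometric heuristic; for curves whose first
  drop dominates it can indicate a smaller k than the generative number of
  profiles.
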