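# Methods

This note documents the models, defaults and numerical conventions behind
`crossonc`, and what the synthetic-data tests do and do not establish.

## Data model

All copy-number arithmetic happens on a shared grid of fixed-width genomic
bins (default 50 kb, the working resolution of shallow CNV-seq), 0-based
half-open internally; SEG files are read and written in the conventional
1-based inclusive dialect, BED in 0-based half-open. Each chromosome of
length L contributes ceil(L / bin_size) bins, the last truncated at L. A
sample is a vector of per-bin log2 ratios (`raw`), a piecewise-constant
`segmented` layer, and optional five-level calls; NaN marks missing bins
throughout.

## Segmentation

`segment_profile` performs greedy recursive binary splitting per chromosome:
the split maximizing the residual-sum-of-squares reduction is accepted iff
the reduction exceeds `penalty * log(n)`, with n the chromosome's
non-missing bin count. The default penalty is twice the noise variance
estimated from the median absolute successive difference
(sigma = median|diff| / 0.9539, exact for i.i.d. Gaussian noise and robust
to sparse true breakpoints). Missing bins are compacted out before fitting
and stay missing.

**Known limitation.** Greedy binary splitting detects step-like changes
reliably (a 1.5-amplitude step in noise sd 0.2 localizes within ±2 bins in
≥95% of runs) but cannot detect short *interior* focal events: carving a
3-bin amplitude-1.0 bump out of 1000 bins requires two breakpoints, and the
best *single* split yields an SSE reduction of only ~0.035, far below the
acceptance threshold (~0.55 at these defaults), so the first split is
rejected and recursion never starts. The pipeline therefore expects focal
analyses to run on externally segmented input (QDNAseq-style upstream
output), which `segment_profile` passes through untouched; the synthetic
generator plays that upstream role by supplying the true segment structure
as the segmented layer. A two-breakpoint (circular) search would lift this
limitation and is a natural extension.

## Gene-level copy number and imputation

A gene's value per sample is the overlap-length-weighted mean of its
non-missing segmented bins. If every overlapping bin is missing, the value
is imputed as the plain mean of non-missing segmented values in a window of
11 bins centered on the bin containing the gene's midpoint (clipped at
chromosome ends), and remains missing when the window holds fewer than 5
values. Window semantics are in bins and centered on the midpoint bin;
imputation reads the segmented (not raw) layer. Genes on chromosomes absent
from the grid are reported missing and logged rather than erroring, so one
annotation file can serve multiple genome builds.

## Instability score

Fraction of non-missing bins whose segmented value strictly exceeds
+t or falls strictly below −t (default t = 0.5 log2 units). Both
conventions that the definition leaves open are resolved explicitly: exact
threshold values do not count, and missing bins are excluded from the
denominator. The score is invariant under bin permutation and global sign
flip, which the property tests exercise.

## Recurrent-region calling

The caller replaces a published recurrence tool while keeping its parameter
surface (focal threshold, min probes, FDR), so settings from real analyses
carry over:

1. **Aggregate score** per bin: sum over samples of the positive part of
   the segmented value (amplifications) or of its negation (deletions);
   missing contributes 0.
2. **Null model**: each permutation rotates every sample's bins cyclically
   within each chromosome by an independent uniform offset. Rotation
   preserves within-sample segment lengths and amplitudes — the burden and
   autocorrelation structure — while destroying cross-sample positional
   alignment, which is precisely the recurrence signal under test.
3. **Empirical p-values**: under rotation all bins of a chromosome share
   the same marginal null, so the null aggregates are pooled within
   chromosome; p_b = (1 + #{pooled null ≥ observed_b}) / (1 + pool size).
   Pooling gives p-value resolution of order 1/(n_permutations × bins per
   chromosome) at desk-scale permutation counts.
4. **FDR control**: Benjamini–Hochberg step-up across all bins at the
   requested level (default 0.25); ties share ranks through the standard
   step-up formulation. Bin scores are positively dependent within
   segments, a regime where BH is conservative in expectation; the
   acceptance suite verifies the empirical false proportion on 200
   driver-free cohorts.
5. **Regions**: maximal runs of adjacent significant bins; runs with fewer
   than `min_probes` bins are dropped; regions wider than
   `focal_threshold` bp are kept but flagged broad. Genes overlapping a
   region by ≥1 bp are annotated as residing in it.

Amplifications and deletions are called in independent passes with
independent seeds. A region minimum of `min_probes = 4` necessarily
excludes any event confined to 3 or fewer bins; callers targeting such
events must lower it (the test suite demonstrates both regimes).

## Cross-species intersection

Ortholog maps are two-column tables with a homology type; the default
policy keeps one2one pairs only (one2many retained on request, with all
partners). Conflicting one2one claims abort with row numbers rather than
silently resolving. A candidate requires same-direction recurrence in both
species — amplification peaks intersect amplification peaks.

## Expression normalization and the correlation filter

Median-of-ratios: the per-gene reference is the geometric mean across
samples over genes with no zero count; size factors are per-sample medians
of count/reference; the normalized layer is log2(count/size_factor + 1)
(pseudocount 1 chosen for integer counts). Note the estimator is
scale-relative: multiplying *every* sample by c leaves all size factors
unchanged (the normalized layer then scales), while multiplying *one*
sample by c scales its factor by exactly c^((m−1)/m) on an all-positive
matrix — the closed form the tests assert.

Spearman's rho is the Pearson correlation of average ranks (ties get mean
rank), computed on pairwise-complete observations, undefined (NaN, flagged)
below 3 pairs or for constant vectors. The filter passes a candidate iff
rho > 0.2 strictly (`positive` mode, default: amplified drivers should gain
expression with dosage) or |rho| > 0.2 (`absolute` mode, kept because both
conventions appear in practice); candidates with missing data fail with a
flag rather than disappearing.

## Mutation-landscape meta-analysis

Variant classification strings are case/punctuation-normalized before
matching. Deleterious = {missense, nonsense, frameshift del, frameshift
ins}; extreme CNA = calls ±2. BRCA1 deficiency: homozygous deletion, a
truncating mutation, or a missense annotated pathogenic (BIC
clinically-important, or Align-GVGD class C15/C25/C65); unannotated
missense variants are excluded and logged, never guessed. Missense counts
as deleterious in the landscape at large; the stricter pathogenicity rule
applies only to cohort selection — a deliberate two-tier reading.
Triple-negative status requires ER, PR and HER2 all negative; any missing
receptor yields "undetermined". Duplicate (sample, gene, event) rows across
source datasets are deduplicated with a configurable source-priority order.

## Synthetic cohorts: what they emulate

Each sample's true profile is baseline 0 plus Poisson-many passenger
segments (log-normal lengths, median ~2 Mb; absolute amplitude ~N(0.6,
0.2²) truncated at 0, sign ±; defaults chosen to mimic moderately unstable
shallow-WGS tumor profiles) plus planted drivers; observed raw bins add
i.i.d. Gaussian noise (default sd 0.2 log2 units, typical of ~50-kb
shallow-coverage bins). Passengers may overlap drivers and values add, so
the caller must tolerate compound segments. Driver penetrance is realized
*exactly*: round(p × n) carriers chosen by seeded shuffle, making recovery
tests deterministic rather than binomially fuzzy. Expression counts are
negative binomial with mean base × 2^(beta × copy number) and dispersion
alpha (variance m + alpha·m²; alpha → 0 falls back to Poisson); beta can be
set per gene to plant dosage-decoupled decoys. The default desk-scale
genome is 3 chromosomes × 50 Mb at 50-kb bins.

Not emulated: read-level data, GC/mappability bias, subclonality,
whole-genome doubling, purity/ploidy shifts, and recurrent breakpoint reuse.
A green synthetic test therefore establishes the statistical machinery
(scores, null calibration, intersection and filtering logic) on idealized
segmental data — not robustness to platform artifacts.

## Determinism

Every stochastic component takes an explicit integer seed. The pipeline
expands its global seed into per-stage child seeds by hashing
(seed, stage-name) with SHA-256 and taking the first 4 bytes mod 2³¹, so
any stage can be rerun in isolation with the stream it had in the full run.
Run manifests record config, per-stage record counts and wall-clock, and
SHA-256 checksums of every output file; reruns with identical config and
seed are byte-identical.
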