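# Methods

This note documents the models, estimators, defaults, and numerical choices
behind the package, and what the synthetic-data validation does and does
not establish.

## Region-level methylation

Per-CpG input is the tab-separated coverage dialect (1-based inclusive
positions; methylated and unmethylated read counts).  Sites below the
coverage floor (default 3×) are discarded on read; the tissue-of-origin
path keeps 1× sites, since marker aggregation restores precision.  Regions
are half-open 0-based intervals; genome-wide tiles default to 3 kb with
step = size (non-overlapping), with a configurable smaller step for sliding
windows.  The level of a region is the *pooled* proportion
Σ meth / Σ (meth + unmeth), i.e. the coverage-weighted mean of per-site
proportions — the minimum-variance choice under binomial sampling, and the
reading we adopt for a "weighted mean" of CpGs.  Opposite-strand CpG
records are kept separate by default (`merge_strand_calls` collapses dyads
when symmetric methylation can be assumed).  Promoter regions are ±1 kb
around each TSS, clipped at contig boundaries; strand is recorded but does
not change the symmetric interval.

## Differential methylation

Replicates are pooled within group per region and each region is tested
with a two-sided Fisher's exact test on the 2×2 pooled-count table
(chi-square with continuity correction available for very large counts).
Pooling mirrors small-cohort practice for count-based DMR callers; a
per-sample overdispersion-aware test is deliberately not implemented and
is the main known limitation — biological replicate variance beyond
binomial is attributed to signal.  Multiplicity is controlled with
Benjamini–Hochberg (missing tests propagate and do not count toward m).
DMR calls require q < 0.01 and a methylation difference **strictly above**
0.15 for genome-wide windows, and **at least** 0.12 for the promoter
preset — the two cutoffs deliberately differ in strictness to match their
respective conventions.  Direction is reported as hyper/hypo in group 1.

## Copy number

Fragments are assigned to 100-kb bins by midpoint (unambiguous for
boundary-spanning fragments).  All normal samples are pooled into a single
panel of normals; its per-bin proportions are the copy-neutral
expectation, and per-normal log2 ratios against the pool give a per-bin
dispersion track.  A sample's copy ratio is
log2((count/total) / proportion), with a 0.5-read pseudocount for
zero-count sample bins (keeps the track dense for the classifier) and
missing values only where the panel itself is empty.  Ratios are invariant
to library size by construction.  Segmentation is recursive binary
splitting on the pooled two-sample t statistic of mean ratio, stopping
when the best split's |t| falls below 5.0 (comfortably above the null
maximum over split points at the bin counts used here, ~3.5–4 for 10³
bins) or a part would drop below 10 bins; segments are called gain/loss
beyond ±0.15 in mean log2 ratio.  The expected ratio of a planted segment
is log2(w/ w̄) with per-bin weight w = 1 + tf·(copy/2 − 1) and w̄ the
genome-mean weight — total-count normalization pulls long alterations
slightly toward zero, which the recovery checks account for.  No GC
correction is applied by default (linear amplification shows little GC
bias); a stratified-median correction is available when per-bin GC is
supplied.  The sample-level rule for declaring a specimen "CNA-positive"
is left to the caller; the package exposes segment calls.

## Deconvolution

Cell-type proportions are estimated by least squares constrained to the
probability simplex, solved as non-negative least squares on a system
augmented with a heavily weighted (100×) sum-to-one row, then
renormalized.  This replaces support-vector-regression-style deconvolution
deliberately: it is deterministic, hyperparameter-free, identical in the
noise-free limit, and checkable against a grid-search oracle (tests verify
1e-3 agreement at 1e-4 grid resolution).  Mega sites are built by
hierarchical clustering of reference sites on their cell-type profiles —
Euclidean distance, complete linkage by default (both configurable; the
method only requires *a* dendrogram cut) — cut into k = 32 groups with
singletons removed; the aggregated reference value is the unweighted mean
of member sites, while sample vectors pool reads over members, so
aggregation commutes with pooling.  Missing mega sites are imputed by
k-nearest-feature regression (k = 10, the convention of the standard
implementation): each missing entry takes the mean of the sample's values
at the k nearest features, with a per-sample mean fallback for features
observed nowhere.  Group comparisons use the two-sided Wilcoxon rank-sum
test (exact for groups ≤ 25 without ties, tie-corrected normal
approximation otherwise) or Welch's t-test.

## Classification

Feature blocks: region/TSS betas, per-bin log2 copy ratios, and inferred
cell proportions with one cell type dropped (compositions are collinear;
the synthetic cohorts drop the NK column, the smallest contributor).  The
cohort is split 1:3 train:test, stratified.  Each wide block is centred
and scaled (sample SD, ddof = 1; zero-variance features get scale 1) and
PCA-reduced to the minimal component prefix reaching 95% cumulative
explained variance; every statistic comes from training samples only, and
a test asserts this by recomputation.  Component signs are fixed
(largest-magnitude loading positive) for reproducibility.  Classifiers:
random forest (300 trees; max_features tuned) and radial-kernel SVM (C
tuned), selected by stratified 5-fold CV maximizing AUC and refitted on
the full training set.  AUC is the normalized Mann–Whitney U with midrank
ties; ROC points are emitted at every distinct score threshold.  Feature
importance is permutation-based (mean AUC drop over column shuffles) so
forest and SVM rankings are comparable.

## Synthetic cohorts

The generator is the package's study design, not a tuning surface.  A
sample is a mixture over cell types: healthy compositions are Dirichlet
draws dominated by neutrophils (the major cfDNA contributor), cases draw a
tumor fraction uniform on [0.05, 0.4] that displaces an equal share of the
normal mix — the ctDNA dilution model — plus a fixed Dirichlet shift of
immune types (CD4 T up, monocytes down).  Default cohort size is 50 cases
vs 34 controls; the balanced classifier cohorts use 42 vs 42.  Coverage is
Poisson (mean 30×; optional gamma-Poisson overdispersion), each read's
source type is categorical in the sample's proportions, methylation is
Bernoulli in the source type's probability, and two symmetric error rates
model bisulfite failure (unmethylated → methylated, 1%) and overconversion
(methylated → unmethylated, 1%) — chosen to match the ~0.8–1% non-CpG
methylation readouts typical of real libraries.  Because a mixture of
Bernoullis is Bernoulli in the mixed probability, counts are drawn
binomially at the error-adjusted mixed probability — exactly the read-level
model, vectorized.  Planted DMRs shift only the tumor component (clipped to
[0,1], so hypermethylation of already-high baselines attenuates); planted
CNAs scale each case's bin weights by its own tumor fraction; bin counts
are multinomial, so totals are exact.  Reference atlases guarantee a
marker margin by construction (flagged type at least `margin` away from
the shared value of all other types) over a bimodal baseline methylome.
Amplification: linear mode gives each molecule 1 + Poisson(mean − 1)
copies; exponential mode gives log-normal copies (jitter = per-cycle
efficiency spread), whose heavier tail raises read-level duplication at
matched depth.

What the synthetic data does **not** emulate: fragment-length biology,
alignment and mapping artifacts, real marker atlases (the reference
matrices are constructed, not curated), locus-specific coverage biases,
and inter-individual baseline variation beyond composition.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not clinical performance on real plasma.

## Problem sizes and determinism

Validation runs use desk-scale sizes chosen so the full suite completes in
minutes while keeping every per-site/per-bin quantity (coverage, bin
counts, marker counts) at realistic magnitudes: two-contig megabase
genomes, 10³ bins of 100 kb at 10⁶ reads, 26 mega-site features over 6
cell types, 200-region DMR cohorts at 5v5 and 30×, 20 replicate
classifier cohorts of 84 samples.  All randomness flows from explicit
seeds (per-sample seeds are spawned from the cohort seed; the CLI fans one
global seed out per stage via a CRC32 offset), and cohort serialization is
bit-reproducible.  Degenerate inputs have defined behaviour throughout:
empty call files parse to empty tables, regions without covered sites are
missing rather than zero, all-tied group comparisons return p = 1,
zero-variance features standardize to zeros, and rank-deficient reference
matrices warn but still return the constrained solution.
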