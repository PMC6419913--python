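# Methods

## Data model and on-disk layout

A cohort lives in a single chunked HDF5 file, probe-major: assays
`methylated`, `unmethylated`, `betas` and (optional) `detection_p` are
float64 arrays of shape (P probes x S samples) under `/assays`, with
probe and sample tables stored as CSV text datasets (`/probes`,
`/samples`), control-probe intensities as a (C x S x 2) array under
`/controls` (channels green, red) with their own probe table, and an
append-only JSON-lines history under `/history` (format version 1).
Probes are fixed at creation from the manifest; every append grows the
sample axis only and never reorders probes, so previously written
columns are bit-identical afterwards.  Missing values are NaN
throughout and all downstream statistics are NaN-aware.

The memory contract is explicit: a `ChunkSpec` carries the HDF5 chunk
rectangle and `max_block_elements`, the largest dense block any
operation may hold (default 2^24 elements ~ 128 MB of float64;
`rows_per_chunk * cols_per_chunk <= max_block_elements` is enforced).
Column-streaming operations use blocks of the full probe axis by
`max_block_elements // P` samples; row-streaming operations the
transpose.  Every materialization funnels through a thread-local
monitor that records the peak and, when armed (as in the tests and the
acceptance script), raises on violation.  The contract bounds each
dense block, not the process RSS: a streaming step may briefly hold a
small number of blocks (e.g. M, U and the beta output) at once.

Beta values are M/(M+U+alpha) with alpha = 100 by default; alpha
damps low-intensity probes toward 0.  Negative or missing intensities
yield NaN betas, counted in a warning.  Signal input is a probe-major
TSV pair for M and U (a text stand-in for vendor binary files, whose
parsing is out of scope) plus a long-format control TSV; floats are
parsed in round-trip precision so export -> import is exact.

## Quantile normalization

Pass 1 sorts each sample column (within a row group, if grouping is
requested) and averages the sorted vectors across samples into the
reference.  Pass 2 replaces each value by the reference value at its
within-column rank.  Ties receive the mean of the reference values at
the tied sort positions — the classic dense tie rule — so for complete
columns the streamed result equals the in-memory algorithm exactly;
the test suite asserts agreement with an independently coded dense
oracle to 1e-10 across chunk geometries up to 5000 x 100.

Columns with missing values have no exact classical counterpart; the
choice here is interpolation: in pass 1 a column's v sorted valid
values are interpolated onto the group-length quantile grid before
averaging, and in pass 2 the (tie-averaged) fractional rank of each
valid value is interpolated into the reference.  NaNs stay NaN.  This
is the established convention when valid counts differ per column, but
it is a convention — other implementations truncate instead, and
results on heavily missing data can differ at the affected quantiles.

`dasen` stratifies by Infinium design type: M and U are normalized
separately within each of the four (array, type) groups, then betas
are recomputed with the standard offset.  Normalized output always
lands in new assays (`*_norm`); raw arrays are immutable because the
qual metric needs them.

## Quality control

**outlyx.**  S samples are projected onto the top k = 2 principal
components of a seeded random probe subset (default 2000 probes).  Two
detectors run on the scores: (a) a robust outlyingness score — each
component standardized by the median and the normal-consistent MAD of
the clean samples, the squared distance mapped through the chi-square
CDF with k degrees of freedom into [0, 1], flagged above 0.5 — and
(b) Tukey fences at 2 x IQR beyond the quartiles on either PC.  A
sample is flagged only on consensus.  The procedure iterates by
peeling: the PC basis, medians, MADs and quartiles are refit on
currently unflagged samples only (all samples are projected onto that
clean basis), newly flagged samples are added, and iteration stops
when a round adds nothing.  Because flags only grow and the statistics
never see flagged samples, the flag set is a fixed point: removing
flagged samples from the input and rerunning reproduces the survivors'
verdicts exactly, which is the masking/swamping-resistance the tests
assert across seeds.  Flagged samples report the score that triggered
them; survivors the final clean-basis score.

**bscon.**  Type II conversion controls read red/(red+green) per
probe.  Type I controls come as converted/unconverted bead pairs with
a designated channel; the pairing is data-driven — the control table
carries an explicit role column and the manifest the channel — and
pairs are matched by order within (category, channel).  The sample
value is 100 x the median over all conversion control probes; it is
scale-invariant by construction.  The conventional screen drops
samples below 85%.

**qual.**  Per-sample RMSD (and mean absolute deviation) between raw
and normalized betas, NaN pairs dropped; the flag fires above 0.05.
It is computed on betas, not intensities, and a streaming variant
accumulates the sums in row blocks.

**Subsampled PCA** takes an exact SVD of the centered (optionally
scaled) random probe subset — no approximation beyond the subsetting —
with a deterministic sign convention; probes containing any NaN are
excluded with a warning.  On low-rank structure, 1% of probes
reproduces PC1 against the planted factor with |r| > 0.99.  The sex
guess is 2-means on the first two PCs, computed on X/Y-chromosome
probes when the manifest annotates them; cluster labels are mapped to
M/F by the majority of reported sexes and fall back to neutral cluster
ids when no mapping is defensible.

## Covariates

**Age.**  A clock is an intercept plus per-probe linear coefficients,
read from CSV (never vendored).  The score passes through the inverse
of F(age) = log(age+1) - log(adult_age+1) for age <= adult_age, else
(age - adult_age)/(adult_age+1); adult_age defaults to 21, the
transform's fixed point.  Probes missing from the data are either
dropped from the sum or imputed with the clock's reference means; if
fewer than 80% of clock probes are present at all, prediction is
refused rather than silently degraded.

**Cell composition.**  Per sample, minimize ||beta - B w||^2 over
w >= 0 with sum(w) <= 1 (default) or = 1, where B is the reference
panel at its discriminating probes (panel selection is upstream and
out of scope).  The solver is Lawson–Hanson active-set NNLS on a
penalty-augmented system: the sum constraint enters as a heavily
weighted row (weight 1e6; a slack variable carries the inequality),
which reproduces the constrained optimum to ~1e-9 without a QP
dependency.  Noise-free mixtures are recovered with RMSE < 0.01,
beta noise of sd 0.02 gives RMSE < 0.03.

Instead of quantile-normalizing reference and study together, the
study's mean M and U quantiles can be imposed on the reference panel
alone (rank -> target-quantile mapping per design-type group, betas
recomputed, study untouched).  The rationale: with a large study the
reference's contribution to joint quantiles is negligible, so the two
routes agree — the tests measure RMSD < 0.03 between imposed and
co-normalized estimates on a 100-sample synthetic cohort.  Imposition
granularity is per design type, matching the dasen grouping; a global
variant would differ slightly on arrays with strong type effects.

## EWAS and bump hunting

Probewise analysis is OLS of beta on the design matrix (intercept
prepended, rank-checked), streamed in row blocks: complete probes are
solved in a single batched projection, probes with missing samples get
an individual fit on their complete cases.  The target coefficient is
reported with its SE, t statistic, two-sided p (Student t with n - d
degrees of freedom) and Benjamini–Hochberg FDR.  Results are invariant
to block size and worker count.

Clusters group probes on one chromosome with positional gaps of at
most `max_gap` (default 500 bp).  Within a cluster, effects are
smoothed by a centered running mean of `smooth_span` probes (default
3, edge windows shrink; clusters shorter than the span stay
unsmoothed).  Candidate bumps are maximal runs with |smoothed| >= the
cutoff; each reports its probe count L, area (sum of |smoothed|) and
mean value, with coordinates converted from the manifest's 1-based
positions to 0-based half-open intervals on output (BED export
included).

Inference permutes the target variable across samples, keeping
covariates attached to their samples, and recomputes
effects/smoothing/bumps per permutation.  So that the same linear
operator applies to every permutation, probes with missing betas are
mean-imputed before bump hunting (a documented approximation; the
probewise EWAS itself does not impute).  A bump's p-value and
family-wise error rate are both the tail probability of its area under
the per-permutation maximum null area, with the observed statistic
counted in the null — hence p >= 1/(n_perm+1).  Defaults (cutoff on
the effect scale, max_gap 500, 100 permutations) are package choices,
declared rather than inherited.  Null calibration: across 50 simulated
null cohorts at 200 permutations, the fraction with any fwer < 0.05
bump stays at or below 0.08 in the suite.

## Synthetic data generator

The generator emulates what the pipeline needs to see, not the full
physics of the assay.  Per-probe base betas come from a three-mode
Beta mixture (hypomethylated Beta(1.5, 8), hemimethylated Beta(5, 5),
hypermethylated Beta(8, 1.5); weights 0.45/0.15/0.40), clipped to
[0.03, 0.95].  Total signal T is lognormal around 6000 (Type I) or
5000 (Type II) with multiplicative sd 0.2; intensities are emitted as
M = beta*T and U = (1-beta)*T - alpha, so that the standard beta
recomputation returns the planted beta exactly (the final beta clip at
0.95 keeps the inversion inside the positive-U region at the default
noise level; the rare clipped cell deviates and is tolerated by the
noisy-path tests).  Per-sample beta noise is Gaussian sd 0.015.

Planted structure: ages uniform on [5, 75] encoded exactly by a toy
linear clock (coefficients uniform 0.5–1.5 with random signs over 50
probes, betas constructed so the score equals the transformed age);
sex as a 0.45 beta separation on chrX probes; cell fractions
Dirichlet(2) mixed through a random three-level reference panel at 60
designated probes (the panel ships with reference M/U at intensity
scale 3000 for imposition tests); per-sample conversion levels
realized on Type I control pairs and Type II controls with
multiplicative noise; outliers as +/-10 pooled-SD shifts on 30% of
probes; DMRs as group-specific beta shifts on whole positional
clusters (reserved before other special probe sets, with base betas
held in [0.15, 0.60] so the planted shift survives clipping; the
truth records the effective post-clip shift).  Probe coordinates come
in runs of 1–12 probes 100 bp apart, 5 kb between runs, across five
autosomes plus chrX.  The two-group phenotype is balanced and shuffled
independently of sex, age and batch.  One integer seed drives
everything through a SeedSequence spawn tree; identical seeds produce
byte-identical files.

What the generator does not model: probe cross-hybridization, SNP
artifacts, dye bias, spatial chip effects, realistic batch structure
(a per-batch label exists, but no batch effect is injected by
default), or EPIC noise spectra.  Passing tests therefore demonstrate
algorithmic correctness and calibration under a clean generative
model, not robustness to every artifact of real arrays.

## Problem sizes and numerics

The validation suite runs at desk scale as a deliberate choice: the
normalization oracle at 2000 x 50 and 5000 x 100, the memory contract
on a 20 000 x 200 store under a 2^20-element cap (0.92 of cap at its
peak), outlier/conversion/sex checks over 20 seeds each, cell
composition at S = 100, and bump-hunter calibration over 50 null
replicates of 300 x 40 at 200 permutations.  Tolerances: 1e-10 for
chunked-vs-dense equality, exact (bitwise) for append partitioning,
1e-6 years for noise-free clock inversion, the recovery bounds quoted
above otherwise.  Ties in normalization are resolved by mean-rank;
k-means uses 10 seeded restarts; SVD signs follow a
largest-|loading|-positive convention; all randomness flows from
explicit integer seeds recorded in reports and provenance files.
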