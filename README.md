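# methylstream

Memory-bounded analysis of Illumina-style DNA methylation micro-arrays
(450K/EPIC scale): a chunked on-disk store with incremental sample
appends, per-sample quality control, out-of-core quantile
normalization, covariate estimation (epigenetic-clock age, sex,
cell-type composition) and probewise EWAS with bump hunting — all under
an explicit peak-memory contract.

## The problem

An epigenome-wide association study (EWAS) tests DNA methylation at
hundreds of thousands of CpG loci against a phenotype.  The working
quantity is the beta value

    beta = M / (M + U + alpha),        alpha = 100 by default,

the methylated fraction of the signal at a probe, with M and U the
methylated and unmethylated intensities and alpha a small offset that
damps low-intensity probes.  Holding the M, U and beta matrices of a
large cohort in RAM simultaneously takes tens of gigabytes; a
workstation-scale alternative is to keep everything on disk, stream it
in blocks, and add samples batch by batch as they come off the scanner.
`methylstream` is that workflow as a Python library: every operation is
written against a chunked HDF5 container and is guaranteed — by an
instrumented allocator the test suite arms — never to materialize a
dense block larger than a configurable cap (default 2^24 elements,
~128 MB of float64).

The statistical toolkit it wraps around the store:

* **Quantile normalization, out of core.**  Pass 1 streams sample
  columns and averages their sorted values into a reference quantile
  vector; pass 2 maps each value to the reference at its within-column
  rank, ties receiving the mean of the tied reference positions.  The
  result is elementwise identical (to 1e-10) to the classic dense
  algorithm, for any chunk geometry.  `dasen` is the stratified
  variant: M and U normalized separately within each Infinium
  design-type group, betas recomputed.
* **QC.**  `outlyx` — unsupervised multivariate outlier detection on a
  random probe subset: a robust PC-space outlyingness score (median/MAD
  standardized, mapped through the chi-square CDF) in consensus with
  Tukey IQR fences on PC1/PC2, iterated by peeling so that flags are
  stable under removal of flagged samples (no masking or swamping).
  `bscon` — bisulfite-conversion efficiency from the array's conversion
  control probes (ideally 100%; below ~85% signals trouble).  `qual` —
  "normalization violence", the per-sample RMSD between raw and
  normalized betas (flag above 0.05).  Subsampled-probe PCA (1% of
  probes suffices for sample-level structure) and a 2-means sex guess
  on its scores.
* **Covariates.**  Linear epigenetic-clock age prediction with the
  piecewise log-linear age transform (fixed point at adult age 21);
  Houseman-style reference-based cell deconvolution by non-negative
  constrained least squares, with the study's M/U quantiles *imposed
  on the reference panel* instead of co-normalizing reference and
  study — with a large cohort the two routes agree, and the study data
  is never touched.
* **Analysis.**  Probewise OLS EWAS streamed in row blocks (identical
  results for any block size or worker count, BH-FDR appended) and a
  bump hunter: effects smoothed by a running mean within positional
  clusters, candidate regions as runs of |smoothed effect| above a
  cutoff, family-wise significance from permutation of the target
  variable.
* **Synthetic data.**  A seeded generator of EPIC-like cohorts with
  planted truth — conversion levels, outliers, sex clusters, clock
  ages, cell mixtures, DMRs — used by every test in the suite.

## Worked example

`examples/04_ewas_and_bumphunting.py` plants an 8-probe DMR (group
beta shift +0.3) in an 800-probe, 60-sample cohort and analyzes it:

```
probewise EWAS: 800 probes tested; 8 of the top 10 hits lie in the planted DMR
min p = 4.61e-62, min FDR = 3.69e-59
top bump: chr1:22099-22800 (8 probes, area 2.40, fwer 0.010)
```

The EWAS ranks the planted probes first; the bump hunter returns the
planted region exactly (8 probes), with `area` the sum of |smoothed
effect| over the run and `fwer` the fraction of 100 label permutations
whose largest null bump reached that area.  The other example scripts
cover import/storage, QC and covariate estimation the same way — each
builds a small simulated input, runs one capability and prints what
the numbers mean.

A thin command-line surface wraps the same library for scripted use:

```bash
methylstream simulate --out data --seed 1
methylstream init --store cohort.h5 --manifest data/manifest.csv
methylstream import --store cohort.h5 --m data/methylated.tsv --u data/unmethylated.tsv
methylstream betas --store cohort.h5
methylstream qc --store cohort.h5 --out qc.csv --seed 1
```

`import` is repeatable (the incremental workflow); `qc` is report-only
unless `--apply-filters` is passed.

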