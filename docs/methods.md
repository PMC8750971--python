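# Methods

## The scoring model

A plasma sample is reduced to per-window counts of short cfDNA fragments
(insert < 170 bp, strict), on a grid of 0.55 Mbp autosomal windows. The
pipeline assumes:

* within a sample, the expected count in window *w* factorizes into a
  sample depth term, a smooth function of window GC content, a
  mappability term, and the relative somatic copy ratio of the window;
* tumor and normal cfDNA mix linearly: with tumor fraction *f* and tumor
  total copy number *c* in a region, the relative copy ratio is
  (2(1−f) + c·f)/2, so the expected log₂ ratio is log₂(1 + f(c−2)/2);
* across samples, a window's normalized log₂ ratio in tumor-free plasma
  is approximately Gaussian, so standardizing against a panel of normals
  yields Z-scores whose null tails are known.

The CNI-Score is Σ|z_w| over windows with |z_w| > z*, z* = 2.84 (strict
inequalities throughout; a sample is called positive when the score
strictly exceeds the cut-off, default 24). For m windows the null
expectation is m·2·φ(z*) — ≈ 9.9 at m = 701 — because
E[|Z|·1{|Z|>c}] = 2φ(c) for standard normal Z. The null median (≈ 9 at
m = 701) is lower than the mean because the window count exceeding z* is
approximately Poisson with mean m·2Φ(−z*) ≈ 3.2 and right-skewed.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| small window size | 550,000 | bp | shallow-WGS bin size giving ~1,800 fragments/window at typical depth |
| condensation factor | 10 | windows | averaging 10 windows (~5.5 Mbp bins) suppresses per-bin noise before Z-scoring |
| fragment length cut | < 170 | bp | enriches tumor-derived sub-mononucleosomal fragments |
| z* (critical difference) | 2.84 | – | per-window two-sided null tail ≈ 0.45%, ~3 expected significant windows per null sample at 701 windows |
| score cut-off | 24 | CNI | ≈ 95th percentile of healthy-control scores |
| panel size | 137 | samples | reference panel for per-window μ, σ |
| lowess span | 0.3 | fraction | smooth enough to keep focal CNAs out of the bias fit, flexible enough for the GC bump |
| SD floor | 1e−6 | log₂ | guards degenerate zero-variance windows |

All constants are configurable at every call site and in the CLI.

## Normalization choices

Bias correction is per-sample and blind to other samples: a locally
weighted regression (lowess, statsmodels) of count on GC over usable
windows, dividing by the fit; then the same on mappability. The **pair of
stages is iterated twice (backfitting)**: GC and mappability tracks vary
smoothly along the genome and can be mutually correlated, in which case a
single sequential pass leaves residual structure — two passes removed
≥ 80% of an injected GC-bias correlation in every test configuration.
Lowess is evaluated with a delta of 1% of the covariate range, making the
fit effectively linear-time. After correction each sample is rescaled so
its median corrected value is 1, which makes the pipeline invariant to
sequencing depth; the log₂ of that rescaled value is the window's log₂
ratio. Zeros and non-positive fitted values are masked (NA), never
dropped, so window indices stay aligned with the panel. A condensed
window is the mean of its unmasked members and is masked when more than
half of them are masked.

Median rescaling anchors the diploid baseline and assumes the majority of
the genome is copy-neutral; profiles in which half or more of the genome
is altered shift the baseline and attenuate the score. This is inherent
to intra-sample normalization without an external diploid reference.

## Panel Z-score calibration

The panel stores each window's mean and n−1 standard deviation of the
panel log₂ ratios. The Z-statistic of a *fresh* sample against estimated
moments is t-distributed with n−1 degrees of freedom and variance above
one, so by default the stored SD is inflated by
√((1 + 1/n)·(n−1)/(n−3)) (≈ 1.1% at n = 137). Without this factor the
null CNI of simulated tumor-free samples runs ~20% high (median ≈ 12
instead of 9–10) because the score integrates exactly the tail region
where the variance excess matters most. `calibrate_prediction=False`
restores the raw sample SD.

## The synthetic-data generator

`synthetic_data` emulates the statistical structure the pipeline
assumes, with one master seed and per-sample streams spawned via numpy
`SeedSequence`, so cohorts are reproducible sample-by-sample:

* **genome** — condensed groups spread near-evenly over 22 equal
  pseudo-autosomes (every chromosome holds whole condensation groups, so
  7,010 small windows condense to exactly 701); GC per window from a
  Gaussian-kernel-smoothed spatial process scaled into [0.3, 0.6],
  mappability likewise into [0.8, 1.0];
* **counts** — negative binomial (gamma–Poisson) with variance
  μ + μ²·d, d = 0.002, around μ = 1800 · bias(GC) · mappability ·
  copy-ratio; the bias curve is a unimodal bump
  1 + 0.3·exp(−(GC−0.45)²/(2·0.08²)), known to the simulator but never to
  the pipeline;
* **tumors** — segments on the condensed grid with a total copy number,
  diluted by a single tumor fraction f through the admixture law above;
* **fragment lengths** — mixture (1−f)·N(167, 10²) + f·N(145, 12²) bp,
  truncated to [50, 400] and rounded: the mononucleosome peak and the
  well-known ctDNA shortening.

What the simulator deliberately does **not** model: inter-individual and
batch-level technical variance between real donors (real healthy cohorts
show a wider CNI spread than the iid null), subclonal heterogeneity
(a single f per sample), sex chromosomes, alignment artifacts, and real
hg19 coordinates. Passing tests therefore demonstrate the pipeline's
statistical behaviour under its own model assumptions — calibration,
bias removal, monotonicity in f, profile recovery — not performance on
any particular patient cohort.

## Statistics conventions

* ROC: positive means score > threshold; thresholds are midpoints
  between consecutive distinct pooled scores plus ∓∞ sentinels; AUC by
  trapezoid, which equals the Mann–Whitney statistic with 0.5 credit for
  ties; the Youden-optimal threshold maximizes sens + spec − 1, ties
  broken toward the lowest threshold (favoring sensitivity).
* Cut-off tables report exact fractions (specificity = controls ≤
  cut-off, sensitivity = cases > cut-off, per group and pooled);
  rounding to integer percent (half away from zero) happens only at
  presentation.
* Wilcoxon rank-sum: exact enumeration when both groups have ≤ 8
  observations and no ties, otherwise the normal approximation with
  continuity and tie correction (scipy). Benjamini–Hochberg step-up is
  implemented directly and cross-checked against statsmodels.
* Sample size: smallest n whose exact noncentral-t power
  P(T_{n−1,δ} > t_{1−α,n−1}), δ = d√n, reaches the target; at d = 0.5,
  α = 0.01 one-sided, power 0.95 this yields n = 66.

## Numerical and degenerate-input policy

Masked values propagate as NaN and are excluded from medians, means,
SDs, and tail sums (a masked window is never significant). All-zero
samples, empty groups, window-set mismatches, and out-of-range
probabilities raise ValueError naming the offending object. Determinism:
identical seeds and inputs give identical outputs end-to-end, including
the CLI `report` subcommand.

## Problem sizes used in the test suite

The suite exercises two geometries: the full 7,010-window genome with a
137-sample panel, 241 simulated controls and 23 simulated cases at
f = 0.1 (end-to-end separation, null calibration, bias removal), and a
reduced 1,200-window genome with a 40-sample panel for per-module
pipeline tests. Null-calibration checks use 10,000 replicate draws of
701-window Z profiles; Monte-Carlo verification of the sample-size
calculation uses 100,000 replicate t-tests. These sizes were chosen so
every statistical assertion has comfortable margin over its Monte-Carlo
error.

## Known limitations

* The score saturates for heavily rearranged genomes (median baseline
  shift), and is blind to copy-neutral events (LOH, balanced
  rearrangements) by construction.
* Window-level Z-scores assume the panel is representative of the test
  sample's technical conditions; batch effects between panel and test
  samples inflate scores and are not modelled here.
* The simulator's iid null understates the between-donor spread of real
  control scores, so real-world specificity at a given cut-off must be
  established on real reference samples.
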