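# Methods

## Problem and model

Gait variability — the stride-to-stride fluctuation of stride length (SL,
in % of body stature) and stride time (ST, in seconds) during steady
walking — is quantified here as the coefficient of variation,

    CoV = (sample SD / mean) × 100  [%],

with the sample SD (n−1 denominator) throughout; this is the convention of
the reliability literature the CoV cut-offs come from.

Clinical recordings are made in confined spaces: a subject walks a short
straight segment repeatedly, turning 180° at each end, and the gait
system's segmentation algorithm excises the turns before exporting one row
per stride (onset timestamp, SL, ST).  The package answers two questions
about that paradigm: (1) do turns contaminate the exported straight-walking
strides, and (2) how many strides does a stable CoV estimate need?

Two protocols are modeled:

* **MD** (movement disorders): 10 m segment walked five times back and
  forth → 5 segments, 4 turns, all turns used for peri-turn analysis.
* **HE** (healthy elderly): 20 m segment back and forth for about a
  minute → 3 segments, 2 turns used (the minimum every participant
  performs).

## Synthetic cohort generator

No stride-level data are distributed, so a generator supplies cohorts with
the statistical structure the analysis assumes.

* Subject means are drawn from Normal(group mean, between-subject SD);
  stride values are i.i.d. Normal(subject mean, subject mean × CoV/100).
  Long-range autocorrelation and drift are deliberately absent: the
  analysis concerns the magnitude of variability, not its temporal
  structure, so passing tests say nothing about fractal or fatigue-related
  features of real gait.
* Default group profiles (`TABLE_PROFILES`) are the observed cohort values
  for healthy elderly (SL 86.13 ± 4.83 %stature, CoV-SL 1.99%; ST
  1.02 ± 0.06 s, CoV-ST 2.10%), cerebellar ataxia (76.06 ± 7.55, 5.61;
  1.12 ± 0.20, 5.65), essential tremor (78.50 ± 6.66, 2.74; 1.02 ± 0.07,
  3.14) and Parkinson's disease (76.02 ± 7.45, 2.81; 0.99 ± 0.05, 2.70).
* Segment sizes default to 8 strides per 10 m and 14 per 20 m (≈1.3 m
  strides), giving 40 strides per MD trial and 42 per HE trial — at least
  the 40 the analysis window requires.
* Turn gaps are drawn uniformly from 2–5 s.  The duration is not critical;
  it only needs to exceed any plausible stride time so that a gap is
  unambiguous.  Onsets accumulate stride times within segments.
* Peri-turn perturbation: strides adjacent to a gap are tagged and, per
  configuration, shortened in length and lengthened in time.  Defaults
  follow the observed effects: after-turn strides 2.8% shorter / 3.2%
  slower in the movement-disorder cohorts (`md_config`), both neighbors
  1.2% / 1.4% in healthy elderly (`he_config`).  Per-disorder effect sizes
  are not separately published, so all disorder groups share the pooled
  values.
* A missed-turn artifact (`inject_missed_turn`) replaces one gap with
  short "turning" strides (default 4 strides at 0.4 × the subject's mean
  SL) filling the former gap — the failure mode where the vendor algorithm
  does not recognize a turn.
* Draws that would fall at or below 10% of the mean are resampled (with a
  logged warning); this floor is inert at realistic CoVs and only guards
  degenerate configurations.
* Reproducibility: per-subject seeds are spawned from the master seed via
  `numpy.random.SeedSequence`; identical inputs give bitwise-identical
  cohorts.

## Turn detection and QC

A turn is detected wherever the inter-onset interval exceeds
`gap_factor × median stride time` (default factor 1.5).  Normalizing by
the subject's own median makes the rule tempo-robust; the parameter is
exposed because vendor rules are undisclosed.  On clean synthetic data
(gaps ≥ 2 s, stride times ≤ 1.5 s) the rule detects every turn with no
false positives.

QC automates the visual check of the stride-series plot with two rules:
fewer detected gaps than the protocol expects, or any non-gap-adjacent
stride shorter than `short_stride_frac` (default 0.5) of the trial median
SL.  Either flag excludes the trial from all downstream statistics; flagged
trials are never repaired.

## Excision modes and analysis windows

`apply_extra_excision(width)` models a more generous segmentation by
dropping `width` additional strides on each side of every gap.  Width 0 is
the vendor-style excision (reference window 40 strides); width 1 removes
8 strides from a 4-turn trial, hence the 32-stride reference window used
with the alternative segmentation.  The cumulative stride count runs over
the concatenated post-excision sequence in onset order; turns contribute
no strides.

## Peri-turn analysis

The strides **directly** before and after each used turn (single records
adjacent to a gap) are expressed as a percentage of the subject's mean
over the first 40 (or 32) analyzed strides — peri-turn strides included in
that reference, since they are part of the exported window.  Pooled
relative values are compared against 100% with a paired t-test
(t = mean(d)/(SD(d)/√n), df = n−1, two-sided p).  Probability-density
histograms (default 20 bins) integrate to unit mass so cohorts of
different sizes are directly comparable; a fitted normal (sample mean/SD)
is provided for overlay.

## Reliability statistics

**ICC(2,1)** — two-way random-effects, absolute-agreement, single-measure
intraclass correlation with segments as repeated measurements:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

from the two-way ANOVA mean squares (subjects MSR, segments MSC, residual
MSE), which are returned for audit.  Subjects with incomplete segment sets
are dropped listwise.  Interpretation bands: < 0.4 poor, 0.4–0.8 (both
ends inclusive) fair to good, > 0.8 excellent.

**Convergence** — for each n in 3..N_max, the Pearson correlation across
subjects between the cumulative statistic (mean or CoV of the first n
strides) and its value at N_max; R at N_max is 1 by construction.  R is
computed on untransformed values (no Fisher z).  The **required stride
count** is the smallest n with R > 0.8, taken at the *first* crossing —
profiles can dip after crossing, and a `sustained=True` switch is provided
for the stricter reading, without any claim about which matches published
tables.  Subjects entering one convergence analysis must share a common
N_max.

**Cut-off classification** counts CoVs *strictly* above 2.6%, the
literature-proposed upper limit of physiological stride-time CoV.

## Numerical choices

* Cumulative moments use running sums with a non-negativity clamp on the
  variance; the endpoint is recomputed directly so the cumulative CoV at
  N_max equals the whole-window CoV to the last bit.
* Stride tables are written with `%.17g` and parsed with pandas
  `float_precision="round_trip"`, so write→read is the identity on IEEE
  doubles.
* Degenerate inputs raise typed errors rather than returning NaN/inf:
  CoV of < 2 values or non-positive mean, zero-variance paired
  differences, constant ICC matrices, zero cross-subject variance at
  N_max.
* Intermediate convergence points with zero cross-subject variance yield
  NaN and can never satisfy the threshold criterion.

## Known limitations and interpretation notes

* The sample SD is biased low at small n (factor c4(n) ≈ 0.965 at n = 8,
  0.994 at n = 40).  Mean per-segment CoVs therefore sit ≈3% (relative)
  below the whole-walk CoV even for i.i.d. data; with the default
  peri-turn perturbation each segment carries its own after-turn stride,
  so the perturbation inflates segment CoVs almost as much as the
  whole-walk CoV.  The whole-walk > segment-mean exceedance the pipeline
  reports on perturbed cohorts thus combines both effects; no bias
  correction is applied because the analysis mirrors how these CoVs are
  computed in practice.
* ICC deflation: with low between-subject spread (homogeneous groups),
  segment-CoV ICCs approach zero even when absolute segment-to-segment
  differences are small (< 0.5 CoV points); the per-segment table reports
  the range alongside the ICC for this reason.
* The generator's i.i.d. structure means required-stride-count estimates
  for CoV on synthetic cohorts reflect pure sampling convergence plus the
  configured peri-turn artifacts, not disease-specific temporal dynamics;
  group-to-group ordering of those estimates should not be over-read.
* Feet are not distinguished; the stride series is one interleaved
  sequence.  Raw IMU signals, curved-path kinematics inside turns and
  nonlinear variability metrics (DFA, entropy) are out of scope.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on generated data:
cohorts of 31 movement-disorder trials (4 turns each) for the counting
checks, 162 healthy-elderly trials for the convergence (R at n = 3) and
segment-ICC bounds (each verified over 10 seeded cohorts, reporting the
minimum), 20–40 seeded replicates for the stochastic property suites, and
10,000-stride single-segment trials for CoV parameter recovery.  The full
suite completes in a few seconds on one CPU.
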