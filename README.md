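# gaitvar

How many strides does a reliable gait-variability measurement need?

Clinical gait assessments with wearable inertial sensors are usually done
in confined spaces: the subject walks a short straight segment repeatedly
with 180° turns at each end, and the analysis software algorithmically
excises the turns before exporting stride-wise parameters.  `gaitvar` is a
toolkit for analyzing such exports — and for asking whether the turning
paradigm itself distorts the headline measure of gait variability, the
coefficient of variation of stride length and stride time,

    CoV = (SD / mean) × 100  [%],

and how many strides a stable CoV estimate requires.  It is aimed at
movement-disorder researchers and gait-analysis methodologists working
with stride-wise exports from ambulatory systems (healthy elderly,
cerebellar ataxia, essential tremor, Parkinson's disease).

What it does:

* **Turn detection & QC** — turns appear as gaps in the stride timestamp
  series (inter-onset interval > 1.5 × the subject's median stride time).
  Trials where the vendor algorithm missed a turn — recognizable by a
  missing gap and implausibly short turning strides in the export — are
  flagged and excluded, since they inflate the CoV far beyond the
  physiological range.
* **Turn excision modes** — the vendor-style excision (analysis window 40
  strides) or a more generous one dropping one extra stride on each side
  of every turn (window 32 strides).
* **Peri-turn analysis** — strides directly before/after turns, normalized
  to the subject's own mean, pooled per group and tested against 100%
  with paired t-tests, plus probability-density histograms.
* **Reliability** — ICC(2,1) (two-way random-effects, single measure) of
  per-segment statistics with poor / fair-to-good / excellent bands at
  0.4 and 0.8; cumulative mean/CoV series for 3..N strides; the Pearson
  correlation of each cumulative statistic with its final value across
  subjects; and the minimum stride count n at which R > 0.8.  Subjects
  with CoV above the 2.6% physiological cut-off are counted.
* **Synthetic cohorts** — a generator reproducing the protocols (5×10 m
  with 4 turns; 3×20 m with 2 used turns), realistic group profiles, turn
  gaps, peri-turn perturbations and injectable missed-turn artifacts, so
  the whole pipeline is testable without any recordings.

## Worked example

```python
import gaitvar as gv

trials = gv.generate_cohort(
    [gv.TABLE_PROFILES[g] for g in ("HE", "ATX", "ET", "PD")],
    n_per_group={"HE": 162, "ATX": 7, "ET": 12, "PD": 12},
    config_by_group={g: (gv.he_config() if g == "HE" else gv.md_config())
                     for g in ("HE", "ATX", "ET", "PD")},
    seed=1,
)
result = gv.run_pipeline(trials, gv.AnalysisConfig(excision_width=0))
print(result.tables["stride_requirement"].head(4).round(2).to_string(index=False))
```

prints

```
group parameter statistic  n_required  avg_at_n  sd_at_n  n_subjects  n_above_cutoff_at_n  frac_above_cutoff_at_n  n_above_cutoff_at_nmax  frac_above_cutoff_at_nmax
   HE        SL  cum_mean           3     86.21     5.21         162                  NaN                     NaN                     NaN                        NaN
   HE        SL   cum_cov          27      1.99     0.29         162                  2.0                    0.01                     1.0                       0.01
   HE        ST  cum_mean           3      1.03     0.07         162                  NaN                     NaN                     NaN                        NaN
   HE        ST   cum_cov          28      2.11     0.26         162                  4.0                    0.02                     4.0                       0.02
```

Read: in the healthy-elderly group the cumulative *mean* stride length and
stride time already correlate with their 40-stride values at R > 0.8 after
3 strides (means converge almost immediately), whereas the cumulative
*CoVs* need 27–28 strides on this i.i.d. synthetic cohort; `avg_at_n` is
the group mean of the cumulative statistic at that stride count, and the
cut-off columns count subjects above 2.6% CoV at n and at the 40-stride
reference.  The bundle also contains the QC report, a group summary table,
per-segment ICCs (segment means come out "excellent", segment CoVs "poor"
in homogeneous groups — the expected ICC deflation), the full cumulative
and convergence series, and peri-turn contrasts; on the
movement-disorders groups the pooled after-turn strides average ≈97.2% of
the subject mean in length and ≈103.1% in time (p < 1e-15), matching the
configured perturbation.

The `examples/` scripts walk through each capability
(`01_simulate_cohort.py`, `02_turn_detection_qc.py`,
`03_periturn_effects.py`, `04_stride_count_requirement.py`); each prints
its numbers with a line on what they mean.  A thin CLI wraps the same
library:

```sh
gaitvar simulate --profile all --seed 1 --out cohort/
gaitvar analyze --manifest cohort/manifest.csv --excision-width 0 --out report/
```

See `docs/methods.md` for the model, parameter defaults and limitations.

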