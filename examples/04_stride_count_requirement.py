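"""How many strides does a reliable gait-variability estimate need?

Runs the full pipeline on a synthetic four-group cohort: QC, turn
excision, cumulative mean/CoV series for 3..40 strides, then the Pearson
correlation of each cumulative statistic with its 40-stride value across
subjects.  The smallest n with R > 0.8 is the required stride count.
Also reports ICC(2,1) consistency across walking segments and the
fraction of subjects above the 2.6% stride-time CoV cut-off.
"""

import gaitvar as gv

trials = gv.generate_cohort(
    [gv.TABLE_PROFILES[g] for g in ("HE", "ATX", "ET", "PD")],
    n_per_group={"HE": 162, "ATX": 7, "ET": 12, "PD": 12},
    config_by_group={g: (gv.he_config() if g == "HE" else gv.md_config())
                     for g in ("HE", "ATX", "ET", "PD")},
    seed=1,
)
result = gv.run_pipeline(trials, gv.AnalysisConfig(excision_width=0))

print("--- required stride counts (first n with R > 0.8) ---")
req = result.tables["stride_requirement"]
cols = ["group", "parameter", "statistic", "n_required", "avg_at_n",
        "n_above_cutoff_at_n", "n_above_cutoff_at_nmax"]
print(req[cols].round(2).to_string(index=False))

print("\n--- segment consistency, ICC(2,1) ---")
icc = result.tables["segment_icc"]
print(icc[["group", "parameter", "measure", "icc", "band"]]
      .round(3).to_string(index=False))

print("\nMeans converge almost immediately (n_required = 3); CoVs need "
      "substantially more strides.  Segment means are excellently "
      "consistent while segment CoVs show the expected ICC deflation in "
      "homogeneous groups.")
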