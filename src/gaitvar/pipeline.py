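"""End-to-end analysis: QC -> turn excision -> metrics -> reliability.

`run_pipeline` sequences the full analysis on a cohort of trials and
returns a bundle of tidy tables: QC accounting, group summary
(means/SDs/CoVs of stride length and time), per-segment ICC, cumulative
series, convergence profiles and the required-stride-count table, plus a
run log with counts at each stage so exclusion accounting is always
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import read_manifest
from .metrics import (
    CumulativeSeries,
    UndefinedStatisticError,
    coefficient_of_variation,
    compare_periturn,
    cumulative_series,
    per_segment_stats,
)
from .model import GaitTrial
from .reliability import (
    classify_above_cutoff,
    convergence_profile,
    icc_two_way_random_single,
    required_stride_count,
)
from .turns import (
    DEFAULT_GAP_FACTOR,
    DEFAULT_SHORT_STRIDE_FRAC,
    SegmentedTrial,
    apply_extra_excision,
    detect_turn_gaps,
    extract_periturn_strides,
    qc_trial,
    segment_by_turns,
)

logger = logging.getLogger(__name__)

#: Movement-disorder subgroups pooled into an "MD" super-group for
#: peri-turn and requirement tables.
MD_SUBGROUPS = ("ATX", "ET", "PD")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed constants of the analysis.

    ``excision_width`` 0 reproduces the vendor-style excision (reference
    window 40 strides); width 1 is the generous alternative that drops one
    extra stride on each side of every turn (reference window 32).
    """

    gap_factor: float = DEFAULT_GAP_FACTOR
    short_stride_frac: float = DEFAULT_SHORT_STRIDE_FRAC
    excision_width: int = 0
    n_max: Optional[int] = None   # default: 40 for width 0, 32 for width 1
    n_min: int = 3
    criterion_r: float = 0.8
    cov_cutoff_pct: float = 2.6
    min_strides: int = 40
    pool_md: bool = True

    def __post_init__(self) -> None:
        if self.excision_width < 0:
            raise ValueError("excision_width must be >= 0")
        if not 0 < self.criterion_r < 1:
            raise ValueError("criterion_r must lie in (0, 1)")
        if self.n_min >= self.resolved_n_max():
            raise ValueError("n_min must be < n_max")

    def resolved_n_max(self) -> int:
        if self.n_max is not None:
            return self.n_max
        return 40 if self.excision_width == 0 else 32


class EmptyCohortError(RuntimeError):
    """All trials were excluded by QC (or none were supplied)."""


@dataclass
class PipelineResult:
    config: AnalysisConfig
    tables: dict[str, pd.DataFrame]
    log_lines: list[str] = field(default_factory=list)

    def write(self, outdir: Union[str, Path]) -> None:
        """Write every table as CSV plus the plain-text run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "run_log.txt").write_text("\n".join(self.log_lines) + "\n")


def _analysis_groups(groups: list[str], pool_md: bool) -> dict[str, list[str]]:
    """Map reporting group -> member group labels (MD pools the disorder
    subgroups when more than one is present)."""
    out = {g: [g] for g in groups}
    md = [g for g in MD_SUBGROUPS if g in groups]
    if pool_md and len(md) > 1:
        out["MD"] = md
    return out


def run_pipeline(trials: list[GaitTrial],
                 config: AnalysisConfig = AnalysisConfig()) -> PipelineResult:
    """Run the full analysis on a cohort; deterministic given inputs."""
    log: list[str] = [
        f"config: gap_factor={config.gap_factor} "
        f"short_stride_frac={config.short_stride_frac} "
        f"excision_width={config.excision_width} "
        f"n_window=[{config.n_min},{config.resolved_n_max()}] "
        f"criterion_r={config.criterion_r} "
        f"cov_cutoff={config.cov_cutoff_pct}% "
        f"min_strides={config.min_strides}",
        f"trials in: {len(trials)}",
    ]
    if not trials:
        raise EmptyCohortError("no trials supplied")

    # --- QC & segmentation --------------------------------------------------
    qc_rows = []
    kept: list[SegmentedTrial] = []
    for trial in trials:
        turns = detect_turn_gaps(trial, config.gap_factor)
        qc = qc_trial(trial, turns, trial.protocol, config.short_stride_frac)
        if len(trial) < config.min_strides and "too_few_strides" not in qc.flags:
            qc.flags.append("too_few_strides")
        qc_rows.append({
            "subject_id": trial.subject_id, "group": trial.group,
            "n_turns_detected": qc.n_turns_detected,
            "n_turns_expected": qc.n_turns_expected,
            "flags": ";".join(qc.flags), "excluded": qc.excluded,
        })
        if qc.excluded:
            continue
        seg = segment_by_turns(trial, turns)
        seg.qc = qc
        kept.append(seg)
    n_excluded = len(trials) - len(kept)
    log.append(f"QC-excluded: {n_excluded} of {len(trials)}")
    log.append(f"analyzed: {len(kept)}")
    if not kept:
        raise EmptyCohortError("all trials QC-excluded")

    n_max = config.resolved_n_max()

    # --- per-subject stride sequences after excision ------------------------
    subject_rows = []
    cum_rows = []
    series_by_group: dict[tuple[str, str], list[CumulativeSeries]] = {}
    subj_stats: dict[str, dict] = {}
    for seg in kept:
        records = apply_extra_excision(seg, config.excision_width)
        if len(records) < n_max:
            log.append(f"dropped {seg.trial.subject_id}: only {len(records)} "
                       f"strides after excision (< {n_max})")
            continue
        window = records[:n_max]
        row = {"subject_id": seg.trial.subject_id, "group": seg.trial.group}
        for param, attr in (("SL", "length_pct_stature"), ("ST", "time_s")):
            values = [getattr(r, attr) for r in window]
            row[f"mean_{param.lower()}"] = float(np.mean(values))
            row[f"cov_{param.lower()}"] = coefficient_of_variation(values)
            cs = cumulative_series(values, n_max=n_max, n_min=config.n_min,
                                   parameter=param)
            series_by_group.setdefault((seg.trial.group, param), []).append(cs)
            for n, m, c in zip(cs.n_values, cs.cum_mean, cs.cum_cov):
                cum_rows.append({"subject_id": seg.trial.subject_id,
                                 "group": seg.trial.group, "parameter": param,
                                 "n": int(n), "cum_mean": m, "cum_cov": c})
        subject_rows.append(row)
        subj_stats[seg.trial.subject_id] = row
    subjects = pd.DataFrame(subject_rows)
    if subjects.empty:
        raise EmptyCohortError("no trial retained enough strides for the "
                               f"{n_max}-stride reference window")
    log.append(f"with full {n_max}-stride window: {len(subjects)}")

    groups_present = list(dict.fromkeys(subjects["group"]))
    report_groups = _analysis_groups(groups_present, config.pool_md)

    # --- group summary ------------------------------------------------------
    summary_rows = []
    for gname, members in report_groups.items():
        sub = subjects[subjects["group"].isin(members)]
        row = {"group": gname, "n": len(sub)}
        for col in ("mean_sl", "cov_sl", "mean_st", "cov_st"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = (float(sub[col].std(ddof=1))
                                if len(sub) > 1 else float("nan"))
        summary_rows.append(row)
        if len(sub) <= 1:
            log.append(f"group {gname}: single subject, SDs undefined")

    # --- per-segment stats and ICC ------------------------------------------
    icc_rows = []
    for gname, members in report_groups.items():
        segs = [s for s in kept if s.trial.group in members
                and s.trial.subject_id in subj_stats]
        for param in ("SL", "ST"):
            for measure in ("seg_mean", "seg_cov"):
                mat, ranges = [], []
                k_expected = None
                for s in segs:
                    try:
                        st = per_segment_stats(s, param)
                    except UndefinedStatisticError:
                        continue
                    vals = st.seg_means if measure == "seg_mean" else st.seg_covs
                    if k_expected is None:
                        k_expected = s.trial.protocol.n_segments
                    if len(vals) != k_expected:
                        continue  # listwise drop of incomplete segment sets
                    mat.append(vals)
                    ranges.append(st.cov_range)
                if len(mat) < 2:
                    continue
                res = icc_two_way_random_single(np.array(mat))
                icc_rows.append({
                    "group": gname, "parameter": param, "measure": measure,
                    "icc": res.icc, "band": res.band,
                    "n_subjects": res.n_subjects,
                    "k_segments": res.k_segments,
                    "mean_cov_range": float(np.mean(ranges)),
                })

    # --- convergence and required stride count ------------------------------
    conv_rows, req_rows = [], []
    for gname, members in report_groups.items():
        for param in ("SL", "ST"):
            series = [cs for g in members
                      for cs in series_by_group.get((g, param), [])]
            if len(series) < 3:
                log.append(f"group {gname}/{param}: <3 subjects, "
                           "convergence skipped")
                continue
            finals_cov = np.array([cs.cum_cov[-1] for cs in series])
            for statistic in ("cum_mean", "cum_cov"):
                prof = convergence_profile(series, statistic)
                for n, r in zip(prof.n_values, prof.r_by_n):
                    conv_rows.append({"group": gname, "parameter": param,
                                      "statistic": statistic, "n": int(n),
                                      "r": float(r)})
                n_req = required_stride_count(prof, config.criterion_r)
                at_n = np.array([cs.at(n_req, statistic) for cs in series])
                row = {"group": gname, "parameter": param,
                       "statistic": statistic, "n_required": n_req,
                       "avg_at_n": float(at_n.mean()),
                       "sd_at_n": float(at_n.std(ddof=1)),
                       "n_subjects": len(series)}
                if statistic == "cum_cov":
                    c_at_n, f_at_n = classify_above_cutoff(
                        at_n, config.cov_cutoff_pct)
                    c_fin, f_fin = classify_above_cutoff(
                        finals_cov, config.cov_cutoff_pct)
                    row.update({"n_above_cutoff_at_n": c_at_n,
                                "frac_above_cutoff_at_n": f_at_n,
                                "n_above_cutoff_at_nmax": c_fin,
                                "frac_above_cutoff_at_nmax": f_fin})
                req_rows.append(row)

    # --- peri-turn contrasts ------------------------------------------------
    periturn_rows = []
    psets = extract_periturn_strides(
        [s for s in kept if s.trial.subject_id in subj_stats],
        reference_n=n_max)
    for gname, members in report_groups.items():
        gsets = [p for p in psets if p.group in members]
        for side in ("before", "after"):
            for param in ("SL", "ST"):
                try:
                    cmp_res = compare_periturn(gsets, side, param)
                except UndefinedStatisticError:
                    continue
                periturn_rows.append({
                    "group": gname, "side": side, "parameter": param,
                    "n_strides": cmp_res.n,
                    "mean_relative_pct": cmp_res.mean_relative_pct,
                    "t": cmp_res.test.t, "df": cmp_res.test.df,
                    "p": cmp_res.test.p,
                })

    tables = {
        "qc_report": pd.DataFrame(qc_rows),
        "group_summary": pd.DataFrame(summary_rows),
        "segment_icc": pd.DataFrame(icc_rows),
        "cumulative_series": pd.DataFrame(cum_rows),
        "convergence": pd.DataFrame(conv_rows),
        "stride_requirement": pd.DataFrame(req_rows),
        "periturn": pd.DataFrame(periturn_rows),
    }
    return PipelineResult(config=config, tables=tables, log_lines=log)


def run_pipeline_from_manifest(manifest: Union[str, Path],
                               config: AnalysisConfig = AnalysisConfig()
                               ) -> PipelineResult:
    """Load a cohort manifest and run the analysis."""
    return run_pipeline(read_manifest(manifest), config)


def summarize_cohort(trials: list[GaitTrial],
                     n_max: int = 40) -> pd.DataFrame:
    """Group-level mean +/- SD of subject-level SL, ST and their CoVs.

    Convenience wrapper computing the summary directly from raw trials
    (first ``n_max`` strides of each), without QC or excision.
    """
    rows = []
    for t in trials:
        window = [r for r in t.records if r.periturn_tag != "turning"][:n_max]
        sl = [r.length_pct_stature for r in window]
        st = [r.time_s for r in window]
        rows.append({"group": t.group, "mean_sl": float(np.mean(sl)),
                     "cov_sl": coefficient_of_variation(sl),
                     "mean_st": float(np.mean(st)),
                     "cov_st": coefficient_of_variation(st)})
    df = pd.DataFrame(rows)
    out = []
    for g, sub in df.groupby("group", sort=False):
        row = {"group": g, "n": len(sub)}
        for col in ("mean_sl", "cov_sl", "mean_st", "cov_st"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = (float(sub[col].std(ddof=1))
                                if len(sub) > 1 else float("nan"))
        out.append(row)
    return pd.DataFrame(out)
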