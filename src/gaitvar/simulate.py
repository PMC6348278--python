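"""Synthetic gait cohorts with turn gaps and peri-turn perturbations.

The generator emulates the tabular output of a sensor-based gait system
after algorithmic turn excision: a subject walks straight segments
separated by 180-degree turns; turns contribute no strides, only timestamp
gaps.  Stride-level structure is deliberately simple — i.i.d. Gaussian
fluctuation about a subject-specific mean — because the downstream
analysis concerns the *magnitude* of variability (CoV), not its temporal
correlation structure.

Group-level generative parameters (between-subject means/SDs and
within-subject CoVs of stride length and stride time) default to the
values observed in a healthy-elderly cohort (n=162) and in cerebellar
ataxia, essential tremor and Parkinson's disease subgroups; see
``TABLE_PROFILES``.

Two artifacts of real recordings can be injected:

* peri-turn perturbation — strides adjacent to a turn are spatially
  shorter and temporally longer than mid-segment strides;
* a *missed* turn — the excision algorithm fails, and drastically short
  turning strides appear in the export instead of a gap, inflating CoV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import GaitTrial, HE_PROTOCOL, MD_PROTOCOL, ProtocolSpec, StrideRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortProfile:
    """Generative parameters for one group.

    Lengths are in percent stature, times in seconds, CoVs in percent.
    ``sd_*_between`` is the between-subject SD of the subject means;
    ``cov_*_pct`` the within-subject stride-to-stride CoV.
    """

    group: str
    mean_sl_pct: float
    sd_sl_between: float
    mean_st_s: float
    sd_st_between: float
    cov_sl_pct: float
    cov_st_pct: float

    def __post_init__(self) -> None:
        if self.mean_sl_pct <= 0 or self.mean_st_s <= 0:
            raise ValueError("means must be positive")
        if min(self.sd_sl_between, self.sd_st_between,
               self.cov_sl_pct, self.cov_st_pct) < 0:
            raise ValueError("SDs and CoVs must be non-negative")


#: Group profiles: mean +/- between-subject SD of stride length (%stature)
#: and stride time (s), plus within-subject CoVs (%), per cohort.
TABLE_PROFILES: dict[str, CohortProfile] = {
    "HE": CohortProfile("HE", 86.13, 4.83, 1.02, 0.06, 1.99, 2.10),
    "ATX": CohortProfile("ATX", 76.06, 7.55, 1.12, 0.20, 5.61, 5.65),
    "ET": CohortProfile("ET", 78.50, 6.66, 1.02, 0.07, 2.74, 3.14),
    "PD": CohortProfile("PD", 76.02, 7.45, 0.99, 0.05, 2.81, 2.70),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Trial-structure parameters for the generator.

    ``strides_per_segment`` defaults to roughly the segment length divided
    by a typical stride (8 strides per 10 m, 14 per 20 m), which yields at
    least 40 strides per trial under both protocols.  ``turn_duration_s``
    is the timestamp gap a turn leaves; the default range comfortably
    exceeds any plausible stride time so gaps are unambiguous.
    ``periturn_scope`` selects which neighbors of each gap are perturbed:
    the movement-disorders cohorts showed the effect after turns
    (deltas 2.8% shorter / 3.2% longer), the healthy elderly a smaller
    effect on both sides (1.2% / 1.4%).
    """

    protocol: ProtocolSpec = MD_PROTOCOL
    strides_per_segment: Optional[int] = None
    turn_duration_s: tuple[float, float] = (2.0, 5.0)
    periturn_delta_len_pct: float = 0.0
    periturn_delta_time_pct: float = 0.0
    periturn_scope: str = "after_only"

    def __post_init__(self) -> None:
        lo, hi = self.turn_duration_s
        if not (0 < lo <= hi):
            raise ValueError("turn_duration_s must be a positive range")
        if self.periturn_delta_len_pct < 0 or self.periturn_delta_time_pct < 0:
            raise ValueError("peri-turn deltas must be >= 0")
        if self.periturn_scope not in ("after_only", "before_and_after"):
            raise ValueError("periturn_scope must be 'after_only' or "
                             "'before_and_after'")

    def resolved_strides_per_segment(self) -> int:
        if self.strides_per_segment is not None:
            return self.strides_per_segment
        # ~1.3 m strides: 8 per 10 m, 14 per 20 m
        return {10.0: 8, 20.0: 14}.get(
            self.protocol.segment_length_m,
            max(3, round(self.protocol.segment_length_m / 1.3)))


def md_config(**overrides) -> GeneratorConfig:
    """Movement-disorders preset: 5x10 m, after-turn perturbation."""
    defaults = dict(protocol=MD_PROTOCOL, periturn_delta_len_pct=2.8,
                    periturn_delta_time_pct=3.2, periturn_scope="after_only")
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def he_config(**overrides) -> GeneratorConfig:
    """Healthy-elderly preset: 3x20 m, perturbation on both turn sides."""
    defaults = dict(protocol=HE_PROTOCOL, periturn_delta_len_pct=1.2,
                    periturn_delta_time_pct=1.4,
                    periturn_scope="before_and_after")
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   size: int) -> np.ndarray:
    """Normal draws with a floor at 10% of the mean (resampled).

    Needed only at extreme CoVs where the Gaussian tail would produce
    non-positive lengths or times.
    """
    floor = 0.1 * mean
    out = rng.normal(mean, sd, size)
    bad = out <= floor
    n_resampled = 0
    while bad.any():
        n_resampled += int(bad.sum())
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= floor
    if n_resampled:
        logger.warning("resampled %d draws below the positivity floor "
                       "(mean=%g, sd=%g)", n_resampled, mean, sd)
    return out


def generate_trial(profile: CohortProfile, config: GeneratorConfig,
                   subject_seed: int, subject_id: Optional[str] = None) -> GaitTrial:
    """Simulate one subject's walk.

    The subject's mean stride length/time are drawn from the
    between-subject normal; each stride then fluctuates independently
    about the subject mean with SD = mean x CoV/100.  Onsets accumulate
    stride times; each segment boundary inserts a turn gap drawn uniformly
    from ``config.turn_duration_s``.  Strides adjacent to gaps are tagged
    ``before_turn``/``after_turn`` and perturbed per config (length
    shortened, time lengthened, in percent of the unperturbed value).
    Deterministic given ``subject_seed``.
    """
    rng = np.random.default_rng(subject_seed)
    proto = config.protocol
    per_seg = config.resolved_strides_per_segment()
    n = per_seg * proto.n_segments

    subj_mean_sl = float(_draw_positive(rng, profile.mean_sl_pct,
                                        profile.sd_sl_between, 1)[0])
    subj_mean_st = float(_draw_positive(rng, profile.mean_st_s,
                                        profile.sd_st_between, 1)[0])
    lengths = _draw_positive(rng, subj_mean_sl,
                             subj_mean_sl * profile.cov_sl_pct / 100.0, n)
    times = _draw_positive(rng, subj_mean_st,
                           subj_mean_st * profile.cov_st_pct / 100.0, n)
    gap_lo, gap_hi = config.turn_duration_s
    gaps = rng.uniform(gap_lo, gap_hi, proto.expected_turns)

    tags = ["none"] * n
    for t in range(proto.expected_turns):
        i_before = (t + 1) * per_seg - 1
        i_after = (t + 1) * per_seg
        tags[i_before] = "before_turn"
        tags[i_after] = "after_turn"
        if config.periturn_scope in ("after_only", "before_and_after"):
            lengths[i_after] *= 1 - config.periturn_delta_len_pct / 100.0
            times[i_after] *= 1 + config.periturn_delta_time_pct / 100.0
        if config.periturn_scope == "before_and_after":
            lengths[i_before] *= 1 - config.periturn_delta_len_pct / 100.0
            times[i_before] *= 1 + config.periturn_delta_time_pct / 100.0

    records = []
    onset = 0.0
    for i in range(n):
        records.append(StrideRecord(index=i, onset_s=onset,
                                    length_pct_stature=float(lengths[i]),
                                    time_s=float(times[i]),
                                    periturn_tag=tags[i]))
        onset += float(times[i])
        if (i + 1) % per_seg == 0 and (i + 1) // per_seg <= proto.expected_turns:
            onset += float(gaps[(i + 1) // per_seg - 1])

    return GaitTrial(subject_id=subject_id or f"{profile.group}_{subject_seed}",
                     group=profile.group, protocol=proto, records=records)


def generate_cohort(profiles: Sequence[CohortProfile],
                    n_per_group: dict[str, int],
                    config_by_group: dict[str, GeneratorConfig],
                    seed: int) -> list[GaitTrial]:
    """Simulate a multi-group cohort, reproducibly.

    Per-subject seeds are spawned from the master seed with
    :class:`numpy.random.SeedSequence`, so the same (profiles, counts,
    configs, seed) always yields the identical cohort.
    """
    trials: list[GaitTrial] = []
    ss = np.random.SeedSequence(seed)
    for profile in profiles:
        n = n_per_group.get(profile.group, 0)
        config = config_by_group[profile.group]
        children = ss.spawn(n)
        for j, child in enumerate(children):
            subject_seed = int(child.generate_state(1)[0] % (2**31))
            trials.append(generate_trial(
                profile, config, subject_seed,
                subject_id=f"{profile.group}{j:03d}"))
    return trials


def _find_gap_positions(trial: GaitTrial) -> list[int]:
    """Indices i such that a timestamp gap follows record i."""
    onsets, times = trial.onsets, trial.times
    slack = onsets[1:] - (onsets[:-1] + times[:-1])
    # anything beyond float fuzz counts as a structural gap here
    return [int(i) for i in np.nonzero(slack > 0.5 * np.median(times))[0]]


def inject_missed_turn(trial: GaitTrial, turn_ordinal: int,
                       n_turn_strides: int = 4,
                       shrink_factor: float = 0.4) -> GaitTrial:
    """Replace one turn gap with short 'turning' strides (a non-detected turn).

    Emulates the failure mode where the excision algorithm misses a turn:
    the gap disappears and drastically shorter strides — length
    ``shrink_factor`` x the subject's mean stride length — fill its
    duration, contaminating the export and inflating the CoV.  With
    ``n_turn_strides = 0`` the gap is simply closed (strides made
    contiguous).
    """
    if not 0 < shrink_factor < 1:
        raise ValueError("shrink_factor must be in (0, 1)")
    gap_positions = _find_gap_positions(trial)
    if not 0 <= turn_ordinal < len(gap_positions):
        raise IndexError(
            f"turn_ordinal {turn_ordinal} out of range; trial has "
            f"{len(gap_positions)} gaps")
    i = gap_positions[turn_ordinal]
    before, after = trial.records[i], trial.records[i + 1]
    gap_start = before.onset_s + before.time_s
    gap_dur = after.onset_s - gap_start
    mean_sl = float(trial.lengths.mean())

    new_records = list(trial.records[: i + 1])
    if n_turn_strides > 0:
        step = gap_dur / n_turn_strides
        for k in range(n_turn_strides):
            new_records.append(StrideRecord(
                index=0, onset_s=gap_start + k * step,
                length_pct_stature=shrink_factor * mean_sl,
                time_s=step, periturn_tag="turning"))
        new_records.extend(trial.records[i + 1:])
    else:
        shift = gap_dur
        new_records.extend(replace(r, onset_s=r.onset_s - shift)
                           for r in trial.records[i + 1:])
    return trial.with_records(new_records)
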