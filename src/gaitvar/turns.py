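"""Turn detection, QC, segmentation, peri-turn extraction and excision.

Turns are detected as gaps in the stride timestamp series: an inter-onset
interval larger than ``gap_factor`` times the subject's own median stride
time marks a turn.  Trials where a turn went undetected (too few gaps, or
implausibly short strides leaking into the export) are flagged and
excluded from downstream statistics rather than repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    GaitTrial,
    MISSED_TURN,
    ProtocolSpec,
    QCReport,
    SHORT_STRIDES,
    StrideRecord,
    TurnEvent,
)

logger = logging.getLogger(__name__)

DEFAULT_GAP_FACTOR = 1.5
DEFAULT_SHORT_STRIDE_FRAC = 0.5


def detect_turn_gaps(trial: GaitTrial,
                     gap_factor: float = DEFAULT_GAP_FACTOR) -> list[TurnEvent]:
    """Detect turns as timestamp gaps.

    A :class:`TurnEvent` is emitted wherever the inter-onset interval
    ``onset[i+1] - onset[i]`` exceeds ``gap_factor`` times the median
    stride time, i.e. the slack beyond the stride itself exceeds
    ``(gap_factor - 1)`` median stride times.  Normalizing by the
    subject's own median makes the rule robust to individual tempo.
    """
    if len(trial) < 2:
        return []
    onsets, times = trial.onsets, trial.times
    med = float(np.median(times))
    events = []
    for i in range(len(trial) - 1):
        if onsets[i + 1] - onsets[i] > gap_factor * med:
            events.append(TurnEvent(gap_start_s=float(onsets[i] + times[i]),
                                    gap_end_s=float(onsets[i + 1]),
                                    idx_before=i, idx_after=i + 1))
    return events


def qc_trial(trial: GaitTrial, turns: list[TurnEvent], protocol: ProtocolSpec,
             short_stride_frac: float = DEFAULT_SHORT_STRIDE_FRAC) -> QCReport:
    """Screen a trial for non-detected turns.

    Two automated proxies for the visual check of the stride-series plot:
    fewer gaps than the protocol's expected turn count
    (``missed_turn_suspected``), and any stride not adjacent to a gap
    shorter than ``short_stride_frac`` of the trial's median stride length
    (``implausible_short_strides`` — turning strides are drastically
    short).  Either flag excludes the trial.
    """
    flags = []
    if len(turns) < protocol.expected_turns:
        flags.append(MISSED_TURN)
    adjacent = set()
    for t in turns:
        if t.idx_before is not None:
            adjacent.add(t.idx_before)
        if t.idx_after is not None:
            adjacent.add(t.idx_after)
    lengths = trial.lengths
    if len(lengths):
        med_sl = float(np.median(lengths))
        for i, v in enumerate(lengths):
            if i not in adjacent and v < short_stride_frac * med_sl:
                flags.append(SHORT_STRIDES)
                break
    return QCReport(subject_id=trial.subject_id, n_turns_detected=len(turns),
                    n_turns_expected=protocol.expected_turns, flags=flags)


@dataclass
class SegmentedTrial:
    """A trial partitioned into straight-walking segments between turns.

    ``segments`` holds ordered record-index lists; records tagged
    ``turning`` (possible only with a missed-turn artifact) belong to no
    segment.  Always ``len(segments) == len(turns) + 1``.
    """

    trial: GaitTrial
    turns: list[TurnEvent]
    segments: list[list[int]]
    qc: QCReport = None  # type: ignore[assignment]

    @property
    def analyzed_records(self) -> list[StrideRecord]:
        """All segmented records in onset order (turning strides dropped)."""
        return [self.trial.records[i] for seg in self.segments for i in seg]


def segment_by_turns(trial: GaitTrial, turns: list[TurnEvent]) -> SegmentedTrial:
    """Partition records into the straight segments between detected turns."""
    boundaries = [t.idx_after if t.idx_after is not None else len(trial)
                  for t in turns]
    segments: list[list[int]] = []
    start = 0
    for b in boundaries + [len(trial)]:
        seg = [i for i in range(start, b)
               if trial.records[i].periturn_tag != "turning"]
        segments.append(seg)
        start = b
    if segments and not segments[0]:
        logger.warning("%s: first segment is empty", trial.subject_id)
    return SegmentedTrial(trial=trial, turns=list(turns), segments=segments)


@dataclass
class PeriTurnSet:
    """Strides directly before/after used turns for one subject, plus the
    subject's reference means over the first ``n`` analyzed strides."""

    subject_id: str
    group: str
    before: list[StrideRecord] = field(default_factory=list)
    after: list[StrideRecord] = field(default_factory=list)
    ref_mean_sl: float = float("nan")
    ref_mean_st: float = float("nan")


def extract_periturn_strides(cohort: list[SegmentedTrial],
                             reference_n: int = 40) -> list[PeriTurnSet]:
    """Pull the single strides adjacent to each used turn, per subject.

    Turns used per trial are capped at ``protocol.max_turns_used`` (the
    healthy-elderly protocol uses only the first two).  The per-subject
    reference means are taken over the first ``reference_n`` analyzed
    strides — the same window the cumulative analyses use.  Callers must
    drop QC-excluded trials first.
    """
    out = []
    for seg in cohort:
        trial = seg.trial
        ps = PeriTurnSet(subject_id=trial.subject_id, group=trial.group)
        used = seg.turns[: trial.protocol.max_turns_used]
        for t in used:
            if t.idx_before is not None:
                ps.before.append(trial.records[t.idx_before])
            if t.idx_after is not None:
                ps.after.append(trial.records[t.idx_after])
        ref = seg.analyzed_records[:reference_n]
        if ref:
            ps.ref_mean_sl = float(np.mean([r.length_pct_stature for r in ref]))
            ps.ref_mean_st = float(np.mean([r.time_s for r in ref]))
        out.append(ps)
    return out


def apply_extra_excision(seg: SegmentedTrial, width: int) -> list[StrideRecord]:
    """Generous turn excision: drop ``width`` extra strides per gap side.

    Removes the ``width`` strides nearest each turn gap on each side
    (fewer if a segment is shorter), modeling a stricter segmentation than
    the vendor's.  ``width=0`` returns all segmented strides unchanged;
    order is preserved.  A 40-stride, 4-turn trial at ``width=1`` keeps 32
    strides, which is why the cumulative analyses are referenced to 32
    under this mode.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    n_seg = len(seg.segments)
    kept: list[StrideRecord] = []
    for s, indices in enumerate(seg.segments):
        trim_front = width if s > 0 else 0          # side facing previous gap
        trim_back = width if s < n_seg - 1 else 0   # side facing next gap
        retained = indices[trim_front: len(indices) - trim_back]
        if trim_front + trim_back >= len(indices):
            retained = []
        kept.extend(seg.trial.records[i] for i in retained)
    return kept
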