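"""Domain types for stride-wise gait records.

An ambulatory gait-analysis system exports, after algorithmic turn excision,
one row per stride: an onset timestamp, the stride length (normalized to
percent of body stature) and the stride time (gait cycle duration).  Turns
show up as *gaps* in the timestamp series.  These types carry that tabular
export plus protocol metadata through the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Allowed values for :attr:`StrideRecord.periturn_tag`.
PERITURN_TAGS = ("none", "before_turn", "after_turn", "turning")

#: Group labels used throughout: healthy elderly, cerebellar ataxia,
#: essential tremor, Parkinson's disease.
GROUPS = ("HE", "ATX", "ET", "PD")


@dataclass(frozen=True)
class StrideRecord:
    """A single stride (gait cycle) in a trial.

    Parameters
    ----------
    index
        Ordinal position within the trial, 0-based and contiguous.
    onset_s
        Stride onset in seconds from trial start.
    length_pct_stature
        Stride length as percent of body height.
    time_s
        Stride duration (gait cycle time) in seconds.
    periturn_tag
        Position relative to a turn: ``none``, ``before_turn``,
        ``after_turn`` or ``turning`` (a stride taken *during* a turn,
        which a correctly working excision algorithm would have removed).
    """

    index: int
    onset_s: float
    length_pct_stature: float
    time_s: float
    periturn_tag: str = "none"

    def __post_init__(self) -> None:
        if self.periturn_tag not in PERITURN_TAGS:
            raise ValueError(
                f"periturn_tag must be one of {PERITURN_TAGS}, "
                f"got {self.periturn_tag!r}"
            )


@dataclass(frozen=True)
class ProtocolSpec:
    """Walking protocol: straight segments separated by 180-degree turns.

    ``max_turns_used`` caps how many turns contribute strides to the
    peri-turn analysis (the healthy-elderly protocol uses only the first
    two turns, the minimum every participant performed).
    """

    name: str
    segment_length_m: float
    n_segments: int
    max_turns_used: int

    @property
    def expected_turns(self) -> int:
        return self.n_segments - 1

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.max_turns_used > self.expected_turns:
            raise ValueError("max_turns_used cannot exceed expected_turns")


#: Movement-disorders protocol: 10 m segment walked five times back and
#: forth (four turns, all used for peri-turn extraction).
MD_PROTOCOL = ProtocolSpec(name="MD", segment_length_m=10.0, n_segments=5,
                           max_turns_used=4)

#: Healthy-elderly protocol: 20 m segment back and forth for about one
#: minute; three segments analyzed, first two turns used.
HE_PROTOCOL = ProtocolSpec(name="HE", segment_length_m=20.0, n_segments=3,
                           max_turns_used=2)

PROTOCOLS = {"MD": MD_PROTOCOL, "HE": HE_PROTOCOL}


@dataclass
class GaitTrial:
    """One subject's ordered stride series plus metadata.

    Invariants: record onsets strictly increasing; indices contiguous
    from 0.  Use :func:`gaitvar.io.validate_trial` to check them.
    """

    subject_id: str
    group: str
    protocol: ProtocolSpec
    records: list[StrideRecord] = field(default_factory=list)
    stature_m: Optional[float] = None

    def __len__(self) -> int:
        return len(self.records)

    # Convenience array views -------------------------------------------------

    @property
    def onsets(self) -> np.ndarray:
        return np.array([r.onset_s for r in self.records], dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length_pct_stature for r in self.records], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_s for r in self.records], dtype=float)

    @property
    def tags(self) -> list[str]:
        return [r.periturn_tag for r in self.records]

    def parameter(self, name: str) -> np.ndarray:
        """Return the stride-wise series for ``'SL'`` (length, %stature)
        or ``'ST'`` (time, s)."""
        if name == "SL":
            return self.lengths
        if name == "ST":
            return self.times
        raise ValueError(f"unknown parameter {name!r}; expected 'SL' or 'ST'")

    def with_records(self, records: list[StrideRecord]) -> "GaitTrial":
        """Copy of the trial with a new record list (indices rewritten)."""
        reindexed = [replace(r, index=i) for i, r in enumerate(records)]
        return GaitTrial(subject_id=self.subject_id, group=self.group,
                         protocol=self.protocol, records=reindexed,
                         stature_m=self.stature_m)


@dataclass(frozen=True)
class TurnEvent:
    """A turn detected as a timestamp gap between consecutive strides.

    ``gap_start_s`` is the end of the last stride before the gap
    (onset + duration); ``gap_end_s`` the onset of the first stride after.
    """

    gap_start_s: float
    gap_end_s: float
    idx_before: Optional[int]
    idx_after: Optional[int]

    def __post_init__(self) -> None:
        if self.gap_end_s <= self.gap_start_s:
            raise ValueError("gap_end_s must exceed gap_start_s")
        if self.idx_before is not None and self.idx_after is not None:
            if self.idx_after != self.idx_before + 1:
                raise ValueError("gap must separate adjacent records")

    @property
    def duration_s(self) -> float:
        return self.gap_end_s - self.gap_start_s


# QC flag labels
MISSED_TURN = "missed_turn_suspected"
SHORT_STRIDES = "implausible_short_strides"
TOO_FEW_STRIDES = "too_few_strides"


@dataclass
class QCReport:
    """Quality-control outcome for one trial.

    A trial is excluded whenever a missed turn is suspected — either
    because fewer gaps than expected were found, or because implausibly
    short strides (turning strides leaking into the export) are present.
    """

    subject_id: str
    n_turns_detected: int
    n_turns_expected: int
    flags: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return MISSED_TURN in self.flags or SHORT_STRIDES in self.flags
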