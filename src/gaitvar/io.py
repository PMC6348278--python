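"""Readers/writers for the stride-table CSV dialect and cohort manifests.

The vendor's native export schema is not public, so the package defines its
own documented dialect: UTF-8 CSV, header row, ``.`` decimal separator,
columns ``subject_id, group, stride_index, onset_s,
stride_length_pct_stature, stride_time_s, periturn_tag``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .model import (
    GaitTrial,
    PERITURN_TAGS,
    PROTOCOLS,
    ProtocolSpec,
    StrideRecord,
    TOO_FEW_STRIDES,
)

logger = logging.getLogger(__name__)

STRIDE_COLUMNS = [
    "subject_id",
    "group",
    "stride_index",
    "onset_s",
    "stride_length_pct_stature",
    "stride_time_s",
    "periturn_tag",
]

MANIFEST_COLUMNS = ["subject_id", "group", "path", "protocol"]


class TrialFormatError(ValueError):
    """Raised when a stride table does not follow the documented schema."""


class TrialValidationError(ValueError):
    """Raised when stride values violate domain invariants."""


def read_trial_table(path: Union[str, Path], protocol: ProtocolSpec) -> GaitTrial:
    """Read one stride table into a :class:`GaitTrial`.

    Records are sorted by onset (a warning is logged if the file was out
    of order) and indices rewritten to be contiguous from 0.
    """
    path = Path(path)
    # round_trip parsing: the writer emits %.17g, so values are exact
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STRIDE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing columns {missing}")
    if len(df.columns) != len(set(df.columns)):
        raise TrialFormatError(f"{path}: duplicate columns")
    if df.empty:
        raise TrialFormatError(f"{path}: no data rows")

    for i, row in enumerate(df.itertuples(index=False)):
        if not row.stride_time_s > 0:
            raise TrialValidationError(
                f"{path} row {i}: stride_time_s must be > 0, "
                f"got {row.stride_time_s}")
        if not row.stride_length_pct_stature > 0:
            raise TrialValidationError(
                f"{path} row {i}: stride_length_pct_stature must be > 0, "
                f"got {row.stride_length_pct_stature}")
        if row.periturn_tag not in PERITURN_TAGS:
            raise TrialValidationError(
                f"{path} row {i}: bad periturn_tag {row.periturn_tag!r}")

    if not df["onset_s"].is_monotonic_increasing:
        logger.warning("%s: onsets out of order; re-sorting", path)
        df = df.sort_values("onset_s", kind="stable")

    records = [
        StrideRecord(index=i, onset_s=float(r.onset_s),
                     length_pct_stature=float(r.stride_length_pct_stature),
                     time_s=float(r.stride_time_s),
                     periturn_tag=str(r.periturn_tag))
        for i, r in enumerate(df.itertuples(index=False))
    ]
    return GaitTrial(subject_id=str(df["subject_id"].iloc[0]),
                     group=str(df["group"].iloc[0]),
                     protocol=protocol, records=records)


def write_trial_table(trial: GaitTrial, path: Union[str, Path]) -> None:
    """Write a trial as a stride-table CSV (round-trips to full precision)."""
    if not trial.records:
        raise ValueError("refusing to write a trial with no records")
    df = trial_to_frame(trial)
    # %.17g guarantees binary round-trip of IEEE doubles
    df.to_csv(path, index=False, float_format="%.17g")


def trial_to_frame(trial: GaitTrial) -> pd.DataFrame:
    """Tabular view of a trial in the documented column schema."""
    return pd.DataFrame({
        "subject_id": trial.subject_id,
        "group": trial.group,
        "stride_index": [r.index for r in trial.records],
        "onset_s": [r.onset_s for r in trial.records],
        "stride_length_pct_stature": [r.length_pct_stature for r in trial.records],
        "stride_time_s": [r.time_s for r in trial.records],
        "periturn_tag": [r.periturn_tag for r in trial.records],
    })


def validate_trial(trial: GaitTrial, min_strides: int = 40) -> list[str]:
    """Report invariant violations; an empty list means the trial is clean.

    Checks positivity of lengths/times, non-negative and strictly
    increasing onsets, contiguous 0-based indices, and the minimum stride
    count required for analysis.
    """
    issues: list[str] = []
    for r in trial.records:
        if r.onset_s < 0:
            issues.append(f"record {r.index}: negative onset {r.onset_s}")
        if not r.time_s > 0:
            issues.append(f"record {r.index}: non-positive time {r.time_s}")
        if not r.length_pct_stature > 0:
            issues.append(
                f"record {r.index}: non-positive length {r.length_pct_stature}")
    onsets = trial.onsets
    if len(onsets) > 1 and not (onsets[1:] > onsets[:-1]).all():
        issues.append("onsets not strictly increasing")
    indices = [r.index for r in trial.records]
    if indices != list(range(len(indices))):
        issues.append("indices not contiguous from 0")
    if len(trial) < min_strides:
        issues.append(f"{TOO_FEW_STRIDES}: {len(trial)} < {min_strides}")
    return issues


def write_manifest(trials_and_paths: list[tuple[GaitTrial, Path]],
                   path: Union[str, Path]) -> None:
    """Write a cohort manifest listing per-subject stride-table files."""
    rows = [{"subject_id": t.subject_id, "group": t.group,
             "path": str(p), "protocol": t.protocol.name}
            for t, p in trials_and_paths]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: Union[str, Path]) -> list[GaitTrial]:
    """Load every trial listed in a cohort manifest.

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: manifest missing columns {missing}")
    trials = []
    for row in df.itertuples(index=False):
        proto = PROTOCOLS[str(row.protocol)]
        fp = Path(row.path)
        if not fp.is_absolute():
            fp = path.parent / fp
        trials.append(read_trial_table(fp, proto))
    return trials
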