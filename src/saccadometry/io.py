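"""File formats for saccade trajectories and participant feature tables.

Two plain-CSV dialects (UTF-8, comma separator, '.' decimal):

* **trajectory samples** — long format, one row per position sample:
  ``participant_id, group, task, trial_index, target_side, t_ms,
  position_deg``.  Times are milliseconds from peripheral-target onset, so
  saccade initiation sits at t = latency.  Positive position = rightward.
* **trial summaries** — one row per trial:
  ``participant_id, group, task, trial_index, target_side, foreperiod_s,
  latency_ms, amplitude_deg, peak_velocity_deg_s, direction_error,
  rejected, reject_reason``.

The native recorder format is proprietary; these dialects are the
package's interchange format and round-trip bit-exactly for finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SaccadeTrajectory",
    "TrajectoryValidationError",
    "write_trajectories",
    "read_trajectories",
    "write_feature_table",
    "read_feature_table",
]

SAMPLE_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "trial_index",
    "target_side",
    "t_ms",
    "position_deg",
]

SUMMARY_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "trial_index",
    "target_side",
    "foreperiod_s",
    "latency_ms",
    "amplitude_deg",
    "peak_velocity_deg_s",
    "direction_error",
    "rejected",
    "reject_reason",
]


class TrajectoryValidationError(ValueError):
    """Raised when a trajectory file violates the format's invariants."""


@dataclass
class SaccadeTrajectory:
    """One trial's sampled angular-position time series plus summaries.

    ``t_ms`` is milliseconds from peripheral-target onset at constant
    spacing; ``latency_ms``, ``amplitude_deg`` and ``peak_velocity_deg_s``
    are the device-reported per-saccade summaries.
    """

    participant_id: str
    group: str  # "PD" | "control"
    task: str  # "prosaccade" | "antisaccade"
    trial_index: int
    target_side: str  # "left" | "right"
    t_ms: np.ndarray
    position_deg: np.ndarray
    latency_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    foreperiod_s: float = np.nan
    direction_error: bool = False
    rejected: bool = False
    reject_reason: str = ""

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.position_deg = np.asarray(self.position_deg, dtype=float)
        if self.t_ms.shape != self.position_deg.shape:
            raise TrajectoryValidationError(
                f"trial {self.trial_key()}: t_ms and position_deg differ in length"
            )
        self.validate()

    def trial_key(self):
        return (self.participant_id, self.task, self.trial_index)

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if self.t_ms.size > 1 else np.nan

    def validate(self):
        if self.t_ms.size >= 2:
            dts = np.diff(self.t_ms)
            if np.any(dts <= 0):
                raise TrajectoryValidationError(
                    f"trial {self.trial_key()}: sample times not strictly increasing"
                )
            if not np.allclose(dts, dts[0], rtol=0, atol=1e-6):
                raise TrajectoryValidationError(
                    f"trial {self.trial_key()}: sampling interval varies"
                )
        if np.isfinite(self.latency_ms) and self.latency_ms < 0:
            raise TrajectoryValidationError(
                f"trial {self.trial_key()}: negative latency"
            )
        if np.isfinite(self.amplitude_deg) and self.amplitude_deg < 0:
            raise TrajectoryValidationError(
                f"trial {self.trial_key()}: negative amplitude"
            )


def write_trajectories(trajectories, samples_path, summary_path):
    """Write a collection of trajectories to the two-file CSV format."""
    sample_rows = []
    summary_rows = []
    for tr in trajectories:
        for t, p in zip(tr.t_ms, tr.position_deg):
            sample_rows.append(
                (tr.participant_id, tr.group, tr.task, tr.trial_index,
                 tr.target_side, t, p)
            )
        summary_rows.append(
            (tr.participant_id, tr.group, tr.task, tr.trial_index,
             tr.target_side, tr.foreperiod_s, tr.latency_ms, tr.amplitude_deg,
             tr.peak_velocity_deg_s, tr.direction_error, tr.rejected,
             tr.reject_reason)
        )
    pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS).to_csv(samples_path, index=False)
    pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS).to_csv(summary_path, index=False)


def read_trajectories(samples_path, summary_path):
    """Read trajectories written by :func:`write_trajectories`.

    Raises :class:`TrajectoryValidationError` naming the offending trial on
    schema or invariant violations (missing columns, non-monotone or
    unevenly spaced times).
    """
    samples = pd.read_csv(samples_path, float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise TrajectoryValidationError(f"samples file missing columns: {missing}")
    summary = pd.read_csv(
        summary_path, dtype={"reject_reason": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise TrajectoryValidationError(f"summary file missing columns: {missing}")

    keyed = {}
    if len(samples):
        for key, grp in samples.groupby(
            ["participant_id", "task", "trial_index"], sort=False
        ):
            keyed[key] = grp

    out = []
    for row in summary.itertuples(index=False):
        key = (row.participant_id, row.task, row.trial_index)
        grp = keyed.get(key)
        if grp is None:
            raise TrajectoryValidationError(f"trial {key}: no samples found")
        reason = row.reject_reason if isinstance(row.reject_reason, str) else ""
        out.append(
            SaccadeTrajectory(
                participant_id=str(row.participant_id),
                group=str(row.group),
                task=str(row.task),
                trial_index=int(row.trial_index),
                target_side=str(row.target_side),
                t_ms=grp["t_ms"].to_numpy(dtype=float),
                position_deg=grp["position_deg"].to_numpy(dtype=float),
                latency_ms=float(row.latency_ms),
                amplitude_deg=float(row.amplitude_deg),
                peak_velocity_deg_s=float(row.peak_velocity_deg_s),
                foreperiod_s=float(row.foreperiod_s),
                direction_error=bool(row.direction_error),
                rejected=bool(row.rejected),
                reject_reason=reason,
            )
        )
    return out


def write_feature_table(features: pd.DataFrame, path):
    """Write a participant feature table with stable column ordering.

    Columns: ``participant_id, group`` then the 61 features in vocabulary
    order.  Missing features become empty cells.  Duplicate participant ids
    are rejected.
    """
    from .features import FEATURE_NAMES

    if features["participant_id"].duplicated().any():
        dupes = features.loc[
            features["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    cols = ["participant_id", "group"] + [
        c for c in FEATURE_NAMES if c in features.columns
    ]
    features[cols].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "participant_id" not in df.columns or "group" not in df.columns:
        raise ValueError("feature table must contain participant_id and group")
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids in feature table")
    return df
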