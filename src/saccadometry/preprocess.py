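"""Saccade segmentation, kinematic summaries, response typing, and QC.

A saccade is the period for which eye velocity exceeds 5 deg/s.  Trials
are excluded as likely recording error when latency < 100 ms or
> 1,000 ms, amplitude > 40 deg, or peak velocity > 1,000 deg/s (strict
inequalities).  Antisaccade trials executed toward the target are
directional errors; prosaccade trials executed away from the target are
never analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QCConfig",
    "compute_velocity",
    "detect_saccade",
    "qc_filter",
    "label_direction_error",
]

PS_CORRECT = "PS_correct"
AS_CORRECT = "AS_correct"
AS_ERROR = "AS_error"
PS_ERROR = "PS_error"
INVALID = "invalid"

RESPONSE_TYPES = (PS_CORRECT, AS_CORRECT, AS_ERROR)


@dataclass
class QCConfig:
    """Sanitization thresholds (all strict inequalities)."""

    latency_min_ms: float = 100.0
    latency_max_ms: float = 1000.0
    amplitude_max_deg: float = 40.0
    peak_velocity_max_deg_s: float = 1000.0
    velocity_threshold_deg_s: float = 5.0
    sigma_se_max: float = 0.5
    smooth_velocity: bool = False  # optional 3-point moving average

    def __post_init__(self):
        if self.latency_min_ms >= self.latency_max_ms:
            raise ValueError("latency_min_ms must be < latency_max_ms")
        for name in (
            "latency_min_ms",
            "amplitude_max_deg",
            "peak_velocity_max_deg_s",
            "velocity_threshold_deg_s",
            "sigma_se_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_velocity(trajectory, smooth=False):
    """Finite-difference velocity in deg/s.

    Central differences at interior samples, one-sided at the ends.
    Requires at least 3 samples at constant dt.  With ``smooth`` a 3-point
    moving average is applied afterwards.
    """
    t = np.asarray(trajectory.t_ms, dtype=float)
    y = np.asarray(trajectory.position_deg, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples to compute velocity")
    v = np.gradient(y, t / 1000.0)  # central interior, one-sided ends
    if smooth:
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    return v


def detect_saccade(velocity, threshold=5.0):
    """Locate the first contiguous supra-threshold run of |velocity|.

    Returns ``(start_index, end_index)`` (inclusive) of the first run with
    |v| > threshold, or ``None`` if the threshold is never exceeded.
    """
    v = np.abs(np.asarray(velocity, dtype=float))
    if v.size == 0:
        raise ValueError("empty velocity series")
    above = v > threshold
    if not above.any():
        return None
    start = int(np.argmax(above))
    after = above[start:]
    drop = np.argmin(after)  # first False after start; 0 if none
    end = start + (int(drop) - 1 if not after.all() else after.size - 1)
    return start, end


# QC reasons, in the order checked; a rejection carries the first match.
_REASONS = ("latency_low", "latency_high", "amplitude_high", "peak_velocity_high")


def _qc_reason(latency, amplitude, peak_velocity, cfg: QCConfig):
    if not (np.isfinite(latency) and np.isfinite(amplitude) and np.isfinite(peak_velocity)):
        return "invalid"
    if latency < cfg.latency_min_ms:
        return "latency_low"
    if latency > cfg.latency_max_ms:
        return "latency_high"
    if amplitude > cfg.amplitude_max_deg:
        return "amplitude_high"
    if peak_velocity > cfg.peak_velocity_max_deg_s:
        return "peak_velocity_high"
    return None


def qc_filter(saccades, config: QCConfig | None = None):
    """Partition saccades into (kept, rejected) by the sanitization rules.

    ``rejected`` is a list of ``(saccade, reason)`` pairs; every saccade
    appears in exactly one of the outputs.  Saccades with missing summary
    fields are rejected with reason ``"invalid"``.
    """
    cfg = config or QCConfig()
    kept, rejected = [], []
    for s in saccades:
        reason = _qc_reason(s.latency_ms, s.amplitude_deg, s.peak_velocity_deg_s, cfg)
        if reason is None:
            kept.append(s)
        else:
            rejected.append((s, reason))
    return kept, rejected


def label_direction_error(saccade):
    """Classify a trial's response type from its net displacement sign.

    Positive position is rightward.  Prosaccades toward the target are
    ``PS_correct``; antisaccades away from the target are ``AS_correct``;
    antisaccades toward the target are ``AS_error`` (a reflexive prosaccade
    that escaped inhibition).  Prosaccades away from the target are
    ``PS_error`` and excluded downstream; zero net displacement is
    ``invalid``.
    """
    y = np.asarray(saccade.position_deg, dtype=float)
    net = y[-1] - y[0]
    if net == 0:
        return INVALID
    toward = (net > 0) == (saccade.target_side == "right")
    if saccade.task == "prosaccade":
        return PS_CORRECT if toward else PS_ERROR
    if saccade.task == "antisaccade":
        return AS_ERROR if toward else AS_CORRECT
    raise ValueError(f"unknown task {saccade.task!r}")
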