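"""Synthetic saccadometry cohorts.

Emulates a step-paradigm saccadometry protocol: a central fixation target,
peripheral targets at +/-10 deg chosen left/right with equal probability
after a truncated-exponential foreperiod of 1.0-2.0 s, recorded at 5 ms
resolution from 25 ms before saccade initiation to 20 ms after the
velocity criterion (5 deg/s) terminates the saccade.

Each trial's trajectory is the analytic second-order step response with
per-trial gain, damping ratio and natural frequency, plus additive
Gaussian measurement noise.  Group/task structure (PD vs. control,
prosaccade vs. antisaccade, antisaccade directional errors behaving like
delayed reflexive prosaccades) enters through the per-condition parameter
distributions; participants contribute random intercepts to latency,
damping, frequency and gain so that mixed-model analyses downstream see
genuine within-participant correlation.

Latencies are shifted-gamma (right-skewed, positive support); damping
ratio, natural frequency and gain are truncated normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .damping import step_response, step_response_velocity
from .io import SaccadeTrajectory
from .preprocess import AS_CORRECT, AS_ERROR, PS_CORRECT

__all__ = [
    "SimulationConfig",
    "default_config",
    "draw_foreperiod",
    "simulate_trajectory",
    "simulate_cohort",
]

GROUPS = ("PD", "control")
_RTYPES = (PS_CORRECT, AS_CORRECT, AS_ERROR)


def _default_latency_params():
    # (shift_ms, gamma shape, gamma scale_ms); mean = shift + shape*scale.
    # Condition means follow the reported contrasts: antisaccades ~121 ms
    # (control) / ~147 ms (PD) slower than prosaccades, AS errors ~14 ms
    # slower than prosaccades, PD slower than control by ~19 ms (PS) /
    # ~45 ms (AS).
    def p(mean):
        shape = 9.0
        return (100.0, shape, (mean - 100.0) / shape)

    return {
        ("control", PS_CORRECT): p(200.0),
        ("control", AS_CORRECT): p(320.9),
        ("control", AS_ERROR): p(214.6),
        ("PD", PS_CORRECT): p(219.0),
        ("PD", AS_CORRECT): p(366.1),
        ("PD", AS_ERROR): p(232.9),
    }


def _default_damping_params():
    # (sigma mean, per-trial sigma SD).  Antisaccades are more damped than
    # prosaccades (+0.06 control, +0.09 PD); AS errors sit close to
    # prosaccades (+0.03 control, +0.02 PD).
    sd = 0.25
    return {
        ("control", PS_CORRECT): (0.95, sd),
        ("control", AS_CORRECT): (1.01, sd),
        ("control", AS_ERROR): (0.98, sd),
        ("PD", PS_CORRECT): (1.00, sd),
        ("PD", AS_CORRECT): (1.09, sd),
        ("PD", AS_ERROR): (1.02, sd),
    }


def _default_amplitude_params():
    # (gain mean deg, per-trial SD): correct antisaccades overshoot in
    # controls (12.31 deg) but not in PD (10.52 deg); prosaccades and AS
    # errors land near the 10 deg eccentricity.
    sd = 1.2
    return {
        ("control", PS_CORRECT): (10.0, sd),
        ("control", AS_CORRECT): (12.31, sd),
        ("control", AS_ERROR): (10.0, sd),
        ("PD", PS_CORRECT): (10.0, sd),
        ("PD", AS_CORRECT): (10.52, sd),
        ("PD", AS_ERROR): (10.0, sd),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator."""

    n_pd: int = 25
    n_control: int = 26
    trials_per_task: int = 100
    dt_ms: float = 5.0
    eccentricity_deg: float = 10.0
    foreperiod_range_s: tuple = (1.0, 2.0)
    foreperiod_rate: float = 1.0
    latency_params: dict = field(default_factory=_default_latency_params)
    damping_params: dict = field(default_factory=_default_damping_params)
    amplitude_params: dict = field(default_factory=_default_amplitude_params)
    omega0_mean: float = 60.0
    omega0_sd: float = 10.0
    # device-calibrated position noise; kept well below the level at which
    # finite-difference velocity noise would swamp the 5 deg/s detection
    # threshold (fit robustness at higher noise is studied separately)
    noise_sd_deg: float = 0.01
    as_error_rate: dict = field(default_factory=lambda: {"PD": 0.25, "control": 0.18})
    # between-participant random-intercept SDs
    participant_latency_sd_ms: float = 20.0
    participant_sigma_sd: float = 0.08
    participant_omega0_sd: float = 5.0
    participant_gain_sd: float = 0.8
    velocity_threshold_deg_s: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pd, self.n_control, self.trials_per_task) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.foreperiod_range_s
        if not lo < hi:
            raise ValueError("foreperiod range must have low < high")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        for key, (m, sd) in self.damping_params.items():
            if m <= 0:
                raise ValueError(f"sigma mean must be positive for {key}")
        if self.omega0_mean <= 0:
            raise ValueError("omega0_mean must be positive")
        for g, r in self.as_error_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"as_error_rate[{g}] outside [0, 1]")

    def with_(self, **kwargs):
        return replace(self, **kwargs)


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def draw_foreperiod(range_s, rate, rng, size=None):
    """Truncated-exponential foreperiod draw(s) on ``range_s``.

    Density proportional to exp(-rate*x) on [low, high].  As rate -> 0 the
    distribution flattens to uniform; rates below 1e-9 use the uniform
    limit directly.
    """
    lo, hi = range_s
    if not lo < hi:
        raise ValueError("empty foreperiod interval")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    u = rng.uniform(size=size)
    if rate < 1e-9:
        return lo + u * (hi - lo)
    z = 1.0 - np.exp(-rate * (hi - lo))
    return lo - np.log1p(-u * z) / rate


def simulate_trajectory(A, sigma, omega0, dt_ms=5.0, duration_ms=200.0,
                        noise_sd=0.0, rng=None):
    """Sample the noisy step response at times 0, dt, 2dt, ...

    Returns ``(t_ms, position)`` arrays; with ``noise_sd = 0`` the samples
    match the analytic step response exactly.
    """
    if sigma <= 0 or omega0 <= 0 or dt_ms <= 0:
        raise ValueError("sigma, omega0 and dt_ms must be positive")
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    y = step_response(t, A, sigma, omega0)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return t, y


def _trunc_normal(rng, mean, sd, low):
    """Normal draw truncated below at ``low`` by rejection (fast here:
    truncation points are many SDs below the means in all defaults)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    return low + abs(rng.normal(0.0, sd))


def _saccade_duration_ms(sigma, omega0, gain, threshold):
    """First time the analytic velocity (deg/s) drops back below threshold."""
    grid = np.arange(0.0, 800.0, 0.5)
    v = np.abs(gain * step_response_velocity(grid, 1.0, sigma, omega0))
    above = v > threshold
    if not above.any():
        return 60.0
    start = int(np.argmax(above))
    after = above[start:]
    if after.all():
        return float(grid[-1])
    end = start + int(np.argmin(after)) - 1
    return float(grid[end])


def simulate_cohort(config: SimulationConfig | None = None,
                    include_trajectories=True):
    """Generate a full synthetic cohort.

    Returns ``(trajectories, truth)`` where ``trajectories`` is a list of
    :class:`~saccadometry.io.SaccadeTrajectory` and ``truth`` is a
    DataFrame with the per-trial generating parameters (latency, sigma,
    omega0, gain, response type) — ground truth for calibration studies.
    Reproducible: identical config (including seed) gives identical output.

    ``include_trajectories=False`` skips synthesizing the sampled position
    time series (returning an empty trajectory list and, in ``truth``,
    the gain in place of the settled amplitude with NaN peak velocity);
    the per-trial parameter draws are identical either way, which keeps
    large parameter-level simulation studies cheap.
    """
    cfg = config or SimulationConfig()
    # separate parameter and measurement-noise streams: the drawn trial
    # parameters are identical whether or not trajectories are synthesized
    param_ss, noise_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(param_ss)
    noise_rng = np.random.default_rng(noise_ss)
    trajectories = []
    truth_rows = []

    roster = [("PD", i, cfg.n_pd) for i in range(cfg.n_pd)]
    roster += [("control", i, cfg.n_control) for i in range(cfg.n_control)]

    for group, idx, _n in roster:
        pid = f"{'pd' if group == 'PD' else 'hc'}{idx:03d}"
        lat_off = rng.normal(0.0, cfg.participant_latency_sd_ms)
        sig_off = rng.normal(0.0, cfg.participant_sigma_sd)
        w_off = rng.normal(0.0, cfg.participant_omega0_sd)
        gain_off = rng.normal(0.0, cfg.participant_gain_sd)
        for task in ("prosaccade", "antisaccade"):
            for trial in range(cfg.trials_per_task):
                foreperiod = float(
                    draw_foreperiod(cfg.foreperiod_range_s, cfg.foreperiod_rate, rng)
                )
                side = "right" if rng.uniform() < 0.5 else "left"
                is_error = (
                    task == "antisaccade"
                    and rng.uniform() < cfg.as_error_rate[group]
                )
                if task == "prosaccade":
                    rtype = PS_CORRECT
                elif is_error:
                    rtype = AS_ERROR
                else:
                    rtype = AS_CORRECT

                shift, shape, scale = cfg.latency_params[(group, rtype)]
                latency = shift + lat_off + rng.gamma(shape, scale)
                latency = max(latency, 1.0)
                s_mean, s_sd = cfg.damping_params[(group, rtype)]
                sigma = _trunc_normal(rng, s_mean + sig_off, s_sd, 0.05)
                omega0 = _trunc_normal(rng, cfg.omega0_mean + w_off, cfg.omega0_sd, 20.0)
                g_mean, g_sd = cfg.amplitude_params[(group, rtype)]
                gain = _trunc_normal(rng, g_mean + gain_off, g_sd, 1.0)

                toward = rtype in (PS_CORRECT, AS_ERROR)
                sign = (1.0 if side == "right" else -1.0) * (1.0 if toward else -1.0)

                if not include_trajectories:
                    truth_rows.append(
                        dict(
                            participant_id=pid, group=group, task=task,
                            trial_index=trial, target_side=side,
                            response_type=rtype, foreperiod_s=foreperiod,
                            latency_ms=float(latency), sigma=float(sigma),
                            omega0=float(omega0), gain=float(gain),
                            amplitude_deg=float(gain),
                            peak_velocity_deg_s=np.nan,
                            direction_error=is_error,
                        )
                    )
                    continue

                dur = _saccade_duration_ms(
                    sigma, omega0, gain, cfg.velocity_threshold_deg_s
                )
                # recording window: 25 ms pre-initiation to 20 ms post-termination,
                # sampled on a grid aligned with initiation
                t_rel = np.arange(-25.0, dur + 20.0 + cfg.dt_ms / 2, cfg.dt_ms)
                pos = sign * gain * step_response(t_rel, 1.0, sigma, omega0)
                if cfg.noise_sd_deg > 0:
                    pos = pos + noise_rng.normal(0.0, cfg.noise_sd_deg, size=pos.size)
                t_ms = latency + t_rel

                fine = np.arange(0.0, dur + 0.25, 0.25)
                pv = float(
                    gain * np.max(np.abs(step_response_velocity(fine, 1.0, sigma, omega0)))
                )
                amp = float(gain * step_response(np.array([dur]), 1.0, sigma, omega0)[0])

                trajectories.append(
                    SaccadeTrajectory(
                        participant_id=pid,
                        group=group,
                        task=task,
                        trial_index=trial,
                        target_side=side,
                        t_ms=t_ms,
                        position_deg=pos,
                        latency_ms=float(latency),
                        amplitude_deg=abs(amp),
                        peak_velocity_deg_s=pv,
                        foreperiod_s=foreperiod,
                        direction_error=is_error,
                    )
                )
                truth_rows.append(
                    dict(
                        participant_id=pid,
                        group=group,
                        task=task,
                        trial_index=trial,
                        target_side=side,
                        response_type=rtype,
                        foreperiod_s=foreperiod,
                        latency_ms=float(latency),
                        sigma=float(sigma),
                        omega0=float(omega0),
                        gain=float(gain),
                        amplitude_deg=abs(amp),
                        peak_velocity_deg_s=pv,
                        direction_error=is_error,
                    )
                )

    return trajectories, pd.DataFrame(truth_rows)
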