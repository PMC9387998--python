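"""Second-order system identification for saccade trajectories.

A saccade is modelled as the step response of a linear second-order system
with gain ``A`` (normalized displacement), damping ratio ``sigma``
(dimensionless) and natural frequency ``omega0`` (rad/s).  The damping
ratio controls the trade-off between speed and terminal stability of the
movement: an underdamped system (sigma < 1) overshoots and oscillates
around the target, a critically damped system (sigma = 1) reaches it as
fast as possible without overshoot, and an overdamped system (sigma > 1)
creeps in monotonically.

Each observed trajectory is normalized to amplitude 1 and fitted from
saccade initiation onwards by bounded nonlinear least squares, with a
continuous time shift ``delta_t`` of up to +/-5 ms absorbing the limited
temporal resolution of the recording device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SecondOrderFit",
    "step_response",
    "step_response_velocity",
    "overshoot_fraction",
    "fit_second_order",
    "fit_samples",
    "filter_by_sigma_se",
]

# Width of the band around sigma = 1 inside which the critical-damping
# closed form is used; outside it the open under/overdamped branches are
# numerically stable.
_CRITICAL_BAND = 1e-6


def step_response(t_ms, A, sigma, omega0):
    """Analytic step response of a second-order system.

    Parameters
    ----------
    t_ms : array-like
        Times in milliseconds, measured from the step (saccade initiation).
        Negative times return 0 (Heaviside gating).
    A : float
        Gain: the asymptotic plateau, in normalized displacement units.
    sigma : float
        Damping ratio, > 0.
    omega0 : float
        Natural frequency in rad/s, > 0.

    Returns
    -------
    ndarray
        Displacement at each time, same shape as ``t_ms``.
    """
    if sigma <= 0 or omega0 <= 0:
        raise ValueError("sigma and omega0 must be positive")
    t = np.asarray(t_ms, dtype=float) / 1000.0  # seconds
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    if abs(sigma - 1.0) < _CRITICAL_BAND:
        y = 1.0 - np.exp(-omega0 * tp) * (1.0 + omega0 * tp)
    elif sigma < 1.0:
        wd = omega0 * np.sqrt(1.0 - sigma**2)
        y = 1.0 - np.exp(-sigma * omega0 * tp) / np.sqrt(1.0 - sigma**2) * np.sin(
            wd * tp + np.arccos(sigma)
        )
    else:
        s = np.sqrt(sigma**2 - 1.0)
        r_fast = omega0 * (sigma + s)  # fast decay rate
        r_slow = omega0 * (sigma - s)
        y = 1.0 + (
            (sigma - s) * np.exp(-r_fast * tp) - (sigma + s) * np.exp(-r_slow * tp)
        ) / (2.0 * s)
    out[pos] = A * y
    return out


def step_response_velocity(t_ms, A, sigma, omega0):
    """Analytic time derivative of :func:`step_response`, in units/s."""
    if sigma <= 0 or omega0 <= 0:
        raise ValueError("sigma and omega0 must be positive")
    t = np.asarray(t_ms, dtype=float) / 1000.0
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    if abs(sigma - 1.0) < _CRITICAL_BAND:
        v = omega0**2 * tp * np.exp(-omega0 * tp)
    elif sigma < 1.0:
        wd = omega0 * np.sqrt(1.0 - sigma**2)
        v = (omega0 / np.sqrt(1.0 - sigma**2)) * np.exp(-sigma * omega0 * tp) * np.sin(
            wd * tp
        )
    else:
        s = np.sqrt(sigma**2 - 1.0)
        r_fast = omega0 * (sigma + s)
        r_slow = omega0 * (sigma - s)
        v = (
            (sigma + s) * r_slow * np.exp(-r_slow * tp)
            - (sigma - s) * r_fast * np.exp(-r_fast * tp)
        ) / (2.0 * s)
    out[pos] = A * v
    return out


def overshoot_fraction(sigma):
    """Peak overshoot of the underdamped step response, as a fraction of the
    plateau: exp(-sigma*pi/sqrt(1-sigma^2)).  Defined for 0 < sigma < 1."""
    if not 0 < sigma < 1:
        raise ValueError("overshoot is defined for 0 < sigma < 1")
    return float(np.exp(-sigma * np.pi / np.sqrt(1.0 - sigma**2)))


@dataclass
class SecondOrderFit:
    """Result of fitting one saccade to the second-order step response.

    ``A`` is in normalized units (the observed trajectory is divided by its
    measured amplitude before fitting, so A ~ 1 with over/undershoot of the
    plateau expressed as deviations from 1).  ``sigma_se`` is the linearized
    standard error of the damping ratio; non-convergent fits carry
    ``sigma_se = inf`` so the precision filter always removes them.
    """

    A: float
    sigma: float
    omega0: float
    delta_t_ms: float
    mse: float
    sigma_se: float
    converged: bool


# Multi-start grid: one start per damping regime x slow/typical/fast
# saccade, to avoid branch-local minima.
_SIGMA_STARTS = (0.5, 1.0, 1.5)
_OMEGA0_STARTS = (30.0, 60.0, 120.0)

_LOWER = np.array([1e-6, 0.05, 5.0, -5.0])  # A, sigma, omega0, delta_t
_UPPER = np.array([3.0, 5.0, 500.0, 5.0])


def fit_samples(t_ms, position, amplitude=None):
    """Fit the second-order step response to post-initiation samples.

    Parameters
    ----------
    t_ms : array-like
        Sample times in ms with t=0 at saccade initiation.
    position : array-like
        Angular positions; sign-free after normalization.
    amplitude : float, optional
        Measured saccade amplitude used for normalization (signed net
        displacement).  Defaults to ``position[-1] - position[0]``.

    Returns
    -------
    SecondOrderFit
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(position, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 post-initiation samples to fit")
    if amplitude is None:
        amplitude = y[-1] - y[0]
    if amplitude == 0:
        return SecondOrderFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
    y_norm = (y - y[0]) / amplitude

    def residuals(p):
        A, sigma, omega0, dt = p
        return step_response(t + dt, A, sigma, omega0) - y_norm

    best = None
    for s0 in _SIGMA_STARTS:
        for w0 in _OMEGA0_STARTS:
            x0 = np.array([1.0, s0, w0, 0.0])
            try:
                sol = least_squares(
                    residuals, x0, bounds=(_LOWER, _UPPER), method="trf", xtol=1e-10
                )
            except Exception:
                continue
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost - 1e-12 or (
                abs(sol.cost - best.cost) <= 1e-12 and sol.x[1] < best.x[1]
            ):
                best = sol
    if best is None:
        return SecondOrderFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)

    A, sigma, omega0, dt = best.x
    n, p = t.size, 4
    ssr = 2.0 * best.cost
    mse = ssr / n
    # sigma hitting the box means the optimum is not interior -> unreliable
    at_bound = bool(
        np.any(np.isclose(best.x, _LOWER, atol=1e-8))
        or np.any(np.isclose(best.x, _UPPER, atol=1e-8))
    )
    sigma_se = np.inf
    if not at_bound and n > p:
        s2 = ssr / (n - p)
        JtJ = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(JtJ)
            if cov[1, 1] >= 0:
                sigma_se = float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
    converged = not at_bound and np.isfinite(sigma_se)
    return SecondOrderFit(
        float(A), float(sigma), float(omega0), float(dt), float(mse), sigma_se, converged
    )


def fit_second_order(trajectory, velocity_threshold=5.0):
    """Fit one :class:`~saccadometry.io.SaccadeTrajectory`.

    Initiation is the first sample whose absolute finite-difference velocity
    exceeds ``velocity_threshold`` (deg/s); the fit uses samples from there
    onwards, normalized by the trajectory's reported amplitude (signed by
    movement direction).
    """
    from .preprocess import compute_velocity, detect_saccade

    v = compute_velocity(trajectory)
    span = detect_saccade(v, velocity_threshold)
    if span is None:
        return SecondOrderFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
    start, _ = span
    t = trajectory.t_ms[start:] - trajectory.t_ms[start]
    y = trajectory.position_deg[start:]
    net = y[-1] - y[0]
    amp = trajectory.amplitude_deg
    signed_amp = np.sign(net) * abs(amp) if amp and np.isfinite(amp) else net
    if t.size < 6:
        raise ValueError("need at least 6 post-initiation samples to fit")
    return fit_samples(t, y, amplitude=signed_amp)


def filter_by_sigma_se(fits, max_se=0.5):
    """Keep fits whose damping-ratio standard error is acceptable.

    A fit survives iff it converged and ``sigma_se <= max_se`` — saccades
    whose damping ratio cannot be estimated with suitable precision
    (SE > 0.5 by default) are excluded from analysis.
    """
    return [f for f in fits if f.converged and f.sigma_se <= max_se]
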