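"""Second-order step response and damping-ratio estimation."""

import numpy as np
import pytest

from saccadometry.damping import (
    SecondOrderFit,
    filter_by_sigma_se,
    fit_samples,
    overshoot_fraction,
    step_response,
    step_response_velocity,
)
from saccadometry.synthetic import simulate_trajectory


class TestStepResponse:
    @pytest.mark.parametrize("sigma", [0.3, 0.7, 1.0, 1.5])
    def test_starts_at_rest_and_reaches_plateau(self, sigma):
        assert step_response([0.0], 2.5, sigma, 60)[0] == pytest.approx(0.0, abs=1e-12)
        assert step_response([-10.0], 2.5, sigma, 60)[0] == 0.0
        # asymptote is the gain for every damping regime
        assert step_response([3000.0], 2.5, sigma, 60)[0] == pytest.approx(2.5, abs=1e-3)

    def test_plateau_for_typical_saccade(self):
        # A=10 deg, sigma=0.7, omega0=60 rad/s settles to 10 deg by 300 ms
        val = step_response([300.0], 10.0, 0.7, 60.0)[0]
        assert val == pytest.approx(10.0, abs=1e-3)

    @pytest.mark.parametrize("sigma", [0.999, 1.001])
    def test_branch_continuity_at_critical_damping(self, sigma):
        t = np.linspace(0, 200, 4001)
        d = np.max(np.abs(step_response(t, 1, sigma, 60) - step_response(t, 1, 1.0, 60)))
        assert d < 1e-3

    @pytest.mark.parametrize("sigma", [0.3, 0.5, 0.7])
    def test_overshoot_identity(self, sigma):
        # classic underdamped overshoot: sup_t phi(t) = 1 + exp(-s*pi/sqrt(1-s^2))
        t = np.linspace(0, 1000, 200001)
        sup = np.max(step_response(t, 1.0, sigma, 50.0))
        assert sup - 1.0 == pytest.approx(overshoot_fraction(sigma), rel=5e-3)

    def test_overdamped_monotone_without_overshoot(self):
        t = np.linspace(0, 500, 5001)
        y = step_response(t, 1.0, 1.5, 50.0)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y <= 1.0 + 1e-12)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_velocity_is_derivative_of_position(self, sigma):
        t = np.linspace(0, 200, 20001)
        y = step_response(t, 1.0, sigma, 60.0)
        v = step_response_velocity(t, 1.0, sigma, 60.0)
        v_num = np.gradient(y, t / 1000.0)
        assert np.allclose(v[10:-10], v_num[10:-10], atol=1e-2 * np.max(np.abs(v)))

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            step_response([1.0], 1.0, -0.5, 60.0)
        with pytest.raises(ValueError):
            step_response([1.0], 1.0, 0.7, 0.0)
        with pytest.raises(ValueError):
            overshoot_fraction(1.2)


class TestFitting:
    def test_noiseless_self_consistency(self):
        t, y = simulate_trajectory(1.0, 0.7, 60.0, dt_ms=5, duration_ms=150)
        f = fit_samples(t, y, amplitude=1.0)
        assert f.converged
        assert f.sigma == pytest.approx(0.7, abs=0.01)
        assert f.omega0 == pytest.approx(60.0, rel=0.01)
        assert f.mse < 1e-8

    @pytest.mark.parametrize("sigma,omega0", [(0.5, 40.0), (1.0, 60.0), (1.3, 80.0)])
    def test_noiseless_recovery_across_regimes(self, sigma, omega0):
        t, y = simulate_trajectory(1.0, sigma, omega0, dt_ms=5, duration_ms=200)
        f = fit_samples(t, y, amplitude=1.0)
        assert f.sigma == pytest.approx(sigma, rel=0.01)
        assert f.omega0 == pytest.approx(omega0, rel=0.01)

    def test_time_shift_recovery(self):
        # samples taken 3 ms late relative to the true step
        t = np.arange(0.0, 150.0, 5.0)
        y = step_response(t + 3.0, 1.0, 0.7, 60.0)
        f = fit_samples(t, y, amplitude=1.0)
        assert f.delta_t_ms == pytest.approx(3.0, abs=1.0)
        assert f.sigma == pytest.approx(0.7, abs=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        t, y = simulate_trajectory(10.0, 0.8, 55.0, dt_ms=5, duration_ms=150,
                                   noise_sd=0.1, rng=rng)
        f1 = fit_samples(t, y, amplitude=10.0)
        c = 3.7
        f2 = fit_samples(t, c * y, amplitude=c * 10.0)
        assert f2.sigma == pytest.approx(f1.sigma, rel=1e-6)
        assert f2.omega0 == pytest.approx(f1.omega0, rel=1e-6)
        assert f2.delta_t_ms == pytest.approx(f1.delta_t_ms, abs=1e-6)

    def test_sigma_se_calibration_under_noise(self):
        # the linearized SE should track the empirical spread of sigma-hat
        # within a factor of 2
        rng = np.random.default_rng(11)
        est, ses = [], []
        for _ in range(80):
            t, y = simulate_trajectory(10.0, 0.9, 60.0, dt_ms=5, duration_ms=120,
                                       noise_sd=0.15, rng=rng)
            f = fit_samples(t, y, amplitude=10.0)
            if f.converged:
                est.append(f.sigma)
                ses.append(f.sigma_se)
        emp_sd = np.std(est)
        med_se = np.median(ses)
        assert emp_sd / 2 < med_se < emp_sd * 2
        assert np.mean(est) == pytest.approx(0.9, abs=0.05)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            fit_samples([0, 5, 10], [0, 0.5, 1.0])

    def test_degenerate_flat_trajectory_flags_nonconvergence(self):
        t = np.arange(0.0, 100.0, 5.0)
        f = fit_samples(t, np.zeros_like(t))
        assert not f.converged
        assert f.sigma_se == np.inf


class TestSigmaSEFilter:
    def test_threshold_is_strict(self):
        fits = [
            SecondOrderFit(1, 0.9, 60, 0, 1e-4, se, True)
            for se in (0.1, 0.49, 0.51, 2.0)
        ]
        kept = filter_by_sigma_se(fits, max_se=0.5)
        assert len(kept) == 2
        assert all(f.sigma_se <= 0.5 for f in kept)

    def test_nonconverged_always_excluded(self):
        fits = [SecondOrderFit(1, 0.9, 60, 0, 1e-4, 0.01, False)]
        assert filter_by_sigma_se(fits, max_se=np.inf) == []

    def test_empty_input(self):
        assert filter_by_sigma_se([], max_se=0.5) == []
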