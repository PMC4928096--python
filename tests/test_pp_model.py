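import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgauss

from pphrv.pp_model import (FitConfig, NARLParameters, ParameterTrajectory,
                            conditional_mean, fit_trajectory, hr_moments,
                            ig_pdf, local_loglikelihood, pack_params,
                            time_rescale, unpack_params)
from pphrv.rr_io import EventSeries
from pphrv.synthetic import simulate_renewal


class TestIgPdf:
    def test_normalization_by_quadrature(self):
        total, _ = integrate.quad(lambda x: ig_pdf(x, 0.8, 1200.0), 1e-9, 10.0)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_first_moment_by_quadrature(self):
        m, _ = integrate.quad(lambda x: x * ig_pdf(x, 0.8, 1200.0), 1e-9, 10.0)
        assert m == pytest.approx(0.8, abs=1e-6)

    @pytest.mark.parametrize("x,mu,shape", [(0.8, 0.8, 0.0), (0.0, 0.8, 100.0),
                                            (0.8, -1.0, 100.0)])
    def test_non_positive_arguments_rejected(self, x, mu, shape):
        with pytest.raises(ValueError):
            ig_pdf(x, mu, shape)


class TestHrMoments:
    def test_against_sampling_oracle(self):
        mu, shape = 0.8, 1500.0
        rng = np.random.default_rng(0)
        hr = 60.0 / rng.wald(mu, shape, size=10**6)
        mu_hr, sigma_hr = hr_moments(mu, shape)
        assert mu_hr == pytest.approx(hr.mean(), rel=3e-4)
        assert sigma_hr == pytest.approx(hr.std(), rel=3e-3)


class TestConditionalMean:
    def test_null_parameters_identity(self):
        p = NARLParameters(shape=1000.0, g1=np.zeros(3), g2=np.zeros((2, 2)))
        assert conditional_mean(p, np.zeros(3), 0.8) == pytest.approx(0.8)

    def test_hand_arithmetic(self):
        p = NARLParameters(shape=1000.0, g0=0.01, g1=np.array([0.5]))
        assert conditional_mean(p, np.array([0.02]), 0.8) == pytest.approx(0.82)

    def test_g2_symmetry_enforced_and_invariant(self):
        g2 = np.array([[0.1, 0.05], [0.05, -0.2]])
        p = NARLParameters(shape=1000.0, g1=np.zeros(2), g2=g2)
        l = np.array([0.3, -0.1])
        v1 = conditional_mean(p, l, 0.8)
        v2 = conditional_mean(
            NARLParameters(shape=1000.0, g1=np.zeros(2), g2=g2.T), l, 0.8)
        assert v1 == pytest.approx(v2, abs=1e-15)
        with pytest.raises(ValueError, match="symmetric"):
            NARLParameters(shape=1.0, g2=np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestLocalLoglikelihood:
    def test_single_interval_equals_log_pdf(self):
        ev = EventSeries.from_rr_intervals(np.full(30, 0.8), t_end=24.0)
        # window short enough that exactly one interval end falls inside
        cfg = FitConfig(window_w=0.79, weight_decay=0.0, censoring=False,
                        p1=1, p2=1, truncation=5, alpha=0.01)
        p = NARLParameters(shape=1200.0, g0=0.0, g1=np.zeros(1),
                           g2=np.zeros((1, 1)))
        t = ev.event_times[-1]  # exactly one interval end in (t-1, t]
        ll = local_loglikelihood(ev, p, t, cfg)
        expected = np.log(ig_pdf(0.8, 0.8, 1200.0))
        assert ll == pytest.approx(float(expected), abs=1e-10)

    def test_gradient_matches_finite_differences(self, renewal_events):
        cfg = FitConfig(step_delta=0.1)
        p = NARLParameters(shape=1200.0, g0=0.01,
                           g1=np.array([0.1, -0.05, 0.02]),
                           g2=np.array([[0.02, 0.01], [0.01, -0.03]]))
        t = 150.0
        _, grad = local_loglikelihood(renewal_events, p, t, cfg,
                                      with_grad=True)
        theta = pack_params(p, 3, 2)
        h = 1e-6
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (local_loglikelihood(renewal_events,
                                      unpack_params(tp, 3, 2), t, cfg)
                  - local_loglikelihood(renewal_events,
                                        unpack_params(tm, 3, 2), t, cfg)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_t_before_first_beat_rejected(self, renewal_events):
        p = NARLParameters(shape=1000.0)
        with pytest.raises(ValueError):
            local_loglikelihood(renewal_events, p, -1.0, FitConfig())


class TestFitTrajectory:
    def test_constant_parameter_recovery(self, fitted_trajectory):
        traj = fitted_trajectory
        post = traj.grid_times > 120.0
        mu_med = np.nanmedian(traj.mu_rr[post])
        assert abs(mu_med - 0.8) / 0.8 < 0.05
        sigma_true = np.sqrt(0.8**3 / 1500.0)
        sig_med = np.nanmedian(traj.sigma_rr[post])
        assert abs(sig_med - sigma_true) / sigma_true < 0.15

    def test_convergence_rate(self, fitted_trajectory):
        assert fitted_trajectory.converged.mean() > 0.9

    def test_positive_moments_where_converged(self, fitted_trajectory):
        c = fitted_trajectory.converged
        assert np.all(fitted_trajectory.mu_rr[c] > 0)
        assert np.all(fitted_trajectory.sigma_rr[c] > 0)

    def test_time_shift_invariance(self, renewal_events):
        cfg = FitConfig(step_delta=0.1)
        shift = 10.0  # an exact multiple of step_delta
        shifted = renewal_events.shifted(shift)
        t1 = fit_trajectory(renewal_events, cfg)
        t2 = fit_trajectory(shifted, cfg)
        np.testing.assert_allclose(t2.grid_times - shift, t1.grid_times,
                                   atol=1e-9)
        np.testing.assert_allclose(t2.mu_rr, t1.mu_rr, rtol=1e-7,
                                   atol=1e-10, equal_nan=True)
        np.testing.assert_allclose(t2.shape, t1.shape, rtol=1e-6)

    def test_step_change_tracked(self):
        ev = simulate_renewal(lambda t: 0.8 if t < 300 else 0.9,
                              2000.0, 600.0, seed=5)
        traj = fit_trajectory(ev, FitConfig(step_delta=0.25))
        late = traj.grid_times > 300 + 2 * traj.config.window_w
        mu_late = np.nanmedian(traj.mu_rr[late])
        assert abs(mu_late - 0.9) / 0.9 < 0.05

    def test_too_short_recording_rejected(self):
        ev = EventSeries.from_rr_intervals(np.full(40, 0.8))
        with pytest.raises(ValueError, match="short"):
            fit_trajectory(ev, FitConfig())


class TestTimeRescale:
    def test_true_parameters_give_uniform_rescaling(self, renewal_events):
        traj = ParameterTrajectory.constant(0.8, 1500.0, 0.0,
                                            renewal_events.t_end, step=1.0)
        g = time_rescale(renewal_events, traj)
        assert g.ks_distance < g.ks_bound95
        assert np.all((g.rescaled > 0) & (g.rescaled < 1))
        assert g.acf_within_fraction > 0.85

    def test_fitted_trajectory_passes(self, renewal_events,
                                      fitted_trajectory):
        g = time_rescale(renewal_events, fitted_trajectory)
        assert g.ks_distance < g.ks_bound95

    def test_coverage_over_seeds(self):
        # nominal 95% coverage of the KS bound on model-generated data
        passes = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            rr = rng.wald(0.8, 1500.0, size=400)
            ev = EventSeries.from_rr_intervals(rr)
            traj = ParameterTrajectory.constant(0.8, 1500.0, 0.0, ev.t_end,
                                                step=1.0)
            g = time_rescale(ev, traj)
            passes += g.ks_distance < g.ks_bound95
        assert passes >= 34  # >= 85% of 40 at nominal 95%

    def test_too_few_intervals_rejected(self):
        ev = EventSeries.from_rr_intervals(np.full(5, 0.8))
        traj = ParameterTrajectory.constant(0.8, 1500.0, 0.0, 4.0, step=1.0)
        with pytest.raises(ValueError, match="10 intervals"):
            time_rescale(ev, traj)
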