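"""Ground-truth simulator checks: determinism, stability, exact algebraic
identities, and agreement with independently derived covariances."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from neurodi import simulators as sim


class TestStableCoefficients:
    def test_ar1_draw_is_in_unit_interval(self):
        c = sim.draw_stable_ar_coefficients(1, np.random.default_rng(0))
        assert -1 < c[0] < 1

    def test_ar5_spectral_radius_below_one(self):
        c = sim.draw_stable_ar_coefficients(5, np.random.default_rng(1))
        comp = np.zeros((5, 5))
        comp[0] = c
        comp[1:, :-1] = np.eye(4)
        assert np.max(np.abs(np.linalg.eigvals(comp))) < 1.0

    def test_deterministic_given_seed(self):
        a = sim.draw_stable_ar_coefficients(5, np.random.default_rng(42))
        b = sim.draw_stable_ar_coefficients(5, np.random.default_rng(42))
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def linear_spec():
    return sim.LinearARSpec.random(np.random.default_rng(100), gamma=0.8)


class TestLinearAR:
    def test_bit_reproducible(self, linear_spec):
        x1, y1 = sim.simulate_linear_ar(linear_spec, 32, 20, seed=9)
        x2, y2 = sim.simulate_linear_ar(linear_spec, 32, 20, seed=9)
        assert np.array_equal(x1.data, x2.data)
        assert np.array_equal(y1.data, y2.data)

    def test_decoupled_limit_is_independent(self):
        rng = np.random.default_rng(101)
        spec = sim.LinearARSpec.random(rng, gamma=0.0)
        x, y = sim.simulate_linear_ar(spec, 2048, 10, seed=10)
        r = np.corrcoef(x.data.ravel(), y.data.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_stationary_after_burn_in(self, linear_spec):
        x, y = sim.simulate_linear_ar(linear_spec, 4096, 40, seed=11)
        for ens in (x, y):
            var = ens.data.var(axis=0)
            assert var[-1] / var[0] < 1.5 and var[0] / var[-1] < 1.5

    def test_cross_covariance_matches_lyapunov_solution(self):
        # stationary covariance of the joint VAR from the discrete Lyapunov
        # equation (Yule-Walker in companion form) as independent oracle;
        # moderate spectral radii so the burn-in reaches stationarity
        rng = np.random.default_rng(200)
        while True:
            s = sim.LinearARSpec.random(rng, gamma=0.8)
            if (sim.ar_spectral_radius(s.alpha) < 0.8
                    and sim.ar_spectral_radius(s.beta) < 0.8):
                break
        p = 5
        A = np.zeros((2 * p, 2 * p))
        A[0, :p] = s.alpha
        A[1:p, : p - 1] = np.eye(p - 1)
        A[p, :p] += s.gamma  # coupling sum over lags p1..p2 = 1..5
        A[p, p : 2 * p] += s.beta
        A[p + 1 : 2 * p, p : 2 * p - 1] = np.eye(p - 1)
        Q = np.zeros((2 * p, 2 * p))
        Q[0, 0] = s.sigma_x**2
        Q[p, p] = s.sigma_y**2
        S = solve_discrete_lyapunov(A, Q)
        n_trials = 8192
        # long burn-in: slow modes (spectral radius near 1) need far more
        # than the default 100 samples to reach the stationary covariance
        x, y = sim.simulate_linear_ar(s, n_trials, 12, seed=12, burn_in=1000)
        for (theo, a, b) in [
            (S[0, 0], x.data[:, -1], x.data[:, -1]),
            (S[p, p], y.data[:, -1], y.data[:, -1]),
            (S[0, p], x.data[:, -1], y.data[:, -1]),
            (S[1, p], x.data[:, -2], y.data[:, -1]),
        ]:
            emp = np.mean(a * b) - np.mean(a) * np.mean(b)
            se = np.sqrt((np.var(a) * np.var(b) + emp**2) / n_trials)
            assert emp == pytest.approx(theo, abs=3 * se + 1e-9)

    def test_unstable_spec_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            sim.LinearARSpec(alpha=[1.2], beta=[0.5])


class TestNonlinearAR:
    def test_sigmoid_output_bounded(self):
        rng = np.random.default_rng(102)
        spec = sim.NonlinearARSpec.random(rng, gamma=0.8)
        x, _ = sim.simulate_nonlinear_ar(spec, 128, 20, seed=13)
        from scipy.special import expit
        s = expit(-(spec.b1 + spec.b2 * x.data))
        # mathematically in (0, 1); float64 saturates at the bounds for
        # large |b2 * x|, so assert the closed interval plus interior mass
        assert np.all(s >= 0) and np.all(s <= 1)
        assert np.any((s > 0) & (s < 1))

    def test_zero_slope_means_constant_coupling(self):
        rng = np.random.default_rng(103)
        spec = sim.NonlinearARSpec.random(rng, gamma=0.8, b2=0.0)
        x, y = sim.simulate_nonlinear_ar(spec, 2048, 10, seed=14)
        r = np.corrcoef(x.data.ravel(), y.data.ravel())[0, 1]
        assert abs(r) < 0.05


class TestMixing:
    def test_identity_at_zero(self):
        rng = np.random.default_rng(104)
        from neurodi.ensemble import TrialEnsemble
        x = TrialEnsemble(rng.standard_normal((8, 10)))
        y = TrialEnsemble(rng.standard_normal((8, 10)))
        xe, ye = sim.apply_mixing(x, y, sim.MixingSpec(0.0))
        assert np.array_equal(xe.data, x.data)
        assert np.array_equal(ye.data, y.data)

    def test_half_gives_identical_mixtures(self):
        rng = np.random.default_rng(105)
        from neurodi.ensemble import TrialEnsemble
        x = TrialEnsemble(rng.standard_normal((8, 10)))
        y = TrialEnsemble(rng.standard_normal((8, 10)))
        xe, ye = sim.apply_mixing(x, y, sim.MixingSpec(0.5))
        assert np.allclose(xe.data, ye.data)

    def test_constant_arithmetic(self):
        from neurodi.ensemble import TrialEnsemble
        x = TrialEnsemble(np.full((2, 4), 2.0))
        y = TrialEnsemble(np.full((2, 4), 4.0))
        xe, ye = sim.apply_mixing(x, y, sim.MixingSpec(0.25))
        assert np.allclose(xe.data, 2.5) and np.allclose(ye.data, 3.5)

    def test_linearity_mix_then_average_equals_average_then_mix(self):
        rng = np.random.default_rng(106)
        from neurodi.ensemble import TrialEnsemble
        x = TrialEnsemble(rng.standard_normal((16, 10)))
        y = TrialEnsemble(rng.standard_normal((16, 10)))
        spec = sim.MixingSpec(0.3)
        xe, _ = sim.apply_mixing(x, y, spec)
        xm = TrialEnsemble(x.data.mean(axis=0, keepdims=True))
        ym = TrialEnsemble(y.data.mean(axis=0, keepdims=True))
        xe_m, _ = sim.apply_mixing(xm, ym, spec)
        assert np.allclose(xe.data.mean(axis=0), xe_m.data[0])


class TestSingleSource:
    def test_full_noise_limit_is_independent(self):
        rng = np.random.default_rng(107)
        spec = sim.SingleSourceSpec.random(rng, epsilon=1.0)
        x, y = sim.simulate_single_source(spec, 4096, 10, seed=15)
        r = np.corrcoef(x.data.ravel(), y.data.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_snr_span_covers_38_db(self):
        # SNR = 10 log10((1-eps)^2 var(S) / eps^2); the eps = 0.1 vs 0.9
        # difference is var(S)-free: 20 log10(81) ~ 38.15 dB
        rng = np.random.default_rng(108)
        spec_lo = sim.SingleSourceSpec.random(rng, epsilon=0.1)
        snrs = {}
        for eps in (0.1, 0.9):
            s = sim.SingleSourceSpec(alpha=spec_lo.alpha, epsilon=eps)
            x, y = sim.simulate_single_source(s, 4096, 20, seed=16)
            signal = (1 - eps) ** 2 * x.data.var()
            noise = np.mean((y.data - (1 - eps) * x.data) ** 2)
            snrs[eps] = 10 * np.log10(signal / noise)
        assert snrs[0.1] - snrs[0.9] == pytest.approx(20 * np.log10(81), abs=1.0)


class TestLorenz:
    def test_delay_in_samples(self):
        assert sim.LorenzSpec().delay_samples == 2
        with pytest.raises(ValueError):
            sim.LorenzSpec(t_p=0.015)

    def test_reproducible_and_shapes(self):
        spec = sim.LorenzSpec()
        a = sim.simulate_lorenz_pair(spec, 16, seed=17)
        b = sim.simulate_lorenz_pair(spec, 16, seed=17)
        assert len(a) == 6
        assert a[0].data.shape == (16, 10)
        for u, v in zip(a, b):
            assert np.array_equal(u.data, v.data)

    def test_decoupled_oscillators_are_independent(self):
        spec = sim.LorenzSpec(beta_coupling=0.0)
        ens = sim.simulate_lorenz_pair(spec, 2048, seed=18)
        r = np.corrcoef(ens[0].data.ravel(), ens[3].data.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_euler_step_halving_convergence(self):
        # against a dt = 0.0025 reference, the dt = 0.005 error must be
        # about half the dt = 0.01 error (forward Euler is O(dt))
        def x1_at_end(dt):
            n = int(round(1.0 / dt))
            spec = sim.LorenzSpec(dt=dt, t_p=0.02, n_total=n, n_discard=0)
            return sim.simulate_lorenz_pair(spec, 8, seed=19)[0].data[:, -1]

        ref = x1_at_end(0.0025)
        err_coarse = np.abs(x1_at_end(0.01) - ref).mean()
        err_fine = np.abs(x1_at_end(0.005) - ref).mean()
        assert err_fine < 0.75 * err_coarse


class TestSpecSerialization:
    def test_round_trip(self):
        rng = np.random.default_rng(109)
        for spec in (sim.LinearARSpec.random(rng),
                     sim.NonlinearARSpec.random(rng),
                     sim.MixingSpec(0.2),
                     sim.SingleSourceSpec.random(rng),
                     sim.LorenzSpec()):
            back = sim.spec_from_json(sim.spec_to_json(spec))
            assert type(back) is type(spec)
            for k, v in vars(spec).items():
                if isinstance(v, np.ndarray):
                    assert np.allclose(v, getattr(back, k))
                else:
                    assert getattr(back, k) == v
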