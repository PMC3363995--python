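"""Directed information, MDI, decomposition, and normalization checks.

The exact Gaussian closed forms on the model covariance of a unidirectional
lag-1 pair (``linear_pair_covariance``) serve as the oracle throughout.
"""

import numpy as np
import pytest

from neurodi.directed_info import (
    DIConfig,
    delayed_and_instantaneous,
    directed_information,
    gaussian_delayed_di_from_cov,
    gaussian_di_from_cov,
    gaussian_mdi_from_cov,
    gaussian_mi_from_cov,
    mdi,
    normalized_di,
    time_lagged_di,
)
from neurodi.ensemble import TrialEnsemble
from neurodi.estimators import EstimatorConfig
from neurodi.simulators import linear_pair_covariance

from conftest import make_lag1_pair

GAUSS = DIConfig(p=5, estimator=EstimatorConfig(method="gaussian"))


@pytest.fixture(scope="module")
def exact_cov():
    return linear_pair_covariance(a=0.5, b=0.4, c=0.6, N=20)


class TestClosedFormOracle:
    def test_reverse_direction_is_exactly_zero(self, exact_cov):
        assert gaussian_di_from_cov(exact_cov, 20, "yx") == pytest.approx(0.0, abs=1e-9)

    def test_conservation_identity(self, exact_cov):
        # DI(DX->Y) + DI(DY->X) + instantaneous = I(X^N; Y^N), Eq-exact
        di_xy = gaussian_di_from_cov(exact_cov, 20, "xy")
        dd_xy = gaussian_delayed_di_from_cov(exact_cov, 20, "xy")
        dd_yx = gaussian_delayed_di_from_cov(exact_cov, 20, "yx")
        inst = di_xy - dd_xy
        mi = gaussian_mi_from_cov(exact_cov, 20)
        assert dd_xy + dd_yx + inst == pytest.approx(mi, abs=1e-8)
        # lag-1 coupling only: no instantaneous exchange
        assert inst == pytest.approx(0.0, abs=1e-8)

    def test_di_sum_equals_mutual_information(self, exact_cov):
        di_xy = gaussian_di_from_cov(exact_cov, 20, "xy")
        di_yx = gaussian_di_from_cov(exact_cov, 20, "yx")
        assert di_xy + di_yx == pytest.approx(gaussian_mi_from_cov(exact_cov, 20), abs=1e-8)

    def test_mdi_upper_bounds_matched_di_tail(self, exact_cov):
        # MDI sums n = p+1..N, so the valid exact bound is against the
        # matching tail DI(N) - DI(p)
        for p in (1, 3, 5):
            cov_p = linear_pair_covariance(0.5, 0.4, 0.6, p)
            tail = (gaussian_di_from_cov(exact_cov, 20, "xy")
                    - gaussian_di_from_cov(cov_p, p, "xy"))
            assert gaussian_mdi_from_cov(exact_cov, 20, p) >= tail - 1e-9

    def test_unidirectional_normalization_is_one_zero(self, exact_cov):
        rho_xy, rho_yx, undefined = normalized_di(
            gaussian_di_from_cov(exact_cov, 20, "xy"),
            gaussian_di_from_cov(exact_cov, 20, "yx"),
        )
        assert not undefined
        assert rho_xy == pytest.approx(1.0, abs=1e-9)
        assert rho_yx == pytest.approx(0.0, abs=1e-9)


class TestDirectedInformation:
    def test_independent_ensembles_near_zero(self):
        rng = np.random.default_rng(11)
        x = TrialEnsemble(rng.standard_normal((2048, 5)))
        y = TrialEnsemble(rng.standard_normal((2048, 5)))
        cfg = DIConfig(p=1, estimator=EstimatorConfig(method="adaptive_partition"))
        assert abs(directed_information(x, y, cfg, horizon=5)) < 0.1

    def test_sample_gaussian_matches_exact_covariance(self, lag1_pair, exact_cov):
        x, y = lag1_pair
        di = directed_information(x, y, GAUSS)
        assert di == pytest.approx(gaussian_di_from_cov(exact_cov, 20, "xy"), abs=0.1)

    def test_unidirectional_reverse_flow_small(self, lag1_pair):
        x, y = lag1_pair
        assert directed_information(y, x, GAUSS) < 0.05

    def test_adaptive_dimension_guard_advises_mdi(self):
        x = TrialEnsemble(np.random.default_rng(0).standard_normal((64, 30)))
        y = TrialEnsemble(np.random.default_rng(1).standard_normal((64, 30)))
        cfg = DIConfig(p=2, estimator=EstimatorConfig(method="adaptive_partition"))
        with pytest.raises(ValueError, match="mdi"):
            directed_information(x, y, cfg, horizon=30)

    def test_geweke_equivalence_linear_gaussian(self):
        # DI rate equals Geweke's index for Gaussian processes (within 10%)
        from neurodi.gc import granger_f

        x, y = make_lag1_pair(0.5, 0.4, 0.6, n_trials=4096, n_time=30, seed=21)
        cfg = DIConfig(p=1, estimator=EstimatorConfig(method="gaussian"))
        # steady-state rate from the increment, avoiding the startup transient
        rate = (directed_information(x, y, cfg, horizon=30)
                - directed_information(x, y, cfg, horizon=15)) / 15
        rng = np.random.default_rng(22)
        T = 16384
        xs = np.zeros(T)
        ys = np.zeros(T)
        for n in range(1, T):
            xs[n] = 0.5 * xs[n - 1] + rng.standard_normal()
            ys[n] = 0.4 * ys[n - 1] + 0.6 * xs[n - 1] + rng.standard_normal()
        f_bits = granger_f(xs, ys, 5) / np.log(2)
        assert rate == pytest.approx(f_bits, rel=0.1)


class TestTimeLagged:
    def test_matches_five_term_closed_form_small_n(self):
        # N = 3, p1 = 1 toy: the implementation must equal the direct
        # evaluation of the two-sample block formula on the exact covariance
        from neurodi.directed_info import gaussian_cmi_from_cov

        N = 3
        cov = linear_pair_covariance(0.5, 0.4, 0.6, N)
        xs = np.arange(N)
        ys = np.arange(N, 2 * N)
        expect = gaussian_cmi_from_cov(cov, xs[:1], ys[0:1], [])
        block = (gaussian_cmi_from_cov(cov, xs[0:1], ys[1:2], [])
                 + gaussian_cmi_from_cov(cov, xs[0:2], ys[2:3], ys[1:2]))
        expect += (N - 1) / (2 * (N - 2)) * block
        x, y = make_lag1_pair(0.5, 0.4, 0.6, n_trials=60000, n_time=N, seed=23)
        cfg = DIConfig(p=1, p1=1, estimator=EstimatorConfig(method="gaussian"))
        assert time_lagged_di(x, y, cfg) == pytest.approx(expect, abs=0.05)

    def test_equals_di_for_memoryless_single_order_system(self):
        # exactly valid case: iid source, target with no own-memory
        x, y = make_lag1_pair(0.0, 0.0, 0.8, n_trials=4096, n_time=15, seed=24)
        cfg = DIConfig(p=1, p1=1, estimator=EstimatorConfig(method="gaussian"))
        di = directed_information(x, y, cfg)
        assert time_lagged_di(x, y, cfg) == pytest.approx(di, abs=0.1)

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(25)
        x = TrialEnsemble(rng.standard_normal((4096, 15)))
        y = TrialEnsemble(rng.standard_normal((4096, 15)))
        cfg = DIConfig(p=1, p1=1, estimator=EstimatorConfig(method="gaussian"))
        assert abs(time_lagged_di(x, y, cfg)) < 0.1

    def test_horizon_too_short_raises(self, lag1_pair):
        x, y = lag1_pair
        with pytest.raises(ValueError):
            time_lagged_di(x, y, DIConfig(p=1, p1=1), horizon=2)


class TestMdi:
    def test_upper_bounds_matched_di_tail_on_samples(self, lag1_pair):
        x, y = lag1_pair
        value = mdi(x, y, GAUSS)
        di_tail = (directed_information(x, y, GAUSS, horizon=20)
                   - directed_information(x, y, GAUSS, horizon=5))
        assert value >= di_tail - 0.05

    def test_identical_copies_give_zero(self):
        rng = np.random.default_rng(26)
        x = TrialEnsemble(rng.standard_normal((512, 12)))
        cfg = DIConfig(p=2, estimator=EstimatorConfig(method="gaussian"))
        # Y_n is a deterministic function of the conditioning set, but the
        # gaussian path degenerates; the adaptive path reads ~0
        acfg = DIConfig(p=2, estimator=EstimatorConfig(method="adaptive_partition"))
        y = TrialEnsemble(x.data.copy())
        assert abs(mdi(x, y, acfg, pool_time=True)) < 0.2

    def test_pooled_and_per_index_agree_for_stationary_gaussian(self, lag1_pair):
        x, y = lag1_pair
        a = mdi(x, y, GAUSS, pool_time=False)
        b = mdi(x, y, GAUSS, pool_time=True)
        # same quantity, different pooling of a near-stationary window
        assert a == pytest.approx(b, rel=0.25)


class TestDecomposition:
    def test_delayed_plus_instantaneous_identity(self, lag1_pair):
        x, y = lag1_pair
        d_xy, inst_xy = delayed_and_instantaneous(x, y, GAUSS)
        d_yx, _ = delayed_and_instantaneous(y, x, GAUSS)
        mi = gaussian_mi_from_cov(linear_pair_covariance(0.5, 0.4, 0.6, 20), 20)
        assert d_xy + d_yx + inst_xy == pytest.approx(mi, abs=0.15)

    def test_strictly_lagged_coupling_has_no_instantaneous_part(self, lag1_pair):
        x, y = lag1_pair
        _, inst = delayed_and_instantaneous(x, y, GAUSS)
        assert abs(inst) < 0.05

    def test_pure_common_signal_is_all_instantaneous(self):
        rng = np.random.default_rng(27)
        base = rng.standard_normal((4096, 10))
        x = TrialEnsemble(base)
        y = TrialEnsemble(base + 0.01 * rng.standard_normal(base.shape))
        cfg = DIConfig(p=1, estimator=EstimatorConfig(method="gaussian"))
        delayed, inst = delayed_and_instantaneous(x, y, cfg)
        assert inst > 10 * max(delayed, 1e-6)


class TestNormalizedDi:
    def test_arithmetic(self):
        assert normalized_di(0.3, 0.1)[:2] == pytest.approx((0.75, 0.25))

    def test_clipping_rule(self):
        rho_xy, rho_yx, undefined = normalized_di(-0.02, 0.05)
        assert (rho_xy, rho_yx) == (0.0, 1.0)
        assert not undefined

    def test_undefined_flag(self):
        rho_xy, rho_yx, undefined = normalized_di(-0.01, 0.0)
        assert undefined
        assert (rho_xy, rho_yx) == (0.5, 0.5)

    def test_shares_sum_to_one_property(self):
        rng = np.random.default_rng(28)
        for _ in range(200):
            a, b = rng.normal(scale=2, size=2)
            rho_xy, rho_yx, undefined = normalized_di(a, b)
            assert 0.0 <= rho_xy <= 1.0 and 0.0 <= rho_yx <= 1.0
            if not undefined:
                assert rho_xy + rho_yx == pytest.approx(1.0, abs=1e-12)
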