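"""Directed information (DI), time-lagged DI, and the modified
time-lagged DI (MDI).

Directed information from process X to process Y over a horizon N is

    DI(X^N -> Y^N) = sum_{n=1..N} I(X^n; Y_n | Y^{n-1})
                   = sum_{n=1..N} [ I(X^n; Y^n) - I(X^n; Y^{n-1}) ],

an asymmetric decomposition of the mutual information I(X^N; Y^N) into a
flow from X to Y, a flow from Y to X, and an instantaneous exchange term.
Estimating it directly requires joint densities whose dimension grows with
N.  Under a stationary Markov model of order p with a one-sample interaction
delay, the modified time-lagged DI

    MDI(X^N -> Y^N) = sum_{n=p+1..N} I(X_{n-p..n-1}; Y_n | Y_{n-p..n-1})

upper-bounds DI while keeping every term (2p+1)-dimensional, which is what
makes model-free estimation from a few thousand trials feasible.

Joint densities at each time index are always estimated across trials
(trials as i.i.d. realizations).  All estimators run in bits by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from ._adaptive import adaptive_mi, rank_transform
from .ensemble import TrialEnsemble, check_aligned
from .estimators import (
    ADAPTIVE,
    EstimatorConfig,
    chi2_critical,
    estimate_cmi,
    estimate_mi,
)

_LOG2PIE_BITS = np.log2(2.0 * np.pi * np.e)

#: largest joint dimension 2N the full-DI adaptive estimator will attempt
#: per trial ensemble; beyond this the window-limited MDI is the right tool.
_ADAPTIVE_TRIALS_PER_DIM = 32


@dataclass
class DIConfig:
    """Model order ``p`` (MDI window length), interaction lag ``p1``
    (fixed to 1 by default; overriding it only matters for the
    two-sample time-lagged DI), and the estimator to use."""

    p: int = 1
    p1: int = 1
    estimator: EstimatorConfig = field(default_factory=lambda: ADAPTIVE)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("model order p must be >= 1")
        if self.p1 < 1:
            raise ValueError("lag p1 must be >= 1")


@dataclass
class DIResult:
    """Directed information in both directions with its normalization and,
    when a significance test was run, the shuffle threshold and p-value."""

    di_xy: float
    di_yx: float
    rho_xy: float
    rho_yx: float
    mi_xy: float
    config: DIConfig
    threshold: Optional[float] = None
    p_value: Optional[float] = None
    undefined_rho: bool = False


def directed_information(x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
                         horizon: Optional[int] = None) -> float:
    """DI(X^N -> Y^N) in bits via growing-window mutual informations.

    Uses ``sum_n [I(X^n; Y^n) - I(X^n; Y^{n-1})]`` with the configured
    estimator on samples pooled across trials.  Deterministic given the
    sample covariances for the gaussian estimator.
    """
    check_aligned(x, y)
    n_time = x.n_time
    N = n_time if horizon is None else int(horizon)
    if N < 1 or N > n_time:
        raise ValueError(f"horizon must be in [1, {n_time}]")
    est = cfg.estimator
    if est.method == "adaptive_partition" and \
            x.n_trials < _ADAPTIVE_TRIALS_PER_DIM * 2 * N:
        raise ValueError(
            f"joint dimension {2 * N} is too large for {x.n_trials} trials with "
            "adaptive partitioning; use mdi() instead"
        )
    total = 0.0
    for n in range(1, N + 1):
        xn = x.columns(0, n)
        cur = estimate_mi(xn, y.columns(0, n), est).value
        prev = estimate_mi(xn, y.columns(0, n - 1), est).value if n > 1 else 0.0
        total += cur - prev
    return total


def di_rate(di_value: float, horizon: int) -> float:
    """Per-sample DI rate; reported DI values are sums over the window."""
    return di_value / horizon


def time_lagged_di(x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
                   horizon: Optional[int] = None) -> float:
    """Two-sample time-lagged DI with explicit lag ``p1``.

    ``sum_{n=1..p1} I(X^n; Y_n | Y^{n-1})`` plus the block sum of the
    five-entropy two-sample terms, weighted by the printed prefactor
    ``(N - p1) / (2 (N - p1 - 1))``.  Matches full DI when the system has a
    single-order dependence at exactly lag ``p1``.
    """
    check_aligned(x, y)
    N = x.n_time if horizon is None else int(horizon)
    p1 = cfg.p1
    if N - p1 - 1 <= 0:
        raise ValueError(f"need N - p1 - 1 > 0 (N={N}, p1={p1})")
    est = cfg.estimator
    total = 0.0
    for n in range(1, p1 + 1):
        total += estimate_cmi(
            x.columns(0, n), y.column(n - 1), y.columns(0, n - 1), est
        ).value
    block = 0.0
    for n in range(p1 + 1, N):  # n = p1+1 .. N-1, 1-based
        i0 = n - p1 - 1  # 0-based index of X_{n-p1}
        term = estimate_mi(x.column(i0), y.column(n - 1), est).value
        term += estimate_cmi(
            x.columns(i0, i0 + 2), y.column(n), y.column(n - 1), est
        ).value
        block += term
    prefactor = (N - p1) / (2.0 * (N - p1 - 1))
    return total + prefactor * block


class MdiEvaluator:
    """Window-sum MDI with precomputed per-column rank transforms.

    Permutation-null computation re-evaluates the statistic for many trial
    permutations of X; since a trial permutation only reorders rows, the
    column-wise rank transforms can be shared across all evaluations, which
    is what makes 100-shuffle nulls cheap.  Only the adaptive-partition
    estimator takes the rank fast path; other estimators fall back to the
    generic routines.

    ``pool_time=True`` activates the stationary mode: all window positions
    are pooled into one large sample and a single conditional MI is scaled
    by the number of positions.  For (near-)stationary data this trades the
    per-index estimates for a several-fold larger effective sample, which
    is what gives the adaptive estimator its power when the joint window
    dimension 2p+1 is large relative to the trial count.  The trial-shuffle
    null remains exact because a permutation of X's trials preserves each
    process's internal overlap structure while breaking the X-Y pairing.

    In the pooled adaptive mode the conditional MI is estimated by
    *stratified conditioning*: the pooled samples are partitioned into
    equal-occupancy strata by recursive median cuts on the Y-window
    coordinates (most recent lag first), and I(X-window; Y_n | Y-window) is
    the occupancy-weighted sum of within-stratum adaptive-partition MI
    values on within-stratum ranks.  Conditioning by partition keeps the
    target's strong self-memory out of the estimator's resolution budget —
    a plain difference of two joint-MI estimates saturates long before the
    X increment becomes visible when Y is highly autocorrelated.  Because
    the strata depend on Y alone they are invariant under trial shuffles of
    X, so shuffled statistics reuse them.
    """

    def __init__(self, x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
                 horizon: Optional[int] = None, include_current: bool = False,
                 pool_time: bool = False, skip_base: bool = False):
        check_aligned(x, y)
        self.cfg = cfg
        self.include_current = include_current
        self.pool_time = pool_time
        # when the statistic is only ever *compared across trial
        # permutations*, the I(Y_n; Y-window) base term is a permutation
        # invariant and can be skipped entirely
        self.skip_base = skip_base
        self.N = x.n_time if horizon is None else int(horizon)
        p = cfg.p
        if self.N <= p:
            raise ValueError(f"horizon {self.N} must exceed the order p={p}")
        if x.n_trials < 4 * cfg.estimator.ap_min_cell:
            raise ValueError("too few trials for the configured estimator")
        dim = 2 * p + 1 + (1 if include_current else 0)
        n_eff = x.n_trials * ((self.N - p) if pool_time else 1)
        if cfg.estimator.method == "adaptive_partition" and n_eff < 16 * dim:
            warnings.warn(
                f"joint window dimension {dim} with only {n_eff} effective "
                "samples: MDI terms may be poorly resolved", stacklevel=2)
        self._x = x
        self._y = y
        self._adaptive = cfg.estimator.method == "adaptive_partition"
        if self._adaptive and self.pool_time:
            self._prepare_stratified()
        elif self._adaptive:
            self._xr = rank_transform(x.data)
            self._yr = rank_transform(y.data)
            dx = p + (1 if include_current else 0)
            # the scalar target Y_n is one side of the partition; the joint
            # past (X window, Y window) is the other
            self._crit = chi2_critical(cfg.estimator.ap_significance, dx + p)
            self._crit_base = chi2_critical(cfg.estimator.ap_significance, p)

    def _windows(self, xd: np.ndarray, yd: np.ndarray):
        """Pooled (target, past-X, past-Y) blocks over window positions."""
        p = self.cfg.p
        extra = 1 if self.include_current else 0
        xw = [xd[:, n - p : n + extra] for n in range(p, self.N)]
        yw = [yd[:, n - p : n] for n in range(p, self.N)]
        yn = [yd[:, n : n + 1] for n in range(p, self.N)]
        return (np.concatenate(xw), np.concatenate(yw), np.concatenate(yn))

    #: target within-stratum occupancy for the stratified-conditioning mode
    _STRATUM_TARGET = 896

    def _prepare_stratified(self) -> None:
        p = self.cfg.p
        extra = 1 if self.include_current else 0
        xw, yw, yn = self._windows(self._x.data, self._y.data)
        n_pool = xw.shape[0]
        self._n_trials = self._x.n_trials
        self._xw = xw
        levels = int(np.clip(np.round(np.log2(max(n_pool, 1)
                                              / self._STRATUM_TARGET)), 2, 5))
        strata = np.zeros(n_pool, dtype=np.int64)
        for lev in range(levels):
            coord = yw[:, p - 1 - (lev % p)]  # most recent lag first
            new = strata * 2
            for s in range(1 << lev):
                members = strata == s
                cut = np.median(coord[members])
                new[members & (coord > cut)] += 1
            strata = new
        order = np.argsort(strata, kind="stable")
        counts = np.bincount(strata, minlength=1 << levels)
        self._strata_rows = np.split(order, np.cumsum(counts)[:-1])
        self._strata_rows = [r for r in self._strata_rows if r.size >= 8]
        self._yn_ranks = [rank_transform(yn[r, 0]) for r in self._strata_rows]
        self._crit = chi2_critical(self.cfg.estimator.ap_significance, p + extra)

    def _stratified_value(self, perm: Optional[np.ndarray]) -> float:
        est = self.cfg.estimator
        k = self.N - self.cfg.p
        xw = self._xw
        if perm is not None:
            rows = np.arange(xw.shape[0])
            idx = (rows // self._n_trials) * self._n_trials \
                + perm[rows % self._n_trials]
            xw = xw[idx]
        n_pool = xw.shape[0]
        total = 0.0
        for rows, ynr in zip(self._strata_rows, self._yn_ranks):
            xs = rank_transform(xw[rows])
            total += rows.size * adaptive_mi(ynr, xs, self._crit[0],
                                             self._crit[1], est.ap_min_cell)
        return k * total / n_pool

    def value(self, perm: Optional[np.ndarray] = None) -> float:
        """MDI with X's trial axis optionally permuted by ``perm``."""
        p = self.cfg.p
        est = self.cfg.estimator
        extra = 1 if self.include_current else 0
        k = self.N - p
        if self._adaptive:
            if self.pool_time:
                return self._stratified_value(perm)
            xr = self._xr if perm is None else self._xr[perm]
            yr = self._yr
            mc = est.ap_min_cell
            total = 0.0
            for n in range(p, self.N):  # 0-based target index
                xw = xr[:, n - p : n + extra]
                yw = yr[:, n - p : n]
                yn = yr[:, n : n + 1]
                full = adaptive_mi(yn, np.hstack([xw, yw]),
                                   self._crit[0], self._crit[1], mc)
                if not self.skip_base:
                    full -= adaptive_mi(yn, yw, self._crit_base[0],
                                        self._crit_base[1], mc)
                total += full
            return total
        xd = self._x.data if perm is None else self._x.data[perm]
        yd = self._y.data
        if self.pool_time:
            xw, yw, yn = self._windows(xd, yd)
            if self.skip_base:
                return k * estimate_mi(yn, np.hstack([xw, yw]), est).value
            return k * estimate_cmi(xw, yn, yw, est).value
        total = 0.0
        for n in range(p, self.N):
            xw = xd[:, n - p : n + extra]
            total += estimate_cmi(xw, yd[:, n : n + 1], yd[:, n - p : n], est).value
        return total


def mdi(x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
        horizon: Optional[int] = None, pool_time: bool = False) -> float:
    """Modified time-lagged DI: ``sum_n I(X_{n-p..n-1}; Y_n | Y_{n-p..n-1})``.

    The stationary-Markov upper bound on DI(X^N -> Y^N); every term is
    estimated across trials via the two-term conditional-MI decomposition.
    ``pool_time`` activates the stationary mode (see
    :class:`MdiEvaluator`).
    """
    return MdiEvaluator(x, y, cfg, horizon, pool_time=pool_time).value()


@dataclass
class MdiDecomposition:
    """MDI in both directions plus the instantaneous exchange share.

    ``instantaneous`` is estimated as the average extra conditional MI
    contributed by the *current* sample of the source, i.e. the windowed
    analogue of DI(X -> Y || DX).  ``rho_xy``/``rho_yx`` normalize each
    directional MDI by the total dependence (both flows plus the
    instantaneous term), so a common source driving both channels pushes
    both rho values toward 0 even when the raw MDI values are sizeable.
    """

    mdi_xy: float
    mdi_yx: float
    instantaneous: float
    rho_xy: float
    rho_yx: float


class MdiRhoEvaluator:
    """Joint evaluator for the normalized MDI decomposition under trial
    permutations of X (all four window sums share the rank transforms)."""

    def __init__(self, x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
                 horizon: Optional[int] = None, pool_time: bool = False):
        self._xy = MdiEvaluator(x, y, cfg, horizon, pool_time=pool_time)
        self._yx = MdiEvaluator(y, x, cfg, horizon, pool_time=pool_time)
        self._xy_inst = MdiEvaluator(x, y, cfg, horizon, include_current=True,
                                     pool_time=pool_time)
        self._yx_inst = MdiEvaluator(y, x, cfg, horizon, include_current=True,
                                     pool_time=pool_time)

    def decomposition(self, perm: Optional[np.ndarray] = None) -> MdiDecomposition:
        # a trial permutation of X permutes the *source* rows for X->Y sums
        # and the *target* rows for Y->X sums; only relative alignment
        # matters, so the inverse permutation is applied to Y's side.
        inv = None
        if perm is not None:
            inv = np.empty_like(perm)
            inv[perm] = np.arange(perm.size)
        a = self._xy.value(perm)
        t_xy = self._xy_inst.value(perm)
        b = self._yx.value(inv)
        t_yx = self._yx_inst.value(inv)
        inst = max(0.5 * ((t_xy - a) + (t_yx - b)), 0.0)
        ac, bc = max(a, 0.0), max(b, 0.0)
        denom = ac + bc + inst
        if denom < 1e-12:
            rho_xy = rho_yx = 0.5
        else:
            rho_xy = ac / denom
            rho_yx = bc / denom
        return MdiDecomposition(a, b, inst, rho_xy, rho_yx)


def mdi_decomposition(x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
                      horizon: Optional[int] = None) -> MdiDecomposition:
    """Directional MDI values, instantaneous exchange, and normalized shares."""
    return MdiRhoEvaluator(x, y, cfg, horizon).decomposition()


def delayed_and_instantaneous(x: TrialEnsemble, y: TrialEnsemble, cfg: DIConfig,
                              horizon: Optional[int] = None) -> Tuple[float, float]:
    """Split DI(X -> Y) into its delayed part DI(DX -> Y) and the
    instantaneous exchange DI(X -> Y) - DI(DX -> Y).

    The delayed sequence DX = (0, X_1, ..., X_{N-1}) starts with a
    constant coordinate that carries no information; the sum is evaluated
    with that coordinate dropped so covariance-based estimators stay
    non-degenerate.
    """
    check_aligned(x, y)
    N = x.n_time if horizon is None else int(horizon)
    est = cfg.estimator
    full = directed_information(x, y, cfg, horizon)
    delayed = 0.0
    for n in range(2, N + 1):  # n = 1 term is I(constant; Y_1) = 0
        xn = x.columns(0, n - 1)
        cur = estimate_mi(xn, y.columns(0, n), est).value
        prev = estimate_mi(xn, y.columns(0, n - 1), est).value
        delayed += cur - prev
    return delayed, full - delayed


def normalized_di(di_xy: float, di_yx: float) -> Tuple[float, float, bool]:
    """Map a DI pair to [0, 1] shares: ``rho = DI / (DI_xy + DI_yx)``.

    Negative estimates are clipped to zero here (and only here).  When both
    clipped values vanish the ratio is undefined; (0.5, 0.5) is returned
    with the ``undefined`` flag set.
    """
    a = max(float(di_xy), 0.0)
    b = max(float(di_yx), 0.0)
    denom = a + b
    if denom < 1e-12:
        return 0.5, 0.5, True
    return a / denom, b / denom, False


# ---------------------------------------------------------------------------
# Exact Gaussian closed forms on a model covariance: the cross-estimator
# oracle.  The covariance is over the stacked vector (X_1..X_N, Y_1..Y_N).
# ---------------------------------------------------------------------------

def _h_gauss_bits(cov: np.ndarray, idx: np.ndarray) -> float:
    if idx.size == 0:
        return 0.0
    sub = cov[np.ix_(idx, idx)]
    sign, logdet = np.linalg.slogdet(sub)
    if sign <= 0:
        raise ValueError("degenerate covariance block in closed-form evaluation")
    return 0.5 * idx.size * _LOG2PIE_BITS + 0.5 * logdet / np.log(2.0)


def gaussian_cmi_from_cov(cov: np.ndarray, ix, iy, iz=()) -> float:
    """Exact I(X; Y | Z) in bits for a jointly Gaussian vector."""
    ix = np.asarray(ix, dtype=int)
    iy = np.asarray(iy, dtype=int)
    iz = np.asarray(iz, dtype=int)
    return (
        _h_gauss_bits(cov, np.concatenate([ix, iz]))
        + _h_gauss_bits(cov, np.concatenate([iy, iz]))
        - _h_gauss_bits(cov, iz)
        - _h_gauss_bits(cov, np.concatenate([ix, iy, iz]))
    )


def gaussian_di_from_cov(cov: np.ndarray, N: int, direction: str = "xy") -> float:
    """Exact DI over horizon N from a (2N x 2N) model covariance.

    Rows 0..N-1 are X_1..X_N, rows N..2N-1 are Y_1..Y_N.  ``direction``
    selects DI(X -> Y) (``"xy"``) or DI(Y -> X) (``"yx"``).
    """
    if cov.shape != (2 * N, 2 * N):
        raise ValueError("covariance must be (2N x 2N)")
    xs = np.arange(N)
    ys = np.arange(N, 2 * N)
    src, tgt = (xs, ys) if direction == "xy" else (ys, xs)
    total = 0.0
    for n in range(1, N + 1):
        total += gaussian_cmi_from_cov(cov, src[:n], tgt[n - 1 : n], tgt[: n - 1])
    return total


def gaussian_mdi_from_cov(cov: np.ndarray, N: int, p: int,
                          direction: str = "xy") -> float:
    """Exact MDI over horizon N from a (2N x 2N) model covariance."""
    xs = np.arange(N)
    ys = np.arange(N, 2 * N)
    src, tgt = (xs, ys) if direction == "xy" else (ys, xs)
    total = 0.0
    for n in range(p, N):  # 0-based target index
        total += gaussian_cmi_from_cov(
            cov, src[n - p : n], tgt[n : n + 1], tgt[n - p : n]
        )
    return total


def gaussian_mi_from_cov(cov: np.ndarray, N: int) -> float:
    """Exact I(X^N; Y^N) in bits from a (2N x 2N) model covariance."""
    return gaussian_cmi_from_cov(cov, np.arange(N), np.arange(N, 2 * N))


def gaussian_delayed_di_from_cov(cov: np.ndarray, N: int,
                                 direction: str = "xy") -> float:
    """Exact DI(D-source -> target): the one-sample-delayed flow
    ``sum_n I(src^{n-1}; tgt_n | tgt^{n-1})`` from a model covariance."""
    xs = np.arange(N)
    ys = np.arange(N, 2 * N)
    src, tgt = (xs, ys) if direction == "xy" else (ys, xs)
    total = 0.0
    for n in range(2, N + 1):
        total += gaussian_cmi_from_cov(cov, src[: n - 1], tgt[n - 1 : n],
                                       tgt[: n - 1])
    return total
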