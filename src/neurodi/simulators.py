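"""Seeded ground-truth benchmark systems.

Five generators with known causal structure exercise every failure mode a
connectivity measure meets in practice:

1. a multi-order bivariate **linear AR** pair with unidirectional coupling
   of strength ``gamma`` acting over lags ``p1..p2``;
2. the same pair coupled through a steep **sigmoid** (nonlinear, invisible
   to linear models);
3. instantaneous **linear mixing** of a coupled pair onto two sensors
   (volume-conduction surrogate);
4. a **common AR source** observed on two sensors with independent noise
   (no lagged causality at all — the specificity benchmark);
5. two **coupled Lorenz oscillators** with a delayed drive (chaotic,
   deterministic nonlinear dynamics).

Every generator is bit-reproducible under a fixed seed, and returns
:class:`~neurodi.ensemble.TrialEnsemble` pairs whose trials are independent
realizations with Gaussian initial conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Tuple

import numpy as np
from scipy.special import expit

from .ensemble import TrialEnsemble

logger = logging.getLogger(__name__)

_DEFAULT_BURN_IN = 100
_MAX_STABLE_DRAWS = 10_000


def ar_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the AR companion matrix for lag coefficients
    ``(a_1, ..., a_p)`` of ``X_n = sum_i a_i X_{n-i} + e_n``."""
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    p = coeffs.size
    if p == 0:
        return 0.0
    companion = np.zeros((p, p))
    companion[0, :] = coeffs
    if p > 1:
        companion[1:, :-1] = np.eye(p - 1)
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def draw_stable_ar_coefficients(order: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal AR coefficients, redrawn until the model is stable.

    Mirrors the benchmark convention of drawing all coefficients from
    N(0, 1) and discarding unstable systems.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    for _ in range(_MAX_STABLE_DRAWS):
        coeffs = rng.standard_normal(order)
        if ar_spectral_radius(coeffs) < 1.0:
            return coeffs
    raise RuntimeError(
        f"no stable AR({order}) coefficient draw in {_MAX_STABLE_DRAWS} attempts"
    )


@dataclass
class LinearARSpec:
    """Parameters of the coupled linear AR pair.

    ``X(n) = sum_i alpha_i X(n-i) + sigma_x eta_x(n)`` and
    ``Y(n) = sum_i beta_i Y(n-i) + gamma * sum_{i=p1..p2} X(n-i)
    + sigma_y eta_y(n)``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: float = 0.8
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    p1: int = 1
    p2: int = 5

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.p1 < 1 or self.p2 < self.p1:
            raise ValueError("need 1 <= p1 <= p2")
        if self.gamma < 0:
            raise ValueError("coupling gamma must be >= 0")
        for name, c in (("alpha", self.alpha), ("beta", self.beta)):
            if ar_spectral_radius(c) >= 1.0:
                raise ValueError(f"unstable marginal AR part {name!r}")

    @property
    def p3(self) -> int:
        return self.beta.size

    @property
    def p4(self) -> int:
        return self.alpha.size

    @classmethod
    def random(cls, rng: np.random.Generator, gamma: float = 0.8, p1: int = 1,
               p2: int = 5, p3: int = 5, p4: int = 5) -> "LinearARSpec":
        """Benchmark draw: stable N(0,1) coefficients, N(0,1) noise scales."""
        return cls(
            alpha=draw_stable_ar_coefficients(p4, rng),
            beta=draw_stable_ar_coefficients(p3, rng),
            gamma=gamma,
            sigma_x=float(rng.standard_normal()),
            sigma_y=float(rng.standard_normal()),
            p1=p1,
            p2=p2,
        )


@dataclass
class NonlinearARSpec(LinearARSpec):
    """Linear AR pair whose coupling passes through the sigmoid
    ``1 / (1 + exp(b1 + b2 * X(n-i)))`` (threshold ``b1``, slope ``b2``)."""

    b1: float = 0.0
    b2: float = 50.0

    @classmethod
    def random(cls, rng: np.random.Generator, gamma: float = 0.8, p1: int = 1,
               p2: int = 5, p3: int = 5, p4: int = 5, b1: float = 0.0,
               b2: float = 50.0) -> "NonlinearARSpec":
        base = LinearARSpec.random(rng, gamma, p1, p2, p3, p4)
        return cls(alpha=base.alpha, beta=base.beta, gamma=gamma,
                   sigma_x=base.sigma_x, sigma_y=base.sigma_y,
                   p1=p1, p2=p2, b1=b1, b2=b2)


@dataclass
class MixingSpec:
    """Instantaneous linear mixing strength; 0.5 makes both sensors equal."""

    epsilon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in [0, 0.5]")


@dataclass
class SingleSourceSpec:
    """Common AR source on two sensors; ``epsilon`` sets the noise weight
    of the second sensor (SNR from +19 dB at 0.1 down to -19 dB at 0.9)."""

    alpha: np.ndarray
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in (0, 1]")
        if ar_spectral_radius(self.alpha) >= 1.0:
            raise ValueError("unstable source AR part")

    @classmethod
    def random(cls, rng: np.random.Generator, epsilon: float = 0.5,
               p4: int = 5) -> "SingleSourceSpec":
        return cls(alpha=draw_stable_ar_coefficients(p4, rng), epsilon=epsilon)


@dataclass
class LorenzSpec:
    """Two Lorenz oscillators; the first drives the second's X component
    with strength ``beta_coupling`` after a delay of ``t_p`` seconds."""

    A: float = 10.0
    R: float = 28.0
    B: float = 8.0 / 3.0
    beta_coupling: float = 0.5
    t_p: float = 0.02
    dt: float = 0.01
    n_total: int = 100
    n_discard: int = 90

    def __post_init__(self) -> None:
        if self.beta_coupling < 0:
            raise ValueError("beta_coupling must be >= 0")
        delay = self.t_p / self.dt
        if abs(delay - round(delay)) > 1e-9 or round(delay) < 1:
            raise ValueError("t_p / dt must be a positive integer (delay in samples)")
        if not 0 <= self.n_discard < self.n_total:
            raise ValueError("need 0 <= n_discard < n_total")

    @property
    def delay_samples(self) -> int:
        return int(round(self.t_p / self.dt))


def _run_ar(update, n_trials: int, n_time: int, order0: int,
            rng: np.random.Generator, burn_in: int) -> np.ndarray:
    total = burn_in + n_time
    data = np.zeros((n_trials, total))
    data[:, :order0] = rng.standard_normal((n_trials, order0))
    for n in range(order0, total):
        data[:, n] = update(data, n)
    return data[:, burn_in:]


def simulate_linear_ar(spec: LinearARSpec, n_trials: int, n_time: int,
                       seed: int, burn_in: int = _DEFAULT_BURN_IN
                       ) -> Tuple[TrialEnsemble, TrialEnsemble]:
    """Trials of the coupled linear AR pair; ``burn_in`` leading samples
    are generated and discarded so the retained window is near-stationary."""
    rng = np.random.default_rng(seed)
    order0 = max(spec.p2, spec.p3, spec.p4)
    if n_time < 1:
        raise ValueError("n_time must be >= 1")
    total = burn_in + n_time
    x = np.zeros((n_trials, total))
    y = np.zeros((n_trials, total))
    x[:, :order0] = rng.standard_normal((n_trials, order0))
    y[:, :order0] = rng.standard_normal((n_trials, order0))
    a_rev = spec.alpha[::-1]
    b_rev = spec.beta[::-1]
    for n in range(order0, total):
        x[:, n] = x[:, n - spec.p4 : n] @ a_rev + spec.sigma_x * rng.standard_normal(n_trials)
        coupling = spec.gamma * x[:, n - spec.p2 : n - spec.p1 + 1].sum(axis=1)
        y[:, n] = (y[:, n - spec.p3 : n] @ b_rev + coupling
                   + spec.sigma_y * rng.standard_normal(n_trials))
    return (
        TrialEnsemble(x[:, burn_in:], label="X"),
        TrialEnsemble(y[:, burn_in:], label="Y"),
    )


def simulate_nonlinear_ar(spec: NonlinearARSpec, n_trials: int, n_time: int,
                          seed: int, burn_in: int = _DEFAULT_BURN_IN
                          ) -> Tuple[TrialEnsemble, TrialEnsemble]:
    """Trials of the sigmoid-coupled nonlinear AR pair."""
    rng = np.random.default_rng(seed)
    order0 = max(spec.p2, spec.p3, spec.p4)
    total = burn_in + n_time
    x = np.zeros((n_trials, total))
    y = np.zeros((n_trials, total))
    x[:, :order0] = rng.standard_normal((n_trials, order0))
    y[:, :order0] = rng.standard_normal((n_trials, order0))
    a_rev = spec.alpha[::-1]
    b_rev = spec.beta[::-1]
    for n in range(order0, total):
        x[:, n] = x[:, n - spec.p4 : n] @ a_rev + spec.sigma_x * rng.standard_normal(n_trials)
        sig = expit(-(spec.b1 + spec.b2 * x[:, n - spec.p2 : n - spec.p1 + 1]))
        y[:, n] = (y[:, n - spec.p3 : n] @ b_rev + spec.gamma * sig.sum(axis=1)
                   + spec.sigma_y * rng.standard_normal(n_trials))
    return (
        TrialEnsemble(x[:, burn_in:], label="X"),
        TrialEnsemble(y[:, burn_in:], label="Y"),
    )


def apply_mixing(x: TrialEnsemble, y: TrialEnsemble, spec: MixingSpec
                 ) -> Tuple[TrialEnsemble, TrialEnsemble]:
    """Instantaneous sensor mixing ``X_eps = (1-eps) X + eps Y`` and
    ``Y_eps = eps X + (1-eps) Y``."""
    e = spec.epsilon
    x_eps = TrialEnsemble((1 - e) * x.data + e * y.data,
                          sampling_rate_hz=x.sampling_rate_hz, label=f"{x.label}_eps")
    y_eps = TrialEnsemble(e * x.data + (1 - e) * y.data,
                          sampling_rate_hz=y.sampling_rate_hz, label=f"{y.label}_eps")
    return x_eps, y_eps


def simulate_single_source(spec: SingleSourceSpec, n_trials: int, n_time: int,
                           seed: int, burn_in: int = _DEFAULT_BURN_IN
                           ) -> Tuple[TrialEnsemble, TrialEnsemble]:
    """Common-source pair: ``X_eps = S`` and
    ``Y_eps = (1-eps) S + eps eta`` with S an AR process."""
    rng = np.random.default_rng(seed)
    p4 = spec.alpha.size
    total = burn_in + n_time
    s = np.zeros((n_trials, total))
    s[:, :p4] = rng.standard_normal((n_trials, p4))
    a_rev = spec.alpha[::-1]
    for n in range(p4, total):
        s[:, n] = s[:, n - p4 : n] @ a_rev + rng.standard_normal(n_trials)
    s = s[:, burn_in:]
    noise = rng.standard_normal(s.shape)
    e = spec.epsilon
    return (
        TrialEnsemble(s.copy(), label="X_eps"),
        TrialEnsemble((1 - e) * s + e * noise, label="Y_eps"),
    )


def simulate_lorenz_pair(spec: LorenzSpec, n_trials: int, seed: int
                         ) -> Tuple[TrialEnsemble, ...]:
    """Forward-Euler integration of the asymmetrically coupled Lorenz pair.

    Returns the six component ensembles (X1, Y1, Z1, X2, Y2, Z2), each with
    ``n_total - n_discard`` retained samples.  The delayed drive uses a ring
    buffer of past X1 values initialized at the trial's initial condition.
    Trials whose state exceeds 1e6 in magnitude are regenerated with fresh
    initial conditions (count logged).
    """
    rng = np.random.default_rng(seed)
    d = spec.delay_samples
    n_keep = spec.n_total - spec.n_discard
    out = np.empty((6, n_trials, n_keep))
    pending = np.arange(n_trials)
    regenerated = 0
    for attempt in range(100):
        m = pending.size
        if m == 0:
            break
        state = rng.standard_normal((6, m))  # X1 Y1 Z1 X2 Y2 Z2
        x1_hist = np.tile(state[0], (d, 1))  # pre-history = initial value
        traj = np.empty((6, m, spec.n_total))
        for n in range(spec.n_total):
            x1, y1, z1, x2, y2, z2 = state
            x1_delayed = x1_hist[n % d].copy()
            dx1 = -spec.A * (x1 - y1)
            dy1 = spec.R * x1 - y1 - x1 * z1
            dz1 = x1 * y1 - spec.B * z1
            dx2 = -spec.A * (x2 - y2) + spec.beta_coupling * x1_delayed
            dy2 = spec.R * x2 - y2 - x2 * z2
            dz2 = x2 * y2 - spec.B * z2
            x1_hist[n % d] = x1
            state = state + spec.dt * np.stack([dx1, dy1, dz1, dx2, dy2, dz2])
            traj[:, :, n] = state
        ok = np.all(np.abs(traj) < 1e6, axis=(0, 2))
        good = pending[ok]
        out[:, good, :] = traj[:, ok, spec.n_discard:]
        regenerated += int((~ok).sum())
        pending = pending[~ok]
    else:
        raise RuntimeError("Lorenz integration kept diverging after 100 rounds")
    if regenerated:
        logger.info("regenerated %d diverging Lorenz trials", regenerated)
    labels = ("X1", "Y1", "Z1", "X2", "Y2", "Z2")
    return tuple(
        TrialEnsemble(out[i], sampling_rate_hz=1.0 / spec.dt, label=labels[i])
        for i in range(6)
    )


def linear_pair_covariance(a: float, b: float, c: float, N: int,
                           sigma_x: float = 1.0, sigma_y: float = 1.0
                           ) -> np.ndarray:
    """Exact (2N x 2N) covariance of a unidirectional lag-1 Gaussian pair.

    ``X_n = a X_{n-1} + sigma_x e_n`` and ``Y_n = b Y_{n-1} + c X_{n-1}
    + sigma_y f_n`` with zero pre-history, stacked as (X_1..X_N, Y_1..Y_N).
    The closed-form oracle for all Gaussian DI identities: no instantaneous
    interaction and no feedback, so DI(Y -> X) is exactly zero.
    """
    M = np.zeros((2 * N, 2 * N))  # maps innovations (e_1..e_N, f_1..f_N)
    for n in range(N):
        if n > 0:
            M[n, :] = a * M[n - 1, :]
            M[N + n, :] = b * M[N + n - 1, :] + c * M[n - 1, :]
        M[n, n] += sigma_x
        M[N + n, N + n] += sigma_y
    return M @ M.T


def spec_to_json(spec) -> str:
    """Serialize any simulator spec (arrays become lists)."""
    d = asdict(spec)
    d["__type__"] = type(spec).__name__
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return json.dumps(d, indent=2)


_SPEC_TYPES = {
    "LinearARSpec": LinearARSpec,
    "NonlinearARSpec": NonlinearARSpec,
    "MixingSpec": MixingSpec,
    "SingleSourceSpec": SingleSourceSpec,
    "LorenzSpec": LorenzSpec,
}


def spec_from_json(text: str):
    """Inverse of :func:`spec_to_json`."""
    d = json.loads(text)
    cls = _SPEC_TYPES[d.pop("__type__")]
    return cls(**d)
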