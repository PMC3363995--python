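"""Model-free order selection via Cao's embedding-dimension criterion.

The MDI window length p equals the order of the underlying Markov model,
which for an observed scalar series corresponds to the minimum embedding
dimension d of its delay reconstruction.  Cao's method tracks how the
distance between a point and its nearest neighbour grows when the
reconstruction is extended by one coordinate:

    a(i, d) = ||v_{d+1}(i) - v_{d+1}(nn_d(i))||_inf
              / ||v_d(i) - v_d(nn_d(i))||_inf,
    E(d)    = mean_i a(i, d),       E1(d) = E(d+1) / E(d).

E1 stops changing once d reaches the dimension that unfolds the dynamics.
At finite sample sizes E1 additionally creeps slowly toward 1 at all d (a
nearest-neighbour saturation artifact that affects even white noise), so
the plateau is detected structurally: changes of E1 at least ``e1_tol``
count as genuine unfolding steps, and the selected dimension is one past
the last such step.  Cao's companion statistic E2(d) = E*(d+1)/E*(d)
distinguishes deterministic data (E2 deviates from 1 for some d) from pure
noise (E2 ~ 1 for all d); it is reported as a ``noise_like`` flag but does
not alter the selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .ensemble import TrialEnsemble

logger = logging.getLogger(__name__)


@dataclass
class CaoConfig:
    """Search ceiling, delay, plateau tolerance and sampling bounds.

    ``tau`` defaults to 1, the standard choice for discrete-time signals.
    ``e1_tol`` is the E1 change threshold: increases of at least this size
    are treated as genuine unfolding steps, smaller ones as the finite-
    sample creep.  ``e2_band`` is the half-width of the band around 1
    within which the whole E2 curve marks the input as noise-like.
    ``max_points`` caps the pooled delay-vector count (deterministic
    strided subsampling) to bound the nearest-neighbour searches.
    """

    max_dim: int = 10
    tau: int = 1
    e1_tol: float = 0.10
    e2_band: float = 0.10
    min_points: int = 50
    max_points: int = 4000

    def __post_init__(self) -> None:
        if self.max_dim < 2:
            raise ValueError("max_dim must be >= 2")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.e1_tol <= 0:
            raise ValueError("e1_tol must be positive")


@dataclass
class CaoResult:
    """Selected dimension with the full E1/E2 curves.

    ``saturated`` is False when E1 shows no unfolding step at all (the
    dimension then falls back to ``max_dim``); ``noise_like`` is True when
    the E2 curve stays within ``e2_band`` of 1 everywhere, the signature of
    data without deterministic structure, for which the E1-based dimension
    is unreliable.
    """

    dimension: int
    e1: np.ndarray
    e2: np.ndarray
    saturated: bool
    noise_like: bool


def _delay_vectors(data: np.ndarray, d: int, tau: int) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled delay vectors of dimension ``d`` plus their one-step
    extension coordinate, across all trials."""
    n_time = data.shape[1]
    span = (d - 1) * tau
    last = n_time - tau - span  # starts with a valid extension sample
    if last < 1:
        raise ValueError(
            f"series of length {n_time} too short for dimension {d} at tau {tau}"
        )
    vecs = []
    exts = []
    for s in range(last):
        vecs.append(data[:, s : s + span + 1 : tau])
        exts.append(data[:, s + span + tau])
    return (
        np.concatenate(vecs, axis=0).reshape(-1, d),
        np.concatenate([e[:, np.newaxis] for e in exts], axis=0).ravel(),
    )


def _cao_curves(data: np.ndarray, cfg: CaoConfig) -> Tuple[np.ndarray, np.ndarray]:
    # cap the search so vectors of dimension max_dim + 1 still fit the record
    max_dim = min(cfg.max_dim, (data.shape[1] - 1) // cfg.tau - 1)
    if max_dim < 2:
        raise ValueError(
            f"series of length {data.shape[1]} too short for Cao's criterion "
            f"at tau={cfg.tau}"
        )
    e_vals = np.empty(max_dim + 1)
    estar_vals = np.empty(max_dim + 1)
    for d in range(1, max_dim + 2):
        vecs, ext = _delay_vectors(data, d, cfg.tau)
        if vecs.shape[0] < cfg.min_points:
            raise ValueError(
                f"only {vecs.shape[0]} delay vectors at dimension {d}; "
                f"need at least {cfg.min_points}"
            )
        if vecs.shape[0] > cfg.max_points:
            stride = int(np.ceil(vecs.shape[0] / cfg.max_points))
            vecs = vecs[::stride]
            ext = ext[::stride]
        nn = NearestNeighbors(n_neighbors=2, metric="chebyshev").fit(vecs)
        dist, idx = nn.kneighbors(vecs)
        nbr = idx[:, 1]
        base = dist[:, 1]
        grown = np.maximum(base, np.abs(ext - ext[nbr]))
        valid = base > 0
        if valid.sum() < cfg.min_points // 2:
            raise ValueError("too many duplicate delay vectors for Cao's ratios")
        e_vals[d - 1] = np.mean(grown[valid] / base[valid])
        estar_vals[d - 1] = np.mean(np.abs(ext - ext[nbr]))
    e1 = e_vals[1:] / e_vals[:-1]          # E1(d), d = 1..max_dim
    e2 = estar_vals[1:] / estar_vals[:-1]  # E2(d)
    return e1, e2


def cao_dimension(series: TrialEnsemble, cfg: CaoConfig | None = None) -> CaoResult:
    """Minimum embedding dimension of a trial ensemble by Cao's criterion.

    Delay vectors are built per trial and pooled; the selected dimension is
    the first d whose E1 value has reached the saturation plateau (all
    later E1 values within ``plateau_band`` of it and the local change
    below ``e1_tol``).  If no plateau appears, ``max_dim`` is returned with
    ``saturated=False``.
    """
    cfg = cfg or CaoConfig()
    e1, e2 = _cao_curves(series.data, cfg)
    logger.debug("Cao E1=%s E2=%s", np.round(e1, 3), np.round(e2, 3))
    max_dim = e1.size  # may be capped below cfg.max_dim by the record length
    steps = np.nonzero(np.diff(e1) >= cfg.e1_tol)[0]  # index d-1 for step at d
    if steps.size:
        dimension = int(steps[-1] + 2)  # one past the last unfolding step
        saturated = dimension <= max_dim
        dimension = min(dimension, max_dim)
    else:
        dimension = max_dim
        saturated = False
        logger.warning("Cao E1 curve shows no unfolding step up to max_dim=%d",
                       max_dim)
    noise_like = bool(np.all(np.abs(e2 - 1.0) <= cfg.e2_band))
    if noise_like:
        logger.info("E2 curve is flat at 1: noise-like input, order estimate "
                    "is unreliable")
    return CaoResult(dimension=dimension, e1=e1, e2=e2, saturated=saturated,
                     noise_like=noise_like)


def select_order(x: TrialEnsemble, y: TrialEnsemble,
                 cfg: CaoConfig | None = None) -> int:
    """Shared MDI order for a channel pair: the larger of the two
    channels' embedding dimensions (p = max(p2, p3))."""
    return max(cao_dimension(x, cfg).dimension, cao_dimension(y, cfg).dimension)
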