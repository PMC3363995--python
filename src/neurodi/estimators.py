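"""Entropy, mutual-information, and conditional-MI estimation.

Three estimator families share one configuration object:

``gaussian``
    Closed-form Gaussian (co)variance plug-in.  Deterministic given the
    sample covariance; captures only linear (second-order) dependence.
``adaptive_partition``
    Darbellay–Vajda recursive partitioning of the joint rank space
    (see :mod:`neurodi._adaptive`).  Model-free; the workhorse for
    directed-information estimation on real data.
``histogram``
    Fixed equiprobable per-coordinate binning with plug-in MI; a simple
    cross-check estimator for low-dimensional problems.

All values are reported in units of ``log_base`` (bits by default).
Nonparametric estimates may be slightly negative; they are returned raw,
and clipping is left to consumers (normalization clips at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional

import numpy as np
from scipy import stats

from ._adaptive import adaptive_mi, rank_transform

_LN2 = np.log(2.0)


@dataclass
class SampleMatrix:
    """``n_samples x n_dims`` matrix: each row is one joint realization."""

    values: np.ndarray
    dim_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, np.newaxis]
        if arr.ndim != 2:
            raise ValueError("sample matrix must be 2-D (n_samples x n_dims)")
        if arr.shape[0] < 1:
            raise ValueError("need at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample matrix contains non-finite values")
        self.values = arr
        if self.dim_labels is not None and len(self.dim_labels) != arr.shape[1]:
            raise ValueError("dim_labels length must match n_dims")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class EstimatorConfig:
    """Which estimator family to use and its parameters.

    ``ap_significance`` is the significance level of the chi-square
    independence test that drives partition refinement (Bonferroni-corrected
    over the candidate cut pairs inside each cell); ``ap_min_cell`` is the
    minimum number of points a child cell may hold.
    """

    method: str = "adaptive_partition"
    log_base: float = 2.0
    ap_significance: float = 0.3
    ap_min_cell: int = 5
    hist_bins: int = 8

    def __post_init__(self) -> None:
        if self.method not in ("adaptive_partition", "histogram", "gaussian"):
            raise ValueError(f"unknown estimator method {self.method!r}")
        if not self.log_base > 1:
            raise ValueError("log_base must be > 1")
        if not 0 < self.ap_significance < 1:
            raise ValueError("ap_significance must lie in (0, 1)")
        if self.ap_min_cell < 1:
            raise ValueError("ap_min_cell must be a positive integer")
        if self.hist_bins < 1:
            raise ValueError("hist_bins must be a positive integer")

    def _from_bits(self, bits: float) -> float:
        return bits * _LN2 / np.log(self.log_base)


@dataclass
class InfoValue:
    """An information estimate with its provenance."""

    value: float
    estimator: EstimatorConfig
    n_samples: int


GAUSSIAN = EstimatorConfig(method="gaussian")
ADAPTIVE = EstimatorConfig(method="adaptive_partition")


def entropy_gaussian(cov: np.ndarray, cfg: EstimatorConfig | None = None) -> InfoValue:
    """Differential entropy of a d-variate Gaussian with covariance ``cov``.

    ``(d/2) log(2 pi e) + (1/2) log det(cov)`` in the configured base.
    """
    cfg = cfg or GAUSSIAN
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError(
            f"covariance is not positive definite: smallest eigenvalue {eigvals.min():.3e}"
        )
    d = cov.shape[0]
    bits = 0.5 * d * np.log2(2.0 * np.pi * np.e) + 0.5 * np.sum(np.log2(eigvals))
    return InfoValue(value=cfg._from_bits(bits), estimator=cfg, n_samples=0)


def _gaussian_mi_bits(xy: np.ndarray, dx: int) -> float:
    cov = np.cov(xy, rowvar=False)
    cov = np.atleast_2d(cov)
    sx = cov[:dx, :dx]
    sy = cov[dx:, dx:]
    for name, block in (("joint", cov), ("x", sx), ("y", sy)):
        sign, _ = np.linalg.slogdet(block)
        if sign <= 0:
            raise ValueError(
                f"singular {name} covariance: a column is degenerate or totally dependent"
            )
    _, ld_joint = np.linalg.slogdet(cov)
    _, ld_x = np.linalg.slogdet(sx)
    _, ld_y = np.linalg.slogdet(sy)
    return 0.5 * (ld_x + ld_y - ld_joint) / _LN2


def _histogram_mi_bits(xv: np.ndarray, yv: np.ndarray, bins: int) -> float:
    n = xv.shape[0]

    def codes(block: np.ndarray) -> np.ndarray:
        out = np.zeros(n, dtype=np.int64)
        for j in range(block.shape[1]):
            ranks = stats.rankdata(block[:, j], method="ordinal") - 1
            digit = np.minimum((ranks * bins) // n, bins - 1)
            out = out * bins + digit
        return out

    cx = codes(xv)
    cy = codes(yv)

    def plugin_h(c: np.ndarray) -> float:
        _, counts = np.unique(c, return_counts=True)
        p = counts / n
        return float(-np.sum(p * np.log2(p)))

    joint = cx * (np.int64(bins) ** yv.shape[1]) + cy
    return plugin_h(cx) + plugin_h(cy) - plugin_h(joint)


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, SampleMatrix):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, np.newaxis]
    return arr


def _canonical(xv: np.ndarray, yv: np.ndarray):
    """Deterministic argument ordering so MI is bit-exactly symmetric."""
    if xv.shape[1] != yv.shape[1]:
        swap = xv.shape[1] > yv.shape[1]
    else:
        swap = xv.tobytes() > yv.tobytes()
    return (yv, xv) if swap else (xv, yv)


def estimate_mi(x, y, cfg: EstimatorConfig | None = None) -> InfoValue:
    """Mutual information ``I(X; Y)`` between two (possibly vector) blocks.

    Symmetric in its arguments by construction on the joint sample.
    """
    cfg = cfg or ADAPTIVE
    xv = _as_matrix(x)
    yv = _as_matrix(y)
    if xv.shape[0] != yv.shape[0]:
        raise ValueError(
            f"sample counts differ: x has {xv.shape[0]}, y has {yv.shape[0]}"
        )
    if xv.shape[1] == 0 or yv.shape[1] == 0:
        return InfoValue(value=0.0, estimator=cfg, n_samples=xv.shape[0])
    n = xv.shape[0]
    xv, yv = _canonical(xv, yv)
    if cfg.method == "gaussian":
        bits = _gaussian_mi_bits(np.hstack([xv, yv]), xv.shape[1])
    elif cfg.method == "histogram":
        bits = _histogram_mi_bits(xv, yv, cfg.hist_bins)
    else:
        if n < 4 * cfg.ap_min_cell:
            raise ValueError(
                f"adaptive partitioning needs at least {4 * cfg.ap_min_cell} samples, got {n}"
            )
        crit1, crit9 = chi2_critical(cfg.ap_significance, xv.shape[1] * yv.shape[1])
        bits = adaptive_mi(rank_transform(xv), rank_transform(yv), crit1, crit9,
                           cfg.ap_min_cell)
    return InfoValue(value=cfg._from_bits(bits), estimator=cfg, n_samples=n)


@lru_cache(maxsize=256)
def chi2_critical(alpha: float, n_pairs: int) -> tuple:
    """Refinement-test critical values (1 and 9 df), Bonferroni over cut pairs."""
    a = alpha / n_pairs
    return float(stats.chi2.isf(a, df=1)), float(stats.chi2.isf(a, df=9))


def estimate_cmi(x, y, z, cfg: EstimatorConfig | None = None) -> InfoValue:
    """Conditional MI ``I(X; Y | Z)`` via the two-term decomposition.

    ``I(X; Y | Z) = I(X; (Y, Z)) - I(X; Z)`` so only pairwise-joint MI
    estimates are needed and estimator bias partially cancels.  A zero-width
    ``z`` reduces exactly to :func:`estimate_mi`.  Since the identity also
    holds with the roles of x and y swapped, the lower-dimensional of the
    two is kept as the standalone block — partitioning a scalar against a
    joint block resolves far better than vector against vector.
    """
    cfg = cfg or ADAPTIVE
    xv = _as_matrix(x)
    yv = _as_matrix(y)
    zv = _as_matrix(z) if z is not None else np.empty((xv.shape[0], 0))
    if not (xv.shape[0] == yv.shape[0] == zv.shape[0]):
        raise ValueError("sample counts differ across x, y, z")
    if zv.shape[1] == 0:
        return estimate_mi(xv, yv, cfg)
    if yv.shape[1] < xv.shape[1]:
        xv, yv = yv, xv
    full = estimate_mi(xv, np.hstack([yv, zv]), cfg)
    base = estimate_mi(xv, zv, cfg)
    return InfoValue(value=full.value - base.value, estimator=cfg, n_samples=xv.shape[0])
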