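"""Time-domain Granger causality (Geweke's index) as the linear baseline.

Two least-squares autoregressions of Y_n are compared: the reduced model on
Y's own past and the full model that adds X's past.  Geweke's index

    F(X -> Y) = (1/2) log( var(resid_reduced) / var(resid_full) )

measures the prediction gain; for jointly Gaussian processes it equals the
directed-information rate, which is the cross-module consistency check this
package exploits in its tests.  F is normalized to [0, 1) as
``1 - exp(-2F)``, the proportional variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MvarFit:
    """Full and reduced least-squares fits of Y on lagged regressors."""

    order: int
    coeff_full: np.ndarray      # (2p,) — own lags then cross lags
    coeff_reduced: np.ndarray   # (p,)
    resid_var_full: float
    resid_var_reduced: float


def _lag_matrix(series: np.ndarray, order: int) -> np.ndarray:
    n = series.size
    cols = [series[order - k - 1 : n - k - 1] for k in range(order)]
    return np.column_stack(cols)  # column k holds lag k+1


def fit_mvar(x: np.ndarray, y: np.ndarray, order: int) -> MvarFit:
    """OLS fits of ``Y_n`` on ``Y_{n-1..n-p}`` (reduced) and on
    ``{Y_{n-1..n-p}, X_{n-1..n-p}}`` (full); residual variances are mean
    squared residuals."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if order < 1:
        raise ValueError("order must be >= 1")
    if y.size <= 10 * order:
        raise ValueError(f"series length {y.size} too short for order {order}")
    target = y[order:]
    own = _lag_matrix(y, order)
    cross = _lag_matrix(x, order)
    full_design = np.hstack([own, cross])
    for name, block in (("own-lag", own), ("cross-lag", cross)):
        if np.linalg.matrix_rank(block) < block.shape[1]:
            raise ValueError(f"rank-deficient {name} design block")
    coeff_red, _, _, _ = np.linalg.lstsq(own, target, rcond=None)
    coeff_full, _, _, _ = np.linalg.lstsq(full_design, target, rcond=None)
    resid_red = target - own @ coeff_red
    resid_full = target - full_design @ coeff_full
    return MvarFit(
        order=order,
        coeff_full=coeff_full,
        coeff_reduced=coeff_red,
        resid_var_full=float(np.mean(resid_full**2)),
        resid_var_reduced=float(np.mean(resid_red**2)),
    )


def granger_f(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """Geweke index F(X -> Y) >= 0 in nats, floored at zero."""
    fit = fit_mvar(x, y, order)
    if fit.resid_var_full <= 0:
        return np.inf
    return max(0.0, 0.5 * np.log(fit.resid_var_reduced / fit.resid_var_full))


def normalize_gc(f: float) -> float:
    """Map F >= 0 to [0, 1) as the proportional variance reduction
    ``1 - exp(-2F)``; monotone, 0 at F = 0."""
    if f < 0:
        raise ValueError("F must be >= 0")
    return 1.0 - np.exp(-2.0 * f)


def concatenate_trials(ensemble_data: np.ndarray) -> np.ndarray:
    """Join trials into one series after per-trial mean removal, for
    applying the single-realization GC machinery to trial data."""
    centered = ensemble_data - ensemble_data.mean(axis=1, keepdims=True)
    return centered.ravel()
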