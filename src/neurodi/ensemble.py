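"""Trial-ensemble container shared by every estimator in the package.

A :class:`TrialEnsemble` holds one channel's recordings as a
``n_trials x n_time`` matrix.  Trials are treated as i.i.d. realizations of
the underlying stochastic process, so joint densities at each time index are
estimated *across* trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class TrialEnsemble:
    """One channel: ``data[m, n]`` is trial ``m`` at time sample ``n``.

    Parameters
    ----------
    data
        Real matrix, ``n_trials x n_time``.  All values must be finite.
    sampling_rate_hz
        Sampling rate of the time axis, in Hz.
    label
        Channel name used in reports and serialized output.
    """

    data: np.ndarray
    sampling_rate_hz: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError("trial data must be a 2-D (n_trials x n_time) matrix")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("trial data must contain at least one trial and one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in trial data for channel {self.label!r}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.data = arr

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    def delayed(self) -> "TrialEnsemble":
        """One-sample delayed copy ``DX = (0, X_1, ..., X_{N-1})``."""
        shifted = np.zeros_like(self.data)
        shifted[:, 1:] = self.data[:, :-1]
        return replace(self, data=shifted, label=f"D{self.label}" if self.label else "D")

    def window(self, start: int, length: int) -> "TrialEnsemble":
        """Contiguous time window ``[start, start + length)``."""
        if start < 0 or start + length > self.n_time:
            raise ValueError(
                f"window [{start}, {start + length}) outside the {self.n_time}-sample record"
            )
        return replace(self, data=self.data[:, start : start + length])

    def column(self, n: int) -> np.ndarray:
        """Samples at time index ``n`` across trials, shape ``(n_trials, 1)``."""
        return self.data[:, n : n + 1]

    def columns(self, start: int, stop: int) -> np.ndarray:
        """Samples at time indices ``[start, stop)`` across trials."""
        return self.data[:, start:stop]


def check_aligned(x: TrialEnsemble, y: TrialEnsemble) -> None:
    """Raise if two ensembles cannot be analyzed jointly."""
    if x.n_trials != y.n_trials:
        raise ValueError(
            f"trial counts differ: {x.label!r} has {x.n_trials}, {y.label!r} has {y.n_trials}"
        )
    if x.n_time != y.n_time:
        raise ValueError(
            f"record lengths differ: {x.label!r} has {x.n_time}, {y.label!r} has {y.n_time}"
        )


def pool_windows(series: np.ndarray, length: int, stride: int = 1,
                 sampling_rate_hz: float = 1.0, label: str = "") -> TrialEnsemble:
    """Turn a single long realization into pseudo-trials by sliding windows.

    For stationary single-trial data this pools overlapping windows of the
    requested length into an ensemble, trading temporal independence for
    sample size.  Trials-as-realizations remains the faithful default for
    multi-trial recordings.
    """
    series = np.asarray(series, dtype=float).ravel()
    if length < 1 or length > series.size:
        raise ValueError("window length must be in [1, len(series)]")
    starts = np.arange(0, series.size - length + 1, stride)
    data = np.stack([series[s : s + length] for s in starts])
    return TrialEnsemble(data=data, sampling_rate_hz=sampling_rate_hz, label=label)
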