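"""Pairwise effective-connectivity pipeline over a multichannel ensemble.

For every ordered channel pair the pipeline band-passes the data, selects a
shared model order with the Cao criterion, computes the modified
time-lagged DI in both directions with trial-shuffle p-values, computes the
Granger comparator on trial-concatenated series with time-shuffle p-values,
and controls the FDR over each measure's pooled p-values.  File I/O uses a
long-form CSV (``channel,trial,time,value``) for ensembles and JSON + CSV
matrices for results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from . import __version__
from .directed_info import DIConfig
from .ensemble import TrialEnsemble
from .estimators import EstimatorConfig
from .gc import concatenate_trials, granger_f
from .inference import fdr_select, mdi_test, time_shuffle_null, empirical_pvalue
from .order_selection import CaoConfig, select_order

logger = logging.getLogger(__name__)


@dataclass
class MultichannelEnsemble:
    """Aligned channels sharing trial count, length, and sampling rate."""

    channels: List[TrialEnsemble]
    channel_names: List[str]

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.channel_names):
            raise ValueError("one name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        ref = self.channels[0]
        for ch in self.channels[1:]:
            if ch.n_trials != ref.n_trials or ch.n_time != ref.n_time:
                raise ValueError("all channels must share n_trials and n_time")
            if ch.sampling_rate_hz != ref.sampling_rate_hz:
                raise ValueError("all channels must share the sampling rate")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_trials(self) -> int:
        return self.channels[0].n_trials

    @property
    def n_time(self) -> int:
        return self.channels[0].n_time

    @property
    def sampling_rate_hz(self) -> float:
        return self.channels[0].sampling_rate_hz


@dataclass
class ConnectivityResult:
    """Square DI/GC matrices (row = source, column = target, NaN diagonal)
    with p-values and post-FDR significance masks."""

    channel_names: List[str]
    di_matrix: np.ndarray
    gc_matrix: np.ndarray
    p_di: np.ndarray
    p_gc: np.ndarray
    mask_di: np.ndarray
    mask_gc: np.ndarray
    order_used: int
    band: Optional[Tuple[float, float]]
    window: Tuple[int, int]
    q_fdr: float
    n_shuffles: int
    seed: int


def bandpass(ensemble: MultichannelEnsemble, low_hz: float, high_hz: float,
             order: int = 4) -> MultichannelEnsemble:
    """Zero-phase Butterworth band-pass applied per trial per channel."""
    fs = ensemble.sampling_rate_hz
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={fs / 2}) Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                        output="sos")
    filtered = [
        TrialEnsemble(signal.sosfiltfilt(sos, ch.data, axis=1),
                      sampling_rate_hz=fs, label=ch.label)
        for ch in ensemble.channels
    ]
    return MultichannelEnsemble(channels=filtered,
                                channel_names=list(ensemble.channel_names))


def pairwise_connectivity(ensemble: MultichannelEnsemble, window_start: int = 0,
                          window_len: int = 53, q_fdr: float = 0.05,
                          n_shuffles: int = 100, seed: int = 0,
                          estimator: Optional[EstimatorConfig] = None,
                          cao: Optional[CaoConfig] = None,
                          max_order: Optional[int] = None,
                          gc_mode: str = "concatenate") -> ConnectivityResult:
    """All ordered channel pairs: MDI + GC with FDR-controlled masks.

    The model order is selected per pair (shared between the two channels);
    GC aggregates trials either by concatenation after per-trial mean
    removal (default) or by averaging per-trial Geweke indices.
    """
    if gc_mode not in ("concatenate", "per-trial-average-F"):
        raise ValueError(f"unknown gc_mode {gc_mode!r}")
    k = ensemble.n_channels
    rng = np.random.default_rng(seed)
    windows = [ch.window(window_start, window_len) for ch in ensemble.channels]
    nan = np.full((k, k), np.nan)
    di_m, gc_m, p_di, p_gc = nan.copy(), nan.copy(), nan.copy(), nan.copy()
    orders = []
    estimator = estimator or EstimatorConfig()
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            pair_seed = int(rng.integers(2**31 - 1))
            try:
                p = select_order(windows[i], windows[j], cao)
                if max_order is not None:
                    p = min(p, max_order)
                orders.append(p)
                cfg = DIConfig(p=p, estimator=estimator)
                test = mdi_test(windows[i], windows[j], cfg,
                                n_shuffles=n_shuffles, seed=pair_seed)
                di_m[i, j] = test.observed
                p_di[i, j] = test.p_value
                if gc_mode == "concatenate":
                    xs = concatenate_trials(windows[i].data)
                    ys = concatenate_trials(windows[j].data)
                    null = time_shuffle_null(
                        xs, ys, lambda a, b: granger_f(a, b, p),
                        n_shuffles=n_shuffles, seed=pair_seed)
                    gc_m[i, j] = granger_f(xs, ys, p)
                    p_gc[i, j] = empirical_pvalue(gc_m[i, j], null)
                else:
                    fs = [granger_f(windows[i].data[t], windows[j].data[t], p)
                          for t in range(windows[i].n_trials)]
                    obs = float(np.mean(fs))
                    perm_rng = np.random.default_rng(pair_seed)
                    vals = np.empty(n_shuffles)
                    for s in range(n_shuffles):
                        pm = perm_rng.permutation(windows[i].n_trials)
                        vals[s] = np.mean([
                            granger_f(windows[i].data[pm[t]], windows[j].data[t], p)
                            for t in range(windows[i].n_trials)])
                    gc_m[i, j] = obs
                    p_gc[i, j] = float((1 + np.sum(vals >= obs)) / (1 + n_shuffles))
            except ValueError as exc:
                logger.warning("pair (%s -> %s) failed: %s",
                               ensemble.channel_names[i],
                               ensemble.channel_names[j], exc)
    off = ~np.eye(k, dtype=bool)
    mask_di = np.zeros((k, k), dtype=bool)
    mask_gc = np.zeros((k, k), dtype=bool)
    valid_di = off & np.isfinite(p_di)
    valid_gc = off & np.isfinite(p_gc)
    if valid_di.any():
        sel = fdr_select(p_di[valid_di], q=q_fdr)
        mask_di[valid_di] = sel.mask
    if valid_gc.any():
        sel = fdr_select(p_gc[valid_gc], q=q_fdr)
        mask_gc[valid_gc] = sel.mask
    return ConnectivityResult(
        channel_names=list(ensemble.channel_names),
        di_matrix=di_m, gc_matrix=gc_m, p_di=p_di, p_gc=p_gc,
        mask_di=mask_di, mask_gc=mask_gc,
        order_used=int(np.median(orders)) if orders else 0,
        band=None, window=(window_start, window_len), q_fdr=q_fdr,
        n_shuffles=n_shuffles, seed=seed,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_ensemble(path, fmt: str = "csv") -> MultichannelEnsemble:
    """Read a long-form ``channel,trial,time,value`` CSV (or an ``.npz``
    container with ``data``/``names``/``fs`` arrays) into an ensemble.

    The CSV grid must be complete: every (channel, trial, time) cell
    present exactly once.  Sampling rate may be supplied via a
    ``# sampling_rate_hz=...`` comment on the first line (default 1 Hz).
    """
    path = Path(path)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            data = z["data"]  # (channel, trial, time)
            names = [str(n) for n in z["names"]]
            fs = float(z["fs"])
        channels = [TrialEnsemble(data[i], sampling_rate_hz=fs, label=names[i])
                    for i in range(data.shape[0])]
        return MultichannelEnsemble(channels=channels, channel_names=names)
    fs = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            fs = float(first.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, float_precision="round_trip")
    required = {"channel", "trial", "time", "value"}
    if set(df.columns) != required:
        raise ValueError(f"expected columns {sorted(required)}, got {list(df.columns)}")
    names = list(dict.fromkeys(df["channel"]))
    n_trials = df["trial"].nunique()
    n_time = df["time"].nunique()
    channels = []
    for name in names:
        sub = df[df["channel"] == name]
        if len(sub) != n_trials * n_time:
            raise ValueError(
                f"channel {name!r} has {len(sub)} rows, expected "
                f"{n_trials} trials x {n_time} samples"
            )
        grid = sub.pivot(index="trial", columns="time", values="value")
        if grid.isna().any().any():
            trial, time = np.argwhere(grid.isna().values)[0]
            raise ValueError(
                f"missing cell for channel {name!r}, trial {grid.index[trial]}, "
                f"time {grid.columns[time]}"
            )
        channels.append(TrialEnsemble(grid.values, sampling_rate_hz=fs, label=name))
    return MultichannelEnsemble(channels=channels, channel_names=names)


def write_ensemble(ensemble: MultichannelEnsemble, path) -> None:
    """Write the long-form CSV (lossless round trip with read_ensemble)."""
    frames = []
    for ch in ensemble.channels:
        trial, time = np.meshgrid(np.arange(ch.n_trials), np.arange(ch.n_time),
                                  indexing="ij")
        frames.append(pd.DataFrame({
            "channel": ch.label,
            "trial": trial.ravel(),
            "time": time.ravel(),
            "value": ch.data.ravel(),
        }))
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={ensemble.sampling_rate_hz}\n")
        # 17 significant digits round-trip float64 exactly
        pd.concat(frames).to_csv(fh, index=False, float_format="%.17g")


def write_result(result: ConnectivityResult, out_dir) -> None:
    """Serialize a connectivity result: JSON for config/p-values/masks plus
    CSV matrices (row = source channel, column = target)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = result.channel_names
    for stem, mat in (("di_matrix", result.di_matrix),
                      ("gc_matrix", result.gc_matrix)):
        pd.DataFrame(mat, index=names, columns=names).to_csv(out / f"{stem}.csv")
    payload = {
        "software_version": __version__,
        "channel_names": names,
        "order_used": result.order_used,
        "band": result.band,
        "window": list(result.window),
        "q_fdr": result.q_fdr,
        "n_shuffles": result.n_shuffles,
        "seed": result.seed,
        "di_matrix": result.di_matrix.tolist(),
        "gc_matrix": result.gc_matrix.tolist(),
        "p_di": result.p_di.tolist(),
        "p_gc": result.p_gc.tolist(),
        "mask_di": result.mask_di.tolist(),
        "mask_gc": result.mask_gc.tolist(),
    }
    with open(out / "result.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def read_result(out_dir) -> ConnectivityResult:
    """Re-load a serialized connectivity result."""
    with open(Path(out_dir) / "result.json") as fh:
        d = json.load(fh)
    return ConnectivityResult(
        channel_names=d["channel_names"],
        di_matrix=np.asarray(d["di_matrix"], dtype=float),
        gc_matrix=np.asarray(d["gc_matrix"], dtype=float),
        p_di=np.asarray(d["p_di"], dtype=float),
        p_gc=np.asarray(d["p_gc"], dtype=float),
        mask_di=np.asarray(d["mask_di"], dtype=bool),
        mask_gc=np.asarray(d["mask_gc"], dtype=bool),
        order_used=d["order_used"],
        band=tuple(d["band"]) if d["band"] else None,
        window=tuple(d["window"]),
        q_fdr=d["q_fdr"],
        n_shuffles=d["n_shuffles"],
        seed=d["seed"],
    )
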