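"""Alpha-band analytic signals and the evoked/total power distinction.

Epochs are band-pass filtered with a fifth-order Butterworth (8-13 Hz by
default), applied forward-backward so that CTF latencies are not
phase-shifted, then Hilbert-transformed to the complex analytic signal.
Evoked power is the squared magnitude of the across-trial mean analytic
signal (phase-locked activity only); total power averages the per-trial
squared magnitudes (all activity).  Power time series are smoothed with a
short moving average and optionally reduced with a PCA rotation fitted on
the training observations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .containers import EpochArray

__all__ = ["AnalyticEpochs", "PowerBlock", "bandpass_hilbert", "evoked_power",
           "total_power", "smooth_power", "pca_reduce"]


@dataclass
class AnalyticEpochs:
    """Complex analytic signal per trial x electrode x sample."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    trial_index: np.ndarray
    band: tuple
    order: int
    window: tuple

    def crop(self, tmin: float | None = None, tmax: float | None = None) -> "AnalyticEpochs":
        tmin = self.window[0] if tmin is None else tmin
        tmax = self.window[1] if tmax is None else tmax
        m = (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)
        return AnalyticEpochs(self.data[:, :, m], self.times[m], self.sfreq,
                              self.trial_index, self.band, self.order,
                              (tmin, tmax))

    def select_trials(self, idx) -> "AnalyticEpochs":
        idx = np.asarray(idx)
        return AnalyticEpochs(self.data[idx], self.times, self.sfreq,
                              self.trial_index[idx], self.band, self.order,
                              self.window)


@dataclass
class PowerBlock:
    """Power observations (one per trial group) x features x samples.

    ``obs`` records the group labels (columns ``set_id`` and ``cue_bin``)
    in observation order; ``kind`` is 'evoked' or 'total'.
    """

    data: np.ndarray
    obs: pd.DataFrame
    kind: str
    times: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.data < -1e-12):
            raise ValueError("power must be non-negative")

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    def as_b_matrix(self) -> np.ndarray:
        """Feature x observation x time layout used by the encoding model."""
        return np.moveaxis(self.data, 0, 1)


def bandpass_hilbert(epochs: EpochArray, lo: float = 8.0, hi: float = 13.0,
                     order: int = 5) -> AnalyticEpochs:
    """Zero-phase Butterworth band-pass followed by a Hilbert transform.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and
    the group delay is zero.  Deterministic.
    """
    nyq = epochs.sfreq / 2.0
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.sfreq,
                              output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1)
    analytic = scipy.signal.hilbert(filtered, axis=-1)
    return AnalyticEpochs(data=analytic, times=epochs.times, sfreq=epochs.sfreq,
                          trial_index=epochs.trial_index, band=(lo, hi),
                          order=order, window=tuple(epochs.window))


def _group_table(groups) -> pd.DataFrame:
    rows = []
    for label, idx in groups.items():
        if np.size(idx) == 0:
            raise ValueError(f"trial group {label!r} is empty")
        if isinstance(label, tuple) and len(label) == 2:
            rows.append({"set_id": label[0], "cue_bin": label[1]})
        else:
            rows.append({"set_id": pd.NA, "cue_bin": label})
    return pd.DataFrame(rows)


def evoked_power(analytic: AnalyticEpochs, groups) -> PowerBlock:
    """Squared magnitude of the across-trial mean analytic signal per group.

    ``groups`` maps labels -- either ``cue_bin`` or ``(set_id, cue_bin)``
    tuples -- to trial positions within ``analytic``.  Only activity with a
    consistent phase across the group's trials survives the complex mean.
    """
    obs = _group_table(groups)
    data = np.stack([np.abs(analytic.data[np.asarray(idx)].mean(axis=0)) ** 2
                     for idx in groups.values()])
    return PowerBlock(data=data, obs=obs, kind="evoked", times=analytic.times)


def total_power(analytic: AnalyticEpochs, groups) -> PowerBlock:
    """Across-trial mean of per-trial squared magnitudes per group."""
    obs = _group_table(groups)
    data = np.stack([(np.abs(analytic.data[np.asarray(idx)]) ** 2).mean(axis=0)
                     for idx in groups.values()])
    return PowerBlock(data=data, obs=obs, kind="total", times=analytic.times)


def smooth_power(power: PowerBlock, window: int = 8, step: int = 1) -> PowerBlock:
    """Moving average over time (window-centered; edges replicate).

    The default 8 samples at 512 Hz spans 15.62 ms.  Only ``step=1`` is
    supported (the analysis keeps the full time axis).
    """
    if step != 1:
        raise NotImplementedError("only step=1 is supported")
    if window > power.data.shape[-1]:
        raise ValueError("window longer than the time series")
    smoothed = scipy.ndimage.uniform_filter1d(power.data, size=window, axis=-1,
                                              mode="nearest")
    return PowerBlock(data=smoothed, obs=power.obs.copy(), kind=power.kind,
                      times=power.times)


def pca_reduce(train: PowerBlock, test: PowerBlock, k: int = 16,
               center: bool = False) -> tuple[PowerBlock, PowerBlock]:
    """Project both blocks onto the top-k principal axes of the training data.

    The rotation is fitted on the training observations only (pooled over
    time samples) and applied unchanged to the test block, so no test
    information leaks into the features.  By default the data are not
    mean-centered: power has a large common offset that itself carries
    signal, and an uncentered rotation keeps the encoding-model solution
    exactly invariant when all components are retained.
    """
    Xtr = np.moveaxis(train.data, 1, 2).reshape(-1, train.data.shape[1])
    if k > train.data.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {train.data.shape[1]}")
    mean = Xtr.mean(axis=0) if center else np.zeros(Xtr.shape[1])
    _, s, Vt = np.linalg.svd(Xtr - mean, full_matrices=False)
    tol = s[0] * max(Xtr.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the training data")
    comps = Vt[:k]  # (k, features), orthonormal rows

    def _apply(block: PowerBlock) -> PowerBlock:
        proj = np.einsum("oft,cf->oct", block.data - mean[None, :, None], comps)
        out = PowerBlock.__new__(PowerBlock)
        out.data = proj  # projected scores may be negative; skip power check
        out.obs = block.obs.copy()
        out.kind = block.kind
        out.times = block.times
        return out

    return _apply(train), _apply(test)
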