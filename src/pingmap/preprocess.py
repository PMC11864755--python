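"""Epoch-level artifact rejection.

Muscle activity is detected by band-pass filtering 110-140 Hz, z-scoring
the envelope per electrode across the whole recording, and flagging epochs
whose electrode-summed z trace exceeds a subject-specific threshold
(a robust median + c * scaled-MAD of that trace within the windows of
interest, so the artifacts themselves cannot inflate it).  Flagged
epochs are not dropped immediately: the electrodes contributing most to
the accumulated z within the artifact period are interpolated one by one
(up to five), re-testing after each; only epochs that still exceed the
threshold are dropped.  Eye movements are rejected from the gaze trace
(excursion beyond 1.2 visual degrees inside the window of interest) or,
as a fallback, from a sliding-window step detector on the HEOG channel
(200 ms window, 10 ms step, 15 uV threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .containers import EpochArray
from .simulate import electrode_positions

__all__ = ["ArtifactReport", "detect_muscle_artifacts", "interpolate_electrode",
           "reject_eye"]


@dataclass
class ArtifactReport:
    """Book-keeping of the muscle-artifact procedure."""

    epoch_scores: np.ndarray           # (n_epochs,) max accumulated z in window
    threshold: float
    flagged: list = field(default_factory=list)
    interpolated: list = field(default_factory=list)   # (epoch, electrode) pairs
    dropped: list = field(default_factory=list)
    reasons: dict = field(default_factory=dict)        # epoch -> reason code
    keep_mask: np.ndarray = None

    def validate(self) -> None:
        if not set(self.dropped) <= set(self.flagged):
            raise AssertionError("dropped epochs must be a subset of flagged epochs")


def _hf_envelope(data: np.ndarray, sfreq: float, band=(110.0, 140.0)) -> np.ndarray:
    if band[1] >= sfreq / 2.0:
        raise ValueError(f"band edge {band[1]} Hz >= Nyquist {sfreq / 2} Hz")
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    filt = scipy.signal.sosfiltfilt(sos, data, axis=-1)
    return np.abs(scipy.signal.hilbert(filt, axis=-1))


def _neighbor_weights(positions: np.ndarray, electrode: int,
                      exclude: set, n_neighbors: int = 4):
    dist = np.linalg.norm(positions - positions[electrode], axis=1)
    order = [e for e in np.argsort(dist)
             if e != electrode and e not in exclude]
    if len(order) < 3:
        return None, None
    nbrs = np.array(order[:n_neighbors])
    w = 1.0 / np.maximum(dist[nbrs], 1e-9)
    return nbrs, w / w.sum()


def interpolate_electrode(epochs: EpochArray, electrode: int,
                          positions: np.ndarray | None = None,
                          exclude=(), epochs_idx=None) -> EpochArray:
    """Replace one electrode by the inverse-distance-weighted mean of its
    nearest four non-excluded neighbors.

    ``epochs_idx`` restricts the replacement to specific epochs (default:
    all).  Other electrodes are untouched.  Applying the same interpolation
    twice is idempotent, because the source electrode does not enter its
    own replacement.
    """
    if positions is None:
        positions = electrode_positions(epochs.n_electrodes)
    nbrs, w = _neighbor_weights(positions, electrode, set(exclude))
    out = epochs.copy()
    if nbrs is None:
        warnings.warn(f"electrode {electrode}: fewer than 3 usable neighbors; "
                      "skipping interpolation", stacklevel=2)
        return out
    sel = np.arange(out.n_trials) if epochs_idx is None else np.atleast_1d(epochs_idx)
    replacement = np.einsum("n,int->it", w, out.data[np.ix_(sel, nbrs)])
    out.data[sel, electrode, :] = replacement
    return out


def detect_muscle_artifacts(epochs: EpochArray, window: tuple | None = None,
                            c: float = 4.0, band=(110.0, 140.0),
                            max_interp: int = 5,
                            positions: np.ndarray | None = None
                            ) -> tuple[EpochArray, ArtifactReport]:
    """Flag, repair, and drop muscle-contaminated epochs.

    Returns the (possibly interpolated) epochs restricted to kept trials
    plus an :class:`ArtifactReport`.  ``window`` defaults to the epochs'
    window of interest; the filter edges must stay below Nyquist.
    """
    if positions is None:
        positions = electrode_positions(epochs.n_electrodes)
    tmask = epochs.time_mask(*(window or epochs.window))
    env = _hf_envelope(epochs.data, epochs.sfreq, band)
    mu = env[:, :, tmask].mean(axis=(0, 2), keepdims=True)
    sd = env[:, :, tmask].std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    z = (env - mu) / sd                       # (n, E, T)
    acc = z.sum(axis=1)                       # accumulated z across electrodes
    acc_win = acc[:, tmask]
    # robust center/scale so contaminated samples do not inflate the threshold
    center = float(np.median(acc_win))
    scale = 1.4826 * float(np.median(np.abs(acc_win - center)))
    threshold = float(center + c * scale)
    scores = acc_win.max(axis=1)
    flagged = np.flatnonzero(scores > threshold)

    out = epochs.copy()
    report = ArtifactReport(epoch_scores=scores, threshold=threshold,
                            flagged=[int(i) for i in flagged])
    dropped = []
    for i in flagged:
        zi = z[i]
        for _ in range(max_interp):
            acc_i = zi.sum(axis=0)
            acc_i_win = acc_i[tmask]
            if acc_i_win.max() <= threshold:
                break
            period = tmask & (zi.sum(axis=0) > threshold)
            if not period.any():
                period = tmask
            contrib = zi[:, period].sum(axis=1)
            worst = int(np.argmax(contrib))
            already = {e for (ep, e) in report.interpolated if ep == int(i)}
            nbrs, w = _neighbor_weights(positions, worst, already)
            if nbrs is None:
                break
            out.data[i, worst, :] = w @ out.data[i, nbrs, :]
            report.interpolated.append((int(i), worst))
            env_i = _hf_envelope(out.data[i][None], epochs.sfreq, band)[0]
            zi = (env_i - mu[0]) / sd[0]
        acc_i_win = zi.sum(axis=0)[tmask]
        if acc_i_win.max() > threshold:
            dropped.append(int(i))
            report.reasons[int(i)] = "muscle"
        else:
            report.reasons[int(i)] = "repaired"
    report.dropped = dropped
    keep = np.ones(epochs.n_trials, dtype=bool)
    keep[dropped] = False
    report.keep_mask = keep
    report.validate()
    return out.select_trials(keep), report


def reject_eye(epochs: EpochArray, *, gaze: np.ndarray | None = None,
               heog: np.ndarray | None = None, window: tuple | None = None,
               gaze_threshold: float = 1.2, heog_window: float = 0.2,
               heog_step: float = 0.01, heog_threshold: float = 15.0
               ) -> tuple[np.ndarray, dict]:
    """Keep mask for eye-movement-free epochs.

    An epoch is rejected when the gaze eccentricity exceeds
    ``gaze_threshold`` visual degrees anywhere inside the window of
    interest.  Without gaze data, a step detector slides a 200 ms window in
    10 ms steps over the HEOG trace and rejects when the absolute
    difference between the means of the window's second and first halves
    exceeds 15 uV.  Raises if neither trace is available.
    """
    gaze = epochs.gaze if gaze is None else gaze
    heog = epochs.heog if heog is None else heog
    tmask = epochs.time_mask(*(window or epochs.window))
    reasons = {}
    n = epochs.n_trials
    keep = np.ones(n, dtype=bool)
    if gaze is not None:
        bad = np.abs(gaze[:, tmask]).max(axis=1) > gaze_threshold
        src = "gaze"
    elif heog is not None:
        half = max(1, int(round(heog_window * epochs.sfreq / 2)))
        step = max(1, int(round(heog_step * epochs.sfreq)))
        sig = heog[:, tmask]
        T = sig.shape[1]
        stat = np.zeros(n)
        for start in range(0, T - 2 * half + 1, step):
            first = sig[:, start:start + half].mean(axis=1)
            second = sig[:, start + half:start + 2 * half].mean(axis=1)
            stat = np.maximum(stat, np.abs(second - first))
        bad = stat > heog_threshold
        src = "heog"
    else:
        raise ValueError("need a gaze trace or an HEOG trace to reject eye "
                         "movements")
    keep[bad] = False
    for i in np.flatnonzero(bad):
        reasons[int(i)] = src
    return keep, reasons
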