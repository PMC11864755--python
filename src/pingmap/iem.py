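"""Inverted encoding model for circular spatial location.

Alpha-band power at each electrode is modeled as a weighted sum of k = 8
spatial channels, each tuned to one of eight equally spaced polar angles
with the half-sinusoid profile sin(0.5*theta)**7 (equivalently, response
cos(d/2)**7 at angular distance d from the channel's preferred angle).
Training estimates the electrode-by-channel weight matrix W from the GLM
B1 = W C1 by least squares; at test the model is inverted, solving
W C2 = B2 for the channel responses C2, which are then circularly
re-centered on the cued location to form channel tuning functions (CTFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import circular_distance_bins

__all__ = ["BasisSet", "make_basis", "predicted_responses", "train_weights",
           "invert_channels", "recenter_ctf", "ChannelResponses"]


@dataclass
class BasisSet:
    """k circular spatial channels evaluated on an integer-degree grid."""

    n_channels: int
    power: int = 7
    angles: np.ndarray = field(default=None)
    response: np.ndarray = field(default=None)  # (k, 360)

    def __post_init__(self):
        if self.angles is None:
            self.angles = np.arange(360.0)
        if self.response is None:
            self.response = self.evaluate(self.angles)

    @property
    def centers(self) -> np.ndarray:
        """Channel peak angles: 0, 45, ..., 315 for k = 8."""
        return np.arange(self.n_channels) * (360.0 / self.n_channels)

    def evaluate(self, angles) -> np.ndarray:
        """Channel responses at arbitrary angles (degrees); shape (k, n).

        Response at angular distance d from a channel's center is
        cos(d/2)**power, the circularly shifted half-sinusoid profile.
        """
        angles = np.atleast_1d(np.asarray(angles, dtype=float))
        d = (angles[None, :] - self.centers[:, None] + 180.0) % 360.0 - 180.0
        return np.cos(np.deg2rad(d) / 2.0) ** self.power


def make_basis(k: int = 8, power: int = 7) -> BasisSet:
    """Standard basis of k half-sinusoid channels; k must divide 360."""
    if 360 % k:
        raise ValueError(f"k={k} does not divide 360")
    return BasisSet(n_channels=k, power=power)


def predicted_responses(cue_angles, basis: BasisSet) -> np.ndarray:
    """Predicted channel responses C1 (k x n) for the given cue angles."""
    cue_angles = np.asarray(cue_angles, dtype=float)
    if np.any((cue_angles < 0) | (cue_angles >= 360)):
        raise ValueError("cue angles must lie in [0, 360)")
    return basis.evaluate(cue_angles)


def train_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Least-squares weight estimate W-hat per time sample.

    Parameters
    ----------
    B1 : (m features, n1 observations, T) or (m, n1) training power
    C1 : (k channels, n1 observations) predicted responses

    Returns
    -------
    W : (m, k, T) (or (m, k) for 2D input), the per-sample least-squares
        solution of B1 = W C1.
    """
    B1 = np.asarray(B1, dtype=float)
    C1 = np.asarray(C1, dtype=float)
    k, n1 = C1.shape
    if n1 < k or np.linalg.matrix_rank(C1) < k:
        raise np.linalg.LinAlgError(
            "C1 is row-rank deficient; the training design does not span "
            "all channels")
    pinv = np.linalg.pinv(C1)  # (n1, k); W = B1 pinv(C1) is the LS solution
    squeeze = B1.ndim == 2
    if squeeze:
        B1 = B1[:, :, None]
    W = np.einsum("fnt,nk->fkt", B1, pinv)
    return W[:, :, 0] if squeeze else W


def invert_channels(W: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Estimated channel responses C2, solving W C2 = B2 per time sample.

    Parameters
    ----------
    W : (m, k, T) or (m, k) estimated weights
    B2 : (m, n2, T) or (m, n2) test power

    Returns
    -------
    C2 : (k, n2, T) (or (k, n2)), the least-squares solution.
    """
    W = np.asarray(W, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    squeeze = B2.ndim == 2
    if squeeze:
        B2 = B2[:, :, None]
        W = W[:, :, None] if W.ndim == 2 else W
    if W.ndim == 2:
        W = np.repeat(W[:, :, None], B2.shape[2], axis=2)
    Wt = np.moveaxis(W, -1, 0)            # (T, m, k)
    B2t = np.moveaxis(B2, -1, 0)          # (T, m, n2)
    G = Wt.transpose(0, 2, 1) @ Wt        # (T, k, k)
    # eigenvalues of W'W are squared singular values of W: cheap rank check
    ev = np.linalg.eigvalsh(G)
    if np.any(ev[:, 0] <= ev[:, -1] * 1e-20) or np.any(ev[:, -1] == 0):
        raise np.linalg.LinAlgError("weight matrix is column-rank deficient")
    C2t = np.linalg.solve(G, Wt.transpose(0, 2, 1) @ B2t)  # (T, k, n2)
    C2 = np.moveaxis(C2t, 0, -1)
    return C2[:, :, 0] if squeeze else C2


@dataclass
class ChannelResponses:
    """Re-centered channel responses (CTFs) and their standard groupings.

    ``ctf`` holds one re-centered response profile per test observation,
    with the offset axis ordered 0, +45, ..., +315 deg relative to the cued
    location (offset 0 = cued channel).  Groupings follow the analysis:

    - ``per_location``: mean CTF per physical cue bin, (8 bins, k, T)
    - ``by_distance``: bins grouped by circular distance to the HPL,
      (5 distances, k, T); requires ``hpl_bin``
    - ``grand``: average over all bins, (k, T)
    """

    ctf: np.ndarray            # (n_obs, k, T)
    cue_bins: np.ndarray       # (n_obs,)
    times: np.ndarray | None = None
    hpl_bin: int | None = None

    @property
    def n_channels(self) -> int:
        return self.ctf.shape[1]

    @property
    def per_location(self) -> np.ndarray:
        k = self.n_channels
        out = np.full((k,) + self.ctf.shape[1:], np.nan)
        for b in range(k):
            sel = self.cue_bins == b
            if sel.any():
                out[b] = self.ctf[sel].mean(axis=0)
        return out

    @property
    def by_distance(self) -> np.ndarray:
        if self.hpl_bin is None:
            raise ValueError("hpl_bin is required for distance grouping")
        k = self.n_channels
        dist = circular_distance_bins(self.cue_bins, self.hpl_bin, k)
        n_dist = k // 2 + 1
        out = np.full((n_dist,) + self.ctf.shape[1:], np.nan)
        for d in range(n_dist):
            sel = dist == d
            if sel.any():
                out[d] = self.ctf[sel].mean(axis=0)
        return out

    @property
    def grand(self) -> np.ndarray:
        return self.per_location.mean(axis=0)


def recenter_ctf(C2: np.ndarray, cue_bins, *, times=None,
                 hpl_bin: int | None = None) -> ChannelResponses:
    """Circularly shift each response vector so the cued channel sits at 0.

    Parameters
    ----------
    C2 : (k, n_obs, T) or (k, n_obs) estimated channel responses
    cue_bins : per-observation cue bin (0..k-1)
    """
    C2 = np.asarray(C2, dtype=float)
    if C2.ndim == 2:
        C2 = C2[:, :, None]
    k, n_obs, T = C2.shape
    cue_bins = np.asarray(cue_bins, dtype=int)
    if cue_bins.shape != (n_obs,):
        raise ValueError("one cue bin per observation required")
    if np.any((cue_bins < 0) | (cue_bins >= k)):
        raise ValueError(f"cue bins must lie in 0..{k - 1}")
    ctf = np.empty((n_obs, k, T))
    for i, b in enumerate(cue_bins):
        ctf[i] = np.roll(C2[:, i, :], -b, axis=0)
    return ChannelResponses(ctf=ctf, cue_bins=cue_bins, times=times,
                            hpl_bin=hpl_bin)
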