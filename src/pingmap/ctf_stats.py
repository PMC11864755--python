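"""CTF slope estimation and nonparametric group inference.

Spatial selectivity is summarized per time sample by the slope of the
re-centered CTF: the two symmetric offsets at each angular distance are
folded (averaged), a least-squares line is fitted to the five points at
distances 0-4, and the fitted coefficient is sign-flipped so that a
positive slope means tuning toward the cued location.  Group inference
uses a cluster-based one-sample sign-flip permutation test on the
subject x time slope matrix, and the distance gradient around the
high-probability location is tested by regressing slope on distance per
subject and per time sample and passing the coefficients to the same
cluster test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.stats

__all__ = ["fold_ctf", "ctf_slope", "cluster_perm_test", "distance_gradient",
           "ClusterResult", "GradientResult"]

# least-squares line through points at x = 0..4: fitted slope = sum(w * y);
# the reported CTF slope negates it so positive = selectivity
_X = np.arange(5.0)
_W_SLOPE = (_X - _X.mean()) / ((_X - _X.mean()) ** 2).sum()


def fold_ctf(ctf: np.ndarray, axis: int = -2) -> np.ndarray:
    """Fold an 8-offset CTF into 5 angular distances (0, 45, 90, 135, 180).

    Offsets +/-45, +/-90 and +/-135 are averaged; offsets 0 and 180 map
    through unchanged.  ``axis`` indexes the 8-channel offset dimension.
    """
    ctf = np.moveaxis(np.asarray(ctf, dtype=float), axis, 0)
    if ctf.shape[0] != 8:
        raise ValueError("folding expects 8 channel offsets")
    folded = np.empty((5,) + ctf.shape[1:])
    folded[0] = ctf[0]
    for d in (1, 2, 3):
        folded[d] = 0.5 * (ctf[d] + ctf[8 - d])
    folded[4] = ctf[4]
    return np.moveaxis(folded, 0, axis)


def ctf_slope(ctf: np.ndarray, axis: int = -2, folded: bool = False) -> np.ndarray:
    """Linear CTF slope per time sample (positive = spatial selectivity).

    ``ctf`` carries 8 channel offsets (or 5 folded distances when
    ``folded=True``) on ``axis``; the slope is the negated least-squares
    coefficient of response against distance 0-4.  A flat CTF maps to
    exactly 0; the estimator is linear in the CTF.
    """
    prof = np.asarray(ctf, dtype=float) if folded else fold_ctf(ctf, axis=axis)
    prof = np.moveaxis(prof, axis, -1)
    if prof.shape[-1] != 5:
        raise ValueError("expected 5 distances after folding")
    return -prof @ _W_SLOPE


@dataclass
class ClusterResult:
    """Outcome of a cluster-based one-sample sign-flip permutation test."""

    tvals: np.ndarray                      # (T,)
    threshold: float
    clusters: list = field(default_factory=list)   # list of (start, stop) sample spans
    masses: np.ndarray = None              # summed t per cluster
    pvals: np.ndarray = None               # (+1)-corrected permutation p per cluster
    sig_mask: np.ndarray = None            # (T,) bool, clusters with p <= alpha
    null_max: np.ndarray = None            # (n_perm,) max |cluster mass| under H0
    alpha: float = 0.05

    @property
    def significant_clusters(self) -> list:
        return [c for c, p in zip(self.clusters, self.pvals) if p <= self.alpha]


def _max_cluster_mass_rows(tmat: np.ndarray, threshold: float) -> np.ndarray:
    """Max |cluster mass| per row of a (rows, T) t-matrix; 0 where none.

    Clusters are runs of contiguous samples whose t exceeds the threshold
    with a consistent sign.  Row-only connectivity.
    """
    rows, T = tmat.shape
    out = np.zeros(rows)
    structure = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
    for sign in (1.0, -1.0):
        mask = sign * tmat > threshold
        labels, n = scipy.ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        sums = np.abs(scipy.ndimage.sum_labels(tmat, labels, idx))
        # row of each cluster: labels are assigned in raster order
        first = scipy.ndimage.minimum_position(
            np.broadcast_to(np.arange(rows)[:, None], tmat.shape), labels, idx)
        label_rows = np.array([p[0] for p in first], dtype=int)
        np.maximum.at(out, label_rows, sums)
    return out


def _find_clusters(tvals: np.ndarray, threshold: float) -> tuple[list, np.ndarray]:
    clusters, masses = [], []
    for sign in (1.0, -1.0):
        mask = sign * tvals > threshold
        labels, n = scipy.ndimage.label(mask)
        for i in range(1, n + 1):
            where = np.flatnonzero(labels == i)
            clusters.append((int(where[0]), int(where[-1]) + 1))
            masses.append(tvals[where].sum())
    order = np.argsort([c[0] for c in clusters])
    return [clusters[i] for i in order], np.asarray(masses)[order]


def cluster_perm_test(values: np.ndarray, n_perm: int = 1024,
                      alpha: float = 0.05, threshold: float | None = None,
                      seed: int | np.random.Generator = 0) -> ClusterResult:
    """Cluster-based one-sample permutation test over time.

    Parameters
    ----------
    values : (n_subjects, T) per-subject time series tested against 0
    n_perm : number of random sign-flip permutations (1024 in the full
        analysis)
    threshold : cluster-forming threshold on |t|; defaults to the two-tailed
        t critical value at ``alpha`` with n_subjects - 1 df

    Notes
    -----
    One-sample t values are computed per sample; contiguous samples with
    |t| above the threshold and a consistent sign form clusters whose mass
    is the summed t.  The null distribution is the maximum |cluster mass|
    over the window for each of ``n_perm`` random per-subject sign flips;
    each observed cluster gets p = (1 + #{null >= |mass|}) / (1 + n_perm).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("values must be (n_subjects >= 2, n_times)")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation distribution",
                      stacklevel=2)
    S, T = values.shape
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if threshold is None:
        threshold = float(scipy.stats.t.ppf(1.0 - alpha / 2.0, S - 1))

    def _tvals(mean, ssq):
        var = (ssq - S * mean ** 2) / (S - 1)
        sd = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(S))
        return np.where(sd == 0, 0.0, t)

    ssq = (values ** 2).sum(axis=0)  # invariant under sign flips
    tvals = _tvals(values.mean(axis=0), ssq)
    clusters, masses = _find_clusters(tvals, threshold)

    flips = rng.choice([-1.0, 1.0], size=(n_perm, S))
    perm_means = flips @ values / S
    perm_t = _tvals(perm_means, ssq[None, :])
    null_max = _max_cluster_mass_rows(perm_t, threshold)

    pvals = np.array([(1 + np.sum(null_max >= abs(m))) / (1 + n_perm)
                      for m in masses])
    sig = np.zeros(T, dtype=bool)
    for (start, stop), p in zip(clusters, pvals):
        if p <= alpha:
            sig[start:stop] = True
    return ClusterResult(tvals=tvals, threshold=threshold, clusters=clusters,
                         masses=masses, pvals=pvals, sig_mask=sig,
                         null_max=null_max, alpha=alpha)


@dataclass
class GradientResult:
    """Distance-gradient regression around the HPL plus its cluster test."""

    coefs: np.ndarray          # (n_subjects, T) slope-vs-distance coefficient
    cluster: ClusterResult


def distance_gradient(slopes: np.ndarray, n_perm: int = 1024,
                      alpha: float = 0.05, threshold: float | None = None,
                      seed: int | np.random.Generator = 0) -> GradientResult:
    """Regress CTF slope on distance from the HPL and cluster-test the fit.

    Parameters
    ----------
    slopes : (n_subjects, 5 distances, T) CTF slopes per distance 0-4

    The per-subject, per-sample least-squares coefficient of slope against
    distance (negative = selectivity decreasing away from the HPL) is
    passed to :func:`cluster_perm_test`.
    """
    slopes = np.asarray(slopes, dtype=float)
    if slopes.ndim != 3 or slopes.shape[1] != 5:
        raise ValueError("slopes must be (n_subjects, 5, n_times)")
    if np.isnan(slopes).any():
        raise ValueError("missing distance level (NaN slopes)")
    coefs = np.einsum("sdt,d->st", slopes, _W_SLOPE)
    cluster = cluster_perm_test(coefs, n_perm=n_perm, alpha=alpha,
                                threshold=threshold, seed=seed)
    return GradientResult(coefs=coefs, cluster=cluster)
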