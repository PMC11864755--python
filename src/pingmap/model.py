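"""Model/results interface over the encoding pipeline.

:class:`SpatialEncodingModel` bundles a subject's trial table and
alpha-band analytic epochs; ``fit()`` runs the partition/train/invert loop
and returns :class:`SpatialEncodingResults` carrying the iteration-averaged
CTFs and their slope time courses.  :class:`GroupResults` stacks per-subject
results and exposes the group-level cluster and gradient tests plus a text
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ctf_stats
from .containers import EpochArray
from .iem import BasisSet, ChannelResponses, make_basis
from .partitioning import run_iem_iterations
from .spectral import AnalyticEpochs, bandpass_hilbert

__all__ = ["SpatialEncodingModel", "SpatialEncodingResults", "GroupResults"]


class SpatialEncodingModel:
    """Inverted spatial encoding model for one subject.

    Parameters
    ----------
    trials : trial table (see containers.TRIAL_COLUMNS)
    analytic_train : alpha-band analytic signal of the training-phase
        (localizer) epochs
    analytic_test : test-phase epochs, required for ``mode='cross'``
    mode : 'within' (3-set partition of the localizer) or 'cross'
        (train on the localizer, test on the test phase)
    kind : 'evoked' or 'total' power
    hpl_bin : high-probability distractor location, for distance groupings
    """

    def __init__(self, trials: pd.DataFrame, analytic_train: AnalyticEpochs,
                 analytic_test: AnalyticEpochs | None = None, *,
                 mode: str = "within", kind: str = "evoked",
                 hpl_bin: int | None = None, smooth_window: int = 8,
                 n_components: int | None = 16, basis: BasisSet | None = None):
        self.trials = trials
        self.analytic_train = analytic_train
        self.analytic_test = analytic_test
        self.mode = mode
        self.kind = kind
        self.hpl_bin = hpl_bin
        self.smooth_window = smooth_window
        self.n_components = n_components
        self.basis = basis or make_basis()

    @classmethod
    def from_epochs(cls, trials: pd.DataFrame, epochs_train: EpochArray,
                    epochs_test: EpochArray | None = None, *,
                    band: tuple = (8.0, 13.0), order: int = 5,
                    crop: bool = True, **kwargs) -> "SpatialEncodingModel":
        """Build the model straight from broadband epochs.

        Filters to the alpha band, takes the analytic signal, and crops the
        filter padding down to the window of interest.
        """
        at = bandpass_hilbert(epochs_train, *band, order=order)
        att = None if epochs_test is None else bandpass_hilbert(epochs_test,
                                                                *band, order=order)
        if crop:
            at = at.crop()
            att = None if att is None else att.crop()
        return cls(trials, at, att, **kwargs)

    def fit(self, n_iter: int = 100, seed: int = 0) -> "SpatialEncodingResults":
        ctf = run_iem_iterations(
            self.trials, self.analytic_train, self.analytic_test,
            mode=self.mode, kind=self.kind, n_iter=n_iter, seed=seed,
            hpl_bin=self.hpl_bin, smooth_window=self.smooth_window,
            n_components=self.n_components, basis=self.basis)
        return SpatialEncodingResults(model=self, ctf=ctf, n_iter=n_iter,
                                      seed=seed)


@dataclass
class SpatialEncodingResults:
    """Iteration-averaged CTFs for one subject."""

    model: SpatialEncodingModel
    ctf: ChannelResponses
    n_iter: int
    seed: int

    @property
    def times(self) -> np.ndarray:
        return self.ctf.times

    def slope(self, grouping: str = "grand") -> np.ndarray:
        """CTF slope time course.

        grouping='grand' -> (T,); 'by_distance' -> (5, T);
        'per_location' -> (8, T).
        """
        prof = getattr(self.ctf, grouping)
        return ctf_stats.ctf_slope(prof, axis=-2)


@dataclass
class GroupResults:
    """Per-subject encoding results stacked for group inference."""

    results: list
    times: np.ndarray = field(init=False)

    def __post_init__(self):
        if len(self.results) < 2:
            raise ValueError("group inference needs at least 2 subjects")
        self.times = self.results[0].times
        for r in self.results[1:]:
            if not np.allclose(r.times, self.times):
                raise ValueError("subjects have mismatching time axes")

    def slopes(self, grouping: str = "grand") -> np.ndarray:
        """(n_subjects, ..., T) stacked slope time courses."""
        return np.stack([r.slope(grouping) for r in self.results])

    def _window_slice(self, window):
        if window is None:
            return slice(None)
        lo, hi = window
        idx = np.flatnonzero((self.times >= lo - 1e-9) & (self.times <= hi + 1e-9))
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def cluster_test(self, window: tuple | None = None, n_perm: int = 1024,
                     alpha: float = 0.05, seed: int = 0,
                     grouping: str = "grand") -> ctf_stats.ClusterResult:
        """Cluster permutation test of the group slope against zero."""
        sl = self._window_slice(window)
        return ctf_stats.cluster_perm_test(self.slopes(grouping)[:, sl],
                                           n_perm=n_perm, alpha=alpha, seed=seed)

    def gradient_test(self, window: tuple | None = None, n_perm: int = 1024,
                      alpha: float = 0.05, seed: int = 0) -> ctf_stats.GradientResult:
        """Distance-gradient regression around the HPL plus cluster test."""
        sl = self._window_slice(window)
        return ctf_stats.distance_gradient(self.slopes("by_distance")[:, :, sl],
                                           n_perm=n_perm, alpha=alpha, seed=seed)

    def summary(self, windows: dict | None = None, n_perm: int = 1024,
                seed: int = 0) -> str:
        """Text summary: mean slopes and cluster/gradient test outcomes."""
        windows = windows or {"full window": None}
        lines = [f"Spatial encoding group results ({len(self.results)} subjects, "
                 f"{self.results[0].model.kind} power, "
                 f"mode={self.results[0].model.mode})"]
        slopes = self.slopes("grand")
        for name, win in windows.items():
            sl = self._window_slice(win)
            mean_slope = slopes[:, sl].mean()
            res = self.cluster_test(win, n_perm=n_perm, seed=seed)
            sig = res.significant_clusters
            lines.append(
                f"  {name}: mean CTF slope {mean_slope:.4f}; "
                f"{len(sig)} significant cluster(s)"
                + (f", smallest p = {res.pvals.min():.4g}" if len(res.pvals) else ""))
        return "\n".join(lines)
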