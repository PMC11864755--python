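"""In-memory containers and file I/O for trial tables and epoched data.

Trial tables are plain :class:`pandas.DataFrame` objects with documented
columns (see :data:`TRIAL_COLUMNS`); epochs live in :class:`EpochArray`,
a light trials x electrodes x samples container persisted as HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Canonical trial-table columns.  ``cue_bin``/``distractor_bin`` use -1 for
#: "none"/"absent" in the CSV serialization and nullable values in memory.
TRIAL_COLUMNS = {
    "subject": "subject identifier (int)",
    "phase": "'training' (localizer, memory task only) or 'test' (search embedded)",
    "block": "block index within phase (0-based)",
    "trial": "trial index within phase (0-based)",
    "cue_bin": "memory-cue location bin 0-7; <NA> on no-memory trials",
    "cue_angle": "exact cue angle in degrees [0, 360); NaN on no-memory trials",
    "no_memory": "True when the memory cue was replaced by a neutral fixation",
    "distractor_bin": "color-singleton distractor bin 0-7; <NA> when absent",
    "target_bin": "shape-singleton target bin 0-7 (test phase); <NA> in training",
    "rt": "search reaction time in ms; NaN where no search task",
    "correct": "search response correct (bool); <NA> where no search task",
    "recall_deviation": "signed angular recall error in degrees; NaN on no-memory trials",
    "set_id": "partition label assigned by partitioning; <NA> before partitioning",
}


def circular_distance_bins(a, b, n_bins: int = 8):
    """Circular bin distance min(|a-b|, n-|a-b|), elementwise."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % n_bins
    return np.minimum(d, n_bins - d)


def write_trials(trials: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    out = trials.copy()
    for col in ("cue_bin", "distractor_bin", "target_bin"):
        if col in out:
            out[col] = out[col].fillna(-1).astype(int)
    out.to_csv(path, sep=sep, index=False)


def read_trials(path: str | Path, sep: str = ",") -> pd.DataFrame:
    trials = pd.read_csv(path, sep=sep)
    for col in ("cue_bin", "distractor_bin", "target_bin"):
        if col in trials:
            trials[col] = trials[col].astype("Int64").where(trials[col] >= 0)
    if "no_memory" in trials:
        trials["no_memory"] = trials["no_memory"].astype(bool)
    if "correct" in trials:
        trials["correct"] = trials["correct"].astype("boolean")
    return trials


@dataclass
class EpochArray:
    """Epoched multichannel data: trials x electrodes x samples.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_electrodes, n_samples)
    times : ndarray, seconds relative to the locking event
    sfreq : sampling rate in Hz
    trial_index : index into the originating trial table
    window : (tmin, tmax) window of interest; samples outside it are filter
        padding
    gaze : optional gaze eccentricity trace in visual degrees, (trials, samples)
    heog : optional horizontal EOG trace in microvolts, (trials, samples)
    truth : optional generator ground truth (see simulate.generate_epochs)
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    trial_index: np.ndarray
    window: tuple = None
    gaze: np.ndarray | None = None
    heog: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_index = np.asarray(self.trial_index)
        if self.data.ndim != 3:
            raise ValueError("EpochArray.data must be trials x electrodes x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length does not match data")
        if self.window is None:
            self.window = (float(self.times[0]), float(self.times[-1]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.times.copy(), self.sfreq,
                          self.trial_index.copy(), tuple(self.window),
                          None if self.gaze is None else self.gaze.copy(),
                          None if self.heog is None else self.heog.copy(),
                          dict(self.truth))

    def time_mask(self, tmin: float | None = None, tmax: float | None = None) -> np.ndarray:
        tmin = self.window[0] if tmin is None else tmin
        tmax = self.window[1] if tmax is None else tmax
        return (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)

    def select_trials(self, mask_or_idx) -> "EpochArray":
        idx = np.asarray(mask_or_idx)
        truth = {}
        for key, val in self.truth.items():
            arr = np.asarray(val)
            truth[key] = arr[idx] if arr.ndim and arr.shape[0] == self.n_trials else val
        return EpochArray(self.data[idx], self.times, self.sfreq,
                          self.trial_index[idx], tuple(self.window),
                          None if self.gaze is None else self.gaze[idx],
                          None if self.heog is None else self.heog[idx],
                          truth)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data, compression=None)
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("trial_index", data=np.asarray(self.trial_index, dtype=np.int64))
            fh.attrs["sfreq"] = self.sfreq
            fh.attrs["window"] = np.asarray(self.window, dtype=float)
            if self.gaze is not None:
                fh.create_dataset("gaze", data=self.gaze)
            if self.heog is not None:
                fh.create_dataset("heog", data=self.heog)
            grp = fh.create_group("truth")
            for key, val in self.truth.items():
                grp.create_dataset(key, data=np.asarray(val))

    @classmethod
    def load(cls, path: str | Path) -> "EpochArray":
        with h5py.File(path, "r") as fh:
            truth = {k: fh["truth"][k][()] for k in fh["truth"]} if "truth" in fh else {}
            return cls(
                data=fh["data"][()],
                times=fh["times"][()],
                sfreq=float(fh.attrs["sfreq"]),
                trial_index=fh["trial_index"][()],
                window=tuple(fh.attrs["window"]),
                gaze=fh["gaze"][()] if "gaze" in fh else None,
                heog=fh["heog"][()] if "heog" in fh else None,
                truth=truth,
            )
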