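"""Configuration objects for the simulated ping/search experiment.

Every stochastic stage takes an explicit seed; :class:`RunConfig` derives
per-stage seeds from one master seed so a full pipeline run is reproducible
from a single integer.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class DesignConfig:
    """Trial composition of the two-phase experiment.

    The training phase is a pure spatial-memory task (the localizer); the
    test phase embeds an additional-singleton search task in the memory
    maintenance interval.  A color-singleton distractor appears on 74% of
    search trials and, when present, sits at one fixed high-probability
    location (HPL) on 65% of trials and at each of the seven low-probability
    locations (LPLs) on 5%.  13% of test-phase trials carry no memory cue.
    """

    n_blocks_train: int = 10
    trials_per_block_train: int = 80
    n_blocks_test: int = 10
    trials_per_block_test: int = 92
    n_locations: int = 8
    jitter_half_range: float = 22.5
    p_distractor_present: float = 0.74
    p_hpl_given_present: float = 0.65
    p_each_lpl_given_present: float = 0.05
    hpl_bin: int = 4
    p_no_memory: float = 0.13
    seed: int = 0

    @property
    def location_centers(self) -> np.ndarray:
        """Bin-center angles in degrees: 0, 45, ..., 315."""
        return np.arange(self.n_locations) * (360.0 / self.n_locations)

    @property
    def n_trials_train(self) -> int:
        return self.n_blocks_train * self.trials_per_block_train

    @property
    def n_trials_test(self) -> int:
        return self.n_blocks_test * self.trials_per_block_test

    def validate(self) -> None:
        probs = (self.p_distractor_present, self.p_hpl_given_present,
                 self.p_each_lpl_given_present, self.p_no_memory)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError(f"probabilities must lie in [0, 1]: {probs}")
        mass = self.p_hpl_given_present + (self.n_locations - 1) * self.p_each_lpl_given_present
        if abs(mass - 1.0) > 1e-12:
            raise ConfigurationError(
                "conditional distractor-location probabilities must sum to 1, "
                f"got {mass!r}")
        if not 0 <= self.hpl_bin < self.n_locations:
            raise ConfigurationError(f"hpl_bin {self.hpl_bin} outside 0..{self.n_locations - 1}")
        if self.jitter_half_range < 0 or self.jitter_half_range > 180.0 / self.n_locations:
            raise ConfigurationError("jitter_half_range must keep bins non-overlapping")


@dataclass
class BehaviorEffects:
    """Planted behavioral effect structure for the search task.

    RT (ms) is additive: base + capture cost when a distractor is present
    + a per-distance delta (distance of the distractor from the HPL,
    0 = at the HPL) + a cost when the target occupies the HPL + a benefit
    when the distractor location repeats, plus Gaussian noise.  Accuracy is
    Bernoulli with per-distance deltas.  Recall deviation is wrapped-normal,
    broader in the test phase where the concurrent search task disrupts
    memory maintenance.
    """

    rt_base: float = 1000.0
    capture_cost: float = 50.0
    delta_by_distance: tuple = (-50.0, -25.0, 0.0, 0.0, 0.0)
    target_at_hpl_cost: float = 60.0
    repeat_delta: float = -40.0
    rt_noise_sd: float = 150.0
    acc_base: float = 0.90
    acc_delta_by_distance: tuple = (0.02, 0.02, -0.01, -0.01, -0.02)
    recall_sd_train: float = 6.0
    recall_sd_test: float = 12.0

    def validate(self) -> None:
        if len(self.delta_by_distance) != 5 or len(self.acc_delta_by_distance) != 5:
            raise ConfigurationError("distance deltas need 5 entries (distances 0-4)")
        if self.rt_base <= 0:
            raise ConfigurationError("rt_base must be positive")


@dataclass
class ForwardModel:
    """Ground-truth generative model mapping 8 spatial channels to electrodes.

    Each channel is a neuronal population tuned to one of the eight display
    locations; its scalp projection is a Gaussian bump over posterior
    electrodes centered at the matching angle.  Electrode signals are
    ``mixing @ activations`` carried by an alpha oscillation whose
    phase-locked (evoked) and random-phase (induced) components are
    separately scaled, plus 1/f ("pink") and white noise.  ``gradient``
    multiplies the ping-evoked tuning amplitude as a function of the cue's
    circular bin distance (0-4) from the HPL, which is how a planted
    priority-map gradient enters the data.

    Amplitudes are in arbitrary units; the noise defaults were calibrated
    once so that single-subject CTF recovery succeeds at roughly 800 trials
    (see docs/methods.md) and are not tuned per experiment.
    """

    n_electrodes: int = 64
    n_channels: int = 8
    alpha_freq: float = 10.0
    evoked_amp: float = 1.0
    induced_amp: float = 1.0
    ping_amp: float = 1.0
    gradient: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    noise_pink: float = 4.0
    noise_white: float = 1.0
    tuning_sigma: float = 0.05
    mixing_seed: int = 0

    def validate(self) -> None:
        if len(self.gradient) != 5:
            raise ConfigurationError("gradient needs 5 entries (distances 0-4)")
        if self.alpha_freq <= 0:
            raise ConfigurationError("alpha_freq must be positive")


@dataclass
class EpochTiming:
    """Event timing and epoch window for simulated epochs.

    Times are seconds relative to the epoch's locking event.  ``pad``
    extends the generated window on both sides so band-pass filtering and
    the Hilbert transform have room beyond the window of interest
    (``tmin``..``tmax``).
    """

    sfreq: float = 512.0
    tmin: float = -0.75
    tmax: float = 1.6
    pad: float = 0.25
    cue_onset: float | None = 0.0
    ping_onset: float | None = 1.2
    evoked_rise: float = 0.05
    evoked_plateau: float = 0.15
    evoked_fall: float = 0.30
    induced_rise: float = 0.10

    @classmethod
    def cue_locked(cls, **kw) -> "EpochTiming":
        return cls(**kw)

    @classmethod
    def ping_locked(cls, *, tmin: float = -0.75, tmax: float = 1.0, **kw) -> "EpochTiming":
        """Epoch locked to placeholder (ping) onset; the memory cue lies
        before the epoch, so only its sustained induced activity is modeled."""
        return cls(tmin=tmin, tmax=tmax, cue_onset=None, ping_onset=0.0, **kw)

    def validate(self) -> None:
        if self.sfreq <= 0 or self.tmax <= self.tmin or self.pad < 0:
            raise ConfigurationError("invalid epoch timing")


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end pipeline run."""

    design: DesignConfig = field(default_factory=DesignConfig)
    effects: BehaviorEffects = field(default_factory=BehaviorEffects)
    forward: ForwardModel = field(default_factory=ForwardModel)
    timing: EpochTiming = field(default_factory=EpochTiming)
    n_subjects: int = 24
    band: tuple = (8.0, 13.0)
    filter_order: int = 5
    power_kind: str = "evoked"
    smooth_window: int = 8
    n_components: int | None = 16
    n_iterations: int = 20
    n_permutations: int = 512
    alpha: float = 0.05
    mode: str = "cross"
    seed: int = 0
    # Desk-scale overrides: simulate fewer trials than the full design so a
    # complete multi-subject run stays tractable on one CPU.
    trials_per_phase: int | None = 400

    def validate(self) -> None:
        self.design.validate()
        self.effects.validate()
        self.forward.validate()
        self.timing.validate()
        if self.mode not in ("within", "cross"):
            raise ConfigurationError(f"mode must be 'within' or 'cross', got {self.mode!r}")
        if self.power_kind not in ("evoked", "total"):
            raise ConfigurationError("power_kind must be 'evoked' or 'total'")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects for group statistics")

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        ss = np.random.SeedSequence([self.seed, tag, index])
        return int(ss.generate_state(1)[0] % (2**31))


_SECTIONS = {"design": DesignConfig, "effects": BehaviorEffects,
             "forward": ForwardModel, "timing": EpochTiming}


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            for name in ("gradient", "delta_by_distance", "acc_delta_by_distance"):
                if name in val:
                    val[name] = tuple(val[name])
            kwargs[key] = _SECTIONS[key](**val)
        else:
            if key in ("band",) and isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
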