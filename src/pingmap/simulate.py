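"""Synthetic two-phase ping/search experiments with known ground truth.

The generator emulates the study design the analysis assumes: a training
phase (spatial-memory localizer, 10 blocks x 80 trials) and a test phase
(10 blocks x 92 trials) in which an additional-singleton search task is
embedded in the memory maintenance interval.  Memory cues are drawn from 8
location bins at 45 deg spacing with +/-22.5 deg angular jitter; a
color-singleton distractor appears on 74% of search trials, at the
high-probability location (HPL) on 65% of those and at each low-probability
location on 5%; 13% of test-phase trials carry no memory cue.

Epochs are produced by a linear forward model: eight location-tuned
spatial channels project to electrodes through a mixing matrix, carried by
an alpha oscillation with separately controllable phase-locked (evoked) and
random-phase (induced) components, a ping-evoked phase-locked revival whose
tuning amplitude can follow a planted gradient over distance from the HPL,
plus pink and white noise.  Full ground truth is stored for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BehaviorEffects, ConfigurationError, DesignConfig, EpochTiming, ForwardModel
from .containers import EpochArray, circular_distance_bins
from .iem import make_basis

__all__ = [
    "generate_design", "generate_behavior", "generate_epochs",
    "inject_artifacts", "electrode_positions", "build_mixing",
    "simulate_subject", "ArtifactConfig",
]


# ---------------------------------------------------------------------------
# Trial design


def generate_design(cfg: DesignConfig, *, subject: int = 0,
                    n_trials_train: int | None = None,
                    n_trials_test: int | None = None) -> pd.DataFrame:
    """Sample a full two-phase trial table.

    Conditions are sampled i.i.d. per trial: distractor presence with
    probability ``p_distractor_present``; given presence, the distractor bin
    is the HPL with probability 0.65 and each other bin with 0.05; target
    and cue bins are uniform; the cue angle adds uniform jitter in
    [-22.5, 22.5) deg to the bin center.  No-memory trials occur only in the
    test phase.  Deterministic given ``cfg.seed`` (offset by ``subject``).

    ``n_trials_*`` override the block-derived counts (e.g. for very large
    composition checks or desk-scale runs); block labels still honour the
    configured trials-per-block.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject]))
    n_train = cfg.n_trials_train if n_trials_train is None else int(n_trials_train)
    n_test = cfg.n_trials_test if n_trials_test is None else int(n_trials_test)
    frames = []
    for phase, n in (("training", n_train), ("test", n_test)):
        per_block = (cfg.trials_per_block_train if phase == "training"
                     else cfg.trials_per_block_test)
        cue_bin = rng.integers(0, cfg.n_locations, n)
        jitter = rng.uniform(-cfg.jitter_half_range, cfg.jitter_half_range, n)
        cue_angle = (cue_bin * (360.0 / cfg.n_locations) + jitter) % 360.0
        tbl = pd.DataFrame({
            "subject": subject,
            "phase": phase,
            "block": np.arange(n) // per_block,
            "trial": np.arange(n),
            "cue_bin": pd.array(cue_bin, dtype="Int64"),
            "cue_angle": cue_angle,
            "no_memory": False,
            "distractor_bin": pd.array([pd.NA] * n, dtype="Int64"),
            "target_bin": pd.array([pd.NA] * n, dtype="Int64"),
        })
        if phase == "test":
            no_mem = rng.random(n) < cfg.p_no_memory
            tbl.loc[no_mem, "no_memory"] = True
            tbl.loc[no_mem, "cue_bin"] = pd.NA
            tbl.loc[no_mem, "cue_angle"] = np.nan
            present = rng.random(n) < cfg.p_distractor_present
            # conditional location: HPL w.p. 0.65, else one of the 7 LPLs
            probs = np.full(cfg.n_locations, cfg.p_each_lpl_given_present)
            probs[cfg.hpl_bin] = cfg.p_hpl_given_present
            dbin = rng.choice(cfg.n_locations, size=n, p=probs)
            tbl.loc[present, "distractor_bin"] = dbin[present]
            # target uniform over bins, never colocated with the distractor
            tbin = rng.integers(0, cfg.n_locations, n)
            clash = present & (tbin == dbin)
            while clash.any():
                tbin[clash] = rng.integers(0, cfg.n_locations, int(clash.sum()))
                clash = present & (tbin == dbin)
            tbl["target_bin"] = pd.array(tbin, dtype="Int64")
        frames.append(tbl)
    trials = pd.concat(frames, ignore_index=True)
    trials["rt"] = np.nan
    trials["correct"] = pd.array([pd.NA] * len(trials), dtype="boolean")
    trials["recall_deviation"] = np.nan
    trials["set_id"] = pd.array([pd.NA] * len(trials), dtype="Int64")
    return trials


def generate_behavior(trials: pd.DataFrame, effects: BehaviorEffects,
                      hpl_bin: int, seed: int = 0) -> pd.DataFrame:
    """Fill rt / correct / recall_deviation columns with planted effects.

    RT = base + capture cost + distance delta + target-at-HPL cost +
    repetition delta + Gaussian noise; negative draws are resampled (the
    count is recorded in ``trials.attrs['n_rt_resampled']``).  Accuracy is
    Bernoulli per condition; recall deviation is wrapped-normal with a
    phase-specific SD.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    out = trials.copy()
    is_search = (out["phase"] == "test").to_numpy()
    n = len(out)

    rt_mean = np.full(n, effects.rt_base)
    dbin = out["distractor_bin"].to_numpy(dtype=float, na_value=np.nan)
    tbin = out["target_bin"].to_numpy(dtype=float, na_value=np.nan)
    present = ~np.isnan(dbin)
    dist = np.zeros(n, dtype=int)
    dist[present] = circular_distance_bins(dbin[present], hpl_bin)
    rt_mean[present] += effects.capture_cost
    rt_mean[present] += np.asarray(effects.delta_by_distance)[dist[present]]
    rt_mean[np.nan_to_num(tbin, nan=-1) == hpl_bin] += effects.target_at_hpl_cost
    # repetition: previous trial (same subject, consecutive) had a distractor
    # at the same location
    prev_dbin = np.full(n, np.nan)
    prev_dbin[1:] = dbin[:-1]
    same_subj = np.ones(n, dtype=bool)
    subj = out["subject"].to_numpy()
    same_subj[1:] = subj[1:] == subj[:-1]
    repeat = present & ~np.isnan(prev_dbin) & (dbin == prev_dbin) & same_subj
    rt_mean[repeat] += effects.repeat_delta

    rt = rt_mean + rng.normal(0.0, effects.rt_noise_sd, n)
    n_resampled = 0
    bad = rt <= 0
    while bad.any():
        n_resampled += int(bad.sum())
        rt[bad] = rt_mean[bad] + rng.normal(0.0, effects.rt_noise_sd, int(bad.sum()))
        bad = rt <= 0
    out.loc[is_search, "rt"] = rt[is_search]

    p_corr = np.full(n, effects.acc_base)
    p_corr[present] += np.asarray(effects.acc_delta_by_distance)[dist[present]]
    correct = rng.random(n) < np.clip(p_corr, 0.0, 1.0)
    out.loc[is_search, "correct"] = correct[is_search]

    has_cue = ~out["no_memory"].to_numpy()
    sd = np.where(out["phase"].to_numpy() == "training",
                  effects.recall_sd_train, effects.recall_sd_test)
    dev = rng.normal(0.0, sd, n)
    dev = (dev + 180.0) % 360.0 - 180.0  # wrapped normal on (-180, 180]
    out.loc[has_cue, "recall_deviation"] = dev[has_cue]
    out.attrs["n_rt_resampled"] = n_resampled
    return out


# ---------------------------------------------------------------------------
# Forward model


def electrode_positions(n_electrodes: int = 64) -> np.ndarray:
    """3D positions (meters) of the standard 64-channel 10-10 layout.

    Loaded from mne's built-in biosemi64 montage; for ``n_electrodes`` < 64
    an evenly spaced subset is returned.  Used only to define interpolation
    neighborhoods and the spatial spread of channel topographies.
    """
    import mne  # local import: mne is slow to import and only needed here

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = np.array([montage.get_positions()["ch_pos"][name]
                    for name in montage.ch_names])
    if n_electrodes > len(pos):
        raise ConfigurationError(f"at most {len(pos)} electrodes available")
    if n_electrodes < len(pos):
        idx = np.round(np.linspace(0, len(pos) - 1, n_electrodes)).astype(int)
        pos = pos[idx]
    return pos


def build_mixing(fwd: ForwardModel, positions: np.ndarray | None = None) -> np.ndarray:
    """Channel-to-electrode mixing matrix (n_electrodes x k).

    Each spatial channel projects as a Gaussian bump (width
    ``fwd.tuning_sigma`` meters) over posterior electrodes, centered at a
    point on a posterior ring at the channel's preferred angle, with a small
    seeded random component to break symmetry.  Raises if the result is
    column-rank deficient.
    """
    fwd.validate()
    if positions is None:
        positions = electrode_positions(fwd.n_electrodes)
    k = fwd.n_channels
    angles = np.deg2rad(np.arange(k) * (360.0 / k))
    # ring over posterior scalp: x lateral, y anterior-posterior, z vertical
    r = 0.07
    centers = np.stack([r * np.sin(angles), -0.04 - 0.03 * np.cos(angles),
                        np.full(k, 0.02)], axis=1)
    d2 = ((positions[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    mixing = np.exp(-d2 / (2.0 * fwd.tuning_sigma ** 2))
    rng = np.random.default_rng(fwd.mixing_seed)
    mixing = mixing + 0.02 * rng.random(mixing.shape)
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    if np.linalg.matrix_rank(mixing) < k:
        raise ConfigurationError("mixing matrix is column-rank deficient")
    return mixing


def _bump(times: np.ndarray, onset: float, rise: float, plateau: float,
          fall: float) -> np.ndarray:
    """Half-cosine rise / plateau / half-cosine fall envelope, peak 1."""
    env = np.zeros_like(times)
    t = times - onset
    up = (t >= 0) & (t < rise)
    env[up] = 0.5 * (1 - np.cos(np.pi * t[up] / max(rise, 1e-9)))
    hold = (t >= rise) & (t < rise + plateau)
    env[hold] = 1.0
    down = (t >= rise + plateau) & (t < rise + plateau + fall)
    env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - rise - plateau) / max(fall, 1e-9)))
    return env


def _ramp(times: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """Half-cosine ramp to 1, sustained to the end of the epoch."""
    env = np.zeros_like(times)
    t = times - onset
    up = (t >= 0) & (t < rise)
    env[up] = 0.5 * (1 - np.cos(np.pi * t[up] / max(rise, 1e-9)))
    env[t >= rise] = 1.0
    return env


def pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float) -> np.ndarray:
    """1/f-power noise with random phases, unit variance, last axis = time."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** -0.5  # amplitude 1/sqrt(f) -> power 1/f
    amp[0] = 0.0
    noise = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = noise.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def generate_epochs(trials: pd.DataFrame, fwd: ForwardModel,
                    timing: EpochTiming, seed: int = 0,
                    hpl_bin: int | None = None,
                    mixing: np.ndarray | None = None) -> EpochArray:
    """Simulate epochs for every trial row with a memory cue.

    Per trial the eight channel activations are the basis responses at the
    exact cue angle; the electrode signal is ``mixing @ activations`` times
    an alpha carrier.  The evoked component has a fixed phase across trials
    (phase-locked to the event), the induced component a uniform random
    phase per trial.  The ping-evoked revival is scaled by
    ``fwd.gradient[dist(cue_bin, hpl_bin)]``.  No-memory trials get
    noise-only epochs (zero activations).

    Ground truth stored in ``truth``: per-trial channel ``profiles`` (n, 8),
    the shared ``cue_env`` / ``ping_env`` / ``induced_env`` envelopes (T,),
    per-trial ``ping_gain``, and the ``mixing`` matrix.
    """
    fwd.validate()
    timing.validate()
    if mixing is None:
        mixing = build_mixing(fwd)
    if np.linalg.matrix_rank(mixing) < fwd.n_channels:
        raise ConfigurationError("mixing matrix is column-rank deficient")
    rng = np.random.default_rng(seed)
    n = len(trials)
    dt = 1.0 / timing.sfreq
    times = np.arange(timing.tmin - timing.pad, timing.tmax + timing.pad + dt / 2, dt)
    T = times.size

    basis = make_basis(fwd.n_channels)
    cue_angle = trials["cue_angle"].to_numpy(dtype=float)
    has_cue = ~np.isnan(cue_angle)
    profiles = np.zeros((n, fwd.n_channels))
    profiles[has_cue] = basis.evaluate(cue_angle[has_cue]).T  # (n, k)

    cue_env = (np.zeros(T) if timing.cue_onset is None else
               _bump(times, timing.cue_onset, timing.evoked_rise,
                     timing.evoked_plateau, timing.evoked_fall))
    ping_env = (np.zeros(T) if timing.ping_onset is None else
                _bump(times, timing.ping_onset, timing.evoked_rise,
                      timing.evoked_plateau, timing.evoked_fall))
    induced_onset = (timing.cue_onset if timing.cue_onset is not None
                     else times[0])
    induced_env = _ramp(times, induced_onset, timing.induced_rise)

    ping_gain = np.full(n, fwd.ping_amp)
    if hpl_bin is not None:
        cue_bin = trials["cue_bin"].to_numpy(dtype=float, na_value=np.nan)
        dist = np.zeros(n, dtype=int)
        ok = ~np.isnan(cue_bin)
        dist[ok] = circular_distance_bins(cue_bin[ok], hpl_bin)
        ping_gain = fwd.ping_amp * np.asarray(fwd.gradient, dtype=float)[dist]
    ping_gain[~has_cue] = 0.0

    omega = 2.0 * np.pi * fwd.alpha_freq
    evoked_carrier = np.cos(omega * times)  # phase 0 at t=0 for every trial
    phases = rng.uniform(0.0, 2.0 * np.pi, n)
    # channel-domain amplitude per trial/time
    evoked_amp_t = (fwd.evoked_amp * cue_env[None, :]
                    + ping_gain[:, None] * ping_env[None, :])  # (n, T)
    induced_amp_t = fwd.induced_amp * induced_env[None, :]
    channel_ts = (profiles[:, :, None]
                  * (evoked_amp_t[:, None, :] * evoked_carrier[None, None, :]
                     + induced_amp_t[:, None, :]
                     * np.cos(omega * times[None, None, :] + phases[:, None, None])))
    data = np.einsum("ek,nkt->net", mixing, channel_ts)
    if fwd.noise_pink > 0:
        data += fwd.noise_pink * pink_noise(rng, data.shape, timing.sfreq)
    if fwd.noise_white > 0:
        data += fwd.noise_white * rng.standard_normal(data.shape)

    truth = {
        "profiles": profiles,
        "cue_env": fwd.evoked_amp * cue_env,
        "ping_env": ping_env,
        "induced_env": fwd.induced_amp * induced_env,
        "ping_gain": ping_gain,
        "mixing": mixing,
    }
    return EpochArray(data=data, times=times, sfreq=timing.sfreq,
                      trial_index=trials.index.to_numpy(),
                      window=(timing.tmin, timing.tmax),
                      gaze=np.zeros((n, T)), heog=np.zeros((n, T)),
                      truth=truth)


# ---------------------------------------------------------------------------
# Artifact injection


@dataclass
class ArtifactConfig:
    """What to contaminate and how strongly.

    Bursts are 110-140 Hz Gaussian-windowed oscillations (muscle activity);
    HEOG steps are sustained deflections of ``heog_step_uv`` microvolts
    (saccade-like); gaze excursions move the simulated gaze trace away from
    fixation by ``gaze_excursion_deg`` visual degrees.
    """

    p_burst_trials: float = 0.0
    burst_amp: float = 50.0
    burst_n_electrodes: int = 1
    burst_freq: float = 125.0
    burst_duration: float = 0.15
    p_heog_trials: float = 0.0
    heog_step_uv: float = 20.0
    heog_step_time: float = 0.1
    p_gaze_trials: float = 0.0
    gaze_excursion_deg: float = 1.3
    gaze_excursion_time: float = 0.2


def inject_artifacts(epochs: EpochArray, cfg: ArtifactConfig,
                     seed: int = 0) -> tuple[EpochArray, dict]:
    """Contaminate a copy of ``epochs``; return it plus a ground-truth mask.

    The returned dict has boolean per-trial masks ``burst``, ``heog`` and
    ``gaze`` plus, for bursts, the contaminated electrodes per trial.
    """
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    n, n_elec, T = out.data.shape
    t = out.times

    burst_mask = rng.random(n) < cfg.p_burst_trials
    burst_electrodes = {}
    if cfg.burst_amp > 0 and burst_mask.any():
        for i in np.flatnonzero(burst_mask):
            elecs = rng.choice(n_elec, size=min(cfg.burst_n_electrodes, n_elec),
                               replace=False)
            burst_electrodes[int(i)] = np.sort(elecs)
            t0 = rng.uniform(out.window[0], out.window[1] - cfg.burst_duration)
            envelope = np.exp(-0.5 * ((t - t0 - cfg.burst_duration / 2)
                                      / (cfg.burst_duration / 4)) ** 2)
            phase = rng.uniform(0, 2 * np.pi)
            wave = cfg.burst_amp * envelope * np.cos(2 * np.pi * cfg.burst_freq * t + phase)
            out.data[i, elecs, :] += wave
    else:
        burst_mask = np.zeros(n, dtype=bool)

    heog_mask = rng.random(n) < cfg.p_heog_trials
    if heog_mask.any() and out.heog is not None:
        step = cfg.heog_step_uv * (t >= cfg.heog_step_time)
        out.heog[heog_mask] += step

    gaze_mask = rng.random(n) < cfg.p_gaze_trials
    if gaze_mask.any() and out.gaze is not None:
        bump = cfg.gaze_excursion_deg * np.exp(
            -0.5 * ((t - cfg.gaze_excursion_time) / 0.05) ** 2)
        out.gaze[gaze_mask] += bump

    mask = {"burst": burst_mask, "heog": heog_mask, "gaze": gaze_mask,
            "burst_electrodes": burst_electrodes}
    return out, mask


# ---------------------------------------------------------------------------
# Convenience: one simulated subject


def simulate_subject(design: DesignConfig, effects: BehaviorEffects,
                     fwd: ForwardModel, timing: EpochTiming, *,
                     subject: int = 0, seed: int = 0,
                     n_trials_train: int | None = None,
                     n_trials_test: int | None = None,
                     mixing: np.ndarray | None = None):
    """Design + behavior + epochs for one subject.

    Returns ``(trials, epochs_train, epochs_test)`` where both epoch arrays
    use the same timing (strictly aligned time samples, as required for
    cross-session encoding).  Gradient multipliers apply only to the test
    phase; the training phase is generated with a flat gradient so the
    localizer is free of selection-history structure.
    """
    ss = np.random.SeedSequence([seed, subject])
    s_design, s_behav, s_train, s_test = (int(x % (2**31))
                                          for x in ss.generate_state(4))
    design = DesignConfig(**{**design.__dict__, "seed": s_design})
    trials = generate_design(design, subject=subject,
                             n_trials_train=n_trials_train,
                             n_trials_test=n_trials_test)
    trials = generate_behavior(trials, effects, design.hpl_bin, seed=s_behav)
    train_rows = trials[trials["phase"] == "training"]
    test_rows = trials[trials["phase"] == "test"]
    flat_fwd = ForwardModel(**{**fwd.__dict__, "gradient": (1.0,) * 5})
    epochs_train = generate_epochs(train_rows, flat_fwd, timing, seed=s_train,
                                   hpl_bin=design.hpl_bin, mixing=mixing)
    epochs_test = generate_epochs(test_rows, fwd, timing, seed=s_test,
                                  hpl_bin=design.hpl_bin, mixing=mixing)
    return trials, epochs_train, epochs_test
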