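"""Generator contracts: design composition, behavioral effects, and the
forward model's ground truth."""

import numpy as np
import pandas as pd
import pytest

from pingmap import BehaviorEffects, ConfigurationError, DesignConfig, EpochTiming, ForwardModel
from pingmap.containers import circular_distance_bins, read_trials, write_trials
from pingmap.simulate import (ArtifactConfig, build_mixing, generate_behavior,
                              generate_design, generate_epochs,
                              inject_artifacts)


class TestDesign:
    def test_composition_matches_design_probabilities(self):
        """Distractor presence, HPL share, per-LPL share and no-memory rate
        land within 4 binomial SEs of the design probabilities."""
        cfg = DesignConfig(seed=101)
        trials = generate_design(cfg, n_trials_train=10, n_trials_test=60000)
        test = trials[trials["phase"] == "test"]
        n = len(test)

        def within(frac, p, m):
            return abs(frac - p) <= 4 * np.sqrt(p * (1 - p) / m)

        present = test["distractor_bin"].notna()
        assert within(present.mean(), 0.74, n)
        db = test.loc[present, "distractor_bin"]
        assert within((db == cfg.hpl_bin).mean(), 0.65, len(db))
        for lpl in (0, 3, 7):
            assert within((db == lpl).mean(), 0.05, len(db))
        assert within(test["no_memory"].mean(), 0.13, n)

    def test_block_structure_uses_configured_counts(self):
        cfg = DesignConfig()
        trials = generate_design(cfg)
        train = trials[trials["phase"] == "training"]
        test = trials[trials["phase"] == "test"]
        assert train.groupby("block").size().eq(80).all() and train["block"].nunique() == 10
        assert test.groupby("block").size().eq(92).all() and test["block"].nunique() == 10

    def test_no_distractor_when_probability_zero(self):
        cfg = DesignConfig(p_distractor_present=0.0, seed=1)
        trials = generate_design(cfg, n_trials_train=10, n_trials_test=500)
        assert trials.loc[trials["phase"] == "test", "distractor_bin"].isna().all()

    def test_seed_determinism(self):
        a = generate_design(DesignConfig(seed=5))
        b = generate_design(DesignConfig(seed=5))
        c = generate_design(DesignConfig(seed=6))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_cue_angle_within_jittered_bin(self, localizer_trials):
        cfg = DesignConfig()
        centers = cfg.location_centers
        delta = (localizer_trials["cue_angle"].to_numpy()
                 - centers[localizer_trials["cue_bin"].to_numpy(dtype=int)])
        delta = (delta + 180) % 360 - 180
        assert np.all(np.abs(delta) <= 22.5)

    def test_target_never_colocated_with_distractor(self):
        trials = generate_design(DesignConfig(seed=3), n_trials_train=10,
                                 n_trials_test=2000)
        test = trials[trials["distractor_bin"].notna()]
        assert not (test["target_bin"] == test["distractor_bin"]).any()

    def test_invalid_probability_mass_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_design(DesignConfig(p_hpl_given_present=0.5))

    def test_trial_table_csv_roundtrip(self, tmp_path, localizer_trials):
        path = tmp_path / "trials.csv"
        write_trials(localizer_trials.reset_index(drop=True), path)
        back = read_trials(path)
        assert back["cue_bin"].tolist() == localizer_trials["cue_bin"].tolist()


class TestBehavior:
    @staticmethod
    def _trials(n, seed, effects, cfg=None):
        cfg = cfg or DesignConfig(seed=seed)
        t = generate_design(cfg, n_trials_train=10, n_trials_test=n)
        return generate_behavior(t, effects, cfg.hpl_bin, seed=seed + 1)

    def test_hpl_benefit_recovered_by_sample_mean(self):
        effects = BehaviorEffects(delta_by_distance=(-50.0, 0, 0, 0, 0),
                                  target_at_hpl_cost=0.0, repeat_delta=0.0)
        t = self._trials(50000, 7, effects)
        test = t[t["distractor_bin"].notna()]
        at_hpl = test["distractor_bin"] == 4
        diff = test.loc[at_hpl, "rt"].mean() - test.loc[~at_hpl, "rt"].mean()
        se = np.sqrt(test.loc[at_hpl, "rt"].var() / at_hpl.sum()
                     + test.loc[~at_hpl, "rt"].var() / (~at_hpl).sum())
        assert abs(diff - (-50.0)) <= 3 * se

    def test_repetition_benefit_recovered(self):
        effects = BehaviorEffects(delta_by_distance=(0.0,) * 5,
                                  target_at_hpl_cost=0.0, repeat_delta=-40.0)
        t = self._trials(50000, 9, effects)
        dbin = t["distractor_bin"]
        rep = dbin.notna() & dbin.shift(1).notna() & (dbin == dbin.shift(1))
        nonrep = dbin.notna() & dbin.shift(1).notna() & (dbin != dbin.shift(1))
        diff = t.loc[rep, "rt"].mean() - t.loc[nonrep, "rt"].mean()
        se = np.sqrt(t.loc[rep, "rt"].var() / rep.sum()
                     + t.loc[nonrep, "rt"].var() / nonrep.sum())
        assert abs(diff - (-40.0)) <= 3 * se

    def test_zero_noise_zero_deltas_gives_constant_rt(self):
        effects = BehaviorEffects(capture_cost=0.0, delta_by_distance=(0.0,) * 5,
                                  target_at_hpl_cost=0.0, repeat_delta=0.0,
                                  rt_noise_sd=0.0)
        t = self._trials(500, 13, effects)
        rts = t.loc[t["phase"] == "test", "rt"]
        assert np.allclose(rts, 1000.0)

    def test_recall_deviation_broader_in_test_phase(self):
        cfg = DesignConfig(seed=17)
        t = generate_design(cfg, n_trials_train=2000, n_trials_test=2000)
        t = generate_behavior(t, BehaviorEffects(), cfg.hpl_bin, seed=18)
        sd_train = t.loc[t["phase"] == "training", "recall_deviation"].std()
        sd_test = t.loc[t["phase"] == "test", "recall_deviation"].std()
        assert sd_train < sd_test
        assert t.loc[t["no_memory"], "recall_deviation"].isna().all()


class TestForwardModel:
    def test_noiseless_envelope_topography_is_mixing_times_profile(
            self, noiseless_epochs):
        """With zero noise and no induced component the alpha envelope
        topography equals mixing @ (profile * envelope) at every sample."""
        ep = noiseless_epochs
        i = 3
        env_t = ep.truth["cue_env"]
        expected = ep.truth["mixing"] @ ep.truth["profiles"][i]
        # at carrier peaks the raw signal equals the envelope exactly
        tpk = np.argmin(np.abs(ep.times - 0.2))
        pred = expected * env_t[tpk] * np.cos(2 * np.pi * 10.0 * ep.times[tpk])
        assert np.allclose(ep.data[i, :, tpk], pred, atol=1e-12)

    def test_noiseless_regression_on_mixing_recovers_activations(
            self, noiseless_epochs):
        """Regressing the peak-sample topography on the mixing matrix
        returns the planted channel activation profile to 1e-6."""
        ep = noiseless_epochs
        mix = ep.truth["mixing"]
        # pick a sample where both the envelope and the carrier are large
        tpk = int(np.argmax(ep.truth["cue_env"]
                            * np.abs(np.cos(2 * np.pi * 10.0 * ep.times))))
        for i in (0, 5, 11):
            target = ep.data[i, :, tpk] / np.cos(2 * np.pi * 10.0 * ep.times[tpk])
            est = np.linalg.lstsq(mix, target, rcond=None)[0]
            planted = ep.truth["profiles"][i] * ep.truth["cue_env"][tpk]
            assert np.abs(est - planted).max() < 1e-6

    def test_induced_only_signal_has_total_but_no_evoked_power(
            self, localizer_trials, small_timing):
        from pingmap.spectral import bandpass_hilbert, evoked_power, total_power

        fwd = ForwardModel(evoked_amp=0.0, induced_amp=1.0, ping_amp=0.0,
                           noise_pink=0.0, noise_white=0.0)
        ep = generate_epochs(localizer_trials, fwd, small_timing, seed=30)
        analytic = bandpass_hilbert(ep).crop(0.2, 0.45)
        groups = {0: np.arange(ep.n_trials)}
        ev = evoked_power(analytic, groups).data.mean()
        tot = total_power(analytic, groups).data.mean()
        assert tot > 50 * ev

    def test_planted_gradient_recorded_in_ground_truth(self, localizer_trials):
        gradient = (2.0, 1.5, 1.0, 0.75, 0.5)
        fwd = ForwardModel(gradient=gradient, noise_pink=0.0, noise_white=0.0)
        timing = EpochTiming.ping_locked(tmin=-0.1, tmax=0.4, pad=0.1)
        ep = generate_epochs(localizer_trials, fwd, timing, seed=31, hpl_bin=4)
        dist = circular_distance_bins(
            localizer_trials["cue_bin"].to_numpy(dtype=int), 4)
        for d in range(5):
            expected = fwd.ping_amp * gradient[d]
            got = ep.truth["ping_gain"][dist == d]
            assert np.allclose(got, expected)

    def test_mixing_full_column_rank_and_rank_deficiency_rejected(self):
        fwd = ForwardModel()
        mix = build_mixing(fwd)
        assert np.linalg.matrix_rank(mix) == fwd.n_channels
        bad = np.zeros_like(mix)
        with pytest.raises(ConfigurationError):
            generate_epochs(generate_design(DesignConfig(seed=1),
                                            n_trials_train=4, n_trials_test=4),
                            fwd, EpochTiming(tmin=0, tmax=0.1, pad=0.05),
                            mixing=bad)

    def test_epoch_generation_deterministic(self, localizer_trials, small_timing):
        fwd = ForwardModel()
        a = generate_epochs(localizer_trials.iloc[:8], fwd, small_timing, seed=5)
        b = generate_epochs(localizer_trials.iloc[:8], fwd, small_timing, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_epoch_hdf5_roundtrip(self, tmp_path, localizer_trials, small_timing):
        fwd = ForwardModel(n_electrodes=16)
        ep = generate_epochs(localizer_trials.iloc[:6], fwd, small_timing, seed=4)
        ep.save(tmp_path / "ep.h5")
        back = type(ep).load(tmp_path / "ep.h5")
        assert np.array_equal(back.data, ep.data)
        assert back.sfreq == ep.sfreq and tuple(back.window) == tuple(ep.window)
        assert np.array_equal(back.truth["profiles"], ep.truth["profiles"])


class TestInjectArtifacts:
    def test_zero_amplitude_is_identity(self, noisy_epochs):
        out, mask = inject_artifacts(
            noisy_epochs, ArtifactConfig(p_burst_trials=0.2, burst_amp=0.0),
            seed=0)
        assert np.array_equal(out.data, noisy_epochs.data)
        assert not mask["burst"].any()

    def test_mask_marks_exactly_contaminated_trials(self, noisy_epochs):
        cfg = ArtifactConfig(p_burst_trials=0.1, burst_amp=50.0)
        out, mask = inject_artifacts(noisy_epochs, cfg, seed=2)
        changed = np.flatnonzero(
            np.any(out.data != noisy_epochs.data, axis=(1, 2)))
        assert np.array_equal(changed, np.flatnonzero(mask["burst"]))
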