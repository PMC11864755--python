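"""Band-pass/Hilbert contracts, the evoked vs total power distinction,
smoothing, and the train-fitted PCA rotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pingmap.containers import EpochArray
from pingmap.spectral import (AnalyticEpochs, PowerBlock, bandpass_hilbert,
                              evoked_power, pca_reduce, smooth_power,
                              total_power)

SFREQ = 512.0


def _sine_epochs(freq, amp=1.0, n_trials=1, n_elec=1, dur=4.0, phase=0.0):
    # generous margins: a narrow-band zero-phase filter rings for ~1 s
    t = np.arange(0, dur, 1 / SFREQ)
    data = amp * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(data, (n_trials, n_elec, 1))
    return EpochArray(data=data, times=t - dur / 2, sfreq=SFREQ,
                      trial_index=np.arange(n_trials),
                      window=(-dur / 2 + 1.2, dur / 2 - 1.2))


def _analytic(values, times=None):
    values = np.asarray(values)
    times = np.arange(values.shape[-1]) / SFREQ if times is None else times
    return AnalyticEpochs(data=values, times=times, sfreq=SFREQ,
                          trial_index=np.arange(values.shape[0]),
                          band=(8, 13), order=5,
                          window=(times[0], times[-1]))


class TestBandpassHilbert:
    def test_passband_sinusoid_envelope_matches_amplitude(self):
        ep = _sine_epochs(10.0, amp=2.5)
        analytic = bandpass_hilbert(ep)
        mid = analytic.crop().data
        assert np.allclose(np.abs(mid), 2.5, rtol=0.02)

    def test_stopband_sinusoid_strongly_attenuated(self):
        ep = _sine_epochs(30.0, amp=1.0)
        mid = bandpass_hilbert(ep).crop().data
        assert np.abs(mid).max() < 0.05

    def test_zero_input_zero_output(self):
        ep = _sine_epochs(10.0, amp=0.0)
        assert np.allclose(bandpass_hilbert(ep).data, 0.0)

    def test_linearity(self):
        a = _sine_epochs(9.0, amp=1.0)
        b = _sine_epochs(11.0, amp=0.5, phase=1.0)
        summed = a.copy()
        summed.data = a.data + b.data
        lhs = bandpass_hilbert(summed).data
        rhs = bandpass_hilbert(a).data + bandpass_hilbert(b).data
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_hilbert(_sine_epochs(10.0), lo=8, hi=300)


class TestEvokedTotal:
    def test_single_trial_group_evoked_equals_total(self):
        z = np.random.default_rng(0).standard_normal((1, 3, 50)) \
            + 1j * np.random.default_rng(1).standard_normal((1, 3, 50))
        an = _analytic(z)
        g = {(0, 0): [0]}
        assert np.allclose(evoked_power(an, g).data, total_power(an, g).data)

    def test_antiphase_pair_cancels_in_evoked_only(self):
        z = np.ones((1, 1, 4)) * (1 + 2j)
        an = _analytic(np.concatenate([z, -z]))
        g = {(0, 0): [0, 1]}
        assert np.allclose(evoked_power(an, g).data, 0.0)
        assert np.allclose(total_power(an, g).data, 5.0)

    def test_total_is_mean_of_squared_magnitudes(self):
        an = _analytic(np.stack([np.full((1, 4), 1.0 + 0j),
                                 np.full((1, 4), 3.0 + 0j)]))
        assert np.allclose(total_power(an, {(0, 0): [0, 1]}).data, 5.0)

    def test_random_phase_large_n_total_a_squared_evoked_vanishes(self):
        rng = np.random.default_rng(5)
        A = 2.0
        z = A * np.exp(1j * rng.uniform(0, 2 * np.pi, (1000, 1, 1)))
        an = _analytic(np.broadcast_to(z, (1000, 1, 8)).copy())
        g = {(0, 0): np.arange(1000)}
        assert np.allclose(total_power(an, g).data, A ** 2)
        assert evoked_power(an, g).data.max() < 3 * A ** 2 / 1000 * 10

    def test_evoked_never_exceeds_total(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((40, 4, 30)) + 1j * rng.standard_normal((40, 4, 30))
        an = _analytic(z)
        g = {(0, b): np.arange(b, 40, 8) for b in range(8)}
        assert np.all(evoked_power(an, g).data
                      <= total_power(an, g).data * (1 + 1e-9) + 1e-12)

    def test_empty_group_raises_with_name(self):
        an = _analytic(np.ones((2, 1, 4), dtype=complex))
        with pytest.raises(ValueError, match="3"):
            evoked_power(an, {(0, 3): []})


class TestSmoothing:
    def _block(self, series):
        data = np.asarray(series, dtype=float)[None, None, :]
        return PowerBlock(data=data, obs=pd.DataFrame({"cue_bin": [0]}),
                          kind="total")

    def test_constant_series_unchanged(self):
        out = smooth_power(self._block(np.full(50, 3.3)), window=8)
        assert np.allclose(out.data, 3.3)

    def test_unit_impulse_spreads_to_eight_eighths(self):
        x = np.zeros(64)
        x[32] = 1.0
        out = smooth_power(self._block(x), window=8).data.ravel()
        assert np.isclose(out[out > 0].sum(), 1.0)
        assert (out > 0).sum() == 8
        assert np.allclose(out[out > 0], 1 / 8)

    def test_interior_mean_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.random(200)
        out = smooth_power(self._block(x), window=8).data.ravel()
        assert np.isclose(out[20:-20].mean(), x[20 - 4:-20 + 4].mean(), rtol=1e-2)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_power(self._block(np.ones(4)), window=8)


class TestPCA:
    def _blocks(self, n_feat=10, n_obs=12, T=6, rank=None, seed=0):
        rng = np.random.default_rng(seed)
        if rank is None:
            tr = rng.random((n_obs, n_feat, T))
            te = rng.random((4, n_feat, T))
        else:
            U = rng.random((n_feat, rank))
            tr = np.einsum("fr,ort->oft", U, rng.random((n_obs, rank, T)))
            te = np.einsum("fr,ort->oft", U, rng.random((4, rank, T)))
        obs_tr = pd.DataFrame({"set_id": 0, "cue_bin": np.arange(n_obs) % 8})
        obs_te = pd.DataFrame({"set_id": 1, "cue_bin": np.arange(4)})
        return (PowerBlock(data=tr, obs=obs_tr, kind="total"),
                PowerBlock(data=te, obs=obs_te, kind="total"))

    def test_low_rank_data_reconstructs_exactly(self):
        tr, te = self._blocks(rank=2)
        trp, tep = pca_reduce(tr, te, k=2)
        # reconstruction via the fitted rotation: scores @ components
        Xtr = np.moveaxis(tr.data, 1, 2).reshape(-1, tr.data.shape[1])
        _, _, Vt = np.linalg.svd(Xtr, full_matrices=False)
        recon = np.einsum("oct,cf->oft", trp.data, Vt[:2])
        assert np.allclose(recon, tr.data, atol=1e-10)

    def test_component_rows_orthonormal(self):
        tr, te = self._blocks()
        trp, _ = pca_reduce(tr, te, k=5)
        Xtr = np.moveaxis(tr.data, 1, 2).reshape(-1, tr.data.shape[1])
        _, _, Vt = np.linalg.svd(Xtr, full_matrices=False)
        assert np.allclose(Vt[:5] @ Vt[:5].T, np.eye(5), atol=1e-10)

    def test_full_rank_projection_leaves_iem_invariant(self):
        from pingmap.iem import (invert_channels, make_basis,
                                 predicted_responses, train_weights)

        rng = np.random.default_rng(4)
        basis = make_basis()
        bins = np.repeat(np.arange(8), 2)
        C1 = predicted_responses(basis.centers[bins], basis)
        obs_tr = pd.DataFrame({"set_id": 0, "cue_bin": bins})
        obs_te = pd.DataFrame({"set_id": 1, "cue_bin": np.arange(8)})
        tr = PowerBlock(data=rng.random((16, 12, 5)), obs=obs_tr, kind="total")
        te = PowerBlock(data=rng.random((8, 12, 5)), obs=obs_te, kind="total")
        trp, tep = pca_reduce(tr, te, k=12)
        C2_raw = invert_channels(train_weights(tr.as_b_matrix(), C1),
                                 te.as_b_matrix())
        C2_pca = invert_channels(train_weights(trp.as_b_matrix(), C1),
                                 tep.as_b_matrix())
        assert np.allclose(C2_raw, C2_pca, atol=1e-8)

    def test_k_beyond_rank_rejected(self):
        tr, te = self._blocks(rank=2)
        with pytest.raises(ValueError):
            pca_reduce(tr, te, k=5)


@given(st.floats(0.1, 5.0), st.integers(0, 6))
def test_power_blocks_reject_negative_power(scale, seed):
    rng = np.random.default_rng(seed)
    data = rng.random((2, 3, 4)) * scale
    PowerBlock(data=data, obs=pd.DataFrame({"cue_bin": [0, 1]}), kind="total")
    with pytest.raises(ValueError):
        PowerBlock(data=data - scale * 2, obs=pd.DataFrame({"cue_bin": [0, 1]}),
                   kind="total")
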