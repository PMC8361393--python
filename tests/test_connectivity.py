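"""Connectivity estimation: filtering, windowing, coherence, cross-correlation."""

import numpy as np
import pytest
from scipy import signal

import ieegnet as ig
from ieegnet.connectivity import pooled_coherence
from ieegnet.types import InvalidSpecError, Recording


def sine_recording(freq, fs=512.0, duration=20.0, n_ch=1, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data=data, fs=fs, channel_ids=[f"c{i}" for i in range(n_ch)])


def band_rms(x, fs, f_lo, f_hi):
    freqs, psd = signal.welch(x, fs=fs, nperseg=1024)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    return np.sqrt(np.trapezoid(psd[sel], freqs[sel]))


class TestPreprocess:
    def test_notch_attenuates_60hz_by_20db(self):
        rec = sine_recording(60.0)
        out = ig.preprocess(rec, "broadband")
        core = slice(1024, -1024)  # avoid zero-phase edge transients
        ratio = np.sqrt(np.mean(out.data[0, core] ** 2)) / np.sqrt(
            np.mean(rec.data[0, core] ** 2))
        assert ratio < 10 ** (-20 / 20)

    def test_passband_20hz_amplitude_within_5pct(self):
        rec = sine_recording(20.0)
        out = ig.preprocess(rec, "broadband")
        core = slice(1024, -1024)
        ratio = np.sqrt(np.mean(out.data[0, core] ** 2)) / np.sqrt(
            np.mean(rec.data[0, core] ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_dc_channel_becomes_zero(self):
        rec = Recording(np.full((1, 4096), 3.7), fs=512.0, channel_ids=["c0"])
        out = ig.preprocess(rec, "broadband")
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_band_mode_only_demeans(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(2.0, 1.0, (2, 1024)), fs=256.0,
                        channel_ids=["a", "b"])
        out = ig.preprocess(rec, "band")
        np.testing.assert_allclose(
            out.data, rec.data - rec.data.mean(1, keepdims=True))

    def test_low_fs_rejected_for_broadband(self):
        rec = Recording(np.zeros((1, 512)), fs=200.0, channel_ids=["c0"])
        with pytest.raises(InvalidSpecError):
            ig.preprocess(rec, "broadband")


class TestSegmentWindows:
    def test_exact_division(self):
        rec = Recording(np.zeros((3, 60 * 512)), fs=512.0,
                        channel_ids=list("abc"))
        wins = ig.segment_windows(rec, 1.0)
        assert wins.shape == (60, 3, 512)

    def test_trailing_partial_window_dropped(self):
        rec = Recording(np.zeros((1, int(60.7 * 512))), fs=512.0,
                        channel_ids=["a"])
        assert ig.segment_windows(rec, 1.0).shape[0] == 60

    def test_too_short_recording_rejected(self):
        rec = Recording(np.zeros((1, 256)), fs=512.0, channel_ids=["a"])
        with pytest.raises(InvalidSpecError):
            ig.segment_windows(rec, 1.0)


class TestCoherenceBand:
    def test_identical_channels_have_unit_coherence(self, rng):
        x = rng.normal(0, 1, (1, 20 * 256))
        rec = Recording(np.vstack([x, x]), fs=256.0, channel_ids=["a", "b"])
        wins = ig.segment_windows(rec)
        series = ig.coherence_band(wins, 256.0, (15, 25))
        assert np.all(np.abs(series.matrices[:, 0, 1] - 1.0) < 1e-9)

    def test_amplitude_rescaling_invariance(self, rng):
        data = rng.normal(0, 1, (3, 30 * 256))
        rec = Recording(data, fs=256.0, channel_ids=list("abc"))
        scaled = Recording(data * np.array([[5.0], [0.2], [1.0]]), fs=256.0,
                           channel_ids=list("abc"))
        a = ig.coherence_band(ig.segment_windows(rec), 256.0, (15, 25))
        b = ig.coherence_band(ig.segment_windows(scaled), 256.0, (15, 25))
        np.testing.assert_allclose(a.matrices, b.matrices, atol=1e-12)

    def test_matrices_symmetric_zero_diagonal_in_unit_interval(self, rng):
        data = rng.normal(0, 1, (4, 10 * 256))
        wins = ig.segment_windows(Recording(data, 256.0, list("abcd")))
        mats = ig.coherence_band(wins, 256.0, (30, 40)).matrices
        assert np.allclose(mats, np.swapaxes(mats, 1, 2))
        assert np.allclose(mats[:, range(4), range(4)], 0.0)
        assert (mats >= 0).all() and (mats <= 1).all()

    def test_empty_band_rejected(self, rng):
        wins = ig.segment_windows(
            Recording(rng.normal(0, 1, (2, 2 * 256)), 256.0, ["a", "b"]))
        with pytest.raises(InvalidSpecError):
            ig.coherence_band(wins, 256.0, (15.2, 15.8))

    def test_pooled_estimator_tracks_per_window_on_shared_source(self, rng):
        # one strongly shared source: both estimators must find the edge
        t = np.arange(40 * 256)
        src = rng.normal(0, 1, t.size)
        sos = signal.butter(4, (15, 25), btype="bandpass", fs=256, output="sos")
        s = signal.sosfiltfilt(sos, src)
        data = np.vstack([s + 0.3 * rng.normal(0, 1, t.size),
                          s + 0.3 * rng.normal(0, 1, t.size)])
        wins = ig.segment_windows(Recording(data, 256.0, ["a", "b"]))
        pooled = pooled_coherence(wins, 256.0, (15, 25)).values[0, 1]
        med = ig.median_adjacency(
            ig.coherence_band(wins, 256.0, (15, 25))).values[0, 1]
        assert pooled > 0.5 and med > 0.5


class TestCrosscorrBroadband:
    def test_copy_has_unit_correlation(self, rng):
        x = rng.normal(0, 1, (1, 4 * 512))
        rec = Recording(np.vstack([x, x]), fs=512.0, channel_ids=["a", "b"])
        wins = ig.segment_windows(rec)
        mats = ig.crosscorr_broadband(wins, 512.0).matrices
        assert np.all(np.abs(mats[:, 0, 1] - 1.0) < 1e-9)

    def test_50ms_delayed_copy_detected_within_lag_window(self, rng):
        fs = 512.0
        lag = int(0.05 * fs)
        x = rng.normal(0, 1, 6 * 512 + lag)
        data = np.vstack([x[:-lag], x[lag:]])
        wins = ig.segment_windows(Recording(data, fs, ["a", "b"]))
        mats = ig.crosscorr_broadband(wins, fs, lag_max_ms=100.0).matrices
        # biased normalization loses lag/n of the overlap
        assert np.all(mats[:, 0, 1] > 1.0 - 2 * lag / 512)

    def test_independent_noise_matches_simulation_oracle(self, rng):
        # oracle: empirical max-|xcorr| level of truly independent pairs
        fs, nper, n_lag = 512.0, 512, int(0.1 * 512)
        sims = []
        for _ in range(300):
            u, v = rng.normal(0, 1, (2, nper))
            u = (u - u.mean()) / u.std()
            v = (v - v.mean()) / v.std()
            cc = np.correlate(u, v, mode="full") / nper
            mid = nper - 1
            sims.append(np.abs(cc[mid - n_lag: mid + n_lag + 1]).max())
        oracle_mean = np.mean(sims)
        data = rng.normal(0, 1, (2, 100 * 512))
        wins = ig.segment_windows(Recording(data, fs, ["a", "b"]))
        observed = ig.crosscorr_broadband(wins, fs).matrices[:, 0, 1].mean()
        assert abs(observed - oracle_mean) < 0.02

    def test_zero_variance_channel_gives_zero_edges(self, rng):
        data = np.vstack([np.zeros(2 * 512), rng.normal(0, 1, 2 * 512)])
        wins = ig.segment_windows(Recording(data, 512.0, ["a", "b"]))
        mats = ig.crosscorr_broadband(wins, 512.0).matrices
        assert np.all(mats[:, 0, 1] == 0.0)


class TestMedianAdjacency:
    def test_constant_series_returns_same_matrix(self, rng):
        m = rng.uniform(0, 1, (3, 3))
        m = np.triu(m, 1) + np.triu(m, 1).T
        series = ig.AdjacencySeries(np.repeat(m[None], 7, axis=0),
                                    "beta_coherence", (15, 25), list("abc"))
        np.testing.assert_allclose(ig.median_adjacency(series).values, m)

    def test_single_outlier_window_does_not_move_median(self, rng):
        base = np.zeros((101, 2, 2))
        base[:, 0, 1] = base[:, 1, 0] = 0.4
        base[50, 0, 1] = base[50, 1, 0] = 0.99
        series = ig.AdjacencySeries(base, "beta_coherence", (15, 25), ["a", "b"])
        assert ig.median_adjacency(series).values[0, 1] == pytest.approx(0.4)

    def test_even_window_count_uses_midpoint_mean(self):
        mats = np.zeros((4, 2, 2))
        for i, v in enumerate((0.1, 0.2, 0.6, 0.9)):
            mats[i, 0, 1] = mats[i, 1, 0] = v
        series = ig.AdjacencySeries(mats, "beta_coherence", (15, 25), ["a", "b"])
        assert ig.median_adjacency(series).values[0, 1] == pytest.approx(0.4)

    def test_window_order_invariance(self, rng):
        mats = rng.uniform(0, 1, (9, 3, 3))
        mats = (mats + np.swapaxes(mats, 1, 2)) / 2
        mats[:, range(3), range(3)] = 0
        series = ig.AdjacencySeries(mats, "beta_coherence", (15, 25), list("abc"))
        shuffled = ig.AdjacencySeries(mats[rng.permutation(9)],
                                      "beta_coherence", (15, 25), list("abc"))
        np.testing.assert_allclose(ig.median_adjacency(series).values,
                                   ig.median_adjacency(shuffled).values)

    def test_empty_series_rejected(self):
        series = ig.AdjacencySeries(np.zeros((0, 2, 2)), "beta_coherence",
                                    (15, 25), ["a", "b"])
        with pytest.raises(InvalidSpecError):
            ig.median_adjacency(series)
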