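"""Unit tests for phase extraction, iPLV and the windowing machinery."""

import numpy as np
import pytest

from nmstate.connectivity import (
    ROITimeseries,
    analytic_phase,
    bandpass_filter,
    compute_dfcg,
    iplv,
    make_window_plan,
    roi_representative_signal,
)
from tests.conftest import constant_lag_phases


class TestROITimeseries:
    def test_valid_construction_and_labels(self):
        ts = ROITimeseries(np.zeros((3, 100)), fs=128.0, band=(13.0, 30.0))
        assert ts.n_nodes == 3 and ts.n_samples == 100
        assert ts.node_labels == ["roi_0", "roi_1", "roi_2"]

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ROITimeseries(np.zeros((2, 100)), fs=50.0, band=(13.0, 30.0))

    def test_non_finite_rejected(self):
        x = np.zeros((2, 100))
        x[0, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ROITimeseries(x, fs=128.0, band=(13.0, 30.0))

    def test_one_dimensional_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            ROITimeseries(np.zeros(100), fs=128.0, band=(13.0, 30.0))


class TestIplv:
    def test_zero_for_identical_phases(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert iplv(ph, ph) == 0.0

    def test_constant_lag_closed_form(self):
        for lag in (np.pi / 6, np.pi / 4, np.pi / 3, np.pi / 2):
            ph = constant_lag_phases(lag)
            assert iplv(ph[0], ph[1]) == pytest.approx(abs(np.sin(lag)), abs=1e-12)

    def test_antiphase_is_invisible(self):
        ph = constant_lag_phases(np.pi)
        assert iplv(ph[0], ph[1]) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_range(self, rng):
        a = rng.uniform(-np.pi, np.pi, 300)
        b = rng.uniform(-np.pi, np.pi, 300)
        assert iplv(a, b) == pytest.approx(iplv(b, a))
        assert 0.0 <= iplv(a, b) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iplv(np.zeros(10), np.zeros(11))


class TestBandpass:
    def test_passband_preserved_stopband_attenuated(self):
        fs = 256.0
        t = np.arange(int(fs * 8)) / fs
        x = np.cos(2 * np.pi * 20 * t) + np.cos(2 * np.pi * 60 * t)
        y = bandpass_filter(x, fs, (13.0, 30.0))[0]
        # compare spectral energy at the two tones
        freqs = np.fft.rfftfreq(t.size, 1 / fs)
        spec = np.abs(np.fft.rfft(y))
        e20 = spec[np.argmin(abs(freqs - 20))]
        e60 = spec[np.argmin(abs(freqs - 60))]
        assert e60 < 0.01 * e20

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), 128.0, (30.0, 13.0))


class TestRepresentativeSignal:
    def test_weights_sum_to_one_and_recover_source(self, rng):
        t = np.arange(512) / 128.0
        src = np.cos(2 * np.pi * 10 * t)
        voxels = src + rng.normal(0, 0.3, (6, t.size))
        rep, w = roi_representative_signal(voxels)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        r = np.corrcoef(rep, src)[0, 1]
        assert r > 0.9

    def test_single_voxel_identity(self):
        x = np.arange(10.0)[None, :]
        rep, w = roi_representative_signal(x)
        assert np.allclose(rep, x[0]) and w.tolist() == [1.0]

    def test_constant_voxel_gets_zero_weight(self, rng):
        voxels = rng.normal(0, 1, (4, 200))
        voxels[2] = 5.0
        with pytest.warns(UserWarning, match="constant voxel"):
            _, w = roi_representative_signal(voxels)
        assert w[2] == 0.0


class TestAnalyticPhase:
    def test_pure_tone_phase_advances_at_carrier_rate(self):
        fs, f = 256.0, 20.0
        t = np.arange(int(fs * 4)) / fs
        ph = analytic_phase(np.cos(2 * np.pi * f * t)[None, :]).phases[0]
        un = np.unwrap(ph)
        rate = (un[-100] - un[100]) / (t[-100] - t[100]) / (2 * np.pi)
        assert rate == pytest.approx(f, rel=1e-3)

    def test_zero_channel_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            analytic_phase(np.zeros((2, 100)))


class TestWindowPlan:
    def test_counts_for_standard_recording(self):
        # 300 s at 128 Hz, 2 s windows advancing by 0.2 s (rounds to 26
        # samples), so (38400 - 256) // 26 + 1 windows fit
        plan = make_window_plan(300 * 128, 128.0, 2.0, 0.2)
        assert plan.window_len == 256
        assert plan.step == 26
        assert plan.n_windows == 1468

    def test_non_overlapping_partition(self):
        plan = make_window_plan(1280, 128.0, 2.0, 2.0)
        assert plan.n_windows == 5
        lo, hi = plan.window(4)
        assert hi == 1280

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            make_window_plan(100, 128.0, 2.0, 2.0)


class TestComputeDfcg:
    def test_tensor_shape_and_matrix_properties(self, rng):
        fs = 128.0
        sig = rng.normal(0, 1, (4, int(fs * 6)))
        ts = ROITimeseries(bandpass_filter(sig, fs, (13.0, 30.0)), fs, (13.0, 30.0))
        plan = make_window_plan(ts.n_samples, fs, 2.0, 2.0)
        T = compute_dfcg(ts, plan)
        assert T.shape == (plan.n_windows, 4, 4)
        for G in T:
            assert np.allclose(G, G.T)
            assert np.all(np.diag(G) == 0)
            assert np.all((G >= 0) & (G <= 1))

    def test_constant_lag_pair_matches_closed_form(self):
        from nmstate.connectivity import PhaseSeries

        lag = np.pi / 4
        ph = constant_lag_phases(lag, duration=8.0)
        plan = make_window_plan(ph.shape[1], 128.0, 2.0, 2.0)
        T = compute_dfcg(PhaseSeries(ph), plan)
        assert np.allclose(T[:, 0, 1], np.sin(lag), atol=1e-12)
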