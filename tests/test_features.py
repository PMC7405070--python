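"""Feature extraction against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claustrum_ephys import features, io, synth
from conftest import make_triangular_spike

FS = 50_000.0
DT_MS = 1000.0 / FS


def brute_force_threshold_scan(v, fs, thresh=10.0):
    """Exhaustive scan oracle: first index whose central-difference slope
    exceeds the criterion after at least 1 ms below it."""
    dv = np.gradient(v) * fs / 1000.0
    deb = int(fs / 1000.0)
    hits = []
    for i in range(1, v.size):
        if dv[i] > thresh and not np.any(dv[max(0, i - deb):i] > thresh):
            hits.append(i)
    return hits


class TestDetectAps:
    def test_flat_trace_has_no_events(self):
        v = np.full(5000, -70.0)
        assert features.detect_aps(v, FS) == []

    def test_threshold_matches_exhaustive_scan(self, triangular_spike):
        v, geom = triangular_spike
        events = features.detect_aps(v, FS)
        assert len(events) == 1
        oracle = brute_force_threshold_scan(v, FS)
        assert events[0].i_thresh == oracle[0]
        # detection lands within one sample of the geometric corner
        assert abs(events[0].i_thresh - geom["i_corner"]) <= 1
        assert events[0].peak_v == pytest.approx(geom["peak"], abs=0.01)

    def test_subzero_peak_rejected(self):
        v, _ = make_triangular_spike(peak=-5.0, after=-45.0)
        assert features.detect_aps(v, FS) == []

    def test_time_shift_invariance(self, triangular_spike):
        v, _ = triangular_spike
        shifted = np.concatenate([np.full(2500, v[0]), v])
        e0 = features.detect_aps(v, FS)[0]
        e1 = features.detect_aps(shifted, FS)[0]
        assert e1.i_thresh - e0.i_thresh == 2500
        assert e1.threshold_v == pytest.approx(e0.threshold_v, abs=1e-9)


class TestPassiveProperties:
    def _sweepset(self, amps, v_fn, n=55_000):
        t = np.arange(n) / FS
        sweeps = np.array([np.full(n, v_fn(a)) for a in amps])
        return io.SweepSet("c", np.asarray(amps, float), sweeps, FS,
                           stim_onset=0.05, stim_offset=1.05)

    def test_exact_linear_relation(self):
        s = self._sweepset([-60, -40, -20, 0, 20], lambda a: -70 + 0.2 * a)
        rmp, rm = features.passive_properties(s, ap_counts=np.zeros(5, int))
        assert rmp == pytest.approx(-70.0, abs=1e-9)
        assert rm == pytest.approx(200.0, abs=1e-6)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        amps = np.array([-60.0, -40.0, -20.0, 0.0, 20.0])
        n = 55_000
        sweeps = np.array([
            np.full(n, -70 + 0.2 * a) + rng.normal(0, 0.5, n) for a in amps
        ])
        s = io.SweepSet("c", amps, sweeps, FS, stim_onset=0.05, stim_offset=1.05)
        rmp, rm = features.passive_properties(s, ap_counts=np.zeros(5, int))
        # closed-form least squares on the measured steady-state means
        sl = s.stim_slice()
        tail = (sl.stop - sl.start) // 5
        vss = sweeps[:, sl.stop - tail:sl.stop].mean(axis=1)
        A = np.vstack([amps, np.ones_like(amps)]).T
        slope, inter = np.linalg.lstsq(A, vss, rcond=None)[0]
        assert rm == pytest.approx(slope * 1000, abs=1e-9)
        assert rmp == pytest.approx(inter, abs=1e-9)

    def test_single_subthreshold_sweep_is_an_error(self):
        s = self._sweepset([-60, 40], lambda a: -70 + 0.2 * a, n=55_000)
        with pytest.raises(ValueError, match="two subthreshold"):
            features.passive_properties(s, ap_counts=np.array([0, 3]))


class TestCurrentThreshold:
    def test_ladder(self):
        amps = np.arange(-60, 141, 20.0)
        counts = np.where(amps >= 60, 3, 0)
        ct, i_ct, i_2x, i_max = features.current_threshold(amps, counts)
        assert ct == 60.0
        assert amps[i_2x] == 120.0

    def test_low_threshold_doubles(self):
        amps = np.array([-60.0, 15.0, 30.0, 45.0, 60.0, 75.0])
        counts = np.array([0, 0, 1, 2, 4, 6])
        ct, _, i_2x, i_max = features.current_threshold(amps, counts)
        assert ct == 30.0 and amps[i_2x] == 60.0 and amps[i_max] == 75.0

    def test_tie_goes_to_lower_amplitude(self):
        amps = np.array([0.0, 50.0, 150.0])  # 100 pA is equidistant
        counts = np.array([0, 1, 5])
        ct, _, i_2x, _ = features.current_threshold(amps, counts)
        assert ct == 50.0 and amps[i_2x] == 50.0

    def test_all_subthreshold_errors(self):
        with pytest.raises(ValueError, match="no current threshold"):
            features.current_threshold(np.array([0.0, 20.0]), np.array([0, 0]))


class TestWaveform:
    def test_triangular_closed_form(self, triangular_spike):
        v, g = triangular_spike
        e = features.detect_aps(v, FS)[0]
        features.ap_waveform(e, v, FS)
        amp = g["peak"] - g["threshold"]  # 75 mV
        assert e.amplitude == pytest.approx(amp, abs=0.2)
        # linear rise: half level crossed at rise_ms/2 after threshold;
        # linear fall to `after`: crossed (peak-half)/(peak-after) into it
        half = g["threshold"] + amp / 2
        t_rise = g["rise_ms"] / 2
        t_fall = g["fall_ms"] * (g["peak"] - half) / (g["peak"] - g["after"])
        expected_hw = (g["rise_ms"] - t_rise) + t_fall
        assert e.half_width == pytest.approx(expected_hw, abs=2 * DT_MS)

    def test_slopes_match_exhaustive_extrema(self, triangular_spike):
        v, _ = triangular_spike
        e = features.detect_aps(v, FS)[0]
        features.ap_waveform(e, v, FS)
        dv = np.gradient(v) * FS / 1000.0
        cap = e.i_thresh + int(10.0 * FS / 1000.0)
        assert e.max_rise == pytest.approx(dv[e.i_thresh:e.i_peak + 1].max())
        assert e.max_decay == pytest.approx(dv[e.i_peak:cap].min())

    def test_narrow_spike_narrower_than_broad(self, simulated_cells):
        _, pv = simulated_cells["PV"]
        _, pn = simulated_cells["PN1"]
        assert pv["ct_half_width"] < pn["ct_half_width"]


class TestAHP:
    def test_prescribed_trough_depth(self):
        # trough engineered exactly 19.1 mV below threshold, recovery upward
        v, g = make_triangular_spike(baseline=-50.0, after=-35.0 - 19.1,
                                     tail_ms=30.0)
        e = features.detect_aps(v, FS)[0]
        features.ahp_features(e, v, FS)
        assert e.ahp_v == pytest.approx(-19.1, abs=0.2)

    def test_trough_matches_argmin_oracle(self, simulated_cells):
        s, _ = simulated_cells["PN1"]
        sl = s.stim_slice()
        idx = s.n_sweeps - 2
        events = features.detect_aps(s.voltages[idx], FS, (sl.start, sl.stop))
        assert len(events) >= 2
        end = events[1].i_thresh
        e = features.ahp_features(events[0], s.voltages[idx], FS, end_idx=end)
        oracle = events[0].i_peak + 1 + int(np.argmin(
            s.voltages[idx][events[0].i_peak + 1:end]
        ))
        assert e.i_ahp == oracle

    def test_no_ahp_still_reported(self):
        # decay only down to a level above threshold: ahp_v >= 0, flagged
        # as no-AHP but still reported
        dt = 1000.0 / FS
        v = np.concatenate([
            np.full(int(5 / dt), -40.0),
            np.linspace(-40.0, -35.0, int(1 / dt), endpoint=False),
            np.linspace(-35.0, 30.0, int(0.5 / dt), endpoint=False),
            np.linspace(30.0, -25.0, int(1.0 / dt), endpoint=False),
            np.full(int(20 / dt), -25.0),
        ])
        events = features.detect_aps(v, FS)
        e = features.ahp_features(events[0], v, FS)
        assert e.ahp_v >= 0

    def test_empty_window_errors(self, triangular_spike):
        v, _ = triangular_spike
        e = features.detect_aps(v, FS)[0]
        with pytest.raises(ValueError, match="empty"):
            features.ahp_features(e, v, FS, end_idx=e.i_peak)


def _train(isis_ms, onset=0.0, amps=None):
    """Build APEvents with prescribed inter-peak intervals."""
    peaks = np.concatenate([[10.0], 10.0 + np.cumsum(isis_ms)])
    amps = amps if amps is not None else np.full(peaks.size, 70.0)
    evs = []
    for t, a in zip(peaks, amps):
        e = features.APEvent(i_thresh=0, i_peak=0, threshold_time=t - 1.0,
                             threshold_v=-35.0, peak_time=t, peak_v=a - 35.0)
        e.amplitude = a
        evs.append(e)
    return evs


class TestTrainStatistics:
    def test_regular_train(self):
        st_ = features.train_statistics(_train([20.0] * 9), 0.0)
        assert st_.cv2_all == 0.0
        assert st_.max_adaptation == pytest.approx(0.0)
        assert st_.isi_ratio == pytest.approx(1.0)
        np.testing.assert_allclose(st_.inst_freqs, 50.0)

    def test_two_isi_closed_forms(self):
        st_ = features.train_statistics(_train([10.0, 30.0]), 0.0)
        assert st_.cv2_all == pytest.approx(1.0)  # 2*20/40
        assert st_.sd_first2_isi == pytest.approx(20.0 / np.sqrt(2))
        assert st_.mean_first2_isi == pytest.approx(20.0)
        assert st_.delta_isi_1_2 == pytest.approx(20.0)
        assert st_.delta_f_1_2 == pytest.approx(1000 / 30 - 1000 / 10)

    def test_adaptation_from_50_to_25_hz(self):
        # first ISI 20 ms (50 Hz), last three ISIs 40 ms (25 Hz)
        st_ = features.train_statistics(_train([20.0, 40.0, 40.0, 40.0]), 0.0)
        assert st_.initial_inst_freq == pytest.approx(50.0)
        assert st_.max_adaptation == pytest.approx(25.0)
        assert st_.isi_ratio == pytest.approx(0.5)

    def test_short_train_yields_missing(self):
        st_ = features.train_statistics(_train([20.0, 20.0]), 0.0)
        assert st_.max_adaptation is None and st_.isi_ratio is None

    def test_amplitude_ratios(self):
        amps = np.array([80.0, 70.0, 68.0, 66.0, 64.0])
        st_ = features.train_statistics(_train([20.0] * 4, amps=amps), 0.0)
        assert st_.amp_ratio_1_2 == pytest.approx(80 / 70)
        assert st_.amp_ratio_2_3 == pytest.approx(70 / 68)
        assert st_.amp_ratio_1_last3 == pytest.approx(80 / np.mean([68, 66, 64]))

    def test_latency_from_stimulus_onset(self):
        # first threshold crossing at 9 ms, stimulus onset at 5 ms
        st_ = features.train_statistics(_train([20.0]), 5.0)
        assert st_.latency_first_ap == pytest.approx(4.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1.0, 200.0), min_size=4, max_size=30))
    def test_adaptation_identity_and_cv2_bounds(self, isis):
        stats = features.train_statistics(_train(isis), 0.0)
        for cv2 in (stats.cv2_all, stats.cv2_excl1, stats.cv2_excl2):
            if cv2 is not None:
                assert 0.0 <= cv2 <= 2.0
        if stats.max_adaptation is not None:
            lhs = stats.isi_ratio * stats.initial_inst_freq + stats.max_adaptation
            assert lhs == pytest.approx(stats.initial_inst_freq, abs=1e-9)


class TestInitialAdaptation:
    def _stats(self, freq_by_sweep):
        out = []
        for f in freq_by_sweep:
            if f is None:
                out.append(features.TrainStats(n_ap=0))
            elif f == "single":
                out.append(features.TrainStats(n_ap=1))
            else:
                s = features.TrainStats(n_ap=5)
                s.initial_inst_freq = f
                out.append(s)
        return out

    def test_two_step_change(self):
        stats = self._stats([None, 20.0, 60.0])
        amps = np.array([60.0, 100.0, 140.0])
        out = features.initial_adaptation_features(amps, stats, ct=100.0, idx_ct=1)
        assert out["max_init_adapt_change"] == pytest.approx(1.0)
        assert out["adapt_change_rel_ct"] == pytest.approx(1.4)

    def test_matches_brute_force_over_pairs(self):
        rng = np.random.default_rng(5)
        freqs = list(20 + 80 * rng.random(6))
        amps = np.arange(100.0, 100.0 + 40 * 7, 40.0)
        stats = self._stats([None] + freqs)
        out = features.initial_adaptation_features(amps, stats, ct=amps[1], idx_ct=1)
        oracle = max(
            (freqs[i + 1] - freqs[i]) / 40.0 for i in range(len(freqs) - 1)
        )
        assert out["max_init_adapt_change"] == pytest.approx(oracle)

    def test_v2_ignores_ct_sweep(self):
        # the biggest jump involves the ct sweep, so v2 must be smaller
        stats = self._stats([None, 10.0, 80.0, 85.0])
        amps = np.array([60.0, 100.0, 140.0, 180.0])
        out = features.initial_adaptation_features(amps, stats, ct=100.0, idx_ct=1)
        assert out["max_init_adapt_change"] == pytest.approx(70 / 40)
        assert out["init_adapt_change_v2"] == pytest.approx(5 / 40)
        assert out["init_adapt_change_v2"] < out["max_init_adapt_change"]

    def test_v2_ignores_pairs_spanning_single_ap_sweeps(self):
        stats = self._stats([None, 30.0, "single", 90.0])
        amps = np.array([60.0, 100.0, 140.0, 180.0])
        out = features.initial_adaptation_features(amps, stats, ct=100.0, idx_ct=1)
        # v1 bridges the single-AP sweep: (90-30)/(180-100)
        assert out["max_init_adapt_change"] == pytest.approx(60 / 80)
        assert np.isnan(out["init_adapt_change_v2"])

    def test_too_few_sweeps_missing(self):
        out = features.initial_adaptation_features(
            np.array([100.0]), self._stats([50.0]), ct=100.0, idx_ct=0
        )
        assert np.isnan(out["max_init_adapt_change"])


class TestExtractFeatures:
    def test_subthreshold_only_cell_errors(self):
        amps = np.array([-60.0, -20.0, 20.0])
        v = np.tile(-70.0, (3, 55_000))
        s = io.SweepSet("c", amps, v, FS, stim_onset=0.05, stim_offset=1.05)
        with pytest.raises(ValueError, match="no current threshold"):
            features.extract_features(s, 38)

    def test_deterministic_across_runs(self, simulated_cells):
        s, fv = simulated_cells["PN1"]
        again = features.extract_features(s, 38)
        for k, val in fv.items():
            assert (np.isnan(val) and np.isnan(again[k])) or val == again[k]

    def test_invalid_feature_set(self, simulated_cells):
        s, _ = simulated_cells["PN1"]
        with pytest.raises(ValueError, match="38 or 63"):
            features.extract_features(s, 50)
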