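"""Transient detection and event-triggered kinetic metrics."""

import numpy as np
import pytest

from fiberphot.kernels import Kinetics, transient_kernel
from fiberphot.transients import (
    DetectionParams,
    ResponseParams,
    Transient,
    build_ensemble,
    detect_transients,
    paired_differences,
    response_metrics,
    transient_stats,
)

RATE = 30.0


def brute_force_detect(z, rate_hz, p: DetectionParams):
    """Independent run-length scan implementation of the detection spec."""
    n = len(z)
    min_run = max(int(round(p.min_dur_s * rate_hz)), 1)
    gap = int(round(p.merge_gap_s * rate_hz))
    raw = []
    i = 0
    while i < n:
        if z[i] >= p.theta_on:
            j = i
            while j < n and z[j] >= p.theta_on:
                j += 1
            if j - i >= min_run:
                s = i
                while s > 0 and z[s - 1] >= p.theta_off:
                    s -= 1
                e = j
                while e < n and z[e] >= p.theta_off:
                    e += 1
                raw.append([s, e])
            i = j
        else:
            i += 1
    merged = []
    for s, e in raw:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        peak = min(range(s, e), key=lambda k: (-z[k], k))
        out.append((s, e, peak))
    return out


class TestDetection:
    def test_zero_trace_no_events(self):
        assert detect_transients(np.zeros(1000), RATE) == []

    def test_boxcar_hand_traced(self):
        z = np.zeros(int(30 * RATE))
        z[int(10 * RATE) : int(15 * RATE)] = 3.0
        (ev,) = detect_transients(z, RATE)
        assert ev.onset_s == pytest.approx(10.0)
        assert ev.end_s == pytest.approx(15.0)
        assert ev.duration_s == pytest.approx(5.0)
        assert ev.peak_z == 3.0
        assert ev.peak_s == pytest.approx(10.0)  # earliest sample on ties

    def test_nearby_boxcars_merged(self):
        z = np.zeros(int(30 * RATE))
        z[int(5 * RATE) : int(8 * RATE)] = 3.0
        z[int(8.3 * RATE) : int(11 * RATE)] = 3.0
        events = detect_transients(z, RATE)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(6.0, abs=0.05)

    def test_short_blip_ignored(self):
        z = np.zeros(int(10 * RATE))
        z[50:55] = 5.0  # 0.17 s << min_dur 1 s
        assert detect_transients(z, RATE) == []

    def test_unnormalized_input_warns(self):
        z = np.zeros(300)
        z[:] = 5.0 + np.sin(np.arange(300))
        with pytest.warns(UserWarning, match="z-normalized"):
            detect_transients(z, RATE)

    def test_matches_brute_force_on_random_traces(self, rng):
        p = DetectionParams()
        for _ in range(200):
            n = int(rng.integers(50, 600))
            z = rng.normal(0, 1.4, n).clip(-4, 4)
            got = detect_transients(z, RATE, p)
            want = brute_force_detect(z, RATE, p)
            assert len(got) == len(want)
            for ev, (s, e, peak) in zip(got, want):
                assert ev.onset_s == pytest.approx(s / RATE)
                assert ev.end_s == pytest.approx(e / RATE)
                assert ev.peak_s == pytest.approx(peak / RATE)


class TestTransientStats:
    def test_frequency(self):
        events = [Transient(i * 10.0, i * 10.0 + 1, i * 10.0 + 2, 3.0) for i in range(6)]
        out = transient_stats(events, 180.0)
        assert out["frequency_per_min"] == pytest.approx(2.0)

    def test_empty(self):
        out = transient_stats([], 60.0)
        assert out["frequency_per_min"] == 0.0
        assert np.isnan(out["fraction_gt_edge"])

    def test_histogram_edge_at_20s(self):
        events = [Transient(0.0, 5.0, 25.0, 3.0), Transient(40.0, 42.0, 45.0, 3.0)]
        out = transient_stats(events, 120.0)
        assert 20.0 in out["hist_edges"]
        assert out["fraction_gt_edge"] == pytest.approx(0.5)


class TestEnsemble:
    def test_single_trial_mean_is_segment(self):
        z = np.arange(300, dtype=float)
        ens = build_ensemble(z, [5.0], 1.0, 2.0, RATE)
        assert ens.matrix.shape == (1, 90)
        assert np.allclose(ens.mean, z[120:210])
        assert np.allclose(ens.sem, 0.0)

    def test_two_constant_trials_mean_and_sem(self):
        z = np.zeros(600)
        z[150:300] = 1.0
        z[450:] = 3.0
        ens = build_ensemble(z, [6.0, 16.0], 1.0, 2.0, RATE)
        assert np.allclose(ens.mean, 2.0)
        assert np.allclose(ens.sem, 1.0)

    def test_out_of_range_trials_dropped(self):
        z = np.zeros(300)
        ens = build_ensemble(z, [0.5, 5.0, 9.9], 1.0, 2.0, RATE)
        assert ens.matrix.shape[0] == 1
        assert ens.dropped == 2

    def test_no_usable_trials_errors(self):
        with pytest.raises(ValueError):
            build_ensemble(np.zeros(30), [0.1], 2.0, 2.0, RATE)

    def test_shuffled_events_on_noise_average_to_zero(self, rng):
        z = rng.normal(0, 1, 40000)
        times = rng.uniform(10, 1300, 40)
        ens = build_ensemble(z, times, 2.0, 2.0, RATE)
        assert np.max(np.abs(ens.mean)) < 3.0 / np.sqrt(40)

    def test_rebaseline_subtracts_pre_mean(self):
        z = np.ones(600) * 5.0
        ens = build_ensemble(z, [10.0], 2.0, 2.0, RATE, rebaseline=True)
        assert np.allclose(ens.matrix, 0.0)


def _trial_matrix(kern, pre_s, post_s, n_trials=3):
    pre = int(pre_s * RATE)
    post = int(post_s * RATE)
    row = np.zeros(pre + post)
    seg = min(len(kern), post)
    row[pre : pre + seg] = kern[:seg]
    return np.tile(row, (n_trials, 1))


class TestResponseMetrics:
    def test_noiseless_astro_kernel_recovers_injected_kinetics(self):
        kin = Kinetics(2.47, 5.66, 20.0, 4.0)
        kern = transient_kernel(kin, RATE)
        mat = _trial_matrix(kern, 5.0, 38.0)
        from fiberphot.transients import EventTriggeredEnsemble

        ens = EventTriggeredEnsemble(mat, 5.0, 38.0, RATE, np.arange(3.0))
        m = response_metrics(ens, ResponseParams(peak_window_s=15.0))
        assert m.latency_s.mean() == pytest.approx(2.47, abs=0.1)
        assert m.peak_time_s.mean() == pytest.approx(5.66, abs=0.1)
        assert m.duration_s.mean() == pytest.approx(20.0, abs=0.3)

    def test_valley_offset_recovered(self):
        """A dip injected 1.50 s after the astro peak is read back as the
        astro-peak-to-neuron-valley interval."""
        astro_kin = Kinetics(2.47, 5.66, 20.0, 4.0)
        neuron_kin = Kinetics(0.42, 1.07, 8.0, 5.0)
        ka = transient_kernel(astro_kin, RATE)
        kn = transient_kernel(neuron_kin, RATE, kernel_fall_s=0.0)
        pre, post = 5.0, 38.0
        t = np.arange(int((pre + post) * RATE)) / RATE - pre
        dip_c = astro_kin.peak_time_s + 1.50
        row_n = np.zeros_like(t)
        seg = min(len(kn), int(post * RATE))
        row_n[int(pre * RATE) : int(pre * RATE) + seg] = kn[:seg]
        row_n -= 3.0 * np.exp(-0.5 * ((t - dip_c) / 0.8) ** 2)
        from fiberphot.transients import EventTriggeredEnsemble

        ens_a = EventTriggeredEnsemble(_trial_matrix(ka, pre, post), pre, post, RATE, np.arange(3.0))
        ens_n = EventTriggeredEnsemble(np.tile(row_n, (3, 1)), pre, post, RATE, np.arange(3.0))
        astro = response_metrics(ens_a, ResponseParams(peak_window_s=15.0))
        neuron = response_metrics(ens_n, ResponseParams(peak_window_s=5.0), with_valley=True)
        d = paired_differences(astro, neuron)
        assert d["astro_peak_to_neuron_valley_s"].mean() == pytest.approx(1.50, abs=0.15)

    def test_flat_trials_are_nonresponders(self):
        from fiberphot.transients import EventTriggeredEnsemble

        kern = transient_kernel(Kinetics(0.42, 1.07, 8.0, 5.0), RATE, kernel_fall_s=0.0)
        mat = _trial_matrix(kern, 5.0, 20.0, n_trials=2)
        mat[1] = 0.0  # flat trial
        ens = EventTriggeredEnsemble(mat, 5.0, 20.0, RATE, np.arange(2.0))
        m = response_metrics(ens, ResponseParams(peak_window_s=5.0))
        assert list(m.responders) == [True, False]

    def test_all_nonresponders_errors(self):
        from fiberphot.transients import EventTriggeredEnsemble

        ens = EventTriggeredEnsemble(np.zeros((3, 600)), 5.0, 15.0, RATE, np.arange(3.0))
        with pytest.raises(ValueError):
            response_metrics(ens)


class TestPairedDifferences:
    def _metrics(self, latencies, peaks, valleys=None):
        from fiberphot.transients import ResponseMetrics

        n = len(latencies)
        return ResponseMetrics(
            latency_s=np.array(latencies),
            peak_time_s=np.array(peaks),
            peak_z=np.full(n, 5.0),
            duration_s=np.full(n, 5.0),
            valley_time_s=np.array(valleys) if valleys is not None else None,
            responders=np.ones(n, dtype=bool),
        )

    def test_identical_inputs_zero_differences(self):
        a = self._metrics([1.0, 2.0], [3.0, 4.0])
        d = paired_differences(a, self._metrics([1.0, 2.0], [3.0, 4.0]))
        assert np.allclose(d["latency_diff_s"], 0.0)
        assert np.allclose(d["peak_diff_s"], 0.0)

    def test_injected_latency_difference(self):
        a = self._metrics([2.47] * 4, [5.66] * 4)
        n = self._metrics([0.42] * 4, [1.07] * 4)
        d = paired_differences(a, n)
        assert d["latency_diff_s"].mean() == pytest.approx(2.05, abs=1e-9)

    def test_sign_convention_astro_later_is_positive(self):
        a = self._metrics([2.0], [6.0])
        n = self._metrics([0.5], [1.0], valleys=[7.5])
        d = paired_differences(a, n)
        assert d["latency_diff_s"][0] > 0
        assert d["astro_peak_to_neuron_valley_s"][0] == pytest.approx(1.5)

    def test_unpaired_counts_error(self):
        a = self._metrics([1.0, 2.0], [3.0, 4.0])
        b = self._metrics([1.0], [3.0])
        with pytest.raises(ValueError):
            paired_differences(a, b)
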