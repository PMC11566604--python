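"""Synthetic-recording generator: behavior, stimulus trains, recordings,
ground-truth annotations, renderers, determinism."""

import dataclasses

import numpy as np
import pytest

from fiberphot.preprocess import extract_roi_traces, process_recording
from fiberphot.simulate import (
    ConfigurationError,
    FootshockParams,
    MicrodomainParams,
    MovementBoutParams,
    SimulationConfig,
    make_behavior,
    make_stimulus_train,
    render_behavior_video,
    render_fiber_bundle_frames,
    simulate_recording,
)


def _small_config(**kw):
    kw.setdefault("duration_s", 120.0)
    kw.setdefault(
        "movement_bouts",
        MovementBoutParams(rate_per_min=0.5, duration_mean_s=3.0, n_bouts=1),
    )
    return SimulationConfig(**kw)


class TestBehavior:
    def test_no_bouts_single_stationary_segment(self):
        cfg = SimulationConfig(
            duration_s=120.0, movement_bouts=MovementBoutParams(rate_per_min=0.0)
        )
        _, segments, truth = make_behavior(cfg)
        assert segments.segments == [(0.0, 120.0, "stationary")]
        assert len(truth.movement_onsets) == 0

    def test_renewal_bout_count_tracks_rate(self):
        """rate 2/min over 600 s -> ~20 bouts within Poisson error."""
        counts = []
        for seed in range(5):
            cfg = SimulationConfig(
                duration_s=600.0,
                movement_bouts=MovementBoutParams(rate_per_min=2.0, duration_mean_s=3.0),
                seed=seed,
            )
            counts.append(len(make_behavior(cfg)[2].bouts))
        mean = np.mean(counts)
        assert 20 - 3 * np.sqrt(20) <= mean <= 20 + 3 * np.sqrt(20)

    def test_min_quiescence_before_every_onset(self):
        cfg = SimulationConfig(
            duration_s=300.0,
            movement_bouts=MovementBoutParams(rate_per_min=2.0, min_quiescence_s=3.0),
            seed=3,
        )
        movement, segments, truth = make_behavior(cfg)
        rate = cfg.rate_hz
        for onset in truth.movement_onsets:
            i = int(onset * rate)
            pre = movement.index[max(i - int(3 * rate), 0) : i - 2]
            assert np.all(pre < 0.05)

    def test_short_session_rejected(self):
        with pytest.raises(ConfigurationError):
            make_behavior(SimulationConfig(duration_s=30.0))

    def test_index_nonnegative(self):
        movement, _, _ = make_behavior(SimulationConfig(duration_s=120.0))
        assert np.all(movement.index >= 0)


class TestStimulusTrain:
    def test_default_five_minute_schedule(self):
        cfg = SimulationConfig(duration_s=1500.0)
        train = make_stimulus_train(cfg)
        assert np.allclose(train.onsets, [300.0, 600.0, 900.0, 1200.0])
        assert train.pulse_s == 1.0
        assert train.amplitude_mA == 0.6

    def test_single_trial(self):
        cfg = SimulationConfig(footshock=FootshockParams(n_trials=1))
        assert len(make_stimulus_train(cfg).onsets) == 1

    def test_pulse_spans_30_samples_at_30hz(self):
        cfg = SimulationConfig()
        train = make_stimulus_train(cfg)
        assert int(train.pulse_s * cfg.rate_hz) == 30

    def test_invalid_counts_and_intervals(self):
        with pytest.raises(ConfigurationError):
            make_stimulus_train(SimulationConfig(footshock=FootshockParams(n_trials=0)))
        with pytest.raises(ConfigurationError):
            make_stimulus_train(
                SimulationConfig(footshock=FootshockParams(interval_s=0.5, pulse_s=1.0))
            )


class TestSimulateRecording:
    def test_deterministic_given_seed(self):
        cfg = _small_config(seed=9)
        rec1, _ = simulate_recording(cfg)
        rec2, _ = simulate_recording(_small_config(seed=9))
        for key in rec1.traces:
            assert np.array_equal(rec1.traces[key], rec2.traces[key])

    def test_different_seeds_differ(self):
        rec1, _ = simulate_recording(_small_config(seed=1))
        rec2, _ = simulate_recording(_small_config(seed=2))
        key = next(iter(rec1.traces))
        assert not np.array_equal(rec1.traces[key], rec2.traces[key])

    def test_eventless_noiseless_limit_is_pure_bleach(self):
        cfg = SimulationConfig(
            duration_s=120.0,
            movement_bouts=MovementBoutParams(rate_per_min=0.0),
            microdomain=MicrodomainParams(rate_per_min=0.0),
            spontaneous_neuron_per_min=0.0,
            coupling=dataclasses.replace(
                SimulationConfig().coupling,
                noise_sd=0.0, white_sd=0.0,
                shared_sd_stationary=0.0, shared_sd_movement=0.0,
            ),
        )
        rec, truth = simulate_recording(cfg)
        assert truth.events == []
        tr = rec.traces[("M1", "astro")]
        # strictly decreasing bleach curve, smooth
        assert np.all(np.diff(tr) <= 0)
        proc = process_recording(rec, window_s=30.0)
        assert np.max(np.abs(proc[("M1", "astro")].dff)) < 1e-3

    def test_one_event_per_onset_per_region(self):
        cfg = _small_config(seed=4, spontaneous_neuron_per_min=0.0,
                            microdomain=MicrodomainParams(rate_per_min=0.0))
        _, truth = simulate_recording(cfg)
        n_onsets = len(truth.movement_onsets)
        astro_mv = truth.events_of("astro", kinds={"movement"})
        assert len(astro_mv) == n_onsets * len(cfg.regions)

    def test_microdomain_amplitude_ratio_ten(self):
        cfg = _small_config(seed=5)
        _, truth = simulate_recording(cfg)
        glob = truth.events_of("astro", kinds={"movement"})
        micro = truth.events_of("astro", kinds={"microdomain"})
        if micro and glob:
            assert glob[0].amplitude_z / micro[0].amplitude_z == pytest.approx(10.0)

    def test_every_event_ordered(self):
        _, truth = simulate_recording(_small_config(seed=6))
        for ev in truth.events:
            assert ev.onset_s < ev.peak_s <= ev.end_s

    def test_control_channels_present_and_event_free(self):
        cfg = _small_config(seed=7, control_channels=True)
        rec, truth = simulate_recording(cfg)
        assert ("M1", "gfp") in rec.traces
        assert ("M1", "mcherry") in rec.traces
        assert all(ev.cell_type in ("astro", "neuron") for ev in truth.events)
        assert rec.channel_meta["gfp"].cell_type == "control"

    def test_coupling_stronger_in_movement(self):
        _, truth = simulate_recording(_small_config(seed=8))
        assert truth.coupling["movement"] > truth.coupling["stationary"]
        assert truth.coupling["movement"] == pytest.approx(0.88, abs=0.03)
        assert truth.coupling["stationary"] == pytest.approx(0.30, abs=0.03)

    def test_mismatched_behavior_length_errors(self):
        cfg = _small_config(seed=1)
        behavior = make_behavior(_small_config(duration_s=150.0, seed=1))
        from fiberphot.simulate import AlignmentError

        with pytest.raises(AlignmentError):
            simulate_recording(cfg, behavior)

    def test_overdense_events_rejected(self):
        cfg = SimulationConfig(
            duration_s=120.0,
            astro_kinetics=dataclasses.replace(
                SimulationConfig().astro_kinetics, amplitude_z=8.0
            ),
            movement_bouts=MovementBoutParams(rate_per_min=2.0, n_bouts=6),
        )
        with pytest.raises(ConfigurationError):
            simulate_recording(cfg)


class TestFiberBundleRendering:
    def _recording(self, value=100.0, n=20):
        from fiberphot.preprocess import RawRecording

        return RawRecording(
            traces={("S1", "astro"): np.full(n, value), ("S1", "neuron"): np.full(n, 200.0)},
            rate_hz=30.0,
        )

    def test_constant_trace_disc_mean(self):
        stack = render_fiber_bundle_frames(self._recording(100.0))
        mask = stack.roi_masks[("S1", "astro")]
        assert stack.frames[0][mask].mean() == pytest.approx(100.0, abs=0.5)

    def test_round_trip_recovers_fraw(self):
        cfg = _small_config(seed=2, duration_s=120.0)
        rec, _ = simulate_recording(cfg)
        short = dataclasses.replace(rec)
        short.traces = {k: v[:60] for k, v in rec.traces.items()}
        stack = render_fiber_bundle_frames(short)
        back = extract_roi_traces(stack)
        for key in short.traces:
            assert np.max(np.abs(back.traces[key] - short.traces[key])) <= 0.5

    def test_empty_layout_errors(self):
        with pytest.raises(ValueError):
            render_fiber_bundle_frames(self._recording(), layout={})

    def test_overlapping_layout_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            render_fiber_bundle_frames(
                self._recording(),
                layout={("S1", "astro"): (20, 20, 8), ("S1", "neuron"): (20, 25, 8)},
            )


class TestBehaviorVideoRendering:
    def test_static_blob_zero_movement_index(self):
        from fiberphot.behavior import analyze_video

        cfg = SimulationConfig(
            duration_s=60.0, movement_bouts=MovementBoutParams(rate_per_min=0.0)
        )
        movement, _, _ = make_behavior(cfg)
        video = render_behavior_video(movement)
        measured = analyze_video(video)
        assert np.allclose(measured.index, 0.0)

    def test_blob_area_constant(self):
        cfg = SimulationConfig(duration_s=60.0)
        movement, _, _ = make_behavior(cfg)
        video = render_behavior_video(movement)
        areas = (video.frames < 128).reshape(video.frames.shape[0], -1).sum(axis=1)
        assert areas.std() / areas.mean() < 0.05

    def test_out_of_bounds_trajectory_errors(self):
        cfg = SimulationConfig(duration_s=60.0)
        movement, _, _ = make_behavior(cfg)
        movement.centroid_px[:] = [2.0, 2.0]
        with pytest.raises(ValueError):
            render_behavior_video(movement)

    def test_shifted_blob_index_matches_pixel_count_oracle(self):
        """A blob translated 2 px/frame: index = |symmetric difference| /
        area, computable from two rendered frames."""
        from fiberphot.behavior import analyze_video

        cfg = SimulationConfig(duration_s=60.0, movement_bouts=MovementBoutParams(rate_per_min=0.0))
        movement, _, _ = make_behavior(cfg)
        n = len(movement.index)
        movement.centroid_px[:, 1] = movement.centroid_px[0, 1] + 2 * np.arange(n) % 40
        video = render_behavior_video(movement)
        measured = analyze_video(video)
        m0 = video.frames[0] < 128
        m1 = video.frames[1] < 128
        expect = (m0 ^ m1).sum() / (0.5 * (m0.sum() + m1.sum()))
        assert measured.index[1] == pytest.approx(expect, rel=1e-6)


def test_config_invariants():
    with pytest.raises(ConfigurationError):
        SimulationConfig(rate_hz=0.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(microdomain=MicrodomainParams(amplitude_fraction=0.0))
    with pytest.raises(ConfigurationError):
        SimulationConfig(movement_bouts=MovementBoutParams(duration_mean_s=-1.0))
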