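"""End-to-end parameter-recovery workflows on synthetic sessions.

Each function generates synthetic recordings with the configured study
conditions, runs the full analysis pipeline (preprocess -> behavior ->
detect -> metrics / connectivity / prediction) and returns the recovered
quantities together with the injected ground truth, so that recovery can be
checked at desk scale.  All randomness is controlled by a single seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import connectivity as conn
from . import prediction as pred
from .behavior import segment_states
from .preprocess import process_recording
from .simulate import (
    MovementBoutParams,
    SimulationConfig,
    make_behavior,
    make_stimulus_train,
    simulate_recording,
)
from .stats import wilcoxon_rank_sum
from .transients import (
    ResponseParams,
    build_ensemble,
    detect_transients,
    paired_differences,
    response_metrics,
)

# Analysis defaults for kinetic recovery: the moving-mean baseline window must
# be long relative to the slowest transient (tens of seconds), both to
# preserve slow events in dF/F and to keep each event's own mass from
# structuring the baseline around it (distortion ~ event integral / window).
BASELINE_WINDOW_S = 300.0
# movement-evoked astro responses have a broad plateau peak -> strong peak
# smoothing; footshock astro peaks are sharp -> default smoothing
ASTRO_PARAMS = ResponseParams(peak_window_s=15.0, smooth_s=1.0, peak_smooth_s=2.0)
FS_ASTRO_PARAMS = ResponseParams(peak_window_s=15.0, smooth_s=0.33)
NEURON_PARAMS = ResponseParams(peak_window_s=5.0)


def _subseed(seed: int, k: int) -> int:
    return int((seed * 100_003 + 7 * k + 1) % 2**31)


def movement_recovery_config(seed: int) -> SimulationConfig:
    """Movement-bout condition: isolated bouts so each onset is one clean
    trial; spontaneous background events are disabled so trials measure the
    evoked response alone.  The movement-evoked astro response is shorter
    (20 s) and larger than the spontaneous default, per-condition amplitudes
    keep the z-variance budget feasible."""
    base = SimulationConfig()
    return SimulationConfig(
        duration_s=2800.0,
        astro_kinetics=dataclasses.replace(
            base.astro_kinetics, duration_s=20.0, amplitude_z=4.0
        ),
        neuron_kinetics=dataclasses.replace(base.neuron_kinetics, amplitude_z=5.0),
        movement_bouts=MovementBoutParams(
            rate_per_min=0.45, duration_mean_s=3.0, duration_sd_s=1.0,
            min_quiescence_s=45.0, n_bouts=21,
        ),
        spontaneous_neuron_per_min=0.0,
        seed=seed,
    )


def movement_recovery(seed: int = 1, n_trials: int = 20, region: str = "M1") -> dict:
    """Recover movement-evoked kinetics from a full simulated session.

    Simulates a session with isolated movement bouts, recovers movement onsets
    from the behavior index, and measures astro/neuron response kinetics on
    event-triggered ensembles of the preprocessed z traces.
    """
    config = movement_recovery_config(seed)
    behavior = make_behavior(config)
    recording, truth = simulate_recording(config, behavior)
    processed = process_recording(recording, window_s=BASELINE_WINDOW_S)

    segs = segment_states(behavior[0].index, config.rate_hz)
    onsets = segs.movement_onsets[:n_trials]

    rate = config.rate_hz
    za = processed[(region, "astro")].z
    zn = processed[(region, "neuron")].z
    ens_a = build_ensemble(za, onsets, 5.0, 38.0, rate, rebaseline=True)
    ens_n = build_ensemble(zn, onsets, 5.0, 38.0, rate, rebaseline=True)
    astro = response_metrics(ens_a, ASTRO_PARAMS, cell_type="astro")
    neuron = response_metrics(ens_n, NEURON_PARAMS, with_valley=True, cell_type="neuron")
    diffs = paired_differences(astro, neuron)
    return {
        "config": config,
        "truth": truth,
        "n_trials": len(onsets),
        "astro": astro,
        "neuron": neuron,
        "differences": diffs,
        "astro_latency_mean": float(astro.latency_s.mean()),
        "neuron_latency_mean": float(neuron.latency_s.mean()),
        "astro_peak_mean": float(astro.peak_time_s.mean()),
        "neuron_peak_mean": float(neuron.peak_time_s.mean()),
        "peak_to_valley_mean": float(
            diffs["astro_peak_to_neuron_valley_s"].mean()
        ),
    }


def footshock_recovery(
    seed: int = 1, n_sessions: int = 5, region: str = "S1"
) -> dict:
    """Recover footshock-evoked kinetics over several 4-shock sessions."""
    mats_a, mats_n = [], []
    config = None
    for k in range(n_sessions):
        config = SimulationConfig.footshock_session(seed=_subseed(seed, k))
        behavior = make_behavior(config)
        stimuli = make_stimulus_train(config)
        recording, _ = simulate_recording(config, behavior, stimuli)
        processed = process_recording(recording, window_s=BASELINE_WINDOW_S)
        rate = config.rate_hz
        ens_a = build_ensemble(
            processed[(region, "astro")].z, stimuli.onsets, 5.0, 20.0, rate, rebaseline=True
        )
        ens_n = build_ensemble(
            processed[(region, "neuron")].z, stimuli.onsets, 5.0, 20.0, rate, rebaseline=True
        )
        mats_a.append(ens_a.matrix)
        mats_n.append(ens_n.matrix)
    ens_a.matrix = np.vstack(mats_a)
    ens_n.matrix = np.vstack(mats_n)
    astro = response_metrics(ens_a, FS_ASTRO_PARAMS, cell_type="astro")
    neuron = response_metrics(ens_n, NEURON_PARAMS, with_valley=True, cell_type="neuron")
    diffs = paired_differences(astro, neuron)
    return {
        "config": config,
        "n_trials": ens_a.matrix.shape[0],
        "astro": astro,
        "neuron": neuron,
        "differences": diffs,
        "astro_latency_mean": float(astro.latency_s.mean()),
        "neuron_latency_mean": float(neuron.latency_s.mean()),
        "astro_duration_mean": float(astro.duration_s.mean()),
        "neuron_duration_mean": float(neuron.duration_s.mean()),
        "peak_to_valley_mean": float(
            diffs["astro_peak_to_neuron_valley_s"].mean()
        ),
    }


def duration_dichotomy(seed: int = 1) -> dict:
    """Detected transient durations on the default free-behavior session:
    astro events mostly > 20 s, neuron events mostly < 20 s.  The default
    bout rate is realised with a fixed count so the event density (and hence
    the z-variance budget) is seed-stable."""
    config = SimulationConfig(
        seed=seed, movement_bouts=MovementBoutParams(rate_per_min=0.2, n_bouts=3)
    )
    recording, truth = simulate_recording(config)
    processed = process_recording(recording, window_s=BASELINE_WINDOW_S)
    durations = {"astro": [], "neuron": []}
    for region in config.regions:
        for cell in ("astro", "neuron"):
            events = detect_transients(
                processed[(region, cell)].z, config.rate_hz, smooth_s=1.0
            )
            durations[cell].extend(ev.duration_s for ev in events)
    da = np.array(durations["astro"])
    dn = np.array(durations["neuron"])
    return {
        "truth": truth,
        "astro_durations": da,
        "neuron_durations": dn,
        "astro_frac_gt20": float((da > 20).mean()) if da.size else float("nan"),
        "neuron_frac_lt20": float((dn < 20).mean()) if dn.size else float("nan"),
    }


def control_false_positives(seed: int = 1) -> dict:
    """Detected event rate on inert control-fluorophore channels."""
    config = SimulationConfig(
        seed=seed,
        control_channels=True,
        movement_bouts=MovementBoutParams(rate_per_min=0.2, n_bouts=3),
    )
    recording, _ = simulate_recording(config)
    processed = process_recording(recording, window_s=BASELINE_WINDOW_S)
    count = 0
    minutes = 0.0
    for (region, channel), proc in processed.items():
        if channel not in ("gfp", "mcherry"):
            continue
        count += len(detect_transients(proc.z, config.rate_hz, smooth_s=1.0))
        minutes += config.duration_s / 60.0
    return {"events_per_min": count / minutes, "n_channels": int(minutes / (config.duration_s / 60.0))}


def connectivity_trial_config(seed: int) -> SimulationConfig:
    """Sustained-locomotion sessions: long bouts with astro activity that
    tracks them (shorter astro responses than the spontaneous default, so the
    shared evoked component stays inside the movement state); amplitudes fit
    the z-variance budget at this event density."""
    base = SimulationConfig()
    return SimulationConfig(
        duration_s=300.0,
        astro_kinetics=dataclasses.replace(
            base.astro_kinetics, duration_s=14.0, amplitude_z=2.4
        ),
        neuron_kinetics=dataclasses.replace(base.neuron_kinetics, amplitude_z=3.5),
        movement_bouts=MovementBoutParams(
            rate_per_min=0.8, duration_mean_s=15.0, duration_sd_s=3.0,
            min_quiescence_s=5.0, n_bouts=4,
        ),
        seed=seed,
    )


def connectivity_ordering(seed: int = 1, n_trials: int = 20, max_lag_s: float = 10.0) -> dict:
    """State-conditioned connectivity over independent simulated trials.

    Per trial: mean off-diagonal inter-region Spearman r per cell type and
    the astro-neuron peak cross-correlation per region, for stationary and
    movement states; rank-sum tests of movement > stationary across trials.
    """
    res = {
        "spearman": {("astro", s): [] for s in ("stationary", "movement")}
        | {("neuron", s): [] for s in ("stationary", "movement")},
        "xcorr": {s: [] for s in ("stationary", "movement")},
    }
    truth_coupling = None
    for k in range(n_trials):
        config = connectivity_trial_config(_subseed(seed, 1000 + k))
        behavior = make_behavior(config)
        recording, truth = simulate_recording(config, behavior)
        truth_coupling = truth.coupling
        processed = process_recording(recording, window_s=BASELINE_WINDOW_S)
        segs = segment_states(behavior[0].index, config.rate_hz)
        for state in ("stationary", "movement"):
            for cell in ("astro", "neuron"):
                traces = {r: processed[(r, cell)].z for r in config.regions}
                series = conn.state_conditioned_series(
                    traces, segs, state, config.rate_hz
                )
                mat = conn.interregion_spearman(series, cell_type=cell, state=state)
                res["spearman"][(cell, state)].append(mat.mean_offdiag())
            peaks = []
            for r in config.regions:
                pair = conn.state_conditioned_series(
                    {
                        "astro": processed[(r, "astro")].z,
                        "neuron": processed[(r, "neuron")].z,
                    },
                    segs,
                    state,
                    config.rate_hz,
                )
                cc = conn.astro_neuron_crosscorr(
                    pair["astro"], pair["neuron"], max_lag_s, config.rate_hz,
                    state=state, region=r,
                )
                peaks.append(cc.peak_r)
            res["xcorr"][state].append(float(np.mean(peaks)))

    out = {"truth_coupling": truth_coupling}
    for cell in ("astro", "neuron"):
        mov = np.array(res["spearman"][(cell, "movement")])
        sta = np.array(res["spearman"][(cell, "stationary")])
        out[f"spearman_{cell}_movement"] = mov
        out[f"spearman_{cell}_stationary"] = sta
        out[f"spearman_{cell}_p"] = wilcoxon_rank_sum(mov, sta).p_value
    mov = np.array(res["xcorr"]["movement"])
    sta = np.array(res["xcorr"]["stationary"])
    out["xcorr_movement"] = mov
    out["xcorr_stationary"] = sta
    out["xcorr_p"] = wilcoxon_rank_sum(mov, sta).p_value
    return out


def prediction_ordering(seed: int = 1, region: str = "M1") -> dict:
    """Variance explained of astro z from lagged neuron z, by state, plus a
    circularly-shifted-target control."""
    base = SimulationConfig()
    config = SimulationConfig(
        duration_s=400.0,
        astro_kinetics=dataclasses.replace(
            base.astro_kinetics, duration_s=14.0, amplitude_z=2.3
        ),
        neuron_kinetics=dataclasses.replace(base.neuron_kinetics, amplitude_z=3.5),
        movement_bouts=MovementBoutParams(
            rate_per_min=0.75, duration_mean_s=20.0, duration_sd_s=4.0,
            min_quiescence_s=5.0, n_bouts=5,
        ),
        seed=seed,
    )
    behavior = make_behavior(config)
    recording, _ = simulate_recording(config, behavior)
    processed = process_recording(recording, window_s=BASELINE_WINDOW_S)
    segs = segment_states(behavior[0].index, config.rate_hz)

    lags = np.arange(0.0, 11.0)
    zn = processed[(region, "neuron")].z
    za = processed[(region, "astro")].z
    X, idx = pred.build_lagged_features(zn, lags, config.rate_hz)
    y = za[idx]
    out = {}
    for state in ("stationary", "movement"):
        mask = segs.state_mask(len(za), config.rate_hz, state)[idx]
        out[state] = pred.fit_variance_explained(
            X[mask], y[mask], seed=_subseed(seed, 77), lags_s=lags,
            region=region, state=state,
        ).variance_explained
    shift = int(60.0 * config.rate_hz)
    y_shift = np.roll(za, shift)[idx]
    out["shifted"] = pred.fit_variance_explained(
        X, y_shift, seed=_subseed(seed, 78), lags_s=lags, region=region,
        state="shifted-control",
    ).variance_explained
    return out


def behavior_recovery(seed: int = 1) -> dict:
    """Render a behavior video from ground truth, run the video pipeline, and
    score movement-onset recovery and centroid accuracy."""
    from .behavior import analyze_video
    from .simulate import render_behavior_video

    config = SimulationConfig(
        duration_s=90.0,
        movement_bouts=MovementBoutParams(
            rate_per_min=3.0, duration_mean_s=4.0, duration_sd_s=1.0,
            min_quiescence_s=3.0,
        ),
        seed=seed,
    )
    movement, segs, truth = make_behavior(config)
    video = render_behavior_video(movement)
    measured = analyze_video(video, method="otsu")
    rec_segs = segment_states(measured.index, config.rate_hz)

    tol = 0.5
    true_onsets = truth.movement_onsets
    got = rec_segs.movement_onsets
    matched = sum(any(abs(g - t) <= tol for g in got) for t in true_onsets)
    recall = matched / len(true_onsets) if len(true_onsets) else float("nan")
    precision = (
        sum(any(abs(g - t) <= tol for t in true_onsets) for g in got) / len(got)
        if len(got)
        else float("nan")
    )
    centroid_err = np.nanmax(
        np.linalg.norm(measured.centroid_px - movement.centroid_px, axis=1)
    )
    return {
        "recall": recall,
        "precision": precision,
        "n_true_onsets": len(true_onsets),
        "n_detected_onsets": len(got),
        "max_centroid_err_px": float(centroid_err),
    }
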