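"""Ground-truth-annotated synthetic dual-color multi-fiber recordings.

The generator emulates the statistical structure of in-vivo dual-color
(GCaMP6f astrocyte / jRGECO1a neuron) multi-region fiber photometry during
free behavior and footshock sessions:

* two-state behavior (stationary / movement bouts) from a renewal process,
  with an open-field trajectory and a body-movement index;
* footshock trains (1 s pulses at fixed intervals);
* event-evoked transients per region: fast short neuronal responses and
  slow long astrocytic responses, with kinetics (latency, peak time,
  duration, z amplitude) configured directly in the units the analysis
  measures — kernels are solved so those observables hold by construction;
* a neuronal "valley": a suppression dip locked a fixed interval after the
  astrocytic peak (negative astro->neuron feedback);
* stationary-state astrocytic microdomain events at a small fraction of the
  movement-state (cell-wide) amplitude;
* a state-dependent shared drive correlating all channels more strongly
  during movement than stationary epochs, plus per-channel noise and slow
  mono-exponential photobleaching;
* optional inert control channels (GFP / mCherry): drive + noise + bleach,
  no events.

Event shapes are built in z units and mapped to raw fluorescence through a
gain calibrated so that, after the standard dF/F + whole-session z-score
pipeline, realized amplitudes equal the configured ``amplitude_z``.  Fixed
seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .behavior import MovementTrace, StateSegments, StimulusTrain, VideoStack
from .kernels import Kinetics, design_kernel, double_exp, transient_kernel
from .preprocess import ChannelMeta, RawRecording, RoiImageStack

__all__ = [
    "MovementBoutParams",
    "MicrodomainParams",
    "CouplingParams",
    "BleachParams",
    "FootshockParams",
    "SimulationConfig",
    "TrueEvent",
    "GroundTruth",
    "make_behavior",
    "make_stimulus_train",
    "simulate_recording",
    "simulate_session",
    "render_fiber_bundle_frames",
    "render_behavior_video",
]

THETA_OFF = 0.5
THETA_CONT = 1.5  # must match transients.ResponseParams.theta_cont


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class MovementBoutParams:
    rate_per_min: float = 0.2
    duration_mean_s: float = 3.0
    duration_sd_s: float = 1.0
    min_quiescence_s: float = 3.0
    # fixed trial structure: exactly n_bouts bouts on a jittered regular
    # schedule instead of the renewal process (None -> renewal)
    n_bouts: int | None = None


@dataclass
class MicrodomainParams:
    rate_per_min: float = 0.3
    amplitude_fraction: float = 0.1


@dataclass
class CouplingParams:
    """Noise floor: a slow hemodynamic/arousal-like drive plus white
    measurement noise, all as fractions of F0.

    The drive has a common component (``shared_sd_*``, state-dependent) and a
    per-channel component (``noise_sd``), both low-pass filtered at
    ``drive_tau_s``; the correlation between two channels' noiseless drive in
    a state is shared_sd^2 / (shared_sd^2 + noise_sd^2) — defaults give ~0.88
    during movement and ~0.30 when stationary.  ``white_sd`` is uncorrelated
    per-sample measurement noise on top."""

    noise_sd: float = 0.001  # per-channel slow drive, fraction of F0
    shared_sd_stationary: float = 0.00065
    shared_sd_movement: float = 0.00271
    white_sd: float = 0.004  # per-channel measurement noise, fraction of F0
    drive_tau_s: float = 2.0


@dataclass
class BleachParams:
    amplitude_fraction: float = 0.1
    tau_s: float = 1800.0


@dataclass
class FootshockParams:
    amplitude_mA: float = 0.6
    pulse_s: float = 1.0
    interval_s: float = 300.0
    n_trials: int = 4
    start_s: float | None = None  # defaults to interval_s


# Kinetics defaults: movement-evoked transients.  Astro latency/peak are the
# reported movement-evoked values; durations are package defaults consistent
# with the >20 s (astro) / <20 s (neuron) duration dichotomy.  Amplitudes are
# bounded by the z-variance budget: dense slow astro events cannot exceed a
# few z, sparse footshock responses can be an order of magnitude larger.
MOVEMENT_ASTRO = Kinetics(onset_latency_s=2.47, peak_time_s=5.66, duration_s=40.0, amplitude_z=3.5)
MOVEMENT_NEURON = Kinetics(onset_latency_s=0.42, peak_time_s=1.07, duration_s=8.0, amplitude_z=5.0)
FOOTSHOCK_ASTRO = Kinetics(onset_latency_s=1.05, peak_time_s=1.67, duration_s=8.05, amplitude_z=14.0)
FOOTSHOCK_NEURON = Kinetics(onset_latency_s=0.20, peak_time_s=0.99, duration_s=6.24, amplitude_z=12.0)


@dataclass
class SimulationConfig:
    duration_s: float = 900.0
    rate_hz: float = 30.0
    regions: tuple[str, ...] = ("S1", "M1", "CA1")
    astro_kinetics: Kinetics = field(default_factory=lambda: dataclasses.replace(MOVEMENT_ASTRO))
    neuron_kinetics: Kinetics = field(default_factory=lambda: dataclasses.replace(MOVEMENT_NEURON))
    valley_offset_s: float = 1.50  # astro peak -> neuron valley
    valley_depth_z: float = 3.0
    movement_bouts: MovementBoutParams = field(default_factory=MovementBoutParams)
    microdomain: MicrodomainParams = field(default_factory=MicrodomainParams)
    spontaneous_neuron_per_min: float = 0.5
    spontaneous_amplitude_fraction: float = 0.7
    coupling: CouplingParams = field(default_factory=CouplingParams)
    bleach: BleachParams = field(default_factory=BleachParams)
    footshock: FootshockParams = field(default_factory=FootshockParams)
    control_channels: bool = False
    f0: float = 1000.0
    arena_cm: tuple[float, float] = (40.0, 40.0)
    video_shape: tuple[int, int] = (180, 320)  # reduced-resolution default
    seed: int = 1

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigurationError("rate_hz must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if not (0 < self.microdomain.amplitude_fraction <= 1):
            raise ConfigurationError("microdomain.amplitude_fraction must be in (0, 1]")
        if self.movement_bouts.duration_mean_s <= 0:
            raise ConfigurationError("movement bout duration must be positive")
        if self.bleach.tau_s <= 0:
            raise ConfigurationError("bleach tau must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))

    @staticmethod
    def footshock_session(**overrides) -> "SimulationConfig":
        """Footshock-session preset: reported footshock kinetics, no bouts."""
        base = dict(
            duration_s=1500.0,
            astro_kinetics=dataclasses.replace(FOOTSHOCK_ASTRO),
            neuron_kinetics=dataclasses.replace(FOOTSHOCK_NEURON),
            valley_offset_s=3.35,
            movement_bouts=MovementBoutParams(rate_per_min=0.0),
            # background events keep their absolute (free-behavior) size; as
            # fractions of the much larger footshock amplitudes they are small
            spontaneous_amplitude_fraction=0.05,
            microdomain=MicrodomainParams(rate_per_min=0.3, amplitude_fraction=0.02),
        )
        base.update(overrides)
        return SimulationConfig(**base)


@dataclass
class TrueEvent:
    region: str
    cell_type: str
    kind: str  # movement | shock | microdomain | spontaneous
    trigger_s: float
    onset_s: float
    peak_s: float
    end_s: float
    amplitude_z: float
    valley_time_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_s <= self.end_s):
            raise ValueError("event must satisfy onset < peak <= end")


@dataclass
class GroundTruth:
    events: list[TrueEvent]
    states: list[tuple[float, float, str]]
    movement_onsets: np.ndarray
    coupling: dict[str, float]
    trajectory_cm: np.ndarray | None = None
    bouts: list[tuple[float, float]] = field(default_factory=list)

    def events_of(self, cell_type: str, region: str | None = None, kinds=None):
        return [
            ev
            for ev in self.events
            if ev.cell_type == cell_type
            and (region is None or ev.region == region)
            and (kinds is None or ev.kind in kinds)
        ]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def make_behavior(
    config: SimulationConfig,
) -> tuple[MovementTrace, StateSegments, GroundTruth]:
    """Two-state renewal behavior: movement bouts, index trace, trajectory.

    Quiescent gaps are at least ``min_quiescence_s`` long with an exponential
    excess sized so the expected bout rate matches ``rate_per_min``; bout
    durations are truncated-normal.  The movement index is a smoothed positive
    signal during bouts and ~0 otherwise.
    """
    if config.duration_s < 60:
        raise ConfigurationError("behavior simulation needs duration_s >= 60")
    bp = config.movement_bouts
    if bp.duration_mean_s <= 0 or bp.min_quiescence_s < 0:
        raise ConfigurationError("bout durations must be positive")
    rng = _rng(config.seed, 0)
    rate = config.rate_hz
    n = config.n_samples

    bouts: list[tuple[float, float]] = []
    if bp.n_bouts:
        margin = min(60.0, config.duration_s / 4.0)
        usable = config.duration_s - 2 * margin
        cycle = usable / bp.n_bouts
        if cycle < bp.min_quiescence_s + bp.duration_mean_s + 2:
            raise ConfigurationError("n_bouts too high for the session duration")
        for k in range(bp.n_bouts):
            start = margin + k * cycle + rng.uniform(0, min(8.0, cycle / 4))
            dur = max(float(rng.normal(bp.duration_mean_s, bp.duration_sd_s)), 0.5)
            bouts.append((start, start + dur))
    elif bp.rate_per_min > 0:
        cycle = 60.0 / bp.rate_per_min
        gap_mean = max(cycle - bp.min_quiescence_s - bp.duration_mean_s, 1.0)
        t = 2.0
        while True:
            start = t + bp.min_quiescence_s + rng.exponential(gap_mean)
            dur = max(float(rng.normal(bp.duration_mean_s, bp.duration_sd_s)), 0.5)
            if start + dur >= config.duration_s - 1.0:
                break
            bouts.append((start, start + dur))
            t = start + dur

    # movement index: smoothed boxcar during bouts + tiny positive noise
    index = np.zeros(n)
    for s, e in bouts:
        index[int(round(s * rate)) : int(round(e * rate))] = 0.35
    index = gaussian_filter1d(index, sigma=max(0.07 * rate, 1.0))
    index += 0.003 * np.abs(rng.standard_normal(n))

    # trajectory: heading-persistent walk during bouts, still otherwise
    margin = 6.0
    pos = np.empty((n, 2))
    cur = np.array([config.arena_cm[0] / 2.0, config.arena_cm[1] / 2.0])
    bout_mask = np.zeros(n, dtype=bool)
    for s, e in bouts:
        bout_mask[int(round(s * rate)) : int(round(e * rate))] = True
    heading = rng.uniform(0, 2 * np.pi)
    speed = 0.0
    for i in range(n):
        if bout_mask[i]:
            if i == 0 or not bout_mask[i - 1]:
                heading = rng.uniform(0, 2 * np.pi)
                speed = rng.uniform(4.0, 8.0)  # cm/s
            heading += rng.normal(0, 0.15)
            step = speed / rate
            cur = cur + step * np.array([np.sin(heading), np.cos(heading)])
            for d in range(2):
                lo, hi = margin, config.arena_cm[d] - margin
                if cur[d] < lo or cur[d] > hi:
                    cur[d] = np.clip(cur[d], lo, hi)
                    heading = heading + np.pi / 2
        pos[i] = cur

    segments, onsets = _segments_from_bouts(bouts, config.duration_s, bp.min_quiescence_s)
    # square arena mapped onto the frame height; centered horizontally
    cm_per_px = config.arena_cm[0] / config.video_shape[0]
    centroid_px = pos / cm_per_px
    centroid_px[:, 1] += (config.video_shape[1] - config.video_shape[0]) / 2.0
    movement = MovementTrace(
        index=index,
        centroid_px=centroid_px,
        body_area_px=np.full(n, 188.0),
        rate_hz=rate,
        cm_per_px=cm_per_px,
    )
    truth = GroundTruth(
        events=[],
        states=segments.segments,
        movement_onsets=onsets,
        coupling={},
        trajectory_cm=pos,
        bouts=bouts,
    )
    return movement, segments, truth


def _segments_from_bouts(
    bouts: list[tuple[float, float]], duration_s: float, min_quiescence_s: float
) -> tuple[StateSegments, np.ndarray]:
    segs: list[tuple[float, float, str]] = []
    onsets = []
    prev_end = 0.0
    for s, e in bouts:
        if s > prev_end:
            segs.append((prev_end, s, "stationary"))
        if s - prev_end >= min_quiescence_s:
            onsets.append(s)
        segs.append((s, e, "movement"))
        prev_end = e
    if prev_end < duration_s:
        segs.append((prev_end, duration_s, "stationary"))
    return StateSegments(segments=segs, movement_onsets=np.array(onsets)), np.array(onsets)


def make_stimulus_train(config: SimulationConfig) -> StimulusTrain:
    """Fixed-interval footshock train (1 s pulses every 5 min by default)."""
    fs = config.footshock
    if fs.n_trials < 1:
        raise ConfigurationError("footshock.n_trials must be >= 1")
    if fs.interval_s <= fs.pulse_s:
        raise ConfigurationError("footshock interval must exceed the pulse duration")
    start = fs.interval_s if fs.start_s is None else fs.start_s
    onsets = start + fs.interval_s * np.arange(fs.n_trials)
    return StimulusTrain(
        onsets=onsets, pulse_s=fs.pulse_s, amplitude_mA=fs.amplitude_mA
    )


def _solve_valley_sigma(
    neuron_kin: Kinetics,
    kernel_tau: tuple[float, float],
    onset_offset_s: float,
    center_s: float,
    depth_z: float,
) -> float:
    """Width of the suppression dip so the composite neuronal response settles
    inside the +/- THETA_OFF band exactly at latency + configured duration."""
    target_end = neuron_kin.onset_latency_s + neuron_kin.duration_s
    tau_r, tau_d = kernel_tau
    amp = neuron_kin.amplitude_z
    t = np.arange(0.0, target_end + 20.0, 1.0 / 240.0)
    kern = amp * double_exp(t - onset_offset_s, tau_r, tau_d)

    def end_time(sigma: float) -> float:
        f = kern - depth_z * np.exp(-0.5 * ((t - center_s) / sigma) ** 2)
        strong = np.flatnonzero(np.abs(f) >= THETA_CONT)
        t_last = t[strong[-1]] if strong.size else 0.0
        after = np.flatnonzero((t >= t_last) & (np.abs(f) < THETA_OFF))
        return t[after[0]] if after.size else t[-1]

    lo, hi = 0.05, 6.0
    if end_time(hi) < target_end or end_time(lo) > target_end:
        raise ConfigurationError(
            "valley width cannot realise the configured neuronal duration; "
            "adjust valley_offset_s / valley_depth_z / duration_s"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if end_time(mid) < target_end:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _add_kernel(trace: np.ndarray, kernel: np.ndarray, at: int, scale: float = 1.0):
    if at >= len(trace):
        return
    k = kernel if at >= 0 else kernel[-at:]
    at = max(at, 0)
    seg = min(len(k), len(trace) - at)
    trace[at : at + seg] += scale * k[:seg]


def simulate_recording(
    config: SimulationConfig,
    behavior: tuple[MovementTrace, StateSegments, GroundTruth] | None = None,
    stimuli: StimulusTrain | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Generate raw multi-region dual-channel fluorescence with ground truth.

    Per region and channel, Fraw = F0 * (1 + gain*shape + drive + noise) *
    bleach(t), where ``shape`` is the z-unit event composition (transient
    kernels at movement onsets / shocks, microdomains, spontaneous events,
    minus the neuronal suppression dips) and ``gain`` is calibrated so the
    post-pipeline z amplitudes equal the configured values.
    """
    rate = config.rate_hz
    n = config.n_samples
    if behavior is None:
        behavior = make_behavior(config)
    movement, segments, btruth = behavior
    if len(movement.index) != n:
        raise AlignmentError(
            f"behavior has {len(movement.index)} samples but config implies {n}"
        )
    if stimuli is not None and len(stimuli.onsets) and stimuli.onsets[-1] > config.duration_s:
        raise AlignmentError("stimulus onsets extend beyond the recording")

    rng = _rng(config.seed, 1)
    times = np.arange(n) / rate

    triggers: list[tuple[float, str]] = [(t, "movement") for t in btruth.movement_onsets]
    if stimuli is not None:
        triggers += [(float(t), "shock") for t in stimuli.onsets]
    triggers.sort()

    astro_kernel = transient_kernel(config.astro_kinetics, rate)
    valley_on = bool(triggers) and config.valley_depth_z > 0
    neuron_rise = config.neuron_kinetics.peak_time_s - config.neuron_kinetics.onset_latency_s
    neuron_fall = 0.0 if valley_on else None  # 0 -> minimum feasible fall (6x rise)
    neuron_kernel = transient_kernel(config.neuron_kinetics, rate, kernel_fall_s=neuron_fall)

    valley_sigma = None
    valley_center_rel = config.astro_kinetics.peak_time_s + config.valley_offset_s
    if valley_on:
        nspec = design_kernel(config.neuron_kinetics, kernel_fall_s=0.0)
        valley_sigma = _solve_valley_sigma(
            config.neuron_kinetics,
            (nspec.tau_r, nspec.tau_d),
            nspec.onset_offset_s,
            valley_center_rel,
            config.valley_depth_z,
        )

    # stationary mask for microdomain placement & drive scaling
    move_mask = segments.state_mask(n, rate, "movement")
    stat_times = times[~move_mask]

    events: list[TrueEvent] = []
    shapes: dict[tuple[str, str], np.ndarray] = {}
    ak, nk = config.astro_kinetics, config.neuron_kinetics
    md = config.microdomain

    for region in config.regions:
        astro = np.zeros(n)
        neuron = np.zeros(n)
        for t0, kind in triggers:
            i0 = int(round(t0 * rate))
            _add_kernel(astro, astro_kernel, i0)
            _add_kernel(neuron, neuron_kernel, i0)
            valley_t = None
            if valley_on:
                c = t0 + valley_center_rel
                lo = int(np.floor((c - 5 * valley_sigma) * rate))
                hi = int(np.ceil((c + 5 * valley_sigma) * rate))
                idx = np.arange(max(lo, 0), min(hi, n))
                neuron[idx] -= config.valley_depth_z * np.exp(
                    -0.5 * ((idx / rate - c) / valley_sigma) ** 2
                )
                valley_t = c
            events.append(TrueEvent(region, "astro", kind, t0, t0 + ak.onset_latency_s,
                                    t0 + ak.peak_time_s, t0 + ak.onset_latency_s + ak.duration_s,
                                    ak.amplitude_z))
            events.append(TrueEvent(region, "neuron", kind, t0, t0 + nk.onset_latency_s,
                                    t0 + nk.peak_time_s, t0 + nk.onset_latency_s + nk.duration_s,
                                    nk.amplitude_z, valley_time_s=valley_t))

        # stationary astro microdomains (small-amplitude local events)
        if md.rate_per_min > 0 and stat_times.size:
            n_md = rng.poisson(md.rate_per_min * len(stat_times) / rate / 60.0)
            for t0 in np.sort(rng.choice(stat_times, size=min(n_md, len(stat_times)), replace=False)):
                _add_kernel(astro, astro_kernel, int(round(t0 * rate)), scale=md.amplitude_fraction)
                events.append(TrueEvent(region, "astro", "microdomain", float(t0),
                                        float(t0) + ak.onset_latency_s, float(t0) + ak.peak_time_s,
                                        float(t0) + ak.onset_latency_s + ak.duration_s,
                                        ak.amplitude_z * md.amplitude_fraction))

        # spontaneous neuronal events at a fraction of the evoked amplitude
        if config.spontaneous_neuron_per_min > 0:
            frac = config.spontaneous_amplitude_fraction
            n_sp = rng.poisson(config.spontaneous_neuron_per_min * config.duration_s / 60.0)
            for t0 in np.sort(rng.uniform(0, config.duration_s - 5.0, size=n_sp)):
                _add_kernel(neuron, neuron_kernel, int(round(t0 * rate)), scale=frac)
                events.append(TrueEvent(region, "neuron", "spontaneous", float(t0),
                                        float(t0) + nk.onset_latency_s, float(t0) + nk.peak_time_s,
                                        float(t0) + nk.onset_latency_s + nk.duration_s,
                                        nk.amplitude_z * frac))

        shapes[(region, "astro")] = astro
        shapes[(region, "neuron")] = neuron
        if config.control_channels:
            shapes[(region, "gfp")] = np.zeros(n)
            shapes[(region, "mcherry")] = np.zeros(n)

    # shared slow drive (common across every channel) + per-channel slow
    # noise + per-channel white measurement noise
    cp = config.coupling
    sigma = max(cp.drive_tau_s * rate, 1.0)

    def _slow(x: np.ndarray) -> np.ndarray:
        y = gaussian_filter1d(x, sigma=sigma)
        sd = y.std()
        return y / sd if sd > 0 else y

    drive = _slow(rng.standard_normal(n))
    sd_vec = np.where(move_mask, cp.shared_sd_movement, cp.shared_sd_stationary)

    bleach = (1 - config.bleach.amplitude_fraction) + config.bleach.amplitude_fraction * np.exp(
        -times / config.bleach.tau_s
    )

    traces: dict[tuple[str, str], np.ndarray] = {}
    for key, shape in shapes.items():
        floor = (
            sd_vec * drive
            + cp.noise_sd * _slow(rng.standard_normal(n))
            + cp.white_sd * rng.standard_normal(n)
        )
        var_shape = float(np.var(shape))
        if var_shape >= 0.995:
            raise ConfigurationError(
                "event amplitudes/density too high: z-unit shape variance "
                f"{var_shape:.2f} leaves no room for the noise floor"
            )
        var_floor = float(np.var(floor))
        gain = np.sqrt(var_floor / (1.0 - var_shape)) if var_floor > 0 else 1.0
        f0 = config.f0 * (0.8 + 0.4 * rng.random())
        traces[key] = f0 * (1.0 + gain * shape + floor) * bleach

    markers = {"session_start": 0.0, "session_end": config.duration_s}
    if stimuli is not None:
        for i, t in enumerate(stimuli.onsets):
            markers[f"shock_{i}"] = float(t)

    def _corr(shared: float) -> float:
        denom = shared**2 + cp.noise_sd**2
        return shared**2 / denom if denom > 0 else 0.0

    truth = GroundTruth(
        events=events,
        states=segments.segments,
        movement_onsets=btruth.movement_onsets,
        coupling={
            "stationary": _corr(cp.shared_sd_stationary),
            "movement": _corr(cp.shared_sd_movement),
        },
        trajectory_cm=btruth.trajectory_cm,
        bouts=btruth.bouts,
    )
    meta = {
        "astro": ChannelMeta(470, "astro"),
        "neuron": ChannelMeta(560, "neuron"),
        "gfp": ChannelMeta(470, "control"),
        "mcherry": ChannelMeta(560, "control"),
    }
    recording = RawRecording(
        traces=traces,
        rate_hz=rate,
        event_markers=markers,
        channel_meta={k: meta[k] for k in {ch for _, ch in traces}},
    )
    return recording, truth


def simulate_session(
    config: SimulationConfig, with_stimuli: bool = False
) -> tuple[RawRecording, GroundTruth, MovementTrace, StateSegments, StimulusTrain | None]:
    """Convenience wrapper: behavior + (optional) stimulus train + recording."""
    behavior = make_behavior(config)
    stimuli = make_stimulus_train(config) if with_stimuli else None
    recording, truth = simulate_recording(config, behavior, stimuli)
    return recording, truth, behavior[0], behavior[1], stimuli


def render_fiber_bundle_frames(
    recording: RawRecording,
    layout: dict[tuple[str, str], tuple[int, int, int]] | None = None,
    background: int = 50,
) -> RoiImageStack:
    """Render traces as a grayscale fiber-bundle image stack.

    ``layout`` maps (region, channel) -> (row, col, radius) in pixels; by
    default channels are laid out on a grid of non-overlapping discs.  Each
    frame's mean intensity inside a disc equals the corresponding Fraw sample
    up to rounding (<= 0.5 gray level).
    """
    keys = list(recording.traces)
    if layout is None:
        regions = sorted({r for r, _ in keys})
        channels = sorted({c for _, c in keys})
        layout = {
            (r, c): (20 + 40 * regions.index(r), 20 + 40 * channels.index(c), 8)
            for (r, c) in keys
        }
    if not layout:
        raise ValueError("empty fiber-bundle layout")
    pts = list(layout.values())
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            (r1, c1, rad1), (r2, c2, rad2) = pts[i], pts[j]
            if np.hypot(r1 - r2, c1 - c2) <= rad1 + rad2:
                raise ValueError("fiber-bundle layout discs overlap")
    h = max(r + rad for r, _, rad in layout.values()) + 10
    w = max(c + rad for _, c, rad in layout.values()) + 10
    n = recording.n_samples
    frames = np.full((n, h, w), background, dtype=np.uint16)
    masks: dict[tuple[str, str], np.ndarray] = {}
    for key, (r, c, rad) in layout.items():
        rr, cc = draw_disk((r, c), rad, shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        masks[key] = mask
        vals = np.clip(np.round(recording.traces[key]), 0, 65535).astype(np.uint16)
        frames[:, rr, cc] = vals[:, None]
    return RoiImageStack(frames=frames, roi_masks=masks, timestamps=recording.times)


def render_behavior_video(
    movement: MovementTrace,
    shape: tuple[int, int] = (180, 320),
    background: int = 240,
    body: int = 20,
    axes_px: tuple[float, float] = (10.0, 6.0),
) -> VideoStack:
    """Dark elliptical mouse on a bright arena at the ground-truth centroid."""
    cent = movement.centroid_px
    a, b = axes_px
    if (
        np.nanmin(cent[:, 0]) < a
        or np.nanmin(cent[:, 1]) < b
        or np.nanmax(cent[:, 0]) > shape[0] - a
        or np.nanmax(cent[:, 1]) > shape[1] - b
    ):
        raise ValueError("trajectory leaves the arena bounds at this resolution")
    n = cent.shape[0]
    frames = np.full((n, *shape), background, dtype=np.uint8)
    for i in range(n):
        rr, cc = draw_ellipse(cent[i, 0], cent[i, 1], a, b, shape=shape)
        frames[i, rr, cc] = body
    return VideoStack(
        frames=frames,
        rate_hz=movement.rate_hz,
        cm_per_px=movement.cm_per_px,
    )
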