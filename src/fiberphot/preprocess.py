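"""Raw fluorescence to normalized traces.

Converts fiber-bundle image stacks or raw traces (Fraw) into baseline-corrected
dF/F and z-scored traces, per brain region and spectral channel:

    dF/F = (Fraw - Fbaseline) / Fbaseline
    z    = (dF/F - mean(dF/F)) / std(dF/F)

Fbaseline is a moving-window average of Fraw (centered by default, trailing
optionally); the z-score uses the population standard deviation over a
configurable normalization span (whole recording by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiImageStack",
    "RawRecording",
    "ProcessedTrace",
    "extract_roi_traces",
    "moving_baseline",
    "compute_dff",
    "compute_zscore",
    "process_trace",
    "process_recording",
    "synchronize",
]


@dataclass
class RoiImageStack:
    """Grayscale fiber-bundle frames plus named ROI masks.

    ``frames`` is (T, H, W); ``roi_masks`` maps ``(region, channel)`` to a
    boolean (H, W) mask.  Masks must be non-empty, in-bounds and pairwise
    disjoint.
    """

    frames: np.ndarray
    roi_masks: dict[tuple[str, str], np.ndarray]
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("timestamps length must match frame count")
        claimed = np.zeros(self.frames.shape[1:], dtype=bool)
        for key, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.frames.shape[1:]:
                raise ValueError(f"mask {key} does not match frame shape")
            if (claimed & mask).any():
                raise ValueError(f"mask {key} overlaps another ROI")
            claimed |= mask
            self.roi_masks[key] = mask


@dataclass
class ChannelMeta:
    excitation_nm: int
    cell_type: str  # "astro" | "neuron" | "control"


@dataclass
class RawRecording:
    """Per-(region, channel) raw fluorescence vectors with shared time base."""

    traces: dict[tuple[str, str], np.ndarray]
    rate_hz: float
    event_markers: dict[str, np.ndarray] = field(default_factory=dict)
    channel_meta: dict[str, ChannelMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_s, region, channel, value)."""
        rows = []
        for (region, channel), trace in self.traces.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": self.times,
                        "region": region,
                        "channel": channel,
                        "value": trace,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class ProcessedTrace:
    baseline: np.ndarray
    dff: np.ndarray
    z: np.ndarray
    window_s: float
    span: tuple[int, int] | None = None  # z normalization span (samples)


def extract_roi_traces(stack: RoiImageStack) -> RawRecording:
    """Average pixel intensity inside each ROI mask, per frame."""
    traces: dict[tuple[str, str], np.ndarray] = {}
    frames = stack.frames.reshape(stack.frames.shape[0], -1).astype(float)
    for key, mask in stack.roi_masks.items():
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError(f"empty ROI mask for {key}")
        traces[key] = frames[:, idx].mean(axis=1)
    ts = np.asarray(stack.timestamps, dtype=float)
    if len(ts) > 1:
        rate = 1.0 / np.median(np.diff(ts))
    else:
        rate = 1.0
    return RawRecording(traces=traces, rate_hz=float(rate))


def moving_baseline(
    trace: np.ndarray, rate_hz: float, window_s: float, mode: str = "centered"
) -> np.ndarray:
    """Moving-window mean of Fraw with edge windows truncated to the data.

    ``mode`` is "centered" (default) or "trailing".
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    w = int(round(window_s * rate_hz))
    if w < 2:
        raise ValueError("baseline window must span at least 2 samples")
    cs = np.concatenate([[0.0], np.cumsum(trace)])
    idx = np.arange(n)
    if mode == "centered":
        lo = np.maximum(idx - (w - 1) // 2, 0)
        hi = np.minimum(idx + w // 2, n - 1)
    elif mode == "trailing":
        lo = np.maximum(idx - (w - 1), 0)
        hi = idx
    else:
        raise ValueError(f"unknown baseline mode: {mode!r}")
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def compute_dff(trace: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if (baseline <= 0).any():
        raise ValueError("baseline must be strictly positive (invalid fluorescence)")
    return (trace - baseline) / baseline


def compute_zscore(dff: np.ndarray, span: tuple[int, int] | None = None) -> np.ndarray:
    """Standardize dF/F with mean and population sd over ``span`` (samples).

    Defaults to the full recording.  Constant input raises (zero sd).
    """
    dff = np.asarray(dff, dtype=float)
    seg = dff if span is None else dff[span[0] : span[1]]
    mu = seg.mean()
    sd = seg.std()  # population sd
    if sd == 0:
        raise ValueError("dF/F is constant over the normalization span; z undefined")
    return (dff - mu) / sd


def process_trace(
    trace: np.ndarray,
    rate_hz: float,
    window_s: float = 30.0,
    span: tuple[int, int] | None = None,
    baseline_mode: str = "centered",
) -> ProcessedTrace:
    baseline = moving_baseline(trace, rate_hz, window_s, mode=baseline_mode)
    dff = compute_dff(trace, baseline)
    z = compute_zscore(dff, span=span)
    return ProcessedTrace(baseline=baseline, dff=dff, z=z, window_s=window_s, span=span)


def process_recording(
    recording: RawRecording,
    window_s: float = 30.0,
    span: tuple[int, int] | None = None,
    baseline_mode: str = "centered",
) -> dict[tuple[str, str], ProcessedTrace]:
    return {
        key: process_trace(tr, recording.rate_hz, window_s, span, baseline_mode)
        for key, tr in recording.traces.items()
    }


def synchronize(
    target_markers: dict[str, float],
    source_markers: dict[str, float],
    source_times: np.ndarray,
) -> np.ndarray:
    """Map a source stream's timestamps onto the photometry clock.

    Both marker dicts map label -> time on the respective clock.  Times between
    shared markers are mapped piecewise-linearly; beyond the outermost markers
    the nearest segment is extrapolated.  The residual at each shared marker is
    exactly zero.
    """
    shared = sorted(set(target_markers) & set(source_markers), key=source_markers.get)
    if not shared:
        raise ValueError("no shared event markers between streams")
    src = np.array([source_markers[k] for k in shared], dtype=float)
    tgt = np.array([target_markers[k] for k in shared], dtype=float)
    source_times = np.asarray(source_times, dtype=float)
    if len(shared) == 1:
        return source_times + (tgt[0] - src[0])
    out = np.interp(source_times, src, tgt)
    # linear extrapolation outside the marker range
    lo = source_times < src[0]
    hi = source_times > src[-1]
    s0 = (tgt[1] - tgt[0]) / (src[1] - src[0])
    s1 = (tgt[-1] - tgt[-2]) / (src[-1] - src[-2])
    out[lo] = tgt[0] + s0 * (source_times[lo] - src[0])
    out[hi] = tgt[-1] + s1 * (source_times[hi] - src[-1])
    return out
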