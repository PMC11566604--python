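"""Movement quantification from open-field video.

Frames are binarized to delineate the mouse (dark animal on a white chamber
by default), the largest connected component is taken as the body, and
movement is quantified relative to body size: the per-frame movement index is
the symmetric difference between consecutive body masks divided by the mean
body area of the two frames.  Thresholding the index partitions the session
into stationary and movement states and yields movement-onset times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VideoStack",
    "MovementTrace",
    "StateSegments",
    "StimulusTrain",
    "binarize_frames",
    "delineate_mouse",
    "movement_index",
    "segment_states",
    "trajectory",
    "analyze_video",
]

INDEX_CAP = 2.0  # degenerate frame-pair policy: full-body appearance caps here


@dataclass
class VideoStack:
    frames: np.ndarray  # T x H x W grayscale
    rate_hz: float = 30.0
    arena_cm: tuple[float, float] = (40.0, 40.0)
    cm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.cm_per_px is None:
            self.cm_per_px = self.arena_cm[0] / self.frames.shape[2]
        if self.cm_per_px <= 0:
            raise ValueError("arena scale must be positive")


@dataclass
class MovementTrace:
    index: np.ndarray
    centroid_px: np.ndarray  # T x 2, (row, col); NaN where no mouse detected
    body_area_px: np.ndarray
    rate_hz: float
    cm_per_px: float = 1.0
    invalid: np.ndarray | None = None


@dataclass
class StateSegments:
    """Non-overlapping (start_s, end_s, label) segments covering the session."""

    segments: list[tuple[float, float, str]]
    movement_onsets: np.ndarray

    def state_mask(self, n: int, rate_hz: float, state: str) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for s, e, lab in self.segments:
            if lab == state:
                mask[int(round(s * rate_hz)) : int(round(e * rate_hz))] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["start_s", "end_s", "label"])


@dataclass
class StimulusTrain:
    onsets: np.ndarray
    pulse_s: float
    amplitude_mA: float = 0.6
    label: str = "footshock"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.pulse_s <= 0:
            raise ValueError("pulse_s must be positive")
        if len(self.onsets) and (np.diff(self.onsets) <= 0).any():
            raise ValueError("stimulus onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)


def binarize_frames(
    video: VideoStack,
    method: str = "otsu",
    threshold: float | None = None,
    dark_on_light: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame boolean body masks plus a per-frame invalid flag.

    ``method`` is "otsu" (histogram split) or "fixed" (requires ``threshold``).
    Frames that binarize to all-foreground or all-background are flagged
    invalid, not fatal.
    """
    frames = video.frames
    if frames.shape[0] == 0:
        raise ValueError("empty video")
    masks = np.zeros(frames.shape, dtype=bool)
    invalid = np.zeros(frames.shape[0], dtype=bool)
    for i, frame in enumerate(frames):
        if method == "fixed":
            if threshold is None:
                raise ValueError("fixed method requires a threshold")
            th = threshold
        elif method == "otsu":
            if np.ptp(frame) == 0:
                invalid[i] = True
                continue
            th = threshold_otsu(frame)
        else:
            raise ValueError(f"unknown binarization method: {method!r}")
        # inclusive on the dark side: Otsu returns the lower mode on a
        # two-valued frame
        mask = frame <= th if dark_on_light else frame > th
        if mask.all() or not mask.any():
            invalid[i] = True
        else:
            masks[i] = mask
    return masks, invalid


def delineate_mouse(
    masks: np.ndarray,
    invalid: np.ndarray | None = None,
    rate_hz: float = 30.0,
    max_gap_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Largest connected component per frame -> (centroids, areas, cleaned masks).

    Invalid frames are interpolated from neighbors; a gap of invalid frames
    longer than ``max_gap_s`` raises.
    """
    n = masks.shape[0]
    invalid = np.zeros(n, dtype=bool) if invalid is None else invalid.copy()
    centroids = np.full((n, 2), np.nan)
    areas = np.zeros(n)
    body = np.zeros_like(masks)
    for i in range(n):
        if invalid[i]:
            continue
        lab, nlab = ndimage.label(masks[i])
        if nlab == 0:
            invalid[i] = True
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        k = int(np.argmax(sizes)) + 1
        comp = lab == k
        body[i] = comp
        areas[i] = sizes[k - 1]
        centroids[i] = ndimage.center_of_mass(comp)
    if invalid.all():
        raise ValueError("no valid frame in the video")
    # gap check + interpolation of centroid/area through invalid frames
    bad = np.flatnonzero(invalid)
    if bad.size:
        runs = np.split(bad, np.flatnonzero(np.diff(bad) > 1) + 1)
        for run in runs:
            if len(run) > max_gap_s * rate_hz:
                raise ValueError(
                    f"gap of {len(run)} invalid frames exceeds {max_gap_s} s"
                )
        good = np.flatnonzero(~invalid)
        for d in range(2):
            centroids[bad, d] = np.interp(bad, good, centroids[good, d])
        areas[bad] = np.interp(bad, good, areas[good])
    return centroids, areas, body


def movement_index(
    masks: np.ndarray, body_area: np.ndarray, cap: float = INDEX_CAP
) -> np.ndarray:
    """Symmetric-difference pixel count over mean body area, per frame pair.

    index[0] = 0; a zero mean area (degenerate pair) yields the cap value.
    """
    n = masks.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    idx = np.zeros(n)
    flat = masks.reshape(n, -1)
    diff = (flat[1:] ^ flat[:-1]).sum(axis=1)
    mean_area = 0.5 * (body_area[1:] + body_area[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = diff / mean_area
    vals = np.where(mean_area > 0, vals, cap)
    idx[1:] = np.minimum(vals, cap)
    return idx


def segment_states(
    index: np.ndarray,
    rate_hz: float,
    theta_move: float = 0.05,
    min_move_s: float = 1.0,
    min_quiescence_s: float = 3.0,
    bridge_s: float = 0.5,
) -> StateSegments:
    """Threshold the movement index into stationary/movement segments.

    A movement segment is a sustained (>= min_move_s) exceedance of
    ``theta_move``; sub-``bridge_s`` gaps are bridged.  Movement onsets are
    movement-segment starts preceded by at least ``min_quiescence_s`` of
    stationary state.
    """
    index = np.asarray(index, dtype=float)
    n = len(index)
    above = index > theta_move

    # bridge short gaps
    gap = int(round(bridge_s * rate_hz))
    if gap > 0:
        below = np.flatnonzero(~above)
        if below.size:
            runs = np.split(below, np.flatnonzero(np.diff(below) > 1) + 1)
            for run in runs:
                if len(run) < gap and run[0] > 0 and run[-1] < n - 1:
                    above[run] = True

    min_run = max(int(round(min_move_s * rate_hz)), 1)
    move = np.zeros(n, dtype=bool)
    on = np.flatnonzero(above)
    if on.size:
        runs = np.split(on, np.flatnonzero(np.diff(on) > 1) + 1)
        for run in runs:
            if len(run) >= min_run:
                move[run] = True

    segments: list[tuple[float, float, str]] = []
    onsets = []
    quiesce = int(round(min_quiescence_s * rate_hz))
    i = 0
    while i < n:
        j = i
        while j < n and move[j] == move[i]:
            j += 1
        label = "movement" if move[i] else "stationary"
        segments.append((i / rate_hz, j / rate_hz, label))
        if move[i] and i >= quiesce and not move[i - quiesce : i].any():
            onsets.append(i / rate_hz)
        i = j
    return StateSegments(segments=segments, movement_onsets=np.array(onsets))


def trajectory(
    movement: MovementTrace, smooth_s: float = 0.0
) -> pd.DataFrame:
    """Centroid path in cm with per-frame speed (cm/s)."""
    if movement.cm_per_px is None or movement.cm_per_px <= 0:
        raise ValueError("missing arena scale (cm_per_px)")
    c = movement.centroid_px * movement.cm_per_px
    if smooth_s > 0:
        w = max(int(round(smooth_s * movement.rate_hz)), 1)
        kernel = np.ones(w) / w
        for d in range(2):
            pad = np.pad(c[:, d], (w // 2, w - 1 - w // 2), mode="edge")
            c[:, d] = np.convolve(pad, kernel, mode="valid")
    disp = np.zeros(len(c))
    disp[1:] = np.linalg.norm(np.diff(c, axis=0), axis=1)
    speed = disp * movement.rate_hz
    t = np.arange(len(c)) / movement.rate_hz
    return pd.DataFrame(
        {"time_s": t, "y_cm": c[:, 0], "x_cm": c[:, 1], "speed_cm_s": speed}
    )


def analyze_video(
    video: VideoStack,
    method: str = "otsu",
    threshold: float | None = None,
    dark_on_light: bool = True,
) -> MovementTrace:
    """Full video pipeline: binarize -> delineate -> movement index."""
    masks, invalid = binarize_frames(video, method, threshold, dark_on_light)
    centroids, areas, body = delineate_mouse(masks, invalid, video.rate_hz)
    idx = movement_index(body, areas)
    idx[np.flatnonzero(invalid)] = 0.0  # interpolated frames carry no motion evidence
    return MovementTrace(
        index=idx,
        centroid_px=centroids,
        body_area_px=areas,
        rate_hz=video.rate_hz,
        cm_per_px=video.cm_per_px,
        invalid=invalid,
    )
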