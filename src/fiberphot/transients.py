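"""Ca2+ transient detection and event-triggered kinetics.

Detection runs on z-scored traces with a two-threshold scheme: a candidate
event is a run of samples at or above ``theta_on`` sustained for at least
``min_dur_s``; its onset is pushed back to the preceding upward crossing of
``theta_off`` and its end forward to the next downward crossing of
``theta_off``.  Events closer than ``merge_gap_s`` are merged.

Event-triggered analysis aligns z segments to behavioral triggers (movement
onsets or footshocks) and measures per-trial kinetics:

* latency: first sustained crossing of ``theta_resp`` after the trigger;
* peak time: argmax of the (lightly smoothed) response;
* valley time (neuronal trace): argmin after the peak, capturing the
  suppression that follows the astrocytic peak;
* response duration: from the latency crossing until the trace finally
  settles back inside the +/- ``theta_off`` band (the post-transient
  suppression counts as part of the response).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import summarize_mean_sem

__all__ = [
    "Transient",
    "DetectionParams",
    "ResponseParams",
    "EventTriggeredEnsemble",
    "ResponseMetrics",
    "detect_transients",
    "transient_stats",
    "build_ensemble",
    "response_metrics",
    "paired_differences",
]


@dataclass
class Transient:
    onset_s: float
    peak_s: float
    end_s: float
    peak_z: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass
class DetectionParams:
    theta_on: float = 2.0
    theta_off: float = 0.5
    min_dur_s: float = 1.0
    merge_gap_s: float = 0.5


def detect_transients(
    z: np.ndarray,
    rate_hz: float,
    params: DetectionParams | None = None,
    smooth_s: float = 0.0,
) -> list[Transient]:
    """Threshold-crossing transient detection on a z-scored trace.

    ``smooth_s`` optionally applies a centered moving average before
    thresholding (useful for slow, low-amplitude astrocytic events whose
    shallow decay makes raw threshold crossings noisy); peak height is still
    read from the raw trace.
    """
    params = params or DetectionParams()
    z = np.asarray(z, dtype=float)
    if abs(z.mean()) > 0.5 or not (0.5 <= z.std() <= 2.0):
        warnings.warn(
            "input does not look z-normalized (mean %.2f, sd %.2f)"
            % (z.mean(), z.std()),
            stacklevel=2,
        )
    n = len(z)
    min_run = max(int(round(params.min_dur_s * rate_hz)), 1)

    z_det = _smooth(z, rate_hz, smooth_s) if smooth_s > 0 else z
    above_on = z_det >= params.theta_on
    above_off = z_det >= params.theta_off

    # candidate runs of theta_on exceedance lasting >= min_dur
    events: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above_on[i]:
            j = i
            while j < n and above_on[j]:
                j += 1
            if j - i >= min_run:
                # extend to the enclosing theta_off exceedance run
                s = i
                while s > 0 and above_off[s - 1]:
                    s -= 1
                e = j
                while e < n and above_off[e]:
                    e += 1
                events.append((s, e))
            i = j
        else:
            i += 1

    # merge events separated by short gaps
    gap = int(round(params.merge_gap_s * rate_hz))
    merged: list[list[int]] = []
    for s, e in events:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        seg = z[s:e]
        p = s + int(np.argmax(seg))  # earliest sample on ties
        out.append(
            Transient(
                onset_s=s / rate_hz,
                peak_s=p / rate_hz,
                end_s=e / rate_hz,
                peak_z=float(z[p]),
            )
        )
    return out


def transient_stats(
    events: list[Transient], duration_s: float, edge_s: float = 20.0
) -> dict:
    """Event frequency (events/min), durations, and the fraction exceeding
    ``edge_s`` (20 s separates the short neuronal from the long astrocytic
    duration mode)."""
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    durations = np.array([ev.duration_s for ev in events])
    frequency = len(events) / (duration_s / 60.0)
    if len(durations):
        edges = np.arange(0.0, max(durations.max(), edge_s) + edge_s, edge_s)
        counts, _ = np.histogram(durations, bins=edges)
        frac_long = float((durations > edge_s).mean())
    else:
        edges, counts, frac_long = np.array([]), np.array([]), float("nan")
    return {
        "frequency_per_min": frequency,
        "durations_s": durations,
        "fraction_gt_edge": frac_long,
        "hist_edges": edges,
        "hist_counts": counts,
    }


@dataclass
class EventTriggeredEnsemble:
    matrix: np.ndarray  # trials x time, z units
    pre_s: float
    post_s: float
    rate_hz: float
    event_times: np.ndarray
    dropped: int = 0

    @property
    def times(self) -> np.ndarray:
        n = self.matrix.shape[1]
        return np.arange(n) / self.rate_hz - self.pre_s

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.matrix.shape[0]
        if n < 2:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(n)


def build_ensemble(
    z: np.ndarray,
    event_times: np.ndarray,
    pre_s: float,
    post_s: float,
    rate_hz: float,
    rebaseline: bool = False,
) -> EventTriggeredEnsemble:
    """Stack z segments [event - pre_s, event + post_s) by trial.

    Trials whose window is not fully inside the recording are dropped.
    ``rebaseline`` subtracts the pre-window mean from each trial.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    pre = int(round(pre_s * rate_hz))
    post = int(round(post_s * rate_hz))
    rows, used, dropped = [], [], 0
    for t in np.asarray(event_times, dtype=float):
        c = int(round(t * rate_hz))
        if c - pre < 0 or c + post > n:
            dropped += 1
            continue
        seg = z[c - pre : c + post].copy()
        if rebaseline and pre > 0:
            seg -= seg[:pre].mean()
        rows.append(seg)
        used.append(t)
    if not rows:
        raise ValueError("no usable trials: every event window falls outside the recording")
    return EventTriggeredEnsemble(
        matrix=np.vstack(rows),
        pre_s=pre_s,
        post_s=post_s,
        rate_hz=rate_hz,
        event_times=np.array(used),
        dropped=dropped,
    )


@dataclass
class ResponseParams:
    theta_resp: float = 2.0
    theta_off: float = 0.5
    sustain_s: float = 0.33
    latency_window_s: float = 10.0
    peak_window_s: float = 15.0  # 15 s resolves the slow astro peak; use 5 s for neurons
    valley_window_s: float = 15.0
    theta_cont: float = 1.5  # continuation threshold for the settling scan
    smooth_s: float = 0.33
    # broad plateau-like peaks (slow astro responses) benefit from stronger
    # smoothing for the argmax alone; None falls back to smooth_s
    peak_smooth_s: float | None = None


def _smooth(x: np.ndarray, rate_hz: float, smooth_s: float) -> np.ndarray:
    w = max(int(round(smooth_s * rate_hz)), 1)
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _sustained_crossing(
    z: np.ndarray, start: int, stop: int, theta: float, sustain: int
) -> int | None:
    above = z >= theta
    run = 0
    first = None
    for i in range(start, min(stop, len(z))):
        if above[i]:
            if run == 0:
                first = i
            run += 1
            if run >= sustain:
                return first
        else:
            run = 0
            first = None
    return None


def _settle_end(
    z_s: np.ndarray, start: int, stop: int, theta_off: float, theta_cont: float
) -> int:
    """Index where the response finally settles inside the +/- theta_off band.

    The last substantive excursion is the last sample with |z| >= theta_cont
    (a continuation threshold well above the noise floor); the end is the
    first sample at or after it whose |z| drops below theta_off.  This is
    robust to noise flicker around theta_off on the slow decay tail.
    """
    stop = min(stop, len(z_s))
    seg = np.abs(z_s[start:stop])
    strong = np.flatnonzero(seg >= theta_cont)
    t_last = start + (int(strong[-1]) if strong.size else 0)
    below = np.flatnonzero(np.abs(z_s[t_last:stop]) < theta_off)
    return t_last + int(below[0]) if below.size else stop - 1


@dataclass
class ResponseMetrics:
    """Per-trial event-aligned kinetics for one cell type."""

    latency_s: np.ndarray
    peak_time_s: np.ndarray
    peak_z: np.ndarray
    duration_s: np.ndarray
    valley_time_s: np.ndarray | None
    responders: np.ndarray  # boolean over input trials
    cell_type: str = ""

    def summary(self) -> dict:
        out = {}
        for name in ("latency_s", "peak_time_s", "peak_z", "duration_s"):
            vals = getattr(self, name)
            if len(vals):
                m, sem, n = summarize_mean_sem(vals)
                out[name] = {"mean": m, "sem": sem, "n": n}
        if self.valley_time_s is not None and len(self.valley_time_s):
            m, sem, n = summarize_mean_sem(self.valley_time_s)
            out["valley_time_s"] = {"mean": m, "sem": sem, "n": n}
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {
            "latency_s": self.latency_s,
            "peak_time_s": self.peak_time_s,
            "peak_z": self.peak_z,
            "duration_s": self.duration_s,
        }
        if self.valley_time_s is not None:
            data["valley_time_s"] = self.valley_time_s
        df = pd.DataFrame(data)
        df.insert(0, "cell_type", self.cell_type)
        return df


def response_metrics(
    ensemble: EventTriggeredEnsemble,
    params: ResponseParams | None = None,
    with_valley: bool = False,
    cell_type: str = "",
) -> ResponseMetrics:
    """Measure per-trial latency, peak, duration (and valley) on an ensemble.

    Trials with no sustained ``theta_resp`` crossing inside the latency window
    are non-responders and excluded; if every trial is a non-responder an
    error is raised.
    """
    params = params or ResponseParams()
    rate = ensemble.rate_hz
    pre = int(round(ensemble.pre_s * rate))
    sustain = max(int(round(params.sustain_s * rate)), 1)
    lat_stop = pre + int(round(params.latency_window_s * rate))
    peak_stop = pre + int(round(params.peak_window_s * rate))

    lat, pk_t, pk_z, dur, val_t, resp = [], [], [], [], [], []
    peak_smooth = params.peak_smooth_s if params.peak_smooth_s is not None else params.smooth_s
    for row in ensemble.matrix:
        row_s = _smooth(row, rate, params.smooth_s)
        row_p = row_s if peak_smooth == params.smooth_s else _smooth(row, rate, peak_smooth)
        onset = _sustained_crossing(row_s, pre + 1, lat_stop, params.theta_resp, sustain)
        if onset is None:
            resp.append(False)
            continue
        resp.append(True)
        lat.append((onset - pre) / rate)

        p = pre + 1 + int(np.argmax(row_p[pre + 1 : peak_stop]))
        pk_t.append((p - pre) / rate)
        pk_z.append(float(row[p]))

        end = _settle_end(row_s, onset, len(row_s), params.theta_off, params.theta_cont)
        dur.append((end - onset) / rate)

        if with_valley:
            v_stop = min(p + 1 + int(round(params.valley_window_s * rate)), len(row_s))
            v = p + 1 + int(np.argmin(row_s[p + 1 : v_stop]))
            val_t.append((v - pre) / rate)

    if not lat:
        raise ValueError("all trials are non-responders")
    return ResponseMetrics(
        latency_s=np.array(lat),
        peak_time_s=np.array(pk_t),
        peak_z=np.array(pk_z),
        duration_s=np.array(dur),
        valley_time_s=np.array(val_t) if with_valley else None,
        responders=np.array(resp, dtype=bool),
        cell_type=cell_type,
    )


def paired_differences(astro: ResponseMetrics, neuron: ResponseMetrics) -> dict:
    """Per-trial astro - neuron timing differences, on jointly responding trials.

    Positive values mean the astrocytic event lags the neuronal one.  The
    astro-peak-to-neuron-valley interval is valley_time(neuron) -
    peak_time(astro): positive when the astro peak precedes the valley.
    """
    if len(astro.responders) != len(neuron.responders):
        raise ValueError("metrics are not from the same trials (unpaired counts)")
    both = astro.responders & neuron.responders
    a_idx = np.cumsum(astro.responders) - 1
    n_idx = np.cumsum(neuron.responders) - 1
    ai = a_idx[both]
    ni = n_idx[both]
    out = {
        "latency_diff_s": astro.latency_s[ai] - neuron.latency_s[ni],
        "peak_diff_s": astro.peak_time_s[ai] - neuron.peak_time_s[ni],
    }
    if neuron.valley_time_s is not None:
        out["astro_peak_to_neuron_valley_s"] = (
            neuron.valley_time_s[ni] - astro.peak_time_s[ai]
        )
    out["summary"] = {
        k: dict(zip(("mean", "sem", "n"), summarize_mean_sem(v)))
        for k, v in out.items()
        if isinstance(v, np.ndarray) and len(v)
    }
    return out
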