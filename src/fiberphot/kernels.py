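"""Calcium-transient waveform kernels.

A population Ca2+ transient is modelled as a difference of exponentials

    h(t) = (exp(-t / tau_d) - exp(-t / tau_r)) / h_max,   t >= 0,

with rise constant ``tau_r`` < decay constant ``tau_d``, normalized to unit
peak.  The analytic peak time is

    t* = tau_r * tau_d / (tau_d - tau_r) * log(tau_d / tau_r).

Rather than asking users for time constants, kernels are specified by the
kinetic quantities a photometry analysis actually measures relative to the
triggering event: response latency (time of the first crossing of a detection
threshold), peak time, and response duration.  ``solve_taus`` inverts the
waveform family numerically so these observables are matched by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "Kinetics",
    "double_exp",
    "analytic_peak_time",
    "crossing_times",
    "solve_taus",
    "transient_kernel",
]

# Detection thresholds (z units) used to anchor latency / duration; these match
# the transient-detection defaults.
THETA_RESP = 2.0
THETA_OFF = 0.5


@dataclass
class Kinetics:
    """Kinetics of an event-evoked transient, relative to the trigger.

    Parameters
    ----------
    onset_latency_s : float
        Time from the trigger to the first sustained crossing of the response
        threshold (``THETA_RESP`` z units).
    peak_time_s : float
        Time from the trigger to the waveform maximum.
    duration_s : float
        Total response duration: from the latency crossing until the trace
        finally settles inside the +/- ``THETA_OFF`` band.
    amplitude_z : float
        Peak amplitude in z-score units.
    """

    onset_latency_s: float
    peak_time_s: float
    duration_s: float
    amplitude_z: float

    def __post_init__(self) -> None:
        if self.peak_time_s <= self.onset_latency_s:
            raise ValueError("peak_time_s must exceed onset_latency_s")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.amplitude_z < 0:
            raise ValueError("amplitude_z must be non-negative")


def double_exp(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials, zero for t < 0."""
    if tau_r <= 0 or tau_d <= 0:
        raise ValueError("time constants must be positive")
    if tau_r >= tau_d:
        raise ValueError("rise tau must be smaller than decay tau")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    raw = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
    t_star = analytic_peak_time(tau_r, tau_d)
    h_max = np.exp(-t_star / tau_d) - np.exp(-t_star / tau_r)
    out[pos] = raw / h_max
    return out


def analytic_peak_time(tau_r: float, tau_d: float) -> float:
    return tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)


def _scalar(t, tau_r, tau_d):
    return float(double_exp(np.atleast_1d(t), tau_r, tau_d)[0])


def crossing_times(
    tau_r: float, tau_d: float, amplitude: float, theta_up: float, theta_down: float
) -> tuple[float, float]:
    """Rising crossing of ``theta_up`` and final falling crossing of ``theta_down``.

    Times are relative to the kernel's own t=0 (where the waveform leaves zero),
    for a kernel scaled to peak ``amplitude``.
    """
    if amplitude <= theta_up:
        raise ValueError("amplitude must exceed the onset threshold")
    t_star = analytic_peak_time(tau_r, tau_d)
    up = brentq(lambda t: amplitude * _scalar(t, tau_r, tau_d) - theta_up, 1e-9, t_star)
    t_hi = t_star + tau_d * (np.log(amplitude / theta_down) + 5.0)
    down = brentq(
        lambda t: amplitude * _scalar(t, tau_r, tau_d) - theta_down, t_star, t_hi
    )
    return float(up), float(down)


def solve_taus(
    rise_to_peak_s: float,
    fall_s: float,
    amplitude: float,
    theta_up: float = THETA_RESP,
    theta_down: float = THETA_OFF,
) -> tuple[float, float]:
    """Solve (tau_r, tau_d) so the scaled kernel rises from its ``theta_up``
    crossing to its peak in ``rise_to_peak_s`` and falls back to ``theta_down``
    after ``fall_s`` (both measured from the ``theta_up`` crossing).

    Raises
    ------
    ValueError
        If no difference-of-exponentials realises the requested shape (the
        family cannot make the rise slower than roughly a fifth of the fall).
    """
    if rise_to_peak_s <= 0 or fall_s <= rise_to_peak_s:
        raise ValueError("need 0 < rise_to_peak_s < fall_s")

    def residuals(logp):
        tau_r = np.exp(logp[0])
        tau_d = tau_r + np.exp(logp[1])
        try:
            up, down = crossing_times(tau_r, tau_d, amplitude, theta_up, theta_down)
        except ValueError:
            return [1e3, 1e3]
        t_star = analytic_peak_time(tau_r, tau_d)
        return [(t_star - up) - rise_to_peak_s, (down - up) - fall_s]

    tau_d0 = max((fall_s - rise_to_peak_s) / max(np.log(amplitude / theta_down), 0.5), 0.05)
    tau_r0 = max(rise_to_peak_s / 2.0, 0.02)
    x0 = np.log([tau_r0, max(tau_d0 - tau_r0, 0.01)])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    res = residuals(sol.x)
    if abs(res[0]) > 2e-3 or abs(res[1]) > 2e-3:
        raise ValueError(
            "no difference-of-exponentials kernel matches the requested "
            f"rise_to_peak={rise_to_peak_s:.3g}s / fall={fall_s:.3g}s at "
            f"amplitude {amplitude:.3g}"
        )
    tau_r = float(np.exp(sol.x[0]))
    tau_d = tau_r + float(np.exp(sol.x[1]))
    return tau_r, tau_d


def _min_fall_ratio(u: float, d: float) -> float:
    """Smallest (fall from onset-threshold crossing)/(rise to peak) the family
    supports, reached in the equal-tau limit x*exp(1-x); ``u`` and ``d`` are
    the up/down thresholds as fractions of the peak."""
    g = lambda x, v: x * np.exp(1.0 - x) - v
    x_up = brentq(g, 1e-12, 1.0, args=(u,))
    x_hi = 2.0
    while g(x_hi, d) > 0:
        x_hi *= 2.0
    x_dn = brentq(g, 1.0, x_hi, args=(d,))
    return (x_dn - x_up) / (1.0 - x_up)


@dataclass
class KernelSpec:
    """A solved kernel: taus plus the trigger-relative placement offset."""

    kinetics: Kinetics
    tau_r: float
    tau_d: float
    onset_offset_s: float  # kernel t=0 relative to the trigger
    fall_s: float  # kernel's own above-theta_off extent from the latency crossing


def design_kernel(
    kinetics: Kinetics,
    kernel_fall_s: float | None = None,
    theta_up: float = THETA_RESP,
    theta_down: float = THETA_OFF,
) -> KernelSpec:
    """Solve a kernel whose trigger-relative latency and peak match ``kinetics``.

    ``kernel_fall_s`` overrides the waveform's own above-threshold fall time
    (measured from the latency crossing); by default the configured duration is
    used, i.e. the kernel alone carries the whole response.
    """
    rise = kinetics.peak_time_s - kinetics.onset_latency_s
    fall = kinetics.duration_s if kernel_fall_s is None else kernel_fall_s
    amp = max(kinetics.amplitude_z, theta_up * 1.25)
    # The family's fall/rise ratio is bounded below by its equal-tau limit
    # h(t) ~ (t/tau) e^(1 - t/tau); clamp the fall to the feasible region.
    fall = max(fall, 1.05 * rise * _min_fall_ratio(theta_up / amp, theta_down / amp))
    tau_r, tau_d = solve_taus(rise, fall, amp, theta_up, theta_down)
    up, _ = crossing_times(tau_r, tau_d, amp, theta_up, theta_down)
    return KernelSpec(
        kinetics=kinetics,
        tau_r=tau_r,
        tau_d=tau_d,
        onset_offset_s=kinetics.onset_latency_s - up,
        fall_s=fall,
    )


def transient_kernel(
    kinetics: Kinetics,
    rate_hz: float,
    kernel_fall_s: float | None = None,
) -> np.ndarray:
    """Sampled trigger-aligned waveform.

    Sample ``k`` holds the kernel value ``k / rate_hz`` seconds after the
    trigger, so from the vector's first sample the threshold crossing sits at
    ``onset_latency_s`` and the argmax at ``peak_time_s`` (within one sample).
    Scaled to peak ``amplitude_z``; a zero amplitude yields a zero vector.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    spec = design_kernel(kinetics, kernel_fall_s=kernel_fall_s)
    t_end = spec.onset_offset_s + analytic_peak_time(spec.tau_r, spec.tau_d) + 8 * spec.tau_d
    n = int(np.ceil(t_end * rate_hz)) + 1
    t = np.arange(n) / rate_hz - spec.onset_offset_s
    return kinetics.amplitude_z * double_exp(t, spec.tau_r, spec.tau_d)
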