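"""Aerobic-assessment quantities from a graded exercise test (GXT).

A GXT here starts at 100 W and adds 40 W every 4 min until exhaustion.
From a breath-by-breath recording of such a test this module computes:

* resting averages of VO2 and respiratory frequency over a pre-test window;
* 20-s rolling-average maxima (VO2MAX, RF_MAX) — time-weighted, because
  breath-by-breath data are irregularly sampled;
* the completed-stage fractional interpolation that attributes a power to
  any event time during the test (used for both the peak power output and
  the ventilatory-threshold powers, e.g. a threshold at minute 18 maps to
  220 W + 2/4 × 40 W = 240 W);
* the three per-athlete intensity levels derived from the threshold powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import BreathSeries

__all__ = [
    "GxtResult",
    "resting_averages",
    "rolling_peak",
    "stage_interpolated_power",
    "stage_time_for_power",
    "intensity_levels",
    "analyze_gxt",
]


@dataclass(frozen=True)
class GxtResult:
    """Summary of one graded exercise test."""

    ppo: float
    vo2max: float
    rf_max: float
    vo2r: float
    rf_rest: float
    p_vt1: float
    p_vt2: float

    def __post_init__(self) -> None:
        if not self.vo2r < self.vo2max:
            raise ValueError("vo2r must be below vo2max")
        if not self.p_vt1 < self.p_vt2 <= self.ppo:
            raise ValueError("require p_vt1 < p_vt2 <= ppo")


def resting_averages(series: BreathSeries, window_s: float = 240.0,
                     start_s: float | None = None) -> tuple[float, float]:
    """Arithmetic mean VO2 and RF over a resting window.

    The window is ``[start_s, start_s + window_s)``; by default it begins at
    the first breath.  Raises if the series does not cover the window.
    """
    t0 = series.t[0] if start_s is None else start_s
    if series.t[-1] - t0 < window_s:
        raise ValueError("series shorter than the resting window")
    mask = (series.t >= t0) & (series.t < t0 + window_s)
    if not mask.any():
        raise ValueError("no breaths inside the resting window")
    return float(series.vo2[mask].mean()), float(series.rf[mask].mean())


def _step_cumulative_integral(values: np.ndarray, times: np.ndarray):
    """Return F with F(t) = ∫ v dt of the left-continuous step function that
    holds values[k] on (times[k-1], times[k]] (values[0] extends to t[0])."""
    knots = np.concatenate(([times[0]], times))
    # integral accumulated at each knot
    areas = np.concatenate(([0.0], values[1:] * np.diff(times)))
    cum = np.concatenate(([0.0], np.cumsum(areas[1:])))

    def F(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(times, t, side="left")
        idx = np.clip(idx, 0, times.size - 1)
        base_t = np.where(idx > 0, times[np.maximum(idx - 1, 0)], times[0])
        base_c = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
        return base_c + values[idx] * (t - base_t)

    return F


def rolling_peak(values: np.ndarray, times: np.ndarray,
                 window_s: float = 20.0) -> float:
    """Maximum over all windows of width ``window_s`` of the time-weighted mean.

    The breath series is treated as a step function where breath k's value
    holds over the inter-breath interval ending at its own time; the window
    mean is the integral of that step function divided by the window width.
    Window endpoints slide continuously; the maximum of the windowed mean is
    attained with a window edge at a breath time, so both anchored families
    (windows ending at each breath, windows starting at each breath) are
    evaluated.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    span = times[-1] - times[0]
    if span < window_s:
        raise ValueError("series shorter than the rolling window")
    if window_s <= 0:
        return float(values.max())
    F = _step_cumulative_integral(values, times)
    ends = times[times >= times[0] + window_s]
    starts = times[times <= times[-1] - window_s]
    edges = np.concatenate((ends, starts + window_s))
    means = (F(edges) - F(edges - window_s)) / window_s
    return float(means.max())


def stage_interpolated_power(event_time_s: float, *, start_w: float = 100.0,
                             increment_w: float = 40.0,
                             stage_s: float = 240.0) -> float:
    """Power attributed to an event at ``event_time_s`` into a graded test.

    Power of the last completed stage plus the completed fraction of the
    current stage times the increment: an event at minute 18 gives
    220 W + (2 min / 4 min) × 40 W = 240 W.
    """
    if event_time_s < stage_s:
        raise ValueError("event precedes the first completed stage")
    n_completed = int(np.floor(event_time_s / stage_s))
    last_power = start_w + (n_completed - 1) * increment_w
    time_into = event_time_s - n_completed * stage_s
    return last_power + (time_into / stage_s) * increment_w


def stage_time_for_power(power_w: float, *, start_w: float = 100.0,
                         increment_w: float = 40.0,
                         stage_s: float = 240.0) -> float:
    """Inverse of :func:`stage_interpolated_power` (event time for a power)."""
    if power_w < start_w:
        raise ValueError("power precedes the first completed stage")
    n_completed = int(np.floor((power_w - start_w) / increment_w)) + 1
    last_power = start_w + (n_completed - 1) * increment_w
    frac = (power_w - last_power) / increment_w
    return (n_completed + frac) * stage_s


def intensity_levels(p_vt1: float, p_vt2: float, ppo: float) -> tuple[float, float, float]:
    """Moderate/heavy/severe power levels from the threshold powers.

    P1 = 0.5·P_VT1; P2 = midpoint of (P_VT1, P_VT2); P3 = midpoint of
    (P_VT2, PPO).
    """
    if not (p_vt1 < p_vt2 < ppo):
        raise ValueError("require p_vt1 < p_vt2 < ppo")
    p1 = 0.5 * p_vt1
    p2 = 0.5 * (p_vt2 - p_vt1) + p_vt1
    p3 = 0.5 * (ppo - p_vt2) + p_vt2
    return p1, p2, p3


def analyze_gxt(series: BreathSeries, vt1_time_s: float, vt2_time_s: float, *,
                rest_s: float = 240.0, test_start_s: float | None = None,
                rolling_window_s: float = 20.0, start_w: float = 100.0,
                increment_w: float = 40.0, stage_s: float = 240.0) -> GxtResult:
    """Full GXT summary from one recording.

    The recording is assumed to begin with ``rest_s`` of seated rest and the
    graded test proper to start at ``test_start_s`` (default: end of rest).
    ``vt1_time_s``/``vt2_time_s`` are event times measured from the test
    start — threshold identification itself is a manual gas-exchange
    procedure and is an input here.
    """
    if test_start_s is None:
        test_start_s = series.t[0] + rest_s
    vo2r, rf_rest = resting_averages(series, window_s=rest_s)
    test_mask = series.t >= test_start_s
    vo2max = rolling_peak(series.vo2[test_mask], series.t[test_mask],
                          rolling_window_s)
    rf_max = rolling_peak(series.rf[test_mask], series.t[test_mask],
                          rolling_window_s)
    end_time = series.t[-1] - test_start_s
    kw = dict(start_w=start_w, increment_w=increment_w, stage_s=stage_s)
    ppo = stage_interpolated_power(end_time, **kw)
    p_vt1 = stage_interpolated_power(vt1_time_s, **kw)
    p_vt2 = stage_interpolated_power(vt2_time_s, **kw)
    return GxtResult(ppo=ppo, vo2max=vo2max, rf_max=rf_max, vo2r=vo2r,
                     rf_rest=rf_rest, p_vt1=p_vt1, p_vt2=p_vt2)
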