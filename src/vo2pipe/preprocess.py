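"""From raw sessions to normalized, windowed supervised datasets.

The supervised problem is next-breath VO2 prediction: each sample is the
history of the four input channels (power, cadence, heart rate, respiratory
frequency) over the ``n_past`` most recent breaths, and the target is the
normalized VO2 at the following breath.  Preparation steps:

1. drop invalid breaths (analyser validity ranges on RF/VE/FeO2/FeCO2);
2. resample the uniformly sampled power/cadence trace onto the irregular
   breath grid by inter-breath interval means;
3. normalize every channel to [0, 1] between physiological anchors
   (VO2: rest→max; RF: rest→max; power: 0→PPO; cadence: 0→max; HR:
   rest→max); supra-maximal efforts legitimately exceed 1 and are not
   clipped;
4. cut sliding windows of ``n_past`` = 70 breaths, never crossing session
   boundaries, giving N − n samples per session of N breaths;
5. assemble the two leave-one-session-out trials (Trial 1 tests on the
   interval protocol Test 1, Trial 2 tests on the Wingate sprint).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import BreathSeries, PowerTrace, VALID_RANGES

__all__ = [
    "CHANNELS",
    "TRIAL_SPLITS",
    "NormalizationAnchors",
    "WindowedDataset",
    "TrialSplit",
    "filter_invalid_breaths",
    "align_to_breaths",
    "normalize_channel",
    "denormalize_channel",
    "normalize_session",
    "build_windows",
    "assemble_trial",
]

#: Input-channel order of every windowed sample.
CHANNELS = ("power", "cadence", "hr", "rf")


@dataclass(frozen=True)
class NormalizationAnchors:
    """(zero_anchor, one_anchor) per channel, in native units."""

    vo2: tuple[float, float]
    rf: tuple[float, float]
    power: tuple[float, float]
    cadence: tuple[float, float]
    hr: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("vo2", "rf", "power", "cadence", "hr"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"degenerate anchors for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class TrialSplit:
    trial_id: int
    train_sessions: tuple[str, ...]
    test_sessions: tuple[str, ...]


#: Leave-one-session-out trial definitions.
TRIAL_SPLITS = {
    1: TrialSplit(1, ("GXT", "WINGATE", "TEST2"), ("TEST1",)),
    2: TrialSplit(2, ("GXT", "TEST1", "TEST2"), ("WINGATE",)),
}


@dataclass(frozen=True)
class WindowedDataset:
    """Supervised windows: X (n_samples, n_past, 4), y next-breath VO2."""

    X: np.ndarray
    y: np.ndarray
    session_id: np.ndarray  # one session label per sample
    n_past: int

    def __post_init__(self) -> None:
        if self.X.ndim != 3 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_samples, n_past, n_channels) matching y")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("windowed data must be finite")

    def __len__(self) -> int:
        return int(self.y.size)

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        n_past = parts[0].n_past
        if any(p.n_past != n_past for p in parts):
            raise ValueError("mismatched n_past")
        return WindowedDataset(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            session_id=np.concatenate([p.session_id for p in parts]),
            n_past=n_past,
        )


def filter_invalid_breaths(series: BreathSeries) -> tuple[BreathSeries, int]:
    """Drop breaths whose RF, VE, FeO2 or FeCO2 falls outside the analyser
    validity ranges (RF 2–90 min⁻¹, VE 0.100–10000 L·min⁻¹, FeO2 5–20%,
    FeCO2 1–10%).  Returns the cleaned series and the number removed."""
    ok = np.ones(len(series), dtype=bool)
    for name, (lo, hi) in VALID_RANGES.items():
        vals = getattr(series, name)
        ok &= (vals >= lo) & (vals <= hi)
    n_removed = int((~ok).sum())
    if not ok.any():
        raise ValueError("all breaths removed by validity filter")
    cleaned = BreathSeries(t=series.t[ok], vo2=series.vo2[ok], hr=series.hr[ok],
                           rf=series.rf[ok], ve=series.ve[ok],
                           feo2=series.feo2[ok], feco2=series.feco2[ok])
    return cleaned, n_removed


def align_to_breaths(trace: PowerTrace,
                     breath_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample the uniform power/cadence trace onto the breath grid.

    Breath k gets the mean of the trace samples falling in the interval
    ``(t_{k-1}, t_k]`` — breath-by-breath gas values are themselves interval
    aggregates, so interval means are the matching resampling rule.  The
    first breath (and any empty interval) takes the nearest trace sample.
    """
    bt = np.asarray(breath_times, dtype=float)
    if bt[0] < trace.t[0] - 1e-9 or bt[-1] > trace.t[-1] + 1e-9:
        raise ValueError("breath times outside the trace span")

    def interval_means(values: np.ndarray) -> np.ndarray:
        csum = np.concatenate(([0.0], np.cumsum(values)))
        # sample i counted in (t_{k-1}, t_k] iff t_{k-1} < trace.t[i] <= t_k
        hi = np.searchsorted(trace.t, bt, side="right")
        lo = np.concatenate(([hi[0]], hi[:-1]))
        counts = hi - lo
        out = np.empty(bt.size)
        nonempty = counts > 0
        out[nonempty] = (csum[hi[nonempty]] - csum[lo[nonempty]]) / counts[nonempty]
        if (~nonempty).any():
            nearest = np.clip(np.searchsorted(trace.t, bt[~nonempty]),
                              0, trace.t.size - 1)
            out[~nonempty] = values[nearest]
        # first breath: nearest sample
        nearest0 = int(np.argmin(np.abs(trace.t - bt[0])))
        out[0] = values[nearest0]
        return out

    return interval_means(trace.power), interval_means(trace.cadence)


def normalize_channel(x: np.ndarray, anchors: tuple[float, float]) -> np.ndarray:
    """Map ``zero_anchor → 0`` and ``one_anchor → 1`` linearly (no clipping)."""
    lo, hi = anchors
    if not hi > lo:
        raise ValueError("degenerate anchors")
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


def denormalize_channel(x: np.ndarray, anchors: tuple[float, float]) -> np.ndarray:
    lo, hi = anchors
    if not hi > lo:
        raise ValueError("degenerate anchors")
    return np.asarray(x, dtype=float) * (hi - lo) + lo


def normalize_session(series: BreathSeries, power: np.ndarray,
                      cadence: np.ndarray,
                      anchors: NormalizationAnchors) -> tuple[np.ndarray, np.ndarray]:
    """Return the (N, 4) normalized input-channel matrix (power, cadence,
    HR, RF order) and the normalized VO2 vector for one session."""
    cols = [
        normalize_channel(power, anchors.power),
        normalize_channel(cadence, anchors.cadence),
        normalize_channel(series.hr, anchors.hr),
        normalize_channel(series.rf, anchors.rf),
    ]
    return np.stack(cols, axis=1), normalize_channel(series.vo2, anchors.vo2)


def build_windows(channels: np.ndarray, vo2_norm: np.ndarray,
                  n_past: int = 70, session_label: str = "") -> WindowedDataset:
    """Cut sliding supervised windows from one session.

    Sample j covers breaths ``j .. j+n_past-1`` (oldest to newest) and its
    target is the normalized VO2 at breath ``j+n_past``; a session of N
    breaths yields N − n_past samples.
    """
    channels = np.asarray(channels, dtype=float)
    vo2_norm = np.asarray(vo2_norm, dtype=float)
    n = channels.shape[0]
    if vo2_norm.shape[0] != n:
        raise ValueError("channels and vo2 must share the breath count")
    if n <= n_past:
        raise ValueError(f"need more than n_past={n_past} breaths, got {n}")
    n_samples = n - n_past
    if n_past == 0:
        X = channels[:-1][:, None, :]
        y = vo2_norm[1:]
        n_samples = n - 1
    else:
        windows = np.lib.stride_tricks.sliding_window_view(
            channels, (n_past, channels.shape[1]))[:, 0]
        X = windows[:n_samples].copy()
        y = vo2_norm[n_past:]
    return WindowedDataset(X=X, y=y,
                           session_id=np.full(X.shape[0], session_label),
                           n_past=n_past)


def assemble_trial(sessions: dict[str, tuple[np.ndarray, np.ndarray]],
                   trial_id: int,
                   n_past: int = 70) -> tuple[WindowedDataset, WindowedDataset]:
    """Build the train/test datasets of one trial for a single athlete.

    ``sessions`` maps session kind to its (channels, vo2_norm) pair.
    Windows are cut per session, so no window straddles two recordings.
    """
    if trial_id not in TRIAL_SPLITS:
        raise ValueError(f"unknown trial {trial_id}")
    split = TRIAL_SPLITS[trial_id]
    missing = [k for k in split.train_sessions + split.test_sessions
               if k not in sessions]
    if missing:
        raise ValueError(f"missing sessions: {missing}")

    def bundle(kinds: tuple[str, ...]) -> WindowedDataset:
        parts = [build_windows(*sessions[k], n_past=n_past, session_label=k)
                 for k in kinds]
        return WindowedDataset.concatenate(parts)

    return bundle(split.train_sessions), bundle(split.test_sessions)
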