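"""Synthetic cyclists and cycling sessions.

Generates seeded cohorts of athlete profiles and protocol-faithful sessions
(graded exercise test, two constant/ramp interval protocols, and a 30-s
Wingate sprint) with the statistical structure the downstream analysis
assumes: irregular breath timing driven by a first-order respiratory-
frequency response, ground-truth VO2 from the two-component kinetic model
plus additive noise, first-order heart-rate dynamics, plausible ventilation
and expired-gas fractions, and an optional fraction of corrupted breaths for
exercising the validity filter.

Cohort anchors are drawn from Gaussians centred on the characteristics of
amateur road cyclists (weight 76.0 (6.6) kg, VO2MAX 4443 (720) mlO2·min⁻¹,
PPO 335 (44) W, intensity levels P1 109 (21), P2 246 (42) W), truncated to
satisfy physiological orderings; ventilatory-threshold powers are
back-solved from the intensity-level formulas so the cohort is internally
consistent with the graded-test arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import Model2Params, simulate

__all__ = [
    "AthleteProfile",
    "Segment",
    "SessionProtocol",
    "PowerTrace",
    "BreathSeries",
    "NoiseConfig",
    "SESSION_KINDS",
    "make_protocol",
    "sample_power_trace",
    "simulate_breaths",
    "make_cohort",
]

SESSION_KINDS = ("GXT", "TEST1", "TEST2", "WINGATE")

#: Validity ranges applied by breath-by-breath gas analysers; breaths with
#: any channel outside these are discarded (see preprocess.filter_invalid_breaths).
VALID_RANGES = {
    "rf": (2.0, 90.0),
    "ve": (0.100, 10000.0),
    "feo2": (5.0, 20.0),
    "feco2": (1.0, 10.0),
}


@dataclass(frozen=True)
class AthleteProfile:
    """Per-athlete physiological anchors plus generator ground truth.

    Powers in W, VO2 in mlO2·min⁻¹, rates in events·min⁻¹, weight in kg.
    ``true_m2`` is the two-component parameter set used to generate this
    athlete's VO2 and is the recovery target for calibration experiments.
    """

    weight: float
    vo2max: float
    vo2r: float
    rf_max: float
    rf_rest: float
    hr_max: float
    hr_rest: float
    ppo: float
    p_vt1: float
    p_vt2: float
    p1: float
    p2: float
    p3: float
    p_max_wingate: float
    cadence_max: float
    true_m2: Model2Params

    def __post_init__(self) -> None:
        if not (0 < self.vo2r < self.vo2max):
            raise ValueError("require 0 < vo2r < vo2max")
        if not (0 < self.p_vt1 < self.p_vt2 < self.ppo):
            raise ValueError("require 0 < p_vt1 < p_vt2 < ppo")
        if not (self.p1 < self.p2 < self.p3):
            raise ValueError("require p1 < p2 < p3")
        if not (self.rf_rest < self.rf_max and self.hr_rest < self.hr_max):
            raise ValueError("resting rates must be below maxima")


@dataclass(frozen=True)
class Segment:
    """One protocol segment: constant power or a linear ramp."""

    shape: str  # "constant" | "ramp"
    duration: float  # s
    power_start: float  # W
    power_end: float  # W

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.shape == "constant" and self.power_start != self.power_end:
            raise ValueError("constant segments need power_start == power_end")
        if self.shape not in ("constant", "ramp"):
            raise ValueError(f"unknown segment shape {self.shape!r}")


@dataclass(frozen=True)
class SessionProtocol:
    session_kind: str
    segments: tuple[Segment, ...]
    target_cadence: float  # rev·min⁻¹

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class PowerTrace:
    """Uniformly sampled power/cadence prescription actually ridden."""

    t: np.ndarray  # s
    power: np.ndarray  # W
    cadence: np.ndarray  # rev·min⁻¹


@dataclass(frozen=True)
class BreathSeries:
    """Irregularly timed breath-by-breath measurements."""

    t: np.ndarray  # s at each breath
    vo2: np.ndarray  # mlO2·min⁻¹
    hr: np.ndarray  # beats·min⁻¹
    rf: np.ndarray  # breaths·min⁻¹
    ve: np.ndarray  # L·min⁻¹
    feo2: np.ndarray  # %
    feco2: np.ndarray  # %

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("vo2", "hr", "rf", "ve", "feo2", "feco2"):
            if getattr(self, name).size != n:
                raise ValueError("all channels must share the breath count")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("breath times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise settings for the breath simulator.

    ``vo2_sd`` defaults to 150 mlO2·min⁻¹, of the order of the typical
    breath-by-breath VO2 noise at high exercise intensity.
    """

    vo2_sd: float = 150.0
    hr_sd: float = 1.5
    rf_sd: float = 0.8
    invalid_rate: float = 0.0


def _constant(power: float, duration: float) -> Segment:
    return Segment("constant", duration, power, power)


def _ramp(p0: float, p1: float, duration: float) -> Segment:
    return Segment("ramp", duration, p0, p1)


def make_protocol(session_kind: str, profile: AthleteProfile, *,
                  rest_s: float | None = None, warmup_s: float = 0.0,
                  warmup_w: float = 85.0,
                  gxt_start_w: float = 100.0, gxt_increment_w: float = 40.0,
                  gxt_stage_s: float = 240.0,
                  exhaustion_power: float | None = None) -> SessionProtocol:
    """Build the power prescription for one of the four session types.

    GXT
        100 W for 4 min, +40 W every 4 min; the test ends partway through
        the stage in which ``exhaustion_power`` (default: the athlete's PPO)
        is reached, so that the completed-stage interpolation rule recovers
        that power exactly.
    TEST1
        4 min at 100 W, then three repetitions of 4-min bouts at P2, P3, P1.
    TEST2
        4-min ramp P1→P3, 1 min P3, 4 min P1, 1-min ramp P1→P2, 3 min P2,
        4 min P1, 2-min ramp P1→P2, 2 min P2, 4 min P1.
    WINGATE
        120 s rest, 30-s all-out sprint modelled as a linear decay from
        ``p_max_wingate`` to 70% of it (a typical fatigue index), then 300 s
        of unloaded recovery so recovery kinetics are observable.

    ``rest_s`` prepends an unloaded rest segment; it defaults to 240 s for
    the interval protocols (the seated rest that precedes them in the
    laboratory) and to 0 for the other sessions.  ``warmup_s`` > 0 prepends
    a warm-up bout at ``warmup_w`` (laboratory practice: 10 min at 85 W);
    it precedes the rest for the interval protocols and follows it for the
    GXT, matching the order of the laboratory visits.
    """
    kind = session_kind.upper()
    if rest_s is None:
        rest_s = 240.0 if kind in ("TEST1", "TEST2") else 0.0
    segs: list[Segment] = []
    if kind == "GXT":
        if rest_s > 0:
            segs.append(_constant(0.0, rest_s))
        if warmup_s > 0:
            segs.append(_constant(warmup_w, warmup_s))
    elif kind in ("TEST1", "TEST2"):
        if warmup_s > 0:
            segs.append(_constant(warmup_w, warmup_s))
        if rest_s > 0:
            segs.append(_constant(0.0, rest_s))
    cadence = profile.cadence_max if kind == "WINGATE" else 90.0

    if kind == "GXT":
        target = exhaustion_power if exhaustion_power is not None else profile.ppo
        if target <= gxt_start_w:
            raise ValueError("exhaustion power must exceed the first stage")
        n_completed = int(np.floor((target - gxt_start_w) / gxt_increment_w)) + 1
        for i in range(n_completed):
            segs.append(_constant(gxt_start_w + i * gxt_increment_w, gxt_stage_s))
        last_completed = gxt_start_w + (n_completed - 1) * gxt_increment_w
        frac = (target - last_completed) / gxt_increment_w
        if frac > 0:
            segs.append(_constant(last_completed + gxt_increment_w,
                                  frac * gxt_stage_s))
    elif kind == "TEST1":
        segs.append(_constant(100.0, 240.0))
        for _ in range(3):
            for p in (profile.p2, profile.p3, profile.p1):
                segs.append(_constant(p, 240.0))
    elif kind == "TEST2":
        p1, p2, p3 = profile.p1, profile.p2, profile.p3
        segs += [
            _ramp(p1, p3, 240.0),
            _constant(p3, 60.0),
            _constant(p1, 240.0),
            _ramp(p1, p2, 60.0),
            _constant(p2, 180.0),
            _constant(p1, 240.0),
            _ramp(p1, p2, 120.0),
            _constant(p2, 120.0),
            _constant(p1, 240.0),
        ]
    elif kind == "WINGATE":
        segs += [
            _constant(0.0, 120.0),
            _ramp(profile.p_max_wingate, 0.70 * profile.p_max_wingate, 30.0),
            _constant(0.0, 300.0),
        ]
    else:
        raise ValueError(f"unknown session kind {session_kind!r}")

    return SessionProtocol(kind, tuple(segs), cadence)


def evaluate_protocol(protocol: SessionProtocol, t: np.ndarray) -> np.ndarray:
    """Exact (noise-free) power prescription at times ``t``."""
    t = np.asarray(t, dtype=float)
    power = np.zeros_like(t)
    start = 0.0
    for seg in protocol.segments:
        end = start + seg.duration
        # last segment owns its right edge so the grid endpoint is covered
        mask = (t >= start) & ((t < end) | (seg is protocol.segments[-1]) & (t <= end))
        if seg.shape == "constant":
            power[mask] = seg.power_start
        else:
            frac = (t[mask] - start) / seg.duration
            power[mask] = seg.power_start + frac * (seg.power_end - seg.power_start)
        start = end
    return power


def sample_power_trace(protocol: SessionProtocol, dt: float = 1.0,
                       noise_sd: float = 0.0, seed: int | None = None) -> PowerTrace:
    """Sample the protocol on a uniform grid with optional measurement noise.

    Cadence is the protocol's target cadence plus small noise wherever power
    is prescribed, and zero during rests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.total_duration + dt / 2, dt)
    base = evaluate_protocol(protocol, t)
    power = base.copy()
    cadence = np.where(base > 0, protocol.target_cadence, 0.0)
    if noise_sd > 0:
        power = np.clip(base + rng.normal(0.0, noise_sd, t.size), 0.0, None)
        power[base == 0] = 0.0
        cad_noise = rng.normal(0.0, 0.5 * noise_sd, t.size)
        cadence = np.where(base > 0, np.clip(cadence + cad_noise, 0.0, None), 0.0)
    return PowerTrace(t=t, power=power, cadence=cadence)


def _first_order_response(times: np.ndarray, targets: np.ndarray,
                          x0: float, tau: float) -> np.ndarray:
    """Euler integration of a first-order lag on an irregular grid."""
    out = np.empty(times.size)
    out[0] = x0
    for k in range(times.size - 1):
        dt = times[k + 1] - times[k]
        out[k + 1] = out[k] + (targets[k] - out[k]) * dt / tau
    return out


def simulate_breaths(trace: PowerTrace, profile: AthleteProfile,
                     noise_cfg: NoiseConfig | None = None,
                     seed: int | None = None, *,
                     tau_hr: float = 30.0, tau_rf: float = 35.0) -> BreathSeries:
    """Simulate one breath-by-breath session riding the given power trace.

    Respiratory frequency follows a first-order response (``tau_rf`` = 35 s)
    toward a power-proportional target between the athlete's resting and
    maximal RF; breath times are then laid down sequentially with
    inter-breath interval 60/RF.  VO2 at the breath times integrates the
    athlete's ground-truth two-component kinetics plus additive Gaussian
    noise; heart rate follows its own first-order response (``tau_hr`` =
    30 s).  Ventilation and expired fractions are filled with values inside
    the analyser validity ranges, and ``noise_cfg.invalid_rate`` of breaths
    are corrupted to violate them (for filter testing).
    """
    if noise_cfg is None:
        noise_cfg = NoiseConfig()
    span = trace.t[-1] - trace.t[0]
    if span < 60.0:
        raise ValueError("trace must cover at least 60 s")
    rng = np.random.default_rng(seed)

    def power_at(t: float) -> float:
        return float(np.interp(t, trace.t, trace.power))

    def rf_target(p: float) -> float:
        frac = min(max(p / profile.ppo, 0.0), 1.0)
        return profile.rf_rest + (profile.rf_max - profile.rf_rest) * frac

    # sequential breath-time generation: the RF state breathes out the clock
    t_breaths: list[float] = []
    rf_vals: list[float] = []
    t = float(trace.t[0])
    rf = profile.rf_rest
    while t <= trace.t[-1]:
        t_breaths.append(t)
        rf_vals.append(rf)
        dt = 60.0 / rf
        rf = rf + (rf_target(power_at(t)) - rf) * dt / tau_rf
        t = t + dt
    times = np.asarray(t_breaths)
    rf_arr = np.asarray(rf_vals)

    power_b = np.interp(times, trace.t, trace.power)

    vo2 = simulate("m2", profile.true_m2, power_b, times,
                   vo2r=profile.vo2r, vo2max=profile.vo2max)

    hr_targets = profile.hr_rest + (profile.hr_max - profile.hr_rest) * \
        np.clip(power_b / profile.ppo, 0.0, 1.0)
    hr = _first_order_response(times, hr_targets, profile.hr_rest, tau_hr)

    if noise_cfg.vo2_sd > 0:
        vo2 = np.clip(vo2 + rng.normal(0.0, noise_cfg.vo2_sd, times.size),
                      1.0, None)
    if noise_cfg.hr_sd > 0:
        hr = hr + rng.normal(0.0, noise_cfg.hr_sd, times.size)
    rf_obs = rf_arr.copy()
    if noise_cfg.rf_sd > 0:
        rf_obs = np.clip(rf_arr + rng.normal(0.0, noise_cfg.rf_sd, times.size),
                         2.1, None)

    # ventilation tracks VO2 (ventilatory equivalent ~24 L per L O2);
    # expired fractions drift with relative intensity but stay in range
    rel = np.clip(vo2 / profile.vo2max, 0.0, 1.2)
    ve = np.clip(24.0 * vo2 / 1000.0 + rng.normal(0.0, 2.0, times.size), 1.0, None)
    feo2 = np.clip(16.0 + 1.8 * rel + rng.normal(0.0, 0.2, times.size), 5.5, 19.5)
    feco2 = np.clip(4.8 - 1.0 * rel + rng.normal(0.0, 0.15, times.size), 1.2, 9.5)

    if noise_cfg.invalid_rate > 0:
        bad = rng.random(times.size) < noise_cfg.invalid_rate
        idx = np.nonzero(bad)[0]
        channel = rng.integers(0, 4, idx.size)
        for j, ch in zip(idx, channel):
            if ch == 0:
                rf_obs[j] = rng.choice([1.0, 95.0])
            elif ch == 1:
                ve[j] = 0.05
            elif ch == 2:
                feo2[j] = rng.choice([3.0, 22.0])
            else:
                feco2[j] = rng.choice([0.5, 11.0])

    return BreathSeries(t=times, vo2=vo2, hr=hr, rf=rf_obs,
                        ve=ve, feo2=feo2, feco2=feco2)


# Cohort anchor distributions: mean, SD.  PPO and weight are drawn
# marginally; the threshold powers are drawn as fractions of PPO (athletes'
# thresholds co-vary strongly with their peak power), which preserves the
# population marginals without the truncation bias that independent draws
# plus the ordering constraints would introduce.  The fraction means invert
# the population values P_VT1 = 218, P_VT2 = 274 at PPO = 335.
_COHORT_STATS = {
    "weight": (76.0, 6.6),
    "ppo": (335.0, 44.0),
    "vt2_frac": (274.0 / 335.0, 0.05),   # P_VT2 / PPO
    "vt1_frac": (218.0 / 274.0, 0.08),   # P_VT1 / P_VT2
    "vo2max_per_ppo": (4443.0 / 335.0, 1.2),  # mlO2·min⁻¹ per W of PPO
}

# Ground-truth two-component parameter distribution (means near published
# cycling estimates; critical power scaled to the athlete's PPO).
_M2_JITTER = {
    "v_delta": (400.0, 80.0),
    "delta": (79.0, 15.0),
    "s_gain": (8.67, 0.4),
    "tau_fast": (43.0, 3.0),
    "tau_slow": (199.0, 30.0),
    "t_fast": (10.0, 3.0),
    "t_slow": (113.0, 20.0),
}


def _draw_profile(rng: np.random.Generator) -> AthleteProfile:
    for _ in range(1000):
        weight = rng.normal(*_COHORT_STATS["weight"])
        ppo = rng.normal(*_COHORT_STATS["ppo"])
        vt2_frac = rng.normal(*_COHORT_STATS["vt2_frac"])
        vt1_frac = rng.normal(*_COHORT_STATS["vt1_frac"])
        vo2max = ppo * rng.normal(*_COHORT_STATS["vo2max_per_ppo"])
        if not (0.5 < vt2_frac < 0.95 and 0.4 < vt1_frac < 0.95):
            continue
        p_vt2 = vt2_frac * ppo
        p_vt1 = vt1_frac * p_vt2
        p1 = 0.5 * p_vt1
        p2 = 0.5 * (p_vt2 - p_vt1) + p_vt1
        p3 = 0.5 * (ppo - p_vt2) + p_vt2
        vo2r = 3.5 * weight + rng.normal(0.0, 20.0)
        if not (0 < p_vt1 < p_vt2 < ppo and p1 < p2 < p3 and
                0 < vo2r < vo2max and weight > 40 and vo2max > 2000):
            continue
        # kinetic ground truth: redrawn in an inner loop so that rejections
        # here never bias the anchor distributions above
        true_m2 = None
        for _ in range(500):
            m2_vals = {k: rng.normal(*v) for k, v in _M2_JITTER.items()}
            m2_vals["p_c"] = 1.07 * ppo + rng.normal(0.0, 10.0)
            try:
                cand = Model2Params(**m2_vals)
            except ValueError:
                continue
            # dynamics must be consistent with the athlete's VO2R: the
            # slow-component residual at zero power stays negligible
            rest_residual = cand.v_delta * np.exp(-cand.p_c / cand.delta)
            if rest_residual <= 0.015 * vo2r:
                true_m2 = cand
                break
        if true_m2 is None:
            continue
        rf_rest = rng.normal(14.0, 1.5)
        rf_max = rng.normal(55.0, 5.0)
        hr_rest = rng.normal(58.0, 6.0)
        hr_max = rng.normal(190.0, 6.0)
        if not (2.5 < rf_rest < rf_max and 30 < hr_rest < hr_max):
            continue
        return AthleteProfile(
            weight=weight, vo2max=vo2max, vo2r=vo2r,
            rf_max=rf_max, rf_rest=rf_rest, hr_max=hr_max, hr_rest=hr_rest,
            ppo=ppo, p_vt1=p_vt1, p_vt2=p_vt2, p1=p1, p2=p2, p3=p3,
            p_max_wingate=2.2 * ppo + rng.normal(0.0, 40.0),
            cadence_max=rng.normal(120.0, 8.0),
            true_m2=true_m2,
        )
    raise RuntimeError("could not draw a valid athlete profile")


def make_cohort(n_athletes: int, seed: int | None = None) -> list[AthleteProfile]:
    """Draw ``n_athletes`` internally consistent athlete profiles.

    Each athlete gets an independent child generator so the cohort is stable
    under extension: athlete i is identical whether n_athletes is 5 or 50.
    """
    if n_athletes < 1:
        raise ValueError("n_athletes must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_athletes)
    return [_draw_profile(np.random.default_rng(ss)) for ss in children]
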