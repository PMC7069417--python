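"""Discrete-time oxygen-uptake kinetic models.

Two analytical descriptions of the VO2 response to mechanical power output
are provided, both formulated as explicit (forward-Euler) steppers on an
irregular breath-by-breath time grid:

* **Model 1** — a single first-order lag.  VO2 relaxes toward the steady
  state ``VO2R + G * P`` with time constant ``tau``.  ``G`` is the aerobic
  gain (mlO2/min per watt, ~10 in trained cyclists).

* **Model 2** — a two-component model with a fast (phase-II) and a slow
  (phase-III) component, each a first-order lag toward a power-dependent
  forcing and each activated only after its own onset delay.  Below the
  critical power ``p_c`` the slow forcing is an exponential of the distance
  to ``p_c``; above it the two forcings sum exactly to ``VO2MAX - VO2R`` so
  that sustained supra-critical work drives VO2 to VO2MAX.

Both steppers preserve their fixed points bit-exactly and are used in two
roles: as generators of synthetic ground-truth VO2 and as candidate
predictors calibrated against measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Model1Params",
    "Model2Params",
    "Model2State",
    "model1_step",
    "model2_forcings",
    "model2_step",
    "simulate",
    "simulate_model1_many",
    "simulate_model2_many",
]


@dataclass(frozen=True)
class Model1Params:
    """First-order model parameters: gain (mlO2·min⁻¹·W⁻¹) and time constant (s)."""

    gain_g: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.gain_g > 0 and self.tau > 0):
            raise ValueError("gain_g and tau must be positive")


@dataclass(frozen=True)
class Model2Params:
    """Two-component model parameters.

    Attributes
    ----------
    v_delta : float
        Amplitude of the sub-critical slow-component forcing, mlO2·min⁻¹.
    p_c : float
        Critical power threshold, W.
    delta : float
        E-folding width of the sub-critical slow forcing, W.
    s_gain : float
        Fast-component gain, mlO2·min⁻¹·W⁻¹.
    tau_fast, tau_slow : float
        Time constants of the fast and slow components, s.
    t_fast, t_slow : float
        Activation delays of the fast and slow components, s, measured
        from exercise onset.
    """

    v_delta: float
    p_c: float
    delta: float
    s_gain: float
    tau_fast: float
    tau_slow: float
    t_fast: float
    t_slow: float

    def __post_init__(self) -> None:
        vals = (self.v_delta, self.p_c, self.delta, self.s_gain,
                self.tau_fast, self.tau_slow)
        if not all(v > 0 for v in vals) or self.t_fast < 0 or self.t_slow < 0:
            raise ValueError("Model2Params values must be positive")
        if not self.t_fast < self.t_slow:
            raise ValueError("t_fast must be < t_slow")
        if not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be < tau_slow")


@dataclass
class Model2State:
    """Instantaneous state of Model 2: the two VO2 components above rest and the clock."""

    comp_fast: float = 0.0
    comp_slow: float = 0.0
    t: float = 0.0


def model1_step(vo2_k: float, p_k: float, dt: float,
                params: Model1Params, vo2r: float) -> float:
    """Advance Model 1 by one irregular time step.

    ``vo2(k+1) = (P(k)·G + VO2R − vo2(k)) · Δt/τ + vo2(k)``
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (p_k * params.gain_g + vo2r - vo2_k) * dt / params.tau + vo2_k


def model2_forcings(p_k: float, params: Model2Params,
                    vo2max: float, vo2r: float) -> tuple[float, float]:
    """Power-dependent forcing of the fast and slow components.

    Fast: ``min(s·P, VO2MAX − VO2R)``.  Slow: ``VΔ·exp(−(Pc−P)/Δ)`` for
    ``P ≤ Pc``, else the complement ``VO2MAX − VO2R − A_fast`` so that the
    two forcings saturate the full aerobic range above critical power.
    """
    if vo2max <= vo2r:
        raise ValueError("vo2max must exceed vo2r")
    reserve = vo2max - vo2r
    a_fast = min(params.s_gain * p_k, reserve)
    if p_k <= params.p_c:
        a_slow = params.v_delta * np.exp(-(params.p_c - p_k) / params.delta)
    else:
        a_slow = reserve - a_fast
    return a_fast, a_slow


def model2_step(state: Model2State, p_k: float, dt: float, params: Model2Params,
                vo2max: float, vo2r: float) -> tuple[Model2State, float]:
    """Advance Model 2 by one step; returns the new state and VO2 at k+1.

    Each component is held at zero while the session clock is below its
    activation delay; afterwards it follows a first-order Euler update
    toward its forcing.  ``vo2(k+1) = VO2R + comp_fast' + comp_slow'``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_fast, a_slow = model2_forcings(p_k, params, vo2max, vo2r)
    cf, cs = state.comp_fast, state.comp_slow
    if state.t >= params.t_fast:
        cf = (a_fast - cf) * dt / params.tau_fast + cf
    if state.t >= params.t_slow:
        cs = (a_slow - cs) * dt / params.tau_slow + cs
    new = Model2State(comp_fast=cf, comp_slow=cs, t=state.t + dt)
    return new, vo2r + cf + cs


def _check_euler_stability(dts: np.ndarray, min_tau: float) -> None:
    # explicit Euler on a first-order lag is stable for dt < 2*tau
    if dts.size and float(np.max(dts)) >= 2.0 * min_tau:
        raise ValueError(
            f"time step {np.max(dts):.1f}s violates Euler stability bound "
            f"2*tau = {2 * min_tau:.1f}s"
        )


def simulate(model_id: str, params: Model1Params | Model2Params,
             power: np.ndarray, times: np.ndarray, vo2r: float,
             vo2max: float | None = None,
             onset_time: float | None = None) -> np.ndarray:
    """Simulate a whole session on an irregular breath grid, starting from rest.

    Parameters
    ----------
    model_id : {"m1", "m2"}
    power : per-breath mechanical power, W.
    times : strictly increasing breath times, s.
    onset_time : Model 2 only — time at which the activation-delay clock
        starts; defaults to the first breath with non-zero power (exercise
        onset), or the first breath if power never rises above zero.

    Returns the predicted VO2 at every breath time (the first breath is the
    resting initial condition).
    """
    power = np.asarray(power, dtype=float)
    times = np.asarray(times, dtype=float)
    if power.shape != times.shape:
        raise ValueError("power and times must have the same shape")
    n = power.size
    if n == 0:
        return np.empty(0)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    dts = np.diff(times)

    if model_id == "m1":
        if not isinstance(params, Model1Params):
            raise TypeError("m1 requires Model1Params")
        _check_euler_stability(dts, params.tau)
        out = np.empty(n)
        out[0] = vo2r
        for k in range(n - 1):
            out[k + 1] = model1_step(out[k], power[k], dts[k], params, vo2r)
        return out

    if model_id == "m2":
        if not isinstance(params, Model2Params):
            raise TypeError("m2 requires Model2Params")
        if vo2max is None:
            raise ValueError("m2 requires vo2max")
        _check_euler_stability(dts, min(params.tau_fast, params.tau_slow))
        if onset_time is None:
            active = np.nonzero(power > 0)[0]
            onset_time = times[active[0]] if active.size else times[0]
        state = Model2State(t=times[0] - onset_time)
        out = np.empty(n)
        out[0] = vo2r + state.comp_fast + state.comp_slow
        for k in range(n - 1):
            state, out[k + 1] = model2_step(state, power[k], dts[k], params,
                                            vo2max, vo2r)
        return out

    raise ValueError(f"unknown model_id {model_id!r}")


# ---------------------------------------------------------------------------
# Batched simulators, vectorized over parameter sets.  These exist so the
# particle-swarm calibration can evaluate a whole swarm per breath-loop pass;
# they must agree with `simulate` to floating-point round-off (tested).

def simulate_model1_many(gain_g: np.ndarray, tau: np.ndarray,
                         power: np.ndarray, times: np.ndarray,
                         vo2r: float) -> np.ndarray:
    """Model 1 predictions for many (G, tau) pairs at once → (n_sets, n_breaths)."""
    gain_g = np.atleast_1d(np.asarray(gain_g, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    power = np.asarray(power, dtype=float)
    times = np.asarray(times, dtype=float)
    n = power.size
    out = np.empty((gain_g.size, n))
    if n == 0:
        return out
    dts = np.diff(times)
    vo2 = np.full(gain_g.size, float(vo2r))
    out[:, 0] = vo2
    for k in range(n - 1):
        vo2 = vo2 + (power[k] * gain_g + vo2r - vo2) * (dts[k] / tau)
        out[:, k + 1] = vo2
    return out


def simulate_model2_many(theta: np.ndarray, power: np.ndarray, times: np.ndarray,
                         vo2r: float, vo2max: float,
                         onset_time: float | None = None) -> np.ndarray:
    """Model 2 predictions for many parameter rows at once.

    ``theta`` has shape (n_sets, 8) with columns ordered as
    (v_delta, p_c, delta, s_gain, tau_fast, tau_slow, t_fast, t_slow).
    Returns (n_sets, n_breaths).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    power = np.asarray(power, dtype=float)
    times = np.asarray(times, dtype=float)
    n = power.size
    m = theta.shape[0]
    out = np.empty((m, n))
    if n == 0:
        return out
    v_delta, p_c, delta, s_gain, tau_fast, tau_slow, t_fast, t_slow = theta.T
    if onset_time is None:
        active = np.nonzero(power > 0)[0]
        onset_time = times[active[0]] if active.size else times[0]
    reserve = vo2max - vo2r
    dts = np.diff(times)
    cf = np.zeros(m)
    cs = np.zeros(m)
    out[:, 0] = vo2r
    t = times[0] - onset_time
    for k in range(n - 1):
        p = power[k]
        a_fast = np.minimum(s_gain * p, reserve)
        a_slow = np.where(p <= p_c,
                          v_delta * np.exp(-(p_c - p) / delta),
                          reserve - a_fast)
        gate_f = t >= t_fast
        gate_s = t >= t_slow
        cf = np.where(gate_f, cf + (a_fast - cf) * (dts[k] / tau_fast), cf)
        cs = np.where(gate_s, cs + (a_slow - cs) * (dts[k] / tau_slow), cs)
        t += dts[k]
        out[:, k + 1] = vo2r + cf + cs
    return out
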