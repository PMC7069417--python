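"""Particle-swarm calibration of the kinetic models.

Model parameters are fitted to one or more training sessions by minimizing
the sum of squared differences between measured and simulated VO2 over all
training breaths (the simulation restarts from rest at each session).  The
optimizer is a global-best particle swarm with constriction coefficients
(inertia 0.729, cognitive = social = 1.494) run for a fixed number of
iterations (default 250); positions are reflected at the box bounds.  The
swarm objective is evaluated through the batched simulators so one breath
loop serves the whole swarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (Model1Params, Model2Params, simulate_model1_many,
                       simulate_model2_many)

__all__ = [
    "SessionData",
    "PsoConfig",
    "FitResult",
    "default_bounds",
    "objective",
    "pso_fit",
]

#: Penalty returned for out-of-bounds or invalid parameter vectors.
PENALTY = 1e15

#: Parameter order of the Model 2 vector.
M2_ORDER = ("v_delta", "p_c", "delta", "s_gain",
            "tau_fast", "tau_slow", "t_fast", "t_slow")


@dataclass(frozen=True)
class SessionData:
    """One training session in absolute units: per-breath power, breath
    times, measured VO2, and the athlete's resting/maximal anchors."""

    power: np.ndarray
    times: np.ndarray
    vo2: np.ndarray
    vo2r: float
    vo2max: float


def default_bounds(model_id: str) -> np.ndarray:
    """Box bounds per parameter, rows (lo, hi).

    Model 1: G ∈ [5, 15] mlO2·min⁻¹·W⁻¹, τ ∈ [10, 120] s.  Model 2 bounds
    bracket published estimates for trained cyclists.
    """
    if model_id == "m1":
        return np.array([[5.0, 15.0], [10.0, 120.0]])
    if model_id == "m2":
        return np.array([
            [50.0, 1500.0],   # v_delta
            [200.0, 500.0],   # p_c
            [10.0, 200.0],    # delta
            [5.0, 15.0],      # s_gain
            [10.0, 120.0],    # tau_fast
            [60.0, 400.0],    # tau_slow
            [0.0, 30.0],      # t_fast
            [30.0, 240.0],    # t_slow
        ])
    raise ValueError(f"unknown model_id {model_id!r}")


@dataclass(frozen=True)
class PsoConfig:
    n_iterations: int = 250
    swarm_size: int = 40
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    bounds: np.ndarray | None = None  # (d, 2); model default when None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.swarm_size < 2:
            raise ValueError("need n_iterations >= 1 and swarm_size >= 2")
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or not np.all(b[:, 0] < b[:, 1]):
                raise ValueError("bounds must be (d, 2) with lo < hi")


@dataclass(frozen=True)
class FitResult:
    params: Model1Params | Model2Params
    sse: float
    convergence: np.ndarray  # best objective per iteration (non-increasing)
    model_id: str = ""


def _params_to_vector(params: Model1Params | Model2Params) -> np.ndarray:
    if isinstance(params, Model1Params):
        return np.array([params.gain_g, params.tau])
    return np.array([getattr(params, k) for k in M2_ORDER])


def _vector_to_params(model_id: str, x: np.ndarray) -> Model1Params | Model2Params:
    if model_id == "m1":
        return Model1Params(gain_g=float(x[0]), tau=float(x[1]))
    return Model2Params(**{k: float(v) for k, v in zip(M2_ORDER, x)})


def _objective_matrix(theta: np.ndarray, sessions: list[SessionData],
                      model_id: str, bounds: np.ndarray) -> np.ndarray:
    """SSE for each parameter row; invalid rows get a graded penalty."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    m = theta.shape[0]
    sse = np.zeros(m)
    below = np.clip(bounds[:, 0] - theta, 0.0, None).sum(axis=1)
    above = np.clip(theta - bounds[:, 1], 0.0, None).sum(axis=1)
    bad = (below + above) > 0
    if model_id == "m2":
        # ordering constraints of the two components
        bad |= theta[:, 4] >= theta[:, 5]  # tau_fast < tau_slow
        bad |= theta[:, 6] >= theta[:, 7]  # t_fast < t_slow
    ok = ~bad
    if ok.any():
        sub = theta[ok]
        total = np.zeros(ok.sum())
        for s in sessions:
            if model_id == "m1":
                pred = simulate_model1_many(sub[:, 0], sub[:, 1],
                                            s.power, s.times, s.vo2r)
            else:
                pred = simulate_model2_many(sub, s.power, s.times,
                                            s.vo2r, s.vo2max)
            total += ((s.vo2[None, :] - pred) ** 2).sum(axis=1)
        sse[ok] = total
    sse[bad] = PENALTY * (1.0 + below[bad] + above[bad])
    return sse


def objective(params: Model1Params | Model2Params,
              sessions: list[SessionData], model_id: str) -> float:
    """Least-squares objective: Σ over all training breaths of
    (measured − simulated)², simulation restarted per session.

    Parameter vectors outside the default box bounds receive a large graded
    penalty rather than raising, so optimizers can probe freely.
    """
    if not sessions:
        raise ValueError("sessions must be non-empty")
    x = _params_to_vector(params)
    return float(_objective_matrix(x[None, :], sessions, model_id,
                                   default_bounds(model_id))[0])


def pso_fit(model_id: str, sessions: list[SessionData],
            config: PsoConfig | None = None,
            objective_fn=None) -> FitResult:
    """Fit a kinetic model to the training sessions by global-best PSO.

    ``objective_fn`` (vectorized: (n, d) → (n,)) can replace the built-in
    least-squares objective, e.g. for optimizer self-tests on analytic
    functions.
    """
    if config is None:
        config = PsoConfig()
    bounds = (np.asarray(config.bounds, dtype=float)
              if config.bounds is not None else default_bounds(model_id))
    d = bounds.shape[0]
    rng = np.random.default_rng(config.seed)

    if objective_fn is None:
        if not sessions:
            raise ValueError("sessions must be non-empty")

        def objective_fn(theta):
            return _objective_matrix(theta, sessions, model_id, bounds)

    span = bounds[:, 1] - bounds[:, 0]
    pos = bounds[:, 0] + rng.random((config.swarm_size, d)) * span
    vel = rng.uniform(-0.1, 0.1, (config.swarm_size, d)) * span

    pbest = pos.copy()
    pbest_val = objective_fn(pos)
    g = int(np.argmin(pbest_val))
    gbest = pbest[g].copy()
    gbest_val = float(pbest_val[g])
    trace = np.empty(config.n_iterations)

    for it in range(config.n_iterations):
        r1 = rng.random((config.swarm_size, d))
        r2 = rng.random((config.swarm_size, d))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest[None, :] - pos))
        pos = pos + vel
        # reflect at the box bounds
        for _ in range(2):  # a particle can overshoot both walls
            low = pos < bounds[:, 0]
            pos = np.where(low, 2 * bounds[:, 0] - pos, pos)
            vel = np.where(low, -vel, vel)
            high = pos > bounds[:, 1]
            pos = np.where(high, 2 * bounds[:, 1] - pos, pos)
            vel = np.where(high, -vel, vel)
        pos = np.clip(pos, bounds[:, 0], bounds[:, 1])

        val = objective_fn(pos)
        better = val < pbest_val
        pbest[better] = pos[better]
        pbest_val[better] = val[better]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest = pbest[g].copy()
            gbest_val = float(pbest_val[g])
        trace[it] = gbest_val

    return FitResult(params=_vector_to_params(model_id, gbest),
                     sse=gbest_val, convergence=trace, model_id=model_id)
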