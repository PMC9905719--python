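"""Bounded global-best particle swarm optimizer with linear inertia decay.

Canonical PSO (minimization): each particle's velocity is pulled toward its
personal best P and the swarm's global best G,

    V <- w(t)*V + c1*r1*(P - Z) + c2*r2*(G - Z),    Z <- Z + V,

with r1, r2 fresh uniform draws per particle per dimension and an inertia
weight that decays linearly, w(t) = 0.9 - 0.4 t / t_max, favouring global
exploration early and local refinement late.  Iteration stops at t_max or
when the global-best fitness has improved by less than ``tol`` over a
patience window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, OptimizationError

log = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class PsoConfig:
    """Swarm settings.  Defaults follow the common water-quality setup:
    swarm and iteration caps of 300, cognitive factor c1 = 1.6 and social
    factor c2 = 2 (c1 > c2 risks trapping particles in local search and is
    warned about)."""

    bounds: tuple[tuple[float, float], ...]
    swarm_size: int = 300
    t_max: int = 300
    c1: float = 1.6
    c2: float = 2.0
    tol: float = 1e-12
    patience: int = 20
    seed: int = 0
    velocity_init_frac: float = 0.1   # initial |V| scale as fraction of box width
    velocity_clamp_frac: float = 0.5  # |V| cap as fraction of box width

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ConfigError("swarm_size must be >= 2")
        if self.t_max < 1:
            raise ConfigError("t_max must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ConfigError("c1 and c2 must be positive")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigError(f"invalid bound ({lo}, {hi}): low must be < high")

    @property
    def low(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def high(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


def inertia(t: int, t_max: int) -> float:
    """Linearly decreasing inertia weight: 0.9 at t = 0 down to 0.5 at t_max."""
    if not 0 <= t <= t_max:
        raise ConfigError(f"t must be in [0, t_max], got t={t}, t_max={t_max}")
    return 0.9 - 0.4 * t / t_max


@dataclass
class SwarmState:
    """Positions Z, velocities V, personal bests, global best and counter t."""

    Z: np.ndarray
    V: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    t: int = 0


def _evaluate(objective: Objective, Z: np.ndarray) -> np.ndarray:
    fit = np.empty(Z.shape[0])
    for i, z in enumerate(Z):
        v = float(objective(z))
        if not np.isfinite(v):
            raise OptimizationError(f"objective returned non-finite value {v!r} at {z!r}")
        fit[i] = v
    return fit


def init_state(objective: Objective, cfg: PsoConfig, rng: np.random.Generator) -> SwarmState:
    low, high = cfg.low, cfg.high
    width = high - low
    Z = rng.uniform(low, high, size=(cfg.swarm_size, len(cfg.bounds)))
    V = rng.uniform(-1.0, 1.0, size=Z.shape) * cfg.velocity_init_frac * width
    fit = _evaluate(objective, Z)
    g = int(np.argmin(fit))
    return SwarmState(
        Z=Z, V=V,
        pbest_pos=Z.copy(), pbest_fit=fit.copy(),
        gbest_pos=Z[g].copy(), gbest_fit=float(fit[g]),
    )


def step(
    state: SwarmState, objective: Objective, cfg: PsoConfig, rng: np.random.Generator
) -> SwarmState:
    """One synchronous swarm update (velocity, position, best bookkeeping)."""
    low, high = cfg.low, cfg.high
    width = high - low
    w = inertia(state.t, cfg.t_max)
    r1 = rng.uniform(size=state.Z.shape)
    r2 = rng.uniform(size=state.Z.shape)
    V = (
        w * state.V
        + cfg.c1 * r1 * (state.pbest_pos - state.Z)
        + cfg.c2 * r2 * (state.gbest_pos - state.Z)
    )
    vmax = cfg.velocity_clamp_frac * width
    V = np.clip(V, -vmax, vmax)
    Z = state.Z + V
    # clip to the box and zero the offending velocity component
    out_low = Z < low
    out_high = Z > high
    Z = np.clip(Z, low, high)
    V[out_low | out_high] = 0.0

    fit = _evaluate(objective, Z)
    improved = fit < state.pbest_fit
    state.pbest_pos[improved] = Z[improved]
    state.pbest_fit[improved] = fit[improved]
    g = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[g] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[g])
        state.gbest_pos = state.pbest_pos[g].copy()
    state.Z, state.V = Z, V
    state.t += 1
    return state


@dataclass
class OptimizeResult:
    position: np.ndarray
    fitness: float
    iterations: int
    history: np.ndarray = field(repr=False)  # gbest fitness after each iteration (incl. init)


def optimize(objective: Objective, cfg: PsoConfig) -> OptimizeResult:
    """Run the swarm until t_max or fitness stagnation over the patience window."""
    if cfg.c1 > cfg.c2:
        log.warning(
            "c1=%.3g > c2=%.3g: particles may get trapped in local search", cfg.c1, cfg.c2
        )
    rng = np.random.default_rng(cfg.seed)
    state = init_state(objective, cfg, rng)
    history = [state.gbest_fit]
    while state.t < cfg.t_max:
        step(state, objective, cfg, rng)
        history.append(state.gbest_fit)
        if len(history) > cfg.patience:
            if history[-1 - cfg.patience] - history[-1] < cfg.tol:
                log.debug("PSO converged at t=%d (stagnant over %d iters)", state.t, cfg.patience)
                break
    return OptimizeResult(
        position=state.gbest_pos.copy(),
        fitness=state.gbest_fit,
        iterations=state.t,
        history=np.array(history),
    )
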