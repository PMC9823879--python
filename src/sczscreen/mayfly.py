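"""Mayfly optimization algorithm (MOA).

A swarm optimizer that blends PSO-style attraction with GA-style mating.
Two equally sized populations ("males" and "females") explore a box-bounded
search space.  Males are pulled toward their personal best and the global
best with exponentially distance-damped coefficients ``C1*exp(-beta*Dp^2)``
and ``C2*exp(-beta*Dg^2)``; the current best male instead performs a
"nuptial dance" (a decaying random jitter).  Females are attracted to their
rank-paired male when he outscores them, otherwise they take a random walk.
Each iteration ends with rank-paired uniform crossover whose offspring
replace the worst same-sex individuals when better.

The convention throughout is **maximization**.  The best-so-far trace is
monotone non-decreasing by elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "MayflyParams",
    "MayflyState",
    "MayflyResult",
    "init_state",
    "male_update",
    "female_update",
    "mate",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass
class MayflyParams:
    """Parameters of the mayfly optimizer.

    ``bounds`` is a pair of per-dimension (low, high) arrays.  Defaults for
    the learning coefficients follow the standard recommendation for this
    optimizer: C1 = 1 (local), C2 = 1.5 (global), visibility exponent
    beta = 2, nuptial dance coefficient d = 5 with geometric decay, 30
    flies per sex and 3000 iterations.
    """

    bounds: tuple[np.ndarray, np.ndarray]
    n_flies: int = 30
    max_iter: int = 3000
    c1: float = 1.0
    c2: float = 1.5
    beta: float = 2.0
    dance: float = 5.0
    dance_decay: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        low = np.atleast_1d(np.asarray(self.bounds[0], dtype=float))
        high = np.atleast_1d(np.asarray(self.bounds[1], dtype=float))
        if low.shape != high.shape:
            raise ValueError("bounds low/high must have the same shape")
        if np.any(low >= high):
            raise ValueError("each dimension requires low < high")
        self.bounds = (low, high)
        if self.n_flies < 2:
            raise ValueError("n_flies must be at least 2")
        if min(self.c1, self.c2, self.beta) < 0 or self.dance < 0:
            raise ValueError("c1, c2, beta and dance must be non-negative")
        if not (0 < self.dance_decay <= 1):
            raise ValueError("dance_decay must lie in (0, 1]")

    @property
    def dim(self) -> int:
        return self.bounds[0].size

    @classmethod
    def for_box(cls, low: float, high: float, dim: int, **kwargs) -> "MayflyParams":
        """Convenience constructor for a cubic search box."""
        return cls(bounds=(np.full(dim, low), np.full(dim, high)), **kwargs)


@dataclass
class MayflyState:
    """Mutable swarm state; arrays are (n_flies, dim)."""

    males: np.ndarray
    male_vel: np.ndarray
    male_fit: np.ndarray
    pbest: np.ndarray
    pbest_fit: np.ndarray
    females: np.ndarray
    female_vel: np.ndarray
    female_fit: np.ndarray
    gbest: np.ndarray
    gbest_fit: float
    rng: np.random.Generator
    iteration: int = 0
    dance_scale: float = 5.0


@dataclass
class MayflyResult:
    position: np.ndarray
    value: float
    trace: np.ndarray  # best-so-far objective value per iteration


def _evaluate(objective: Objective, positions: np.ndarray) -> np.ndarray:
    vals = np.empty(positions.shape[0])
    for i, pos in enumerate(positions):
        v = float(objective(pos))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value at position {pos!r}")
        vals[i] = v
    return vals


def _clamp(positions: np.ndarray, velocities: np.ndarray, params: MayflyParams) -> None:
    """Clamp to bounds in place, zeroing velocity on clamped dimensions."""
    low, high = params.bounds
    below = positions < low
    above = positions > high
    positions[below] = np.broadcast_to(low, positions.shape)[below]
    positions[above] = np.broadcast_to(high, positions.shape)[above]
    velocities[below | above] = 0.0


def init_state(
    objective: Objective,
    params: MayflyParams,
    rng: Optional[np.random.Generator] = None,
    init_males: Optional[np.ndarray] = None,
    init_females: Optional[np.ndarray] = None,
    init_male_vel: Optional[np.ndarray] = None,
) -> MayflyState:
    rng = np.random.default_rng(params.seed) if rng is None else rng
    low, high = params.bounds
    n, d = params.n_flies, params.dim
    males = rng.uniform(low, high, size=(n, d)) if init_males is None else np.array(init_males, float)
    females = rng.uniform(low, high, size=(n, d)) if init_females is None else np.array(init_females, float)
    male_vel = np.zeros((n, d)) if init_male_vel is None else np.array(init_male_vel, float)
    male_fit = _evaluate(objective, males)
    female_fit = _evaluate(objective, females)
    all_pos = np.vstack([males, females])
    all_fit = np.concatenate([male_fit, female_fit])
    best = int(np.argmax(all_fit))
    return MayflyState(
        males=males,
        male_vel=male_vel,
        male_fit=male_fit,
        pbest=males.copy(),
        pbest_fit=male_fit.copy(),
        females=females,
        female_vel=np.zeros((n, d)),
        female_fit=female_fit,
        gbest=all_pos[best].copy(),
        gbest_fit=float(all_fit[best]),
        rng=rng,
        dance_scale=params.dance,
    )


def _refresh_gbest(state: MayflyState, positions: np.ndarray, fits: np.ndarray) -> None:
    best = int(np.argmax(fits))
    if fits[best] > state.gbest_fit:
        state.gbest_fit = float(fits[best])
        state.gbest = positions[best].copy()


def male_update(state: MayflyState, objective: Objective, params: MayflyParams) -> MayflyState:
    """One male move: damped attraction to pbest/gbest, dance for the leader."""
    P, V = state.males, state.male_vel
    dp = np.linalg.norm(P - state.pbest, axis=1)
    dg = np.linalg.norm(P - state.gbest, axis=1)
    attract = (
        params.c1 * np.exp(-params.beta * dp**2)[:, None] * (state.pbest - P)
        + params.c2 * np.exp(-params.beta * dg**2)[:, None] * (state.gbest - P)
    )
    best = int(np.argmax(state.male_fit))
    attract[best] = state.dance_scale * state.rng.uniform(-1.0, 1.0, size=P.shape[1])
    V += attract
    P += V
    _clamp(P, V, params)
    state.male_fit = _evaluate(objective, P)
    improved = state.male_fit > state.pbest_fit
    state.pbest[improved] = P[improved]
    state.pbest_fit[improved] = state.male_fit[improved]
    _refresh_gbest(state, P, state.male_fit)
    return state


def _rank_pairs(state: MayflyState) -> tuple[np.ndarray, np.ndarray]:
    """Pair sexes by fitness rank, best-to-best."""
    m_order = np.argsort(-state.male_fit, kind="stable")
    f_order = np.argsort(-state.female_fit, kind="stable")
    return m_order, f_order


def female_update(state: MayflyState, objective: Objective, params: MayflyParams) -> MayflyState:
    """One female move: attraction to the paired male if he is strictly better,
    otherwise a random walk with the (decaying) dance step scale."""
    m_order, f_order = _rank_pairs(state)
    P, V = state.females, state.female_vel
    d = P.shape[1]
    for m_i, f_i in zip(m_order, f_order):
        if state.male_fit[m_i] > state.female_fit[f_i]:
            diff = state.males[m_i] - P[f_i]
            dmf = np.linalg.norm(diff)
            V[f_i] += params.c2 * np.exp(-params.beta * dmf**2) * diff
        else:
            V[f_i] += state.dance_scale * state.rng.uniform(-1.0, 1.0, size=d)
    P += V
    _clamp(P, V, params)
    state.female_fit = _evaluate(objective, P)
    _refresh_gbest(state, P, state.female_fit)
    return state


def mate(state: MayflyState, objective: Objective, params: MayflyParams) -> MayflyState:
    """Rank-paired uniform crossover; offspring replace the worst same-sex
    individuals when strictly better (elitist replacement)."""
    m_order, f_order = _rank_pairs(state)
    L = state.rng.uniform(0.0, 1.0, size=(len(m_order), state.males.shape[1]))
    sires = state.males[m_order]
    dams = state.females[f_order]
    off_m = L * sires + (1.0 - L) * dams
    off_f = (1.0 - L) * sires + L * dams
    off_m_fit = _evaluate(objective, off_m)
    off_f_fit = _evaluate(objective, off_f)

    for off, fit in ((off_m, off_m_fit), (off_f, off_f_fit)):
        _refresh_gbest(state, off, fit)

    order = np.argsort(-off_m_fit, kind="stable")
    for idx in order:
        worst = int(np.argmin(state.male_fit))
        if off_m_fit[idx] > state.male_fit[worst]:
            state.males[worst] = off_m[idx]
            state.male_vel[worst] = 0.0
            state.male_fit[worst] = off_m_fit[idx]
            if off_m_fit[idx] > state.pbest_fit[worst]:
                state.pbest[worst] = off_m[idx]
                state.pbest_fit[worst] = off_m_fit[idx]
        else:
            break
    order = np.argsort(-off_f_fit, kind="stable")
    for idx in order:
        worst = int(np.argmin(state.female_fit))
        if off_f_fit[idx] > state.female_fit[worst]:
            state.females[worst] = off_f[idx]
            state.female_vel[worst] = 0.0
            state.female_fit[worst] = off_f_fit[idx]
        else:
            break
    return state


def optimize(
    objective: Objective,
    params: MayflyParams,
    callback: Optional[Callable[[MayflyState], None]] = None,
) -> MayflyResult:
    """Run init -> loop{male_update; female_update; mate} for ``max_iter``
    iterations and return the global best with its best-so-far trace."""
    state = init_state(objective, params)
    trace = np.empty(params.max_iter)
    for t in range(params.max_iter):
        state.iteration = t
        male_update(state, objective, params)
        female_update(state, objective, params)
        mate(state, objective, params)
        state.dance_scale *= params.dance_decay
        trace[t] = state.gbest_fit
        if callback is not None:
            callback(state)
    return MayflyResult(position=state.gbest.copy(), value=state.gbest_fit, trace=trace)
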