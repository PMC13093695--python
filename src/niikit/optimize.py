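"""Hybrid Nelder-Mead / particle-swarm global minimizer and a grid-search oracle.

The hybrid scheme runs a constriction-coefficient particle swarm over a
bounded box and periodically refines the swarm's best point with a bounded
Nelder-Mead simplex; a final simplex polish is applied before returning.
A single seeded run is the contract: the global phase removes the need for
multiple randomly initialised restarts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SwarmConfig",
    "HybridResult",
    "OptimizationError",
    "minimize_hybrid",
    "grid_oracle",
    "benchmark_suite",
]


class OptimizationError(RuntimeError):
    pass


@dataclass
class SwarmConfig:
    """PSO + simplex hybrid settings (constriction defaults: Clerc-Kennedy)."""

    n_particles: int = 40
    n_iterations: int = 200
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    nm_period: int = 10       # iterations between simplex refinements of the best
    nm_max_evals: int = 200
    tol: float = 1e-8         # stagnation tolerance on the best objective
    patience: int = 20        # iterations of sub-tol improvement before stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class HybridResult:
    x: np.ndarray
    fun: float
    nfev: int

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.x, self.fun, self.nfev))


def _reflect(x: np.ndarray, v: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Reflect positions at box faces, flipping the offending velocity."""
    for _ in range(8):
        below, above = x < lo, x > hi
        if not (below.any() or above.any()):
            return x, v
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
        v = np.where(below | above, -v, v)
    return np.clip(x, lo, hi), v


def minimize_hybrid(objective, bounds, config: SwarmConfig | None = None,
                    init_points: np.ndarray | None = None) -> HybridResult:
    """Globally minimize ``objective`` over a box; deterministic per seed.

    ``init_points`` (k x p) are clamped into the box and replace the first k
    random particles — used to seed the swarm with domain-informed starts.
    """
    if config is None:
        config = SwarmConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a (p, 2) array of (lo, hi) pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not (np.all(np.isfinite(bounds)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with lo < hi")
    p = bounds.shape[0]

    nfev = 0

    def f(x: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        val = float(objective(np.asarray(x, dtype=float)))
        if not np.isfinite(val):
            raise OptimizationError(f"non-finite objective {val} at {x}")
        return val

    rng = np.random.default_rng(config.seed)
    span = hi - lo
    pos = lo + rng.uniform(size=(config.n_particles, p)) * span
    if init_points is not None:
        init_points = np.atleast_2d(np.asarray(init_points, dtype=float))
        k = min(init_points.shape[0], config.n_particles)
        pos[:k] = np.clip(init_points[:k], lo, hi)
    vel = rng.uniform(-0.1, 0.1, size=(config.n_particles, p)) * span
    pcost = np.array([f(x) for x in pos])
    pbest, pbest_cost = pos.copy(), pcost.copy()
    gi = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[gi].copy(), float(pbest_cost[gi])

    def nm_refine(x0: np.ndarray, budget: int) -> None:
        nonlocal gbest, gbest_cost
        res = minimize(
            f, x0, method="Nelder-Mead",
            bounds=[(l, h) for l, h in bounds],
            options={"maxfev": budget, "xatol": 1e-10, "fatol": 1e-12},
        )
        if res.fun < gbest_cost:
            gbest, gbest_cost = np.clip(res.x, lo, hi), float(res.fun)

    stall = 0
    for it in range(config.n_iterations):
        r1 = rng.uniform(size=(config.n_particles, p))
        r2 = rng.uniform(size=(config.n_particles, p))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest - pos))
        pos, vel = _reflect(pos + vel, vel, lo, hi)
        cost = np.array([f(x) for x in pos])
        improved = cost < pbest_cost
        pbest[improved], pbest_cost[improved] = pos[improved], cost[improved]
        prev_best = gbest_cost
        gi = int(np.argmin(pbest_cost))
        if pbest_cost[gi] < gbest_cost:
            gbest, gbest_cost = pbest[gi].copy(), float(pbest_cost[gi])
        if (it + 1) % config.nm_period == 0:
            nm_refine(gbest, config.nm_max_evals)
        stall = stall + 1 if prev_best - gbest_cost < config.tol else 0
        if stall >= config.patience:
            break
    for _ in range(3):  # final polish, repeated while it still helps
        prev = gbest_cost
        nm_refine(gbest, 2 * config.nm_max_evals)
        if prev - gbest_cost < config.tol:
            break
    return HybridResult(x=gbest, fun=gbest_cost, nfev=nfev)


def grid_oracle(objective, bounds, points_per_dim: int):
    """Exhaustive lattice search; exact lattice minimum. Guard: p <= 4."""
    bounds = np.asarray(bounds, dtype=float)
    p = bounds.shape[0]
    if p > 4:
        raise ValueError(f"grid_oracle refuses dimension {p} > 4")
    axes = [np.linspace(lo, hi, points_per_dim) for lo, hi in bounds]
    best_x, best_val = None, np.inf
    for point in itertools.product(*axes):
        val = float(objective(np.asarray(point)))
        if val < best_val:
            best_x, best_val = np.asarray(point), val
    return best_x, best_val


def benchmark_suite() -> list[tuple]:
    """Five 2-D multimodal test objectives as (name, fn, bounds) triples."""

    def double_well(x):
        g1 = np.exp(-np.sum((x - np.array([0.2, 0.3])) ** 2) / 0.01)
        g2 = np.exp(-np.sum((x - np.array([0.75, 0.8])) ** 2) / 0.01)
        return -(0.6 * g1 + 1.0 * g2)

    def rastrigin(x):
        z = 10.0 * (x - 0.5)
        return float(20 + np.sum(z * z - 10 * np.cos(2 * np.pi * z)))

    def ackley(x):
        z = 8.0 * (x - 0.4)
        return float(-20 * np.exp(-0.2 * np.sqrt(np.mean(z * z)))
                     - np.exp(np.mean(np.cos(2 * np.pi * z))) + 20 + np.e)

    def himmelblau(x):
        u, v = 10.0 * x - 5.0
        return float((u * u + v - 11) ** 2 + (u + v * v - 7) ** 2)

    def eggcrate(x):
        u, v = 8.0 * (x - 0.5)
        return float(u * u + v * v + 25 * (np.sin(u) ** 2 + np.sin(v) ** 2))

    box = [(0.0, 1.0), (0.0, 1.0)]
    return [
        ("double_well", double_well, box),
        ("rastrigin", rastrigin, box),
        ("ackley", ackley, box),
        ("himmelblau", himmelblau, box),
        ("eggcrate", eggcrate, box),
    ]
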