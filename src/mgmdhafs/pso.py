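"""Canonical global-best particle swarm optimization.

Velocity update: v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x), with
positions clipped to the search box after every move.  Defaults (swarm 30,
100 iterations, inertia 0.72, c1 = c2 = 1.49) are the standard
constriction-equivalent settings.  Fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PsoConfig:
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds: tuple = (-10.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if not 0.0 <= self.inertia <= 1.0:
            raise ValueError("inertia must be in [0,1]")
        if self.cognitive <= 0 or self.social <= 0:
            raise ValueError("c1 and c2 must be positive")
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be a finite (low, high) pair")


@dataclass
class PsoResult:
    x: np.ndarray
    value: float
    n_iterations: int
    history: np.ndarray = field(repr=False)  # best value per iteration


def pso_maximize(objective, dim: int, config: PsoConfig | None = None,
                 rng: np.random.Generator | None = None,
                 initial_positions: np.ndarray | None = None) -> PsoResult:
    """Maximize a batched objective f(positions: m x dim) -> (m,) over a box.

    *initial_positions* (k x dim, k <= swarm size) seeds the first k particles
    (warm starts); the rest are drawn uniformly from the box.
    """
    cfg = config or PsoConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    span = hi - lo
    m = cfg.swarm_size
    x = rng.uniform(lo, hi, size=(m, dim))
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, dtype=float))[:m]
        x[: len(seeds)] = np.clip(seeds, lo, hi)
    v = rng.uniform(-0.1 * span, 0.1 * span, size=(m, dim))
    fitness = np.asarray(objective(x), dtype=float)
    pbest_x = x.copy()
    pbest_f = fitness.copy()
    g = int(np.argmax(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    history = np.empty(cfg.iterations)
    for t in range(cfg.iterations):
        r1 = rng.uniform(size=(m, dim))
        r2 = rng.uniform(size=(m, dim))
        v = (cfg.inertia * v
             + cfg.cognitive * r1 * (pbest_x - x)
             + cfg.social * r2 * (gbest_x[None, :] - x))
        x = np.clip(x + v, lo, hi)
        fitness = np.asarray(objective(x), dtype=float)
        improved = fitness > pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fitness[improved]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history[t] = gbest_f
    return PsoResult(gbest_x, gbest_f, cfg.iterations, history)
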