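"""Seeded particle swarm optimizer over box bounds.

Standard inertia-weight PSO (Shi-Eberhart style coefficients) with
reflecting bounds and a mandatory seed.  The objective is evaluated on the
whole swarm at once, so callers supply a vectorized function mapping an
``(n_particles, n_dims)`` position matrix to ``(n_particles,)`` values.
The global best over every evaluated position is returned, and any
caller-supplied initial point is injected as a particle, so the result can
never fall below the initializer's objective value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PSOConfig", "pso_maximize"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters.

    Defaults (swarm 40, inertia 0.72, cognitive = social = 1.49,
    300 iterations) are the usual constriction-equivalent settings.
    """

    n_particles: int = 40
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    n_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_particles < 2 or self.n_iter < 1:
            raise ValueError("need >= 2 particles and >= 1 iteration")


def pso_maximize(
    objective,
    bounds,
    seed: int,
    config: PSOConfig = PSOConfig(),
    init: np.ndarray | None = None,
):
    """Maximize ``objective`` over a box.

    Parameters
    ----------
    objective
        Callable mapping positions ``(n_particles, d)`` -> values ``(n_particles,)``.
    bounds
        Sequence of (low, high) per dimension; low < high required.
    seed
        Seed for the swarm's random number generator (mandatory).
    init
        Optional starting point injected as particle 0 (clipped to bounds).

    Returns
    -------
    (x_best, f_best) : best position found and its objective value.
    """
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("infeasible bounds: low >= high")
    d = lo.size
    rng = np.random.default_rng(seed)
    n = config.n_particles

    x = rng.uniform(lo, hi, size=(n, d))
    if init is not None:
        x[0] = np.clip(np.asarray(init, dtype=float), lo, hi)
    span = hi - lo
    v = rng.uniform(-0.1, 0.1, size=(n, d)) * span

    f = np.asarray(objective(x), dtype=float)
    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmax(f))
    gbest_x = x[g].copy()
    gbest_f = float(f[g])

    for _ in range(config.n_iter):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        x = x + v
        # reflect at the box walls, flipping the velocity component
        under = x < lo
        over = x > hi
        x = np.where(under, 2 * lo - x, x)
        x = np.where(over, 2 * hi - x, x)
        v = np.where(under | over, -v, v)
        x = np.clip(x, lo, hi)  # guards double reflections on wide steps

        f = np.asarray(objective(x), dtype=float)
        better = f > pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()

    return gbest_x, gbest_f
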