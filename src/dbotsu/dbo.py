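"""Dung Beetle Optimizer (DBO).

A population metaheuristic with four behavioral roles.  Rollers move along a
light-guided direction (or perform a reorientation dance when blocked),
breeders lay eggs inside a shrinking region around the current iteration's
best position, foragers explore a shrinking region around the global best,
and thieves raid the neighborhood of the global best.  Moves are accepted
greedily per agent, so the best-fitness trace is non-increasing.

All update rules are exposed as free functions so each can be unit-tested in
isolation; :func:`run_dbo` wires them into the main loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DBOParams",
    "DBOResult",
    "role_counts",
    "select_alpha",
    "roll_update",
    "dance_update",
    "spawn_bounds",
    "breeding_update",
    "forage_bounds",
    "forager_update",
    "thief_update",
    "run_dbo",
]

# role order is fixed: rollers, breeders, foragers ("small" beetles), thieves
DEFAULT_ROLE_FRACTIONS = (0.20, 0.20, 0.25, 0.35)

_ANGLE_TOL = 1e-12


@dataclass
class DBOParams:
    """Tunable parameters of the optimizer.

    Defaults follow the standard published setting: population 60, 200
    iterations, role split 20/20/25/35 %, deflection coefficient k = 0.1,
    rolling constant b = 0.3, thief scale S = 0.5.  ``bounds_convention``
    selects the spawning/foraging upper-bound formula: ``"corrected"`` uses
    X*(1+R) (the usable form), ``"as_printed"`` uses X*(1-R) for both bounds,
    which collapses the interval and is kept only for auditing.
    """

    dim: int
    lb: float = 1.0
    ub: float = 256.0
    n: int = 60
    t_max: int = 200
    role_fractions: tuple = DEFAULT_ROLE_FRACTIONS
    k: float = 0.1
    b: float = 0.3
    s: float = 0.5
    delta_threshold: float = 0.9  # roll-vs-dance probability split
    alpha_prob: float = 0.5  # probability l in the alpha-selection rule
    bounds_convention: str = "corrected"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("population size must be at least 4")
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")
        if not 0.0 < self.k <= 0.2:
            raise ValueError("deflection coefficient k must lie in (0, 0.2]")
        if not 0.0 < self.b < 1.0:
            raise ValueError("constant b must lie in (0, 1)")
        if abs(sum(self.role_fractions) - 1.0) > 1e-9:
            raise ValueError("role fractions must sum to 1")
        if self.bounds_convention not in ("corrected", "as_printed"):
            raise ValueError("bounds_convention must be 'corrected' or 'as_printed'")
        if not np.all(np.asarray(self.lb) <= np.asarray(self.ub)):
            raise ValueError("lb must not exceed ub")


@dataclass
class DBOResult:
    best_x: np.ndarray
    best_f: float
    trace: np.ndarray  # best fitness after initialization and each iteration

    def trace_to_csv(self, path) -> None:
        arr = np.column_stack([np.arange(self.trace.size), self.trace])
        np.savetxt(
            path, arr, delimiter=",", header="iteration,best_fitness", comments=""
        )


def role_counts(n: int, fractions=DEFAULT_ROLE_FRACTIONS) -> tuple:
    """Integer role counts summing exactly to ``n`` (largest-remainder rounding)."""
    raw = [n * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return tuple(counts)


def select_alpha(l: float, rng: np.random.Generator) -> int:
    """Natural-coefficient selection: draw h ~ U(0,1); alpha = +1 if h > l else -1."""
    return 1 if rng.random() > l else -1


def roll_update(x_t, x_prev, x_worst, alpha: int, k: float, b: float) -> np.ndarray:
    """Rolling move: x(t+1) = x(t) + alpha*k*x(t-1) + b*|x(t) - X_worst|."""
    x_t = np.asarray(x_t, dtype=float)
    dx = np.abs(x_t - np.asarray(x_worst, dtype=float))
    return x_t + alpha * k * np.asarray(x_prev, dtype=float) + b * dx


def dance_update(x_t, x_prev, theta: float) -> np.ndarray:
    """Reorientation dance: x(t+1) = x(t) + tan(theta)*|x(t) - x(t-1)|.

    Angles of exactly 0, pi/2 or pi (within 1e-12) leave the position
    unchanged, so a vertical tangent never produces an overflow.
    """
    x_t = np.asarray(x_t, dtype=float)
    for special in (0.0, math.pi / 2.0, math.pi):
        if abs(theta - special) <= _ANGLE_TOL:
            return x_t.copy()
    return x_t + math.tan(theta) * np.abs(x_t - np.asarray(x_prev, dtype=float))


def _shrinking_bounds(center, r: float, lb, ub, convention: str):
    center = np.asarray(center, dtype=float)
    lo = np.maximum(center * (1.0 - r), lb)
    if convention == "corrected":
        hi = np.minimum(center * (1.0 + r), ub)
    else:  # as printed: both bounds use (1 - R)
        hi = np.minimum(center * (1.0 - r), ub)
    # guard against inverted intervals (possible for negative centers or the
    # as-printed convention)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return lo, hi


def spawn_bounds(x_star, t: int, params: DBOParams):
    """Spawning-area bounds around the current local best; R = 1 - t/T_max."""
    r = 1.0 - t / params.t_max if params.t_max > 0 else 0.0
    return _shrinking_bounds(x_star, r, params.lb, params.ub, params.bounds_convention)


def forage_bounds(x_best, t: int, params: DBOParams):
    """Foraging-area bounds around the global best; same structure as spawning."""
    r = 1.0 - t / params.t_max if params.t_max > 0 else 0.0
    return _shrinking_bounds(x_best, r, params.lb, params.ub, params.bounds_convention)


def breeding_update(b_i, x_star, lo, hi, rng: np.random.Generator) -> np.ndarray:
    """Breeding-ball move, clamped into the spawning area [lo, hi]."""
    b_i = np.asarray(b_i, dtype=float)
    d = b_i.shape[-1] if b_i.ndim else 1
    b1 = rng.random(d)
    b2 = rng.random(d)
    new = np.asarray(x_star, dtype=float) + b1 * (b_i - lo) + b2 * (b_i - hi)
    return np.clip(new, lo, hi)


def forager_update(x_t, lo, hi, rng: np.random.Generator) -> np.ndarray:
    """Forager move: x + C1*(x - lo) + C2*(x - hi), C1 ~ N(0,1) scalar, C2 ~ U(0,1)^D."""
    x_t = np.asarray(x_t, dtype=float)
    d = x_t.shape[-1] if x_t.ndim else 1
    c1 = rng.standard_normal()
    c2 = rng.random(d)
    return x_t + c1 * (x_t - lo) + c2 * (x_t - hi)


def thief_update(x_t, x_best, x_star, s: float, rng: np.random.Generator) -> np.ndarray:
    """Thief move: X_best + S*g*(|x - X*| + |x - X_best|), g ~ N(0,1)^D."""
    x_t = np.asarray(x_t, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    d = x_t.shape[-1] if x_t.ndim else 1
    g = rng.standard_normal(d)
    return x_best + s * g * (np.abs(x_t - np.asarray(x_star, dtype=float)) + np.abs(x_t - x_best))


def run_dbo(objective, params: DBOParams) -> DBOResult:
    """Minimize ``objective`` over [lb, ub]^dim.

    ``objective`` maps a 1-D position vector to a scalar; non-finite values
    are treated as +inf (the move is rejected).  Every proposed position is
    clamped to the global bounds, and a move is kept only if it improves the
    agent's own fitness.  Returns the global best and the per-iteration trace
    of the best fitness (length t_max + 1, including the initial population).
    """
    rng = np.random.default_rng(params.seed)
    n, d = params.n, params.dim
    lb = np.broadcast_to(np.asarray(params.lb, dtype=float), (d,))
    ub = np.broadcast_to(np.asarray(params.ub, dtype=float), (d,))

    def evaluate(x: np.ndarray) -> float:
        v = float(objective(x))
        return v if math.isfinite(v) else math.inf

    positions = rng.uniform(lb, ub, size=(n, d))
    prev = positions.copy()
    fitness = np.array([evaluate(x) for x in positions])

    counts = role_counts(n, params.role_fractions)
    roles = np.repeat(np.arange(4), counts)  # 0 roll, 1 breed, 2 forage, 3 thieve

    best_i = int(np.argmin(fitness))
    worst_i = int(np.argmax(fitness))
    x_best = positions[best_i].copy()
    f_best = float(fitness[best_i])
    x_worst = positions[worst_i].copy()
    f_worst = float(fitness[worst_i])
    x_star = x_best.copy()  # best of the current iteration's population

    trace = [f_best]
    for t in range(1, params.t_max + 1):
        old = positions.copy()
        spawn_lo, spawn_hi = spawn_bounds(x_star, t, params)
        forage_lo, forage_hi = forage_bounds(x_best, t, params)
        for i in range(n):
            role = roles[i]
            if role == 0:
                delta = rng.random()
                if delta < params.delta_threshold:
                    alpha = select_alpha(params.alpha_prob, rng)
                    new = roll_update(old[i], prev[i], x_worst, alpha, params.k, params.b)
                else:
                    theta = rng.uniform(0.0, math.pi)
                    new = dance_update(old[i], prev[i], theta)
            elif role == 1:
                new = breeding_update(old[i], x_star, spawn_lo, spawn_hi, rng)
            elif role == 2:
                new = forager_update(old[i], forage_lo, forage_hi, rng)
            else:
                new = thief_update(old[i], x_best, x_star, params.s, rng)
            new = np.clip(new, lb, ub)
            f_new = evaluate(new)
            if f_new < fitness[i]:  # greedy per-agent acceptance
                positions[i] = new
                fitness[i] = f_new
        prev = old

        it_best = int(np.argmin(fitness))
        x_star = positions[it_best].copy()
        if fitness[it_best] < f_best:
            f_best = float(fitness[it_best])
            x_best = positions[it_best].copy()
        it_worst = int(np.argmax(fitness))
        if fitness[it_worst] > f_worst:
            f_worst = float(fitness[it_worst])
            x_worst = positions[it_worst].copy()
        trace.append(f_best)

    return DBOResult(best_x=x_best, best_f=f_best, trace=np.asarray(trace))
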