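"""Whale optimization algorithm with an improved (cubic) convergence factor.

WOA is a population metaheuristic for bounded black-box minimization.  Each
candidate ("whale") updates its position each iteration by one of three
moves, chosen by a per-whale draw p ~ U[0,1) and the magnitude of the
coefficient vector A = 2 a r - a (r ~ U[0,1) per dimension):

* p < 0.5, |A| < 1  — encircling: X <- X* - A |C X* - X|          (exploit)
* p < 0.5, |A| >= 1 — random search: X <- Xr - A |C Xr - X|       (explore)
* p >= 0.5          — log-spiral around the best: X <- |X*-X| e^{bl} cos(2 pi l) + X*

with C = 2 r', l ~ U(-1,1), X* the best-so-far position and Xr a random
whale.  The convergence factor a controls the explore/exploit balance; the
classic schedule decays linearly from 2 to 0.  The improved variant decays
cubically,

    a(t) = (a_init - a_final) * ((T_max - t) / T_max)^3,

which shrinks a faster in early iterations (stronger pull toward promising
regions) while flattening near the end (finer local search).

Search-space conveniences: per-dimension integer rounding (applied when
evaluating fitness; positions stay continuous) and log10-scaled dimensions
(e.g. learning rates), both handled transparently by :func:`optimize`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceSchedule",
    "SearchSpace",
    "IWOAConfig",
    "Whale",
    "MoveContext",
    "convergence_factor",
    "update_position",
    "optimize",
    "OptimizeResult",
]


class ConvergenceSchedule(str, Enum):
    LINEAR = "linear"
    CUBIC = "cubic"


@dataclass(frozen=True)
class SearchSpace:
    """Box constraints with per-dimension integer / log10 handling.

    ``log_scale_mask`` dimensions are searched in log10 space: bounds given
    here are on the original scale and are transformed internally; decoded
    values are exponentiated back.  ``integer_mask`` dimensions are rounded
    at decode time.
    """

    lower: np.ndarray
    upper: np.ndarray
    integer_mask: np.ndarray | None = None
    log_scale_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not np.all(hi > lo):
            raise ValueError("upper bounds must exceed lower bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        for name in ("integer_mask", "log_scale_mask"):
            m = getattr(self, name)
            m = np.zeros(lo.size, bool) if m is None else np.asarray(m, bool)
            if m.shape != lo.shape:
                raise ValueError(f"{name} length mismatch")
            object.__setattr__(self, name, m)
        if np.any(self.log_scale_mask & (lo <= 0)):
            raise ValueError("log-scaled dimensions need positive lower bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.where(self.log_scale_mask,
                      np.log10(np.where(self.log_scale_mask, self.lower, 1.0)), self.lower)
        hi = np.where(self.log_scale_mask,
                      np.log10(np.where(self.log_scale_mask, self.upper, 1.0)), self.upper)
        return lo, hi

    def decode(self, position: np.ndarray) -> np.ndarray:
        """Internal position -> original-scale values (de-logged, rounded)."""
        x = np.where(self.log_scale_mask, 10.0 ** np.asarray(position, float), position)
        return np.where(self.integer_mask, np.round(x), x)

    def encode(self, values: np.ndarray) -> np.ndarray:
        """Original-scale values -> internal position, clipped to bounds."""
        v = np.asarray(values, float)
        x = np.where(self.log_scale_mask,
                     np.log10(np.where(self.log_scale_mask, np.maximum(v, 1e-300), 1.0)), v)
        lo, hi = self.internal_bounds()
        return np.clip(x, lo, hi)


@dataclass(frozen=True)
class IWOAConfig:
    pop_size: int = 50
    t_max: int = 200
    a_init: float = 2.0
    a_final: float = 0.0
    spiral_b: float = 1.0
    convergence: ConvergenceSchedule = ConvergenceSchedule.CUBIC
    seed: int = 0
    fitness_tol: float | None = None  # optional early-stop absolute fitness

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not (self.a_init > self.a_final):
            raise ValueError("a_init must exceed a_final")


@dataclass
class Whale:
    position: np.ndarray
    fitness: float = math.inf


@dataclass(frozen=True)
class MoveContext:
    """Per-whale per-iteration stochastic coefficients."""

    a: float
    A: np.ndarray
    C: np.ndarray
    l: float
    p: float


def convergence_factor(t: int, config: IWOAConfig) -> float:
    """a(t): linear decay or the improved cubic decay.

    linear: a = a_init - (a_init - a_final) * t / T_max
    cubic:  a = (a_init - a_final) * ((T_max - t)/T_max)^3
    """
    if not (0 <= t <= config.t_max):
        raise ValueError("iteration out of range")
    frac = t / config.t_max
    if config.convergence == ConvergenceSchedule.LINEAR:
        return config.a_init - (config.a_init - config.a_final) * frac
    return (config.a_init - config.a_final) * (1.0 - frac) ** 3


def _draw_context(a: float, dim: int, rng: np.random.Generator) -> MoveContext:
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return MoveContext(
        a=a,
        A=2.0 * a * r1 - a,
        C=2.0 * r2,
        l=rng.uniform(-1.0, 1.0),
        p=rng.random(),
    )


def update_position(whale: Whale, best: Whale, random_whale: Whale,
                    ctx: MoveContext, config: IWOAConfig,
                    lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """One WOA move (encircle / random search / spiral), clipped to bounds."""
    x = whale.position
    if x.shape != best.position.shape or x.shape != random_whale.position.shape:
        raise ValueError("dimension mismatch")
    if ctx.p < 0.5:
        ref = best.position if np.linalg.norm(ctx.A) < 1.0 else random_whale.position
        new = ref - ctx.A * np.abs(ctx.C * ref - x)
    else:
        dist = np.abs(best.position - x)
        new = dist * np.exp(config.spiral_b * ctx.l) * np.cos(2.0 * np.pi * ctx.l) \
            + best.position
    return np.clip(new, lower, upper)


@dataclass(frozen=True)
class OptimizeResult:
    best_position: np.ndarray   # original-scale, decoded
    best_fitness: float
    history: np.ndarray         # best-so-far fitness per iteration
    n_evaluations: int


def optimize(fitness: Callable[[np.ndarray], float], space: SearchSpace,
             config: IWOAConfig = IWOAConfig(),
             initial_guesses: Sequence[np.ndarray] | None = None) -> OptimizeResult:
    """Minimize *fitness* over *space* with (I)WOA.

    The fitness function receives decoded, original-scale vectors (integer
    dimensions rounded, log dimensions exponentiated).  Non-finite fitness
    values are treated as +inf with a warning.  Fully deterministic for a
    fixed config seed.

    ``initial_guesses`` (original-scale vectors) warm-start the population:
    each replaces one randomly initialized whale.  Seeding the swarm with a
    known-reasonable configuration is standard practice when the budget is
    small; the search can only improve on it in fitness terms.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = space.internal_bounds()
    dim = space.dim

    def safe_eval(pos: np.ndarray) -> float:
        val = fitness(space.decode(pos))
        if not np.isfinite(val):
            logger.warning("non-finite fitness at %s; treating as +inf", pos)
            return math.inf
        return float(val)

    pop = [Whale(position=lo + (hi - lo) * rng.random(dim)) for _ in range(config.pop_size)]
    for i, guess in enumerate(initial_guesses or []):
        if i >= config.pop_size:
            break
        pop[i] = Whale(position=space.encode(np.asarray(guess, float)))
    n_eval = 0
    for w in pop:
        w.fitness = safe_eval(w.position)
        n_eval += 1
    best = min(pop, key=lambda w: w.fitness)
    best = Whale(position=best.position.copy(), fitness=best.fitness)

    history = []
    for t in range(1, config.t_max + 1):
        a = convergence_factor(t, config)
        for i, w in enumerate(pop):
            ctx = _draw_context(a, dim, rng)
            j = int(rng.integers(config.pop_size))
            w.position = update_position(w, best, pop[j], ctx, config, lo, hi)
            w.fitness = safe_eval(w.position)
            n_eval += 1
            if w.fitness < best.fitness:
                best = Whale(position=w.position.copy(), fitness=w.fitness)
        history.append(best.fitness)
        if config.fitness_tol is not None and best.fitness <= config.fitness_tol:
            break

    return OptimizeResult(
        best_position=space.decode(best.position),
        best_fitness=best.fitness,
        history=np.asarray(history),
        n_evaluations=n_eval,
    )
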