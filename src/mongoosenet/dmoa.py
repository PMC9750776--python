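"""Dwarf Mongoose Optimization Algorithm (DMOA).

A population-based metaheuristic modelled on the foraging behaviour of
dwarf mongoose packs.  Each candidate solution is a "mongoose"; the pack
alternates between an *alpha* (exploitation) phase, in which members take
steps scaled by the vocalization ("peep") of the alpha female, and a
*scout* (exploration) phase searching for the next sleeping mound, in
which members move relative to the pack movement vector with a step size
that decays over the run; periodically the *babysitter exchange* returns
the worst pack members to the search as fresh random solutions.  Acceptance is greedy: a move
is kept only if it lowers the fitness, so the best-so-far fitness is
non-increasing by construction.

Used in this package to minimise the mean-squared classification error
of the fire-module network over its flat weight vector, but the
optimizer is a general box-constrained black-box minimizer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "fitness_mse",
    "alpha_probabilities",
    "sleeping_mound",
    "average_sleeping_mound",
    "control_factor",
    "movement_vector",
    "alpha_phase_update",
    "scout_phase_update",
    "MongoosePopulation",
    "FitnessRecord",
    "DwarfMongooseOptimizer",
]

FitnessFn = Callable[[np.ndarray], float]


def fitness_mse(predicted: np.ndarray, expected: np.ndarray) -> float:
    """Mean squared error between predicted scores and expected outcomes.

    ``predicted`` is the network's abnormal-class probability (or any real
    score), ``expected`` the 0/1 reference label.
    """
    predicted = np.asarray(predicted, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if predicted.shape != expected.shape:
        raise ValueError(
            f"length mismatch: predicted has shape {predicted.shape}, "
            f"expected has shape {expected.shape}"
        )
    if predicted.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((expected - predicted) ** 2))


def alpha_probabilities(fitness: np.ndarray, weighting: str = "printed") -> np.ndarray:
    """Selection probabilities for the alpha female.

    ``weighting="printed"`` normalises raw fitness values (k_p = b_p / sum b),
    which under minimisation gives *worse* solutions more weight; it is kept
    as the default for fidelity to the published update rule.
    ``weighting="inverted"`` uses max(b) - b + eps so better solutions are
    favoured.  A degenerate all-zero fitness vector (perfect population)
    yields uniform probabilities.
    """
    b = np.asarray(fitness, dtype=float)
    if b.ndim != 1 or b.size < 1:
        raise ValueError("fitness must be a non-empty 1-D vector")
    if np.any(b < 0):
        raise ValueError("fitness values must be non-negative")
    if weighting == "inverted":
        w = b.max() - b + 1e-12
    elif weighting == "printed":
        w = b
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = w.sum()
    if total == 0:
        warnings.warn("all fitness values are zero; using uniform alpha probabilities")
        return np.full(b.size, 1.0 / b.size)
    return w / total


def sleeping_mound(prev_fitness: np.ndarray, new_fitness: np.ndarray) -> np.ndarray:
    """Per-mongoose normalised fitness change L_r in [-1, 1].

    L_r,p = (b_new,p - b_prev,p) / max_p |b_new,p - b_prev,p|; if every
    difference is zero the defined limit is the zero vector.
    """
    prev = np.asarray(prev_fitness, dtype=float)
    new = np.asarray(new_fitness, dtype=float)
    if prev.shape != new.shape:
        raise ValueError("fitness vectors must have equal length")
    diff = new - prev
    scale = np.max(np.abs(diff)) if diff.size else 0.0
    if scale == 0.0:
        return np.zeros_like(diff)
    return diff / scale


def average_sleeping_mound(mounds: np.ndarray) -> float:
    """Population average of the sleeping-mound values (the quantity ω)."""
    m = np.asarray(mounds, dtype=float)
    if m.size == 0:
        raise ValueError("empty mound vector")
    return float(m.mean())


def control_factor(iteration: int, max_iterations: int) -> float:
    """Decaying exploration factor D = (1 - U/HU)^(2·U/HU).

    Equals 1 at the first iteration and 0 at the last.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not 0 <= iteration <= max_iterations:
        raise ValueError("iteration must lie in [0, max_iterations]")
    frac = iteration / max_iterations
    return float((1.0 - frac) ** (2.0 * frac))


def movement_vector(solutions: np.ndarray, mounds: np.ndarray) -> np.ndarray:
    """Pack movement vector S = Σ_p (s_p ⊙ L_r,p) / s_p, element-wise.

    Where a component of s_p is exactly zero the term contributes zero,
    keeping the vector finite.
    """
    s = np.atleast_2d(np.asarray(solutions, dtype=float))
    m = np.asarray(mounds, dtype=float)
    if s.shape[0] != m.size:
        raise ValueError("one mound value per solution required")
    terms = np.where(s != 0.0, m[:, None], 0.0)
    return terms.sum(axis=0)


@dataclass
class FitnessRecord:
    """One row of the convergence trace."""

    iteration: int
    best: float
    mean: float
    phase: str


@dataclass
class MongoosePopulation:
    """State of the pack during an optimization run."""

    solutions: np.ndarray            # (t, W)
    fitness: np.ndarray              # (t,)
    best_solution: np.ndarray        # (W,)
    best_fitness: float
    lower: np.ndarray
    upper: np.ndarray
    mounds: np.ndarray | None = None
    omega: float = 0.0
    iteration: int = 0
    max_iterations: int = 0
    babysitter_count: int = 0
    babysitter_counter: int = 0
    n_evaluations: int = 0

    @property
    def size(self) -> int:
        return self.solutions.shape[0]

    def _evaluate(self, fitness_fn: FitnessFn, x: np.ndarray, index: int) -> float:
        try:
            f = float(fitness_fn(x))
        except Exception as exc:  # re-raise with the offending solution index
            raise RuntimeError(f"fitness function failed on solution {index}") from exc
        self.n_evaluations += 1
        return f

    def _refresh_best(self) -> None:
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_solution = self.solutions[i].copy()


def _greedy_step(
    pop: MongoosePopulation,
    steps: np.ndarray,
    fitness_fn: FitnessFn,
) -> None:
    """Propose solution + step per mongoose; accept only improvements."""
    for p in range(pop.size):
        candidate = np.clip(pop.solutions[p] + steps[p], pop.lower, pop.upper)
        f = pop._evaluate(fitness_fn, candidate, p)
        if f < pop.fitness[p]:
            pop.solutions[p] = candidate
            pop.fitness[p] = f
    pop._refresh_best()


def alpha_phase_update(
    pop: MongoosePopulation,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    peep: float = 2.0,
    weighting: str = "printed",
) -> MongoosePopulation:
    """Exploitation step: s_p + α_p·Q with α_p ~ U(-1,1) per dimension.

    The alpha female is drawn from the likelihood weights for bookkeeping;
    movement itself is the vocalization-scaled random step with greedy
    acceptance.
    """
    probs = alpha_probabilities(pop.fitness, weighting=weighting)
    rng.choice(pop.size, p=probs)  # alpha selection draw (recorded in stream)
    steps = rng.uniform(-1.0, 1.0, size=pop.solutions.shape) * peep
    _greedy_step(pop, steps, fitness_fn)
    return pop


def scout_phase_update(
    pop: MongoosePopulation,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    omega_prev: float,
    peep: float = 2.0,
) -> MongoosePopulation:
    """Exploration step toward/away from the movement vector.

    If the pack-average sleeping mound improved (ω_new > ω_prev) the pack
    moves as s_p − D·α_p·z·(s_p − S), otherwise s_p + D·α_p·z·(s_p − S);
    z is a fresh U(0,1) draw per mongoose, D the decaying control factor.
    """
    if pop.mounds is None:
        raise RuntimeError("scout phase requires sleeping-mound values")
    d = control_factor(pop.iteration, pop.max_iterations)
    s_vec = movement_vector(pop.solutions, pop.mounds)
    sign = -1.0 if pop.omega > omega_prev else 1.0
    z = rng.uniform(0.0, 1.0, size=pop.size)
    alpha = rng.uniform(-1.0, 1.0, size=pop.solutions.shape) * peep
    steps = sign * d * alpha * z[:, None] * (pop.solutions - s_vec)
    _greedy_step(pop, steps, fitness_fn)
    return pop


@dataclass
class OptimizeResult:
    """Outcome of a DMOA run."""

    best_solution: np.ndarray
    best_fitness: float
    history: list[FitnessRecord] = field(default_factory=list)
    n_evaluations: int = 0
    n_iterations: int = 0

    def trace(self) -> np.ndarray:
        """Best-so-far fitness per recorded phase, in order."""
        return np.array([r.best for r in self.history])


class DwarfMongooseOptimizer:
    """Box-constrained black-box minimizer.

    Parameters
    ----------
    n_mongooses : population size t (>= 2).
    max_iter : iteration budget HU.
    peep : vocalization scale Q of the alpha female; multiplies the
        per-dimension U(-1,1) draw in both phases.  Default 2, the
        convention of the algorithm's source description.
    n_babysitters : number of worst solutions re-randomized at each
        babysitter exchange.
    exchange_period : iterations between babysitter exchanges; default
        ceil(0.1 · max_iter).  Each exchange is followed by a scout phase.
    patience : stop after this many iterations without improvement of the
        best fitness; None disables stalling.
    alpha_weighting : "printed" (raw-fitness likelihoods) or "inverted".
    seed : RNG seed; identical seed + config + fitness gives an identical
        run.
    """

    def __init__(
        self,
        n_mongooses: int = 30,
        max_iter: int = 200,
        peep: float = 2.0,
        n_babysitters: int = 3,
        exchange_period: int | None = None,
        patience: int | None = 50,
        alpha_weighting: str = "printed",
        seed: int | None = None,
    ):
        self.n_mongooses = n_mongooses
        self.max_iter = max_iter
        self.peep = peep
        self.n_babysitters = n_babysitters
        self.exchange_period = exchange_period
        self.patience = patience
        self.alpha_weighting = alpha_weighting
        self.seed = seed

    def _validate(self, dim: int, bounds) -> tuple[np.ndarray, np.ndarray]:
        if self.n_mongooses < 2:
            raise ValueError("population size must be >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if dim < 1:
            raise ValueError("dimension must be >= 1")
        if not 0 <= self.n_babysitters < self.n_mongooses:
            raise ValueError("n_babysitters must lie in [0, n_mongooses)")
        if self.exchange_period is not None and self.exchange_period < 1:
            raise ValueError("exchange_period must be >= 1")
        lo, hi = bounds
        lower = np.broadcast_to(np.asarray(lo, dtype=float), (dim,)).copy()
        upper = np.broadcast_to(np.asarray(hi, dtype=float), (dim,)).copy()
        if np.any(lower >= upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        return lower, upper

    def optimize(
        self,
        fitness_fn: FitnessFn,
        dim: int,
        bounds: tuple[float, float] | tuple[Sequence[float], Sequence[float]] = (-1.0, 1.0),
    ) -> OptimizeResult:
        lower, upper = self._validate(dim, bounds)
        rng = np.random.default_rng(self.seed)
        period = self.exchange_period or max(1, math.ceil(0.1 * max(self.max_iter, 1)))

        t = self.n_mongooses
        solutions = rng.uniform(lower, upper, size=(t, dim))
        pop = MongoosePopulation(
            solutions=solutions,
            fitness=np.empty(t),
            best_solution=solutions[0].copy(),
            best_fitness=np.inf,
            lower=lower,
            upper=upper,
            max_iterations=max(self.max_iter, 1),
            babysitter_count=self.n_babysitters,
        )
        for p in range(t):
            pop.fitness[p] = pop._evaluate(fitness_fn, pop.solutions[p], p)
        pop._refresh_best()

        history: list[FitnessRecord] = [
            FitnessRecord(0, pop.best_fitness, float(pop.fitness.mean()), "init")
        ]
        omega_prev = 0.0
        stall = 0
        iterations_run = 0
        for u in range(1, self.max_iter + 1):
            pop.iteration = u
            best_before = pop.best_fitness
            prev_fitness = pop.fitness.copy()

            alpha_phase_update(pop, fitness_fn, rng, self.peep, self.alpha_weighting)
            pop.mounds = sleeping_mound(prev_fitness, pop.fitness)
            pop.omega = average_sleeping_mound(pop.mounds)
            history.append(
                FitnessRecord(u, pop.best_fitness, float(pop.fitness.mean()), "alpha")
            )

            pop.babysitter_counter += 1
            if pop.babysitter_counter >= period:
                # babysitter exchange: the youngsters re-enter the pack as
                # fresh random solutions, replacing the worst performers
                pop.babysitter_counter = 0
                if self.n_babysitters > 0:
                    worst = np.argsort(pop.fitness)[-self.n_babysitters:]
                    pop.solutions[worst] = rng.uniform(
                        lower, upper, size=(self.n_babysitters, dim)
                    )
                    for p in worst:
                        pop.fitness[p] = pop._evaluate(fitness_fn, pop.solutions[p], p)
                    pop._refresh_best()
                    history.append(
                        FitnessRecord(
                            u, pop.best_fitness, float(pop.fitness.mean()), "exchange"
                        )
                    )
            scout_phase_update(pop, fitness_fn, rng, omega_prev, self.peep)
            history.append(
                FitnessRecord(u, pop.best_fitness, float(pop.fitness.mean()), "scout")
            )
            omega_prev = pop.omega
            iterations_run = u

            if pop.best_fitness < best_before:
                stall = 0
            else:
                stall += 1
                if self.patience is not None and stall >= self.patience:
                    break

        return OptimizeResult(
            best_solution=pop.best_solution.copy(),
            best_fitness=pop.best_fitness,
            history=history,
            n_evaluations=pop.n_evaluations,
            n_iterations=iterations_run,
        )


def write_trace_csv(history: Sequence[FitnessRecord], path) -> None:
    """Write the convergence trace as CSV (iteration, best, mean, phase)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "best", "mean", "phase"])
        for r in history:
            w.writerow([r.iteration, repr(r.best), repr(r.mean), r.phase])
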