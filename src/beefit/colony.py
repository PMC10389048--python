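"""From-scratch Artificial Bee Colony (ABC) optimizer.

ABC maintains SN "food sources" (candidate parameter vectors). Each cycle
runs four phases:

1. employed — each source is perturbed once in a single random dimension
   toward/away from a random partner, and the better of (source, candidate)
   is kept (greedy selection);
2. onlooker — SN further perturbations, with the source to exploit drawn by
   roulette wheel proportional to fitness (recomputed after each
   replacement);
3. memorize — the best-so-far position is updated;
4. scout — a source whose ``trial`` counter (consecutive failed
   improvements) reached ``limit`` is abandoned and replaced by a fresh
   uniform draw; at most one source per cycle.

All randomness flows through a single seeded generator in a fixed,
documented call order, so runs are bit-reproducible:

* initialization draws ``rng.random(D)`` per source, in source order;
* a neighbor move draws partner ``k = rng.integers(SN-1)`` (mapped to skip
  the source itself), then dimension ``d = rng.integers(D)``, then
  ``phi = rng.uniform(-1, 1)`` (with ``perturb_all_dims`` the last two
  become ``rng.uniform(-1, 1, D)``);
* an onlooker placement draws ``rng.random()`` for the roulette wheel, then
  the neighbor-move draws;
* a scout replacement draws ``rng.random(D)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DegenerateColonyError, InvalidInputError
from .objective import fitness as fitness_transform


@dataclass(frozen=True)
class Bounds:
    """Elementwise box constraints x_min <= x <= x_max."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1:
            raise InvalidInputError("lower and upper must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise InvalidInputError("bounds must be finite")
        if np.any(lower > upper):
            raise InvalidInputError("lower bound exceeds upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(x, self.lower), self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def sample(self, rng) -> np.ndarray:
        """Uniform draw per dimension: lower + U(0,1)·(upper − lower)."""
        return self.lower + rng.random(self.dim) * (self.upper - self.lower)

    def to_dict(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}


@dataclass
class FoodSource:
    """A candidate solution: position, objective f, fitness, trial counter."""

    position: np.ndarray
    objective: float
    fitness: float
    trial: int = 0


@dataclass
class Colony:
    """SN food sources plus the best position/objective ever seen."""

    sources: list
    best_position: np.ndarray
    best_objective: float
    cycle: int = 0

    @property
    def size(self) -> int:
        return len(self.sources)


@dataclass(frozen=True)
class ABCConfig:
    """ABC hyperparameters.

    Defaults follow the bundled benchmark protocol: colony size 40,
    abandonment limit 30, 20 cycles.
    """

    bounds: Bounds
    colony_size: int = 40
    limit: int = 30
    max_cycles: int = 20
    seed: int | None = None
    perturb_all_dims: bool = False
    init_retry_cap: int = 20

    def __post_init__(self):
        if self.colony_size < 2:
            raise InvalidInputError("colony_size must be >= 2")
        if self.limit < 1:
            raise InvalidInputError("limit must be >= 1")
        if self.max_cycles < 0:
            raise InvalidInputError("max_cycles must be >= 0")

    def to_dict(self) -> dict:
        return {
            "bounds": self.bounds.to_dict(),
            "colony_size": self.colony_size,
            "limit": self.limit,
            "max_cycles": self.max_cycles,
            "seed": self.seed,
            "perturb_all_dims": self.perturb_all_dims,
        }


@dataclass
class EstimationResult:
    """Common optimizer output shape shared by ABC and the baselines."""

    algorithm: str
    best_position: np.ndarray
    best_objective: float
    trace: list  # best-so-far objective per cycle/outer iteration
    n_evaluations: int
    seed: int | None
    config: dict = field(default_factory=dict)

    def to_dict(self, parameter_names: Sequence[str] | None = None) -> dict:
        if parameter_names is not None:
            best = dict(zip(parameter_names, np.asarray(self.best_position).tolist()))
        else:
            best = np.asarray(self.best_position).tolist()
        return {
            "algorithm": self.algorithm,
            "best_parameters": best,
            "best_objective": self.best_objective,
            "trace": list(self.trace),
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self, path, parameter_names: Sequence[str] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(parameter_names), fh, indent=2)


def _evaluate(objective_fn, x: np.ndarray) -> float:
    f = float(objective_fn(x))
    if not math.isfinite(f):
        raise InvalidInputError(f"objective returned non-finite value {f!r} at {x!r}")
    return f


def _make_source(objective_fn, position: np.ndarray) -> FoodSource:
    f = _evaluate(objective_fn, position)
    return FoodSource(position=position, objective=f, fitness=fitness_transform(f), trial=0)


def init_colony(objective_fn, config: ABCConfig, rng) -> tuple:
    """Draw and evaluate the initial colony; returns (colony, n_evaluations).

    A failed evaluation at an initial point is retried with a fresh draw up
    to ``config.init_retry_cap`` times before the error propagates.
    """
    sources = []
    n_evals = 0
    for _ in range(config.colony_size):
        last_err = None
        for _attempt in range(1 + config.init_retry_cap):
            position = config.bounds.sample(rng)
            try:
                n_evals += 1
                sources.append(_make_source(objective_fn, position))
                last_err = None
                break
            except Exception as err:  # noqa: BLE001 — retry any evaluation failure
                last_err = err
        if last_err is not None:
            raise last_err
    best = min(sources, key=lambda s: s.objective)
    colony = Colony(
        sources=sources,
        best_position=best.position.copy(),
        best_objective=best.objective,
        cycle=0,
    )
    return colony, n_evals


def neighbor(colony: Colony, i: int, config: ABCConfig, rng) -> np.ndarray:
    """Candidate position near source i: one random dimension d is moved by
    phi·(x_{i,d} − x_{k,d}) with phi ~ U[−1,1] and partner k != i; the result
    is clipped to the bounds."""
    sn = colony.size
    if sn < 2:
        raise DegenerateColonyError("neighbor search needs at least 2 sources")
    k = int(rng.integers(sn - 1))
    if k >= i:
        k += 1
    xi = colony.sources[i].position
    xk = colony.sources[k].position
    v = xi.copy()
    if config.perturb_all_dims:
        phi = rng.uniform(-1.0, 1.0, xi.size)
        v = xi + phi * (xi - xk)
    else:
        d = int(rng.integers(xi.size))
        phi = float(rng.uniform(-1.0, 1.0))
        v[d] = xi[d] + phi * (xi[d] - xk[d])
    return config.bounds.clip(v)


def greedy_select(current: FoodSource, candidate_position: np.ndarray,
                  candidate_objective: float) -> FoodSource:
    """Keep the fitter of (current, candidate); ties keep the incumbent and
    increment its trial counter (a non-improvement counts as a failure)."""
    cand_fitness = fitness_transform(candidate_objective)
    if cand_fitness > current.fitness:
        return FoodSource(
            position=np.asarray(candidate_position, dtype=float),
            objective=float(candidate_objective),
            fitness=cand_fitness,
            trial=0,
        )
    current.trial += 1
    return current


def selection_probabilities(colony: Colony) -> np.ndarray:
    """Roulette-wheel weights p_i = fit_i / Σ fit_j."""
    fits = np.array([s.fitness for s in colony.sources], dtype=float)
    total = fits.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateColonyError("total colony fitness is not positive")
    return fits / total


def employed_phase(colony: Colony, objective_fn, config: ABCConfig, rng) -> int:
    """One neighbor move + greedy selection per source; returns eval count."""
    for i in range(colony.size):
        v = neighbor(colony, i, config, rng)
        f = _evaluate(objective_fn, v)
        colony.sources[i] = greedy_select(colony.sources[i], v, f)
    return colony.size


def onlooker_phase(colony: Colony, objective_fn, config: ABCConfig, rng) -> int:
    """SN roulette-selected neighbor moves; probabilities are recomputed
    after every placement so replacements immediately reweight the wheel."""
    for _ in range(colony.size):
        probs = selection_probabilities(colony)
        r = float(rng.random())
        i = int(np.searchsorted(np.cumsum(probs), r, side="right"))
        i = min(i, colony.size - 1)  # guard against cumsum rounding at r ~ 1
        v = neighbor(colony, i, config, rng)
        f = _evaluate(objective_fn, v)
        colony.sources[i] = greedy_select(colony.sources[i], v, f)
    return colony.size


def memorize_best(colony: Colony) -> None:
    """Update the best-so-far memory; never increases the best objective."""
    best = min(colony.sources, key=lambda s: s.objective)
    if best.objective < colony.best_objective:
        colony.best_objective = best.objective
        colony.best_position = best.position.copy()


def scout_phase(colony: Colony, objective_fn, config: ABCConfig, rng) -> int:
    """Replace at most one exhausted source (trial >= limit) per cycle.

    Among sources over the limit, the one with the largest trial counter is
    abandoned (lowest index on ties) and re-drawn uniformly within bounds.
    The best-so-far solution is never discarded: a source currently holding
    the best objective is exempt from abandonment (selection pressure sends
    most onlookers to the best source, so its trial counter races ahead;
    without the exemption the scout would destroy the colony's only
    refining source every few cycles). Returns the number of evaluations
    spent (0 or 1).
    """
    best_objective = min(s.objective for s in colony.sources)
    protected = next(
        i for i, s in enumerate(colony.sources) if s.objective == best_objective
    )
    worst_i = -1
    worst_trial = config.limit - 1
    for i, s in enumerate(colony.sources):
        if i == protected:
            continue
        if s.trial > worst_trial:
            worst_trial = s.trial
            worst_i = i
    if worst_i < 0:
        return 0
    position = config.bounds.sample(rng)
    colony.sources[worst_i] = _make_source(objective_fn, position)
    return 1


def run_abc(objective_fn: Callable[[np.ndarray], float], config: ABCConfig) -> EstimationResult:
    """Run the full ABC loop: init, then employed → onlooker → memorize →
    scout for ``max_cycles`` cycles.

    Total evaluations = SN (init) + 2·SN·cycles + scout redraws. The
    best-so-far trace has one entry per cycle boundary (including the
    initial colony) and is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    colony, n_evals = init_colony(objective_fn, config, rng)
    trace = [colony.best_objective]
    for cycle in range(config.max_cycles):
        colony.cycle = cycle + 1
        n_evals += employed_phase(colony, objective_fn, config, rng)
        n_evals += onlooker_phase(colony, objective_fn, config, rng)
        memorize_best(colony)
        n_evals += scout_phase(colony, objective_fn, config, rng)
        trace.append(colony.best_objective)
    return EstimationResult(
        algorithm="abc",
        best_position=colony.best_position,
        best_objective=colony.best_objective,
        trace=trace,
        n_evaluations=n_evals,
        seed=config.seed,
        config=config.to_dict(),
    )
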