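"""Baseline optimizers behind the same contract as :func:`beefit.run_abc`.

Both comparison algorithms respect the box bounds at every reported iterate
and record their objective-evaluation counts so benchmarks can be matched
on evaluation budget rather than on loosely-defined "iterations".

* Simulated Annealing: Metropolis acceptance with geometric cooling and
  Gaussian proposals scaled to the bound widths.
* Nelder–Mead simplex: the standard reflect/expand/contract/shrink scheme
  with out-of-bounds vertices clipped to the box; deterministic given the
  initial guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .colony import Bounds, EstimationResult, _evaluate
from .errors import InvalidInputError


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing settings.

    ``initial_temperature=None`` sets T0 to the objective value at the
    starting point, so the first sweep accepts most moves regardless of the
    objective's scale. ``step_scale`` is the proposal SD as a fraction of
    each bound width. ``max_evaluations`` caps the budget.
    """

    bounds: Bounds
    initial_temperature: float | None = None
    cooling_rate: float = 0.95
    steps_per_temperature: int = 20
    step_scale: float = 0.1
    max_evaluations: int = 10_000
    min_temperature: float = 1e-12
    seed: int | None = None

    def __post_init__(self):
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise InvalidInputError("initial_temperature must be positive")
        if not 0.0 < self.cooling_rate < 1.0:
            raise InvalidInputError("cooling_rate must be in (0, 1)")
        if self.steps_per_temperature < 1 or self.max_evaluations < 1:
            raise InvalidInputError("steps_per_temperature and max_evaluations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "bounds": self.bounds.to_dict(),
            "initial_temperature": self.initial_temperature,
            "cooling_rate": self.cooling_rate,
            "steps_per_temperature": self.steps_per_temperature,
            "step_scale": self.step_scale,
            "max_evaluations": self.max_evaluations,
            "seed": self.seed,
        }


def run_simulated_annealing(objective_fn, config: SAConfig) -> EstimationResult:
    """Metropolis SA with geometric cooling; proposals clipped to bounds."""
    rng = np.random.default_rng(config.seed)
    bounds = config.bounds
    x = bounds.sample(rng)
    f = _evaluate(objective_fn, x)
    n_evals = 1
    best_x, best_f = x.copy(), f
    temp = config.initial_temperature if config.initial_temperature is not None else max(f, 1e-12)
    widths = bounds.upper - bounds.lower
    trace = [best_f]
    while n_evals < config.max_evaluations and temp > config.min_temperature:
        for _ in range(config.steps_per_temperature):
            if n_evals >= config.max_evaluations:
                break
            proposal = bounds.clip(x + rng.normal(0.0, 1.0, x.size) * config.step_scale * widths)
            f_prop = _evaluate(objective_fn, proposal)
            n_evals += 1
            delta = f_prop - f
            if delta <= 0.0 or rng.random() < math.exp(-delta / temp):
                x, f = proposal, f_prop
                if f < best_f:
                    best_x, best_f = x.copy(), f
        trace.append(best_f)
        temp *= config.cooling_rate
    return EstimationResult(
        algorithm="sa",
        best_position=best_x,
        best_objective=best_f,
        trace=trace,
        n_evaluations=n_evals,
        seed=config.seed,
        config=config.to_dict(),
    )


@dataclass(frozen=True)
class SimplexConfig:
    """Nelder–Mead settings with the standard coefficients (1, 2, 0.5, 0.5)."""

    bounds: Bounds
    initial_guess: np.ndarray | None = None
    reflection: float = 1.0
    expansion: float = 2.0
    contraction: float = 0.5
    shrink: float = 0.5
    max_evaluations: int = 10_000
    tolerance: float = 1e-10
    initial_step: float = 0.05  # first-simplex edge, fraction of bound width
    seed: int | None = None  # used only when initial_guess is None

    def __post_init__(self):
        if self.reflection <= 0 or self.expansion <= 1:
            raise InvalidInputError("need reflection > 0 and expansion > 1")
        if not (0 < self.contraction < 1 and 0 < self.shrink < 1):
            raise InvalidInputError("contraction and shrink must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "bounds": self.bounds.to_dict(),
            "initial_guess": None if self.initial_guess is None
            else np.asarray(self.initial_guess, float).tolist(),
            "coefficients": [self.reflection, self.expansion, self.contraction, self.shrink],
            "max_evaluations": self.max_evaluations,
            "tolerance": self.tolerance,
            "initial_step": self.initial_step,
            "seed": self.seed,
        }


def run_simplex(objective_fn, config: SimplexConfig) -> EstimationResult:
    """Bounded Nelder–Mead: standard moves, vertices clipped to the box.

    Terminates when the simplex's objective spread falls below ``tolerance``
    (or the simplex degenerates geometrically), or at the evaluation budget.
    Deterministic for a given initial guess.
    """
    bounds = config.bounds
    dim = bounds.dim
    widths = bounds.upper - bounds.lower
    if config.initial_guess is not None:
        x0 = bounds.clip(np.asarray(config.initial_guess, dtype=float))
    else:
        x0 = bounds.sample(np.random.default_rng(config.seed))

    # initial simplex: x0 plus one offset vertex per dimension
    verts = [x0.copy()]
    for d in range(dim):
        v = x0.copy()
        step = config.initial_step * widths[d]
        if step == 0.0:
            step = config.initial_step if x0[d] == 0 else config.initial_step * abs(x0[d])
        v[d] += step if v[d] + step <= bounds.upper[d] else -step
        verts.append(bounds.clip(v))
    verts = np.array(verts)
    fvals = np.array([_evaluate(objective_fn, v) for v in verts])
    n_evals = dim + 1
    trace = [float(fvals.min())]
    degenerate = False

    while n_evals + 2 <= config.max_evaluations:
        order = np.argsort(fvals, kind="stable")
        verts, fvals = verts[order], fvals[order]
        if fvals[-1] - fvals[0] <= config.tolerance:
            break
        if np.max(np.abs(verts[1:] - verts[0])) <= 1e-15:
            degenerate = True
            break
        centroid = verts[:-1].mean(axis=0)
        xr = bounds.clip(centroid + config.reflection * (centroid - verts[-1]))
        fr = _evaluate(objective_fn, xr)
        n_evals += 1
        if fr < fvals[0]:
            xe = bounds.clip(centroid + config.expansion * (xr - centroid))
            fe = _evaluate(objective_fn, xe)
            n_evals += 1
            if fe < fr:
                verts[-1], fvals[-1] = xe, fe
            else:
                verts[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            verts[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = bounds.clip(centroid + config.contraction * (xr - centroid))
            else:  # inside contraction
                xc = bounds.clip(centroid - config.contraction * (centroid - verts[-1]))
            fc = _evaluate(objective_fn, xc)
            n_evals += 1
            if fc < min(fr, fvals[-1]):
                verts[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                for j in range(1, dim + 1):
                    if n_evals >= config.max_evaluations:
                        break
                    verts[j] = bounds.clip(verts[0] + config.shrink * (verts[j] - verts[0]))
                    fvals[j] = _evaluate(objective_fn, verts[j])
                    n_evals += 1
        trace.append(float(fvals.min()))

    i_best = int(np.argmin(fvals))
    result_config = config.to_dict()
    result_config["degenerate"] = degenerate
    return EstimationResult(
        algorithm="simplex",
        best_position=verts[i_best].copy(),
        best_objective=float(fvals[i_best]),
        trace=trace,
        n_evaluations=n_evals,
        seed=config.seed,
        config=result_config,
    )
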