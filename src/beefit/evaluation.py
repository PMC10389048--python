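"""Multi-run evaluation metrics and the algorithm-comparison harness.

Over N independent estimation runs, the metrics are

* error rate      e   = Σ_runs Σ_components (y_true − y_est)²,
* average error   A   = e / N,
* STD             √(e/N) by default (a deviation on the original scale),
                  with a ``literal`` mode returning e/N.

The "components" can be either the kinetic parameters (parameter-space
batches, comparing each run's estimate to the ground truth) or the glucose
time series (series-space batches, comparing each run's best-fit trajectory
to the experimental series). Both readings are supported and every report
records which one it used; the benchmark harness reports both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .colony import ABCConfig, Bounds, EstimationResult, run_abc
from .baselines import SAConfig, SimplexConfig, run_simulated_annealing, run_simplex
from .errors import InvalidInputError
from .model import PARAMETER_NAMES, KineticParameters, TimeSeries
from .objective import build_objective

STD_MODES = ("rms", "literal")


@dataclass(frozen=True)
class RunBatch:
    """Per-run estimates of one algorithm against a shared reference.

    ``truth`` is the reference vector (parameter truth, or the experimental
    series values); ``estimates`` is the (N, D) matrix of per-run results in
    the same space. ``space`` records which reading the batch uses.
    """

    algorithm: str
    truth: np.ndarray
    estimates: np.ndarray
    objectives: np.ndarray | None = None
    space: str = "parameters"

    def __post_init__(self):
        truth = np.asarray(self.truth, dtype=float)
        estimates = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        if truth.ndim != 1 or estimates.shape[1] != truth.size:
            raise InvalidInputError(
                f"estimates shape {estimates.shape} does not match truth length {truth.size}"
            )
        if estimates.shape[0] < 1:
            raise InvalidInputError("a batch needs at least one run")
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "estimates", estimates)

    @property
    def n_runs(self) -> int:
        return self.estimates.shape[0]


@dataclass(frozen=True)
class EvaluationSummary:
    """e, A and STD for one batch; ``std_mode`` records the STD reading."""

    algorithm: str
    e: float
    A: float
    STD: float
    n_runs: int
    std_mode: str
    space: str


def error_rate(batch: RunBatch) -> float:
    """e = Σ over runs of the squared distance to the reference vector."""
    diff = batch.estimates - batch.truth
    return float(np.sum(diff * diff))


def error_rate_per_component(batch: RunBatch) -> np.ndarray:
    """Per-component breakdown of e (sums to error_rate)."""
    diff = batch.estimates - batch.truth
    return np.sum(diff * diff, axis=0)


def average_error_rate(e: float, n_runs: int) -> float:
    """A = e/N."""
    if n_runs < 1:
        raise InvalidInputError("n_runs must be >= 1")
    return e / n_runs


def std_metric(e: float, n_runs: int, mode: str = "rms") -> float:
    """STD of a batch: √(e/N) in the default ``rms`` mode (a root-mean-squared
    deviation on the original scale), or e/N in ``literal`` mode."""
    if n_runs < 1:
        raise InvalidInputError("n_runs must be >= 1")
    if mode not in STD_MODES:
        raise InvalidInputError(f"std mode must be one of {STD_MODES}, got {mode!r}")
    a = e / n_runs
    return float(np.sqrt(a)) if mode == "rms" else a


def summarize_batch(batch: RunBatch, std_mode: str = "rms") -> EvaluationSummary:
    e = error_rate(batch)
    return EvaluationSummary(
        algorithm=batch.algorithm,
        e=e,
        A=average_error_rate(e, batch.n_runs),
        STD=std_metric(e, batch.n_runs, std_mode),
        n_runs=batch.n_runs,
        std_mode=std_mode,
        space=batch.space,
    )


def compare_algorithms(batches: Sequence[RunBatch], std_mode: str = "rms") -> pd.DataFrame:
    """Tabulate A and STD per algorithm and flag the minima.

    All batches must share the reference vector and space. Returns a frame
    with one row per algorithm and boolean ``best_A`` / ``best_STD`` columns
    marking the per-criterion winners.
    """
    if not batches:
        raise InvalidInputError("need at least one batch")
    ref = batches[0]
    for b in batches[1:]:
        if b.space != ref.space or not np.array_equal(b.truth, ref.truth):
            raise InvalidInputError("batches do not share the same problem reference")
    rows = [summarize_batch(b, std_mode) for b in batches]
    df = pd.DataFrame(
        {
            "algorithm": [r.algorithm for r in rows],
            "A": [r.A for r in rows],
            "STD": [r.STD for r in rows],
            "N": [r.n_runs for r in rows],
            "mode": [r.std_mode for r in rows],
            "space": [r.space for r in rows],
        }
    )
    df["best_A"] = df["A"] == df["A"].min()
    df["best_STD"] = df["STD"] == df["STD"].min()
    return df


def overlay_series(y_exp: TimeSeries, best_fits: dict) -> pd.DataFrame:
    """Long-format overlay of the experimental series and each algorithm's
    best-fit trajectory (concentration vs time), for comparison plots."""
    frames = [
        pd.DataFrame({"time": y_exp.times, "series": "experimental", "value": y_exp.values})
    ]
    for label, ts in best_fits.items():
        if not y_exp.same_grid(ts):
            raise InvalidInputError(f"best-fit series for {label!r} is on a different grid")
        frames.append(pd.DataFrame({"time": ts.times, "series": label, "value": ts.values}))
    return pd.concat(frames, ignore_index=True)


def plot_overlay(overlay: pd.DataFrame, path) -> None:
    """Write a concentration-vs-time overlay plot (experimental + fits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, grp in overlay.groupby("series"):
        style = {"lw": 2, "color": "k"} if label == "experimental" else {"lw": 1.2}
        ax.plot(grp["time"], grp["value"], label=label, **style)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Glci concentration (mmol/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Everything the multi-run comparison produces."""

    parameter_table: pd.DataFrame
    series_table: pd.DataFrame
    results: dict  # algorithm -> list[EstimationResult]
    batches_parameters: dict
    batches_series: dict
    overlay: pd.DataFrame
    evaluation_budget: int


def _abc_budget(config: ABCConfig) -> int:
    return config.colony_size + 2 * config.colony_size * config.max_cycles


def run_benchmark(
    problem,
    n_runs: int = 50,
    algorithms: Sequence[str] = ("abc", "sa", "simplex"),
    seed: int = 0,
    abc_cycles: int = 200,
    colony_size: int = 40,
    limit: int = 30,
    std_mode: str = "rms",
    dt_max: float = 0.05,
) -> BenchmarkResult:
    """Run ``n_runs`` independent seeded estimations per algorithm on one
    problem instance at matched objective-evaluation budgets.

    The budget is set by the ABC protocol (SN + 2·SN·cycles evaluations);
    SA and the simplex receive the same cap (the simplex may stop early at
    its own convergence tolerance — its evaluation count is recorded).
    Returns comparison tables in both metric spaces plus the best-fit
    trajectory overlay of each algorithm's best run.
    """
    from .model import ModelEnvironment, simulate  # local import to avoid cycles
    from .synthetic import ProblemInstance  # noqa: F401 — typing only

    objective = build_objective(problem.experimental_series, problem.env, dt_max=dt_max)
    bounds = problem.bounds
    budget = _abc_budget(
        ABCConfig(bounds=bounds, colony_size=colony_size, limit=limit, max_cycles=abc_cycles)
    )
    runners: dict[str, Callable[[int], EstimationResult]] = {
        "abc": lambda s: run_abc(
            objective,
            ABCConfig(bounds=bounds, colony_size=colony_size, limit=limit,
                      max_cycles=abc_cycles, seed=s),
        ),
        "sa": lambda s: run_simulated_annealing(
            objective, SAConfig(bounds=bounds, max_evaluations=budget, seed=s)
        ),
        "simplex": lambda s: run_simplex(
            objective, SimplexConfig(bounds=bounds, max_evaluations=budget, seed=s)
        ),
    }
    unknown = set(algorithms) - set(runners)
    if unknown:
        raise InvalidInputError(f"unknown algorithms: {sorted(unknown)}")

    truth_params = problem.truth.to_array()
    y_exp = problem.experimental_series
    results: dict[str, list[EstimationResult]] = {}
    batches_p: dict[str, RunBatch] = {}
    batches_s: dict[str, RunBatch] = {}
    best_fits: dict[str, TimeSeries] = {}
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) for s in ss.generate_state(n_runs * len(algorithms)) >> 1]

    for a_idx, algo in enumerate(algorithms):
        algo_results = [
            runners[algo](run_seeds[a_idx * n_runs + r]) for r in range(n_runs)
        ]
        results[algo] = algo_results
        estimates = np.array([r.best_position for r in algo_results])
        objectives = np.array([r.best_objective for r in algo_results])
        batches_p[algo] = RunBatch(
            algorithm=algo, truth=truth_params, estimates=estimates,
            objectives=objectives, space="parameters",
        )
        fits = np.array([
            simulate(KineticParameters.from_array(r.best_position), problem.env,
                     y_exp.times).values
            for r in algo_results
        ])
        batches_s[algo] = RunBatch(
            algorithm=algo, truth=y_exp.values, estimates=fits,
            objectives=objectives, space="series",
        )
        best_run = int(np.argmin(objectives))
        best_fits[algo] = TimeSeries(times=y_exp.times, values=fits[best_run])

    return BenchmarkResult(
        parameter_table=compare_algorithms(list(batches_p.values()), std_mode),
        series_table=compare_algorithms(list(batches_s.values()), std_mode),
        results=results,
        batches_parameters=batches_p,
        batches_series=batches_s,
        overlay=overlay_series(y_exp, best_fits),
        evaluation_budget=budget,
    )


# ---------------------------------------------------------------------------
# Profile-sweep identifiability
# ---------------------------------------------------------------------------

def profile_identifiability(
    problem,
    rel_offsets: Sequence[float] = (0.8, 1.2),
    floor_factor: float = 1e-6,
    max_evaluations: int = 6000,
    dt_max: float = 0.05,
) -> pd.DataFrame:
    """Practical identifiability of each parameter at a problem instance.

    For each parameter, fix it at truth × offset and re-optimize the other
    five (Nelder–Mead in log-space, started at the truth). A parameter is
    practically identifiable when no such compensation brings the SSE back
    below the recovery floor ``floor_factor × n_points`` at every offset —
    i.e. the data genuinely pin the parameter down. Returns a frame with
    the profile SSE per (parameter, offset) and an ``identifiable`` flag.
    """
    from scipy.optimize import minimize

    objective = build_objective(problem.experimental_series, problem.env, dt_max=dt_max)
    truth = problem.truth.to_array()
    n = len(problem.experimental_series)
    floor = floor_factor * n
    rows = []
    for i, name in enumerate(PARAMETER_NAMES):
        profile_sses = []
        for offset in rel_offsets:
            fixed = truth[i] * offset
            others = np.delete(truth, i)
            # optimize in log-space to keep parameters positive
            with np.errstate(divide="ignore"):
                z0 = np.log(np.maximum(others, 1e-12))

            def profile_obj(z, i=i, fixed=fixed):
                x = np.insert(np.exp(z), i, fixed)
                return objective(x)

            # restart once from the first solution: a fresh simplex escapes
            # the premature collapse Nelder-Mead is prone to in 5-D
            z, best = z0, np.inf
            for _ in range(2):
                res = minimize(
                    profile_obj, z, method="Nelder-Mead",
                    options={"maxfev": max_evaluations, "xatol": 1e-10, "fatol": 1e-14},
                )
                z, best = res.x, float(res.fun)
            profile_sses.append(best)
        identifiable = all(s > floor for s in profile_sses)
        for offset, s in zip(rel_offsets, profile_sses):
            rows.append({"parameter": name, "offset": offset, "profile_sse": s,
                         "identifiable": identifiable})
    return pd.DataFrame(rows)


def identifiable_parameters(problem, **kwargs) -> list:
    """Names of the parameters the profile sweep flags as identifiable."""
    df = profile_identifiability(problem, **kwargs)
    return sorted(df[df["identifiable"]]["parameter"].unique())
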