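"""Self-contained synthetic estimation problems.

A problem instance is built by simulating the glucose subsystem at a
ground-truth parameter vector, sampling the trajectory on a fixed grid,
optionally adding zero-mean Gaussian observation noise, and deriving an
initial guess and a ×10 / ÷10 search box around it. Everything is
reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colony import Bounds
from .errors import InvalidInputError
from .model import (
    PARAMETER_NAMES,
    KineticParameters,
    ModelEnvironment,
    TimeSeries,
    simulate,
)
from .objective import NoiseSpec, add_noise

#: Documented default ground truth of the bundled benchmark instance
#: (mmol/L and s units; saturating hexokinase kinetics with glucose relaxing
#: toward a steady state ~2.5 mmol/L inside the 100 s window).
DEFAULT_TRUTH = KineticParameters(
    vin_vm1=1.5,
    vin_kilg6p=0.1,
    vhk_vm2=2.0,
    vhk_km2glc=0.5,
    vhk_km2atp=0.2,
    vhk_ks2glc=0.3,
)

#: Default sampling grid: 0-100 s, 201 instants.
DEFAULT_TIMES = np.linspace(0.0, 100.0, 201)


@dataclass(frozen=True)
class ProblemInstance:
    """A complete, reproducible estimation problem."""

    truth: KineticParameters
    env: ModelEnvironment
    times: np.ndarray
    experimental_series: TimeSeries
    initial_guess: np.ndarray
    bounds: Bounds
    seed: int | None
    sigma: float

    def save(self, directory) -> None:
        """Serialize to a directory: truth.json, config.json, experimental.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "truth.json", "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2)
        config = {
            "env": self.env.to_dict(),
            "times": self.times.tolist(),
            "initial_guess": self.initial_guess.tolist(),
            "bounds": self.bounds.to_dict(),
            "seed": self.seed,
            "sigma": self.sigma,
        }
        with open(directory / "config.json", "w") as fh:
            json.dump(config, fh, indent=2)
        self.experimental_series.to_csv(directory / "experimental.csv")

    @classmethod
    def load(cls, directory) -> "ProblemInstance":
        directory = Path(directory)
        with open(directory / "truth.json") as fh:
            truth = KineticParameters(**json.load(fh))
        with open(directory / "config.json") as fh:
            config = json.load(fh)
        return cls(
            truth=truth,
            env=ModelEnvironment(**config["env"]),
            times=np.asarray(config["times"], dtype=float),
            experimental_series=TimeSeries.from_csv(directory / "experimental.csv"),
            initial_guess=np.asarray(config["initial_guess"], dtype=float),
            bounds=Bounds(**config["bounds"]),
            seed=config["seed"],
            sigma=config["sigma"],
        )


def bounds_from_guess(guess) -> Bounds:
    """The ×10 / ÷10 search box: lower = guess/10, upper = guess×10.

    Requires a strictly positive guess (the multiplicative scheme is
    meaningless otherwise)."""
    guess = np.atleast_1d(np.asarray(guess, dtype=float))
    if np.any(guess <= 0) or not np.all(np.isfinite(guess)):
        raise InvalidInputError("the x10 bound scheme requires a strictly positive guess")
    return Bounds(lower=guess / 10.0, upper=guess * 10.0)


def make_problem(
    truth: KineticParameters,
    env: ModelEnvironment | None = None,
    times=None,
    noise: NoiseSpec | None = None,
    guess_perturbation: float = 3.0,
    seed: int | None = None,
) -> ProblemInstance:
    """Build a reproducible estimation problem around a ground truth.

    The experimental series is the simulated trajectory at the truth plus
    Gaussian noise. ``noise=None`` selects the default sigma, 1% of the
    clean trajectory's dynamic range (pass ``NoiseSpec(0)`` for a noiseless
    instance). The initial guess multiplies each true parameter by an
    independent log-uniform factor in [1/guess_perturbation,
    guess_perturbation]; the ×10 / ÷10 box around the guess then always
    contains the truth for perturbation factors below 10.
    """
    env = env if env is not None else ModelEnvironment()
    times = np.asarray(times, dtype=float) if times is not None else DEFAULT_TIMES.copy()
    if guess_perturbation < 1.0:
        raise InvalidInputError("guess_perturbation must be >= 1")
    truth_arr = truth.to_array()
    if np.any(truth_arr <= 0):
        raise InvalidInputError("make_problem requires a strictly positive truth vector")

    rng = np.random.default_rng(seed)
    log_p = np.log(guess_perturbation)
    factors = np.exp(rng.uniform(-log_p, log_p, truth_arr.size))
    initial_guess = truth_arr * factors

    clean = simulate(truth, env, times)
    if noise is None:
        sigma = 0.01 * float(np.ptp(clean.values))
        noise = NoiseSpec(sigma=sigma, seed=int(rng.integers(2**31)))
    elif noise.sigma > 0 and noise.seed is None:
        noise = NoiseSpec(sigma=noise.sigma, seed=int(rng.integers(2**31)))
    experimental = add_noise(clean, noise)

    return ProblemInstance(
        truth=truth,
        env=env,
        times=times,
        experimental_series=experimental,
        initial_guess=initial_guess,
        bounds=bounds_from_guess(initial_guess),
        seed=seed,
        sigma=noise.sigma,
    )


def default_problem(seed: int | None = 0, sigma: float | None = None) -> ProblemInstance:
    """The bundled benchmark instance: default truth, environment and grid.

    ``sigma=None`` uses the default noise (1% of dynamic range); pass
    ``sigma=0.0`` for the noiseless variant.
    """
    noise = None if sigma is None else NoiseSpec(sigma=sigma)
    return make_problem(DEFAULT_TRUTH, noise=noise, seed=seed)
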