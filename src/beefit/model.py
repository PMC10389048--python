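"""Glucose subsystem of the S. cerevisiae fermentation pathway.

The bundled model tracks a single state, intracellular glucose ``Glci``
(mmol/L), governed by two fluxes inside a constant-volume cytoplasm:

* ``Vin`` — glucose transport into the cell, with a maximal rate ``Vm1``
  and product inhibition by glucose-6-phosphate (coefficient ``KilG6P``):
  ``Vin = volume * (Vm1 - KilG6P * G6P)``.
* ``Vhk`` — hexokinase, a reversible Michaelis-Menten style rate with
  half-saturation constants for glucose and ATP and a coupling term:
  ``Vhk = volume * Vm2 / (1 + Km2Glc/Glci + Km2ATP/ATP
  + Ks2Glc*Km2ATP/(Glci*ATP))``.

The balance is ``d(Glci)/dt = (Vin - Vhk) / volume``. G6P and ATP appear in
the rate laws but their dynamics are not part of this subsystem; both are
carried as fixed environment concentrations. The six rate-law coefficients
are the estimable parameters, in the fixed order given by
:data:`PARAMETER_NAMES`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import GridMismatchError, InvalidInputError, SimulationError, SingularRateError

#: Fixed, documented order of the six estimable kinetic parameters.
PARAMETER_NAMES = (
    "vin_vm1",
    "vin_kilg6p",
    "vhk_vm2",
    "vhk_km2glc",
    "vhk_km2atp",
    "vhk_ks2glc",
)

N_PARAMETERS = len(PARAMETER_NAMES)


def _check_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise InvalidInputError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class KineticParameters:
    """The six estimable kinetic parameters of the glucose subsystem.

    Units: maximal rates (``vin_vm1``, ``vhk_vm2``) in mmol/L/s;
    half-saturation and coupling coefficients (``vhk_km2glc``,
    ``vhk_km2atp``, ``vhk_ks2glc``) in mmol/L; the inhibition coefficient
    ``vin_kilg6p`` is treated as an opaque positive coefficient
    (rate contribution per mmol/L of G6P).
    """

    vin_vm1: float
    vin_kilg6p: float
    vhk_vm2: float
    vhk_km2glc: float
    vhk_km2atp: float
    vhk_ks2glc: float

    def __post_init__(self):
        for name in PARAMETER_NAMES:
            object.__setattr__(self, name, _check_finite_nonneg(name, getattr(self, name)))

    def to_array(self) -> np.ndarray:
        """Parameter values as a length-6 float array in canonical order."""
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "KineticParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_PARAMETERS,):
            raise InvalidInputError(
                f"expected {N_PARAMETERS} parameter values, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAMETER_NAMES, values)))

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAMETER_NAMES}


@dataclass(frozen=True)
class ModelEnvironment:
    """Fixed (non-estimated) quantities of the glucose subsystem.

    The cytoplasm is a constant one-liter compartment by default; G6P and
    ATP concentrations are held fixed because their dynamics are not part
    of the subsystem. ``glci0`` is the initial intracellular glucose.
    """

    cytoplasm_volume: float = 1.0  # L
    g6p: float = 1.0  # mmol/L
    atp: float = 1.0  # mmol/L
    glci0: float = 1.0  # mmol/L

    def __post_init__(self):
        if not math.isfinite(self.cytoplasm_volume) or self.cytoplasm_volume <= 0:
            raise InvalidInputError(
                f"cytoplasm_volume must be positive, got {self.cytoplasm_volume!r}"
            )
        for name in ("g6p", "atp", "glci0"):
            object.__setattr__(self, name, _check_finite_nonneg(name, getattr(self, name)))

    def to_dict(self) -> dict:
        return {
            "cytoplasm_volume": self.cytoplasm_volume,
            "g6p": self.g6p,
            "atp": self.atp,
            "glci0": self.glci0,
        }


@dataclass(frozen=True)
class TimeSeries:
    """Sampled concentrations (mmol/L) of one species versus time (s)."""

    times: np.ndarray
    values: np.ndarray
    species_id: str = "Glci"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise InvalidInputError("times and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise InvalidInputError("a time series needs at least 2 instants")
        if not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise InvalidInputError("times and values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size

    def same_grid(self, other: "TimeSeries") -> bool:
        return self.times.size == other.times.size and np.array_equal(self.times, other.times)

    def to_csv(self, path) -> None:
        """Write the series in the shared CSV dialect: ``time,species,value``."""
        import pandas as pd

        pd.DataFrame(
            {"time": self.times, "species": self.species_id, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species_id: str | None = None) -> "TimeSeries":
        """Read a series from the ``time,species,value`` CSV dialect.

        If the file holds several species, ``species_id`` selects one.
        """
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"time", "species", "value"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"CSV is missing columns {sorted(missing)}")
        if species_id is None:
            species = df["species"].unique()
            if len(species) != 1:
                raise InvalidInputError(
                    f"CSV holds species {list(species)}; pass species_id to pick one"
                )
            species_id = str(species[0])
        sub = df[df["species"] == species_id].sort_values("time")
        if sub.empty:
            raise InvalidInputError(f"no rows for species {species_id!r}")
        return cls(
            times=sub["time"].to_numpy(float),
            values=sub["value"].to_numpy(float),
            species_id=species_id,
        )


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def rate_vin(params: KineticParameters, env: ModelEnvironment) -> float:
    """Glucose transport flux Vin (mmol/s).

    ``Vin = volume * (Vm1 - KilG6P * G6P)``. May be negative (net efflux
    when G6P inhibition exceeds the maximal rate); callers decide whether
    that is admissible.
    """
    return env.cytoplasm_volume * (params.vin_vm1 - params.vin_kilg6p * env.g6p)


def rate_vhk(params: KineticParameters, glci: float, env: ModelEnvironment) -> float:
    """Hexokinase flux Vhk (mmol/s) at intracellular glucose ``glci``.

    Reversible-hexokinase form with the full four-term denominator:
    ``volume * Vm2 / (1 + Km2Glc/Glci + Km2ATP/ATP + Ks2Glc*Km2ATP/(Glci*ATP))``.

    Raises :class:`SingularRateError` when ``glci`` or ``atp`` is zero while
    any saturation coefficient is nonzero (the denominator is singular there;
    an explicit error beats a silent infinity).
    """
    glci = float(glci)
    if not math.isfinite(glci) or glci < 0:
        raise InvalidInputError(f"glci must be finite and >= 0, got {glci!r}")
    km2glc, km2atp, ks2glc = params.vhk_km2glc, params.vhk_km2atp, params.vhk_ks2glc
    if km2glc == km2atp == ks2glc == 0.0:
        return env.cytoplasm_volume * params.vhk_vm2
    if glci <= 0.0 or env.atp <= 0.0:
        raise SingularRateError(
            f"Vhk is singular at glci={glci}, atp={env.atp} with nonzero saturation coefficients"
        )
    denom = 1.0 + km2glc / glci + km2atp / env.atp + ks2glc * km2atp / (glci * env.atp)
    return env.cytoplasm_volume * params.vhk_vm2 / denom


def dglci_dt(params: KineticParameters, glci: float, env: ModelEnvironment) -> float:
    """Net rate of change of intracellular glucose (mmol/L/s):
    ``(Vin - Vhk) / volume``."""
    return (rate_vin(params, env) - rate_vhk(params, glci, env)) / env.cytoplasm_volume


def reduced_rate_constants(params: KineticParameters, env: ModelEnvironment) -> tuple:
    """Lumped constants (a, vm2, A, B) of the reduced concentration balance.

    With fixed G6P and ATP the balance collapses to the autonomous form
    ``dG/dt = a - vm2*G / (A*G + B)`` with

    * ``a = Vm1 - KilG6P*G6P`` (net transport, concentration units),
    * ``A = 1 + Km2ATP/ATP``,
    * ``B = Km2Glc + Ks2Glc*Km2ATP/ATP``.

    The trajectory depends on the six parameters only through ``a``,
    ``vm2/A`` and ``B/A`` — the source of the subsystem's structural
    non-identifiability (see docs/methods.md).
    """
    a = params.vin_vm1 - params.vin_kilg6p * env.g6p
    if env.atp > 0:
        A = 1.0 + params.vhk_km2atp / env.atp
        B = params.vhk_km2glc + params.vhk_ks2glc * params.vhk_km2atp / env.atp
    else:
        if params.vhk_km2atp != 0 or params.vhk_ks2glc != 0:
            raise SingularRateError("atp=0 with nonzero ATP-dependent coefficients")
        A = 1.0
        B = params.vhk_km2glc
    return a, params.vhk_vm2, A, B


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _validate_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise InvalidInputError("times must be a 1-D array with at least 2 instants")
    if not np.all(np.diff(times) > 0):
        raise InvalidInputError("times must be strictly increasing")
    return times


def simulate(
    params: KineticParameters,
    env: ModelEnvironment,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> TimeSeries:
    """Integrate the glucose balance and return Glci at the requested instants.

    Uses an adaptive Runge-Kutta scheme (the one-state subsystem is not
    stiff). The state is clamped at zero — concentrations are non-negative —
    and a warning is issued if clamping was active. Deterministic for fixed
    inputs and tolerances.
    """
    times = _validate_times(times)
    a, vm2, A, B = reduced_rate_constants(params, env)

    def rhs(t, y):
        g = y[0]
        ge = g if g > 0.0 else 0.0
        if B > 0.0:
            vhk = vm2 * ge / (A * ge + B)
        else:
            vhk = vm2 / A
        r = a - vhk
        if ge == 0.0 and r < 0.0:
            r = 0.0  # clamp: no flux out of an empty pool
        return [r]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [env.glci0],
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}",
            time=float(sol.t[-1]) if sol.t.size else float(times[0]),
        )
    values = sol.y[0]
    if np.any(values < 0):
        warnings.warn(
            "Glci reached 0 during integration; state clamped at 0", RuntimeWarning
        )
        values = np.maximum(values, 0.0)
    return TimeSeries(times=times, values=values, species_id="Glci")


def simulate_rk4(
    params: KineticParameters,
    env: ModelEnvironment,
    times,
    dt_max: float = 1e-3,
) -> TimeSeries:
    """Fixed-step classical 4th-order Runge-Kutta reference integration.

    Independent of :func:`simulate`'s adaptive path; used as a cross-check
    and as the engine behind the fast fitting objective (see
    :mod:`beefit._fast`).
    """
    from ._fast import rk4_trajectory

    times = _validate_times(times)
    a, vm2, A, B = reduced_rate_constants(params, env)
    values = rk4_trajectory(a, vm2, A, B, env.glci0, times, float(dt_max))
    return TimeSeries(times=times, values=values, species_id="Glci")
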