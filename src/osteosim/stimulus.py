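"""Daily mechanical stimulus, reference-stimulus accommodation, load scenarios.

The daily stimulus ζ condenses the day's loading history into one scalar,
the cycle-weighted m-norm of the effective strains of the habitual load
cases (Mikić–Carter form):  ζ = (Σ_i N_i ε_i^m)^(1/m) with m = 4.

Bone compares ζ against a slowly adapting reference ζ_ref (accommodation,
dζ_ref/dt = φ(ζ − ζ_ref)): a sustained load change first drives the error
ζ − ζ_ref out of the mechanostat dead zone and is then gradually absorbed
as ζ_ref tracks the new habit.

The organ-level strain field is reduced to per-site habitual stress
amplitudes with the uniaxial surrogate ε = σ/E; stresses are chosen at
initialization so each site sits at stimulus equilibrium (ζ = ζ_ref).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LoadCase",
    "StimulusParams",
    "StimulusState",
    "LoadSchedule",
    "DEFAULT_HABITUAL_STRAINS",
    "site_strain",
    "daily_stimulus",
    "update_reference",
    "scenario_factor",
]


@dataclass(frozen=True)
class LoadCase:
    """One habitual load: daily cycle count and site-level stress amplitude (MPa)."""

    label: str
    cycles_per_day: float
    stress_amplitude: float

    def __post_init__(self) -> None:
        if self.cycles_per_day < 0 or self.stress_amplitude < 0:
            raise ValueError("cycle count and stress amplitude must be non-negative")


#: Habitual activity pattern: daily cycle counts and the peak strains each
#: activity is assumed to impose at stimulus equilibrium.  5000 walking and
#: 500 stair-climbing cycles per day; peak strain levels (1500 µε walking,
#: 1800 µε stair-climbing) are in the physiological range for locomotion.
DEFAULT_HABITUAL_STRAINS = (
    ("walking", 5000.0, 1.5e-3),
    ("stair_climbing", 500.0, 1.8e-3),
)


@dataclass(frozen=True)
class StimulusParams:
    """Cycle-weighting exponent m (≥ 1) and accommodation rate φ (1/day)."""

    m: float = 4.0
    phi: float = 1.0e-4

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


@dataclass(frozen=True)
class StimulusState:
    """Daily stimulus ζ and accommodated reference ζ_ref (both ≥ 0)."""

    zeta: float
    zeta_ref: float

    def __post_init__(self) -> None:
        if self.zeta < 0 or self.zeta_ref < 0:
            raise ValueError("stimulus values must be non-negative")


@dataclass(frozen=True)
class LoadSchedule:
    """A step change of all load amplitudes by ``factor`` at ``tolc_years``.

    factor 1.3 models a 30% overload (sustained exercise), 0.7 a 30%
    underload (sedentary shift); tolc_years is the time of load change in
    years relative to the last menses.
    """

    factor: float = 1.0
    tolc_years: float = 0.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("load factor must be positive")


def site_strain(sigma, E: float):
    """Uniaxial effective strain ε = σ/E of the site surrogate."""
    if E <= 0:
        raise ValueError("degenerate tissue: elastic modulus must be positive")
    sigma = np.asarray(sigma, dtype=float)
    out = sigma / E
    return out if out.ndim else float(out)


def daily_stimulus(cases, m: float = 4.0) -> float:
    """Cycle-weighted m-norm of strain amplitudes, ζ = (Σ N_i ε_i^m)^(1/m).

    ``cases`` is an iterable of (cycles_per_day, strain) pairs.  The result
    scales linearly with a common strain factor; an empty list gives 0.
    """
    cases = list(cases)
    if not cases:
        return 0.0
    n = np.array([c[0] for c in cases], dtype=float)
    eps = np.array([c[1] for c in cases], dtype=float)
    if np.any(n < 0) or np.any(eps < 0):
        raise ValueError("cycle counts and strains must be non-negative")
    return float(np.sum(n * eps**m) ** (1.0 / m))


def update_reference(state: StimulusState, phi: float, dt: float = 1.0) -> StimulusState:
    """One explicit-Euler accommodation step: ζ_ref ← ζ_ref + φ(ζ − ζ_ref)dt.

    A contraction toward ζ with per-step factor (1 − φ·dt); φ·dt must be
    below 1 for stability (φ·dt = 1e-4 at the daily step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if phi * dt >= 1.0 or phi <= 0:
        raise ValueError("require 0 < phi*dt < 1 for a stable accommodation step")
    new_ref = state.zeta_ref + phi * (state.zeta - state.zeta_ref) * dt
    return replace(state, zeta_ref=new_ref)


def scenario_factor(t_years, schedule: LoadSchedule):
    """Load multiplier at time t: 1 before the load change, ``factor`` after."""
    t = np.asarray(t_years, dtype=float)
    out = np.where(t < schedule.tolc_years, 1.0, schedule.factor)
    return out if out.ndim else float(out)
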