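"""Least-squares calibration of the menopause/ageing κ parameters.

Given an observation series of relative BMD̄ versus time (years relative to
the last menses), the calibrator fits the permanent level κ_perm and the
long-term per-day slope of the active κ channel(s) by minimizing the mean
squared error between the femur-averaged simulated BMD̄ (linearly
interpolated to the observation times) and the observations.

The search formalizes a successive-approximation scheme: a coarse grid over
the free parameters, a refined local grid around the best coarse point, and
a final derivative-free Nelder–Mead polish (bounds enforced by clipping
inside the objective).  The fit is fully deterministic.

Free parameters per scenario: ``fbio_only`` and ``fbb_only`` fit the
(κ_perm, slope) pair of their channel; ``combined`` fits all four.  Bounds
default to κ_perm ∈ [1, 2] (f_bio, non-decreasing), κ_perm ∈ [0.5, 1]
(f_bb, non-increasing) and |slope| ≤ 1e-3 per day with the sign fixed by
the channel's direction of drift.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .engine import SimulationConfig, SimulationResult, run_simulation
from .menopause import KappaParams, MenopauseSchedule

__all__ = [
    "ObservationSeries",
    "CalibrationResult",
    "FitBudget",
    "DEFAULT_BOUNDS",
    "mse_between",
    "fit_parameters",
]


@dataclass(frozen=True)
class ObservationSeries:
    """Relative BMD̄ observations: strictly increasing times (years), values > 0."""

    times: np.ndarray
    values: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size < 2 or y.shape != t.shape:
            raise ValueError("times and values must be aligned 1-d arrays (n >= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(y <= 0):
            raise ValueError("relative BMD values must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)

    def normalized(self) -> "ObservationSeries":
        """Series rescaled so the first observation equals 1."""
        return ObservationSeries(self.times, self.values / self.values[0], self.noise_sd)

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        df = pd.read_csv(path)
        sd = df["sd"].iloc[0] if "sd" in df.columns else None
        return cls(df["t_years"].to_numpy(), df["bmd_rel"].to_numpy(), sd)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"t_years": self.times, "bmd_rel": self.values})
        if self.noise_sd is not None:
            df["sd"] = self.noise_sd
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class FitBudget:
    """Search effort: coarse/refined grid resolution and polish iterations."""

    grid_perm: int = 5
    grid_slope: int = 4
    refine_levels: int = 2
    polish_maxfev: int = 160
    n_starts: int = 3

    def grid_shape(self, n_free: int) -> tuple[int, ...]:
        # the 4-parameter combined fit uses a leaner grid per axis
        if n_free == 4:
            return (max(self.grid_perm - 1, 3), max(self.grid_slope, 3)) * 2
        return (self.grid_perm, self.grid_slope)


@dataclass(frozen=True)
class ParamBounds:
    perm_fbio: tuple[float, float] = (1.0, 2.0)
    slope_fbio: tuple[float, float] = (0.0, 1.0e-3)
    perm_fbb: tuple[float, float] = (0.5, 1.0)
    slope_fbb: tuple[float, float] = (-1.0e-3, 0.0)


DEFAULT_BOUNDS = ParamBounds()


@dataclass
class CalibrationResult:
    """Fitted schedule with its MSE and the evaluation trace."""

    scenario: str
    schedule: MenopauseSchedule
    mse: float
    n_evaluations: int
    trace: list[tuple[tuple[float, ...], float]] = field(default_factory=list)

    @property
    def params(self) -> dict[str, float]:
        return {
            "kappa_perm_fbio": self.schedule.kappa_fbio.kappa_perm,
            "slope_fbio": self.schedule.kappa_fbio.slope_per_day,
            "kappa_perm_fbb": self.schedule.kappa_fbb.kappa_perm,
            "slope_fbb": self.schedule.kappa_fbb.slope_per_day,
        }


def mse_between(sim: SimulationResult, obs: ObservationSeries) -> float:
    """Mean squared error of simulated BMD̄ against the observations.

    The simulated femur-average BMD̄ is linearly interpolated to the
    observation times; observations outside the simulated span are an error.
    """
    t = sim.t_years
    if obs.times[0] < t[0] - 1e-9 or obs.times[-1] > t[-1] + 1e-9:
        raise ValueError(
            f"observations span [{obs.times[0]}, {obs.times[-1]}] y but the "
            f"simulation covers [{t[0]:.3f}, {t[-1]:.3f}] y"
        )
    pred = np.interp(obs.times, t, sim.bmd_norm)
    return float(np.mean((pred - obs.values) ** 2))


_FREE_PARAMS = {
    "fbio_only": ("perm_fbio", "slope_fbio"),
    "fbb_only": ("perm_fbb", "slope_fbb"),
    "combined": ("perm_fbio", "slope_fbio", "perm_fbb", "slope_fbb"),
}


def _schedule_from_vector(scenario: str, x: np.ndarray) -> MenopauseSchedule:
    vals = dict(zip(_FREE_PARAMS[scenario], x))
    fbio = KappaParams(
        kappa_perm=vals.get("perm_fbio", 1.0),
        slope_per_day=vals.get("slope_fbio", 0.0),
    )
    fbb = KappaParams(
        kappa_perm=vals.get("perm_fbb", 1.0),
        slope_per_day=vals.get("slope_fbb", 0.0),
    )
    return MenopauseSchedule(kappa_fbio=fbio, kappa_fbb=fbb, scenario=scenario)


def fit_parameters(
    obs: ObservationSeries,
    scenario: str,
    base_config: SimulationConfig,
    bounds: ParamBounds = DEFAULT_BOUNDS,
    budget: FitBudget = FitBudget(),
) -> CalibrationResult:
    """Fit the scenario's free κ parameters to an observation series.

    Deterministic: grid search (with one local refinement level) followed by
    a Nelder–Mead polish started from the best grid point.  Returns the
    best-so-far parameters even if the polish stops at its budget.
    """
    if scenario not in _FREE_PARAMS:
        raise ValueError(f"scenario must be one of {sorted(_FREE_PARAMS)}")
    # the model predicts BMD̄ relative to its own start, so only the shape of
    # the observation series is informative: normalize to the first value
    # (making the fit invariant to any overall rescaling of the series)
    obs = obs.normalized()
    names = _FREE_PARAMS[scenario]
    lo = np.array([getattr(bounds, n)[0] for n in names])
    hi = np.array([getattr(bounds, n)[1] for n in names])

    # the simulation must cover the observation span
    t_end = max(base_config.t_end, float(obs.times[-1]))
    t_start = min(base_config.t_start, float(obs.times[0]))
    config = replace(base_config, t_start=t_start, t_end=t_end)

    trace: list[tuple[tuple[float, ...], float]] = []

    def objective(x: np.ndarray) -> float:
        x_clip = np.clip(x, lo, hi)
        penalty = float(np.sum((x - x_clip) ** 2))
        schedule = _schedule_from_vector(scenario, x_clip)
        sim = run_simulation(replace(config, menopause=schedule))
        err = mse_between(sim, obs) + penalty
        trace.append((tuple(float(v) for v in x_clip), err))
        return err

    def axis(name: str, l: float, h: float, k: int) -> np.ndarray:
        # the long-term drift acts over ~10^4 days, so the bound |slope| <=
        # 1e-3/day spans two orders of magnitude of effect; sample those
        # axes geometrically from zero, the κ_perm axes linearly
        if name.startswith("slope"):
            mag = max(abs(l), abs(h))
            sign = 1.0 if h > 0 else -1.0
            return np.concatenate(([0.0], sign * np.geomspace(mag / 64.0, mag, k - 1)))
        return np.linspace(l, h, k)

    # --- coarse grid, then refined local grids around the incumbent
    shape = budget.grid_shape(len(names))
    axes = [axis(n, l, h, k) for n, l, h, k in zip(names, lo, hi, shape)]
    grid_evals: list[tuple[np.ndarray, float]] = []
    best_x, best_f = None, np.inf
    for point in itertools.product(*axes):
        xp = np.asarray(point)
        f = objective(xp)
        grid_evals.append((xp, f))
        if f < best_f:
            best_x, best_f = xp, f
    for _ in range(budget.refine_levels):
        new_axes = []
        for ax, x, l, h in zip(axes, best_x, lo, hi):
            ax_sorted = np.sort(ax)
            i = int(np.argmin(np.abs(ax_sorted - x)))
            gap_lo = ax_sorted[i] - ax_sorted[max(i - 1, 0)]
            gap_hi = ax_sorted[min(i + 1, ax_sorted.size - 1)] - ax_sorted[i]
            span = max(gap_lo, gap_hi, 1e-12)
            new_axes.append(np.linspace(max(x - span, l), min(x + span, h), 3))
        axes = new_axes
        for point in itertools.product(*axes):
            f = objective(np.asarray(point))
            if f < best_f:
                best_x, best_f = np.asarray(point), f

    # --- multi-start simplex polish: Nelder-Mead from the refined incumbent
    # and from the best mutually-distant coarse-grid basins, then one final
    # restart at the overall best (a fresh simplex escapes the degenerate
    # shapes a single simplex run can collapse into)
    maxfev = budget.polish_maxfev * max(len(names) // 2, 1)
    width = np.maximum(hi - lo, 1e-12)
    starts = [best_x]
    for xg, _ in sorted(grid_evals, key=lambda e: e[1]):
        if len(starts) >= budget.n_starts:
            break
        if all(np.max(np.abs(xg - s) / width) > 0.15 for s in starts):
            starts.append(xg)

    def polish(x0: np.ndarray, scale_frac: float) -> tuple[np.ndarray, float]:
        scale = np.maximum(scale_frac * width, 1e-9)
        simplex = np.vstack(
            [x0] + [x0 + np.eye(len(names))[i] * scale[i] for i in range(len(names))]
        )
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": maxfev,
                "initial_simplex": np.clip(simplex, lo, hi),
                "xatol": 1e-6,
                "fatol": 1e-14,
            },
        )
        return np.clip(res.x, lo, hi), float(res.fun)

    x_fit, f_fit = best_x, best_f
    for x0 in starts:
        x1, f1 = polish(x0, 0.05)
        if f1 < f_fit:
            x_fit, f_fit = x1, f1
    x1, f1 = polish(x_fit, 0.01)
    if f1 < f_fit:
        x_fit, f_fit = x1, f1

    return CalibrationResult(
        scenario=scenario,
        schedule=_schedule_from_vector(scenario, x_fit),
        mse=f_fit,
        n_evaluations=len(trace),
        trace=trace,
    )
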