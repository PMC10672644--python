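"""Daily-stepped multi-site bone remodeling simulation.

A femur is represented by a small ensemble of material sites spanning the
cortical-to-trabecular range of bone volume fractions, each with a
mass-averaging weight, habitual load cases, a mineralization layer stack,
a BMU history and a stimulus state.  Each simulated day every site goes
through a fixed update order (composition → stiffness → stimulus → focal
balance → activation → origination → delayed formation/resorption →
layer turnover → accommodation → history push); femur-level series are
weight-averaged over sites and BMD̄ is normalized to its value at the
start of the run.

Sites are initialized in stimulus equilibrium: habitual stress amplitudes
are solved so that the target strains are realized at the prescribed
initial volume fraction, the reference stimulus equals the daily stimulus,
and the BMU history is pre-filled with the matching constant origination
rate.  With both menopause channels frozen (κ ≡ 1) and unchanged loads the
ensemble therefore persists at its initial state.

The forward model is deterministic: identical configurations produce
bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tissue
from ._kernel import (
    COL_ALPHA,
    COL_FOR,
    COL_NDOT,
    COL_VB,
    COL_VFDOT,
    COL_VM,
    COL_VRDOT,
    COL_ZETA,
    COL_ZETA_REF,
    simulate_site,
)
from .kinetics import (
    BMUHistory,
    BMUParams,
    Layer,
    LayerStack,
    MineralizationLaw,
    activation_frequency,
    apply_turnover,
    focal_balance,
    formation_rate,
    origination_rate,
    resorption_rate,
    stack_summary,
)
from .menopause import DAYS_PER_YEAR, MenopauseSchedule, PRESETS
from .stimulus import (
    DEFAULT_HABITUAL_STRAINS,
    LoadCase,
    LoadSchedule,
    StimulusParams,
    StimulusState,
    daily_stimulus,
    scenario_factor,
    site_strain,
    update_reference,
)
from .tissue import DEFAULT_CONSTANTS, MARTIN_SV_COEFFS, TissueConstants, elastic_modulus

__all__ = [
    "SiteSpec",
    "Site",
    "SimulationConfig",
    "SimulationResult",
    "DEFAULT_ENSEMBLE",
    "initialize_site",
    "equilibrate_site",
    "step_site",
    "run_simulation",
    "femur_average",
]


@dataclass(frozen=True)
class SiteSpec:
    """Declarative site definition: label, averaging weight, starting v_b."""

    label: str
    weight: float
    initial_vb: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("site weight must be positive")
        if not (0.0 < self.initial_vb < 1.0):
            raise ValueError("initial_vb must lie in (0, 1)")


#: Default five-site ensemble spanning cortical bone (v_b 0.95, 0.85),
#: the transition zone (0.6) and trabecular bone (0.35, 0.2), with mass
#: weights reflecting the dominance of compact tissue in the femur.
DEFAULT_ENSEMBLE: tuple[SiteSpec, ...] = (
    SiteSpec("cortical_dense", 0.35, 0.95),
    SiteSpec("cortical_porous", 0.25, 0.85),
    SiteSpec("transition", 0.15, 0.60),
    SiteSpec("trabecular_dense", 0.15, 0.35),
    SiteSpec("trabecular_porous", 0.10, 0.20),
)


@dataclass
class Site:
    """Mutable per-site state used by the pure-Python stepping path."""

    label: str
    weight: float
    loads: tuple[LoadCase, ...]
    stack: LayerStack
    history: BMUHistory
    stimulus: StimulusState


@dataclass(frozen=True)
class SimulationConfig:
    """Full forward-model configuration (time base is 1 day, 365 d/year)."""

    tissue: TissueConstants = DEFAULT_CONSTANTS
    bmu: BMUParams = BMUParams()
    mineralization: MineralizationLaw = MineralizationLaw()
    stimulus: StimulusParams = StimulusParams()
    sv_coeffs: tuple[float, ...] = MARTIN_SV_COEFFS
    habitual_strains: tuple[tuple[str, float, float], ...] = DEFAULT_HABITUAL_STRAINS
    sites: tuple[SiteSpec, ...] = DEFAULT_ENSEMBLE
    menopause: MenopauseSchedule = PRESETS["none"]
    load_schedule: LoadSchedule = LoadSchedule()
    t_start: float = -4.0
    t_end: float = 15.0
    initial_tissue_age_years: float = 30.0
    coalesce_gap_days: float = 30.0
    run_in_tolerance: float = 1e-7
    max_run_in_years: float = 30.0

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if not self.sites:
            raise ValueError("at least one site is required")
        if self.t_start > self.menopause.kappa_fbio.t1 and self.menopause.scenario != "none":
            raise ValueError(
                "t_start must not be later than the perimenopause onset t1: the "
                "initial state is a premenopausal equilibrium"
            )

    @property
    def n_days(self) -> int:
        return int(round((self.t_end - self.t_start) * DAYS_PER_YEAR)) + 1

    @property
    def t_years(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_days) / DAYS_PER_YEAR


@dataclass
class SimulationResult:
    """Daily series per site and femur-averaged, plus run metadata.

    ``sites`` maps label → dict of named series (v_b, v_m, alpha, bmd,
    porosity, rho_mat, rho_app, zeta, zeta_ref, f_or, n_dot, v_f_dot,
    v_r_dot); ``femur`` holds the weight-averaged series plus ``bmd_norm``,
    the femur BMD normalized to 1 at t_start.
    """

    t_years: np.ndarray
    sites: dict[str, dict[str, np.ndarray]]
    femur: dict[str, np.ndarray]
    weights: dict[str, float]
    config: SimulationConfig
    warnings: dict[str, int] = field(default_factory=dict)

    @property
    def bmd_norm(self) -> np.ndarray:
        return self.femur["bmd_norm"]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-site frame with columns (t_years, site, variable, value)."""
        parts = []
        for label, series in self.sites.items():
            for var, arr in series.items():
                parts.append(
                    pd.DataFrame(
                        {
                            "t_years": self.t_years,
                            "site": label,
                            "variable": var,
                            "value": arr,
                        }
                    )
                )
        return pd.concat(parts, ignore_index=True)

    def femur_frame(self) -> pd.DataFrame:
        """Wide femur-average frame, one column per variable."""
        return pd.DataFrame({"t_years": self.t_years, **self.femur})


def _solved_loads(
    spec: SiteSpec, config: SimulationConfig
) -> tuple[tuple[LoadCase, ...], float, float]:
    """Solve habitual stress amplitudes so ζ = ζ_ref at the initial v_b.

    Returns the load cases, the equilibrium stimulus and the initial mean
    ash fraction of the (aged) starting tissue.
    """
    alpha_init = config.mineralization(config.initial_tissue_age_years * DAYS_PER_YEAR)
    e0 = elastic_modulus(spec.initial_vb, alpha_init)
    loads = tuple(
        LoadCase(label, cycles, strain * e0)
        for label, cycles, strain in config.habitual_strains
    )
    zeta_eq = daily_stimulus(
        [(cycles, strain) for _, cycles, strain in config.habitual_strains],
        config.stimulus.m,
    )
    return loads, zeta_eq, alpha_init


def initialize_site(spec: SiteSpec, config: SimulationConfig) -> Site:
    """Construct a site in analytic premenopausal equilibrium."""
    loads, zeta_eq, _ = _solved_loads(spec, config)
    stack = LayerStack(
        [Layer(spec.initial_vb, config.initial_tissue_age_years * DAYS_PER_YEAR)],
        coalesce_gap_days=config.coalesce_gap_days,
    )
    f_or = activation_frequency(zeta_eq, zeta_eq, config.bmu.f_bio)
    s_v = tissue.specific_surface(1.0 - spec.initial_vb, config.sv_coeffs)
    history = BMUHistory.equilibrium(origination_rate(f_or, s_v), config.bmu)
    return Site(
        label=spec.label,
        weight=spec.weight,
        loads=loads,
        stack=stack,
        history=history,
        stimulus=StimulusState(zeta=zeta_eq, zeta_ref=zeta_eq),
    )


def step_site(
    site: Site,
    t_years: float,
    config: SimulationConfig,
    schedule: MenopauseSchedule | None = None,
    load_schedule: LoadSchedule | None = None,
) -> Site:
    """Advance a site by one day (pure-Python reference path).

    Follows the fixed update order documented in the module docstring.
    The compiled kernel used by :func:`run_simulation` implements the same
    semantics; the two are cross-checked in the test suite.
    """
    schedule = schedule if schedule is not None else config.menopause
    load_schedule = load_schedule if load_schedule is not None else config.load_schedule
    bmu, law = config.bmu, config.mineralization

    v_b, _, alpha = stack_summary(site.stack, law, config.tissue)
    if v_b <= 0.0:
        raise RuntimeError(f"site {site.label!r}: degenerate tissue (v_b = 0)")
    e_mod = elastic_modulus(v_b, alpha)
    factor = scenario_factor(t_years, load_schedule)
    eps = [site_strain(factor * lc.stress_amplitude, e_mod) for lc in site.loads]
    zeta = daily_stimulus(
        [(lc.cycles_per_day, e) for lc, e in zip(site.loads, eps)], config.stimulus.m
    )
    zeta_ref = site.stimulus.zeta_ref

    kappa_fbb = schedule.kappa_fbb_at(t_years)
    fbb_now = focal_balance(zeta - zeta_ref, kappa_fbb, bmu)
    f_or = activation_frequency(zeta, zeta_ref, bmu.f_bio * schedule.kappa_fbio_at(t_years))
    n_dot = origination_rate(f_or, tissue.specific_surface(1.0 - v_b, config.sv_coeffs))

    v_f_dot = formation_rate(site.history, bmu)
    v_r_dot = resorption_rate(site.history, bmu)
    apply_turnover(site.stack, v_f_dot, v_r_dot, dt=1.0)

    site.stimulus = update_reference(
        StimulusState(zeta=zeta, zeta_ref=zeta_ref), config.stimulus.phi, dt=1.0
    )
    site.history.push(n_dot, fbb_now)
    return site


def equilibrate_site(
    spec: SiteSpec, config: SimulationConfig, settle_days: int = 730
) -> tuple[Site, dict[str, float]]:
    """Verify that the analytically initialized site is a remodeling fixed point.

    Runs the site forward with κ ≡ 1 and unchanged loads for ``settle_days``
    and checks that the volume-fraction drift stays below the configured
    run-in tolerance and the stimulus error stays inside the dead zone.
    Returns the (freshly initialized) site and drift diagnostics; raises if
    the state is not stationary within ``max_run_in_years``.
    """
    max_days = int(config.max_run_in_years * DAYS_PER_YEAR)
    settle_days = min(int(settle_days), max_days)
    quiet = replace(
        config,
        menopause=PRESETS["none"],
        load_schedule=LoadSchedule(),
        t_start=config.t_start,
        t_end=config.t_start + settle_days / DAYS_PER_YEAR,
    )
    out, _ = _run_site_kernel(spec, quiet)
    vb = out[:, COL_VB]
    tail = slice(max(settle_days // 2, 1), None)
    drift = float(np.max(np.abs(np.diff(vb[tail]))))
    gap = float(np.max(np.abs(out[tail, COL_ZETA] - out[tail, COL_ZETA_REF])))
    diagnostics = {"max_daily_vb_drift": drift, "max_stimulus_gap": gap}
    if drift > config.run_in_tolerance or gap > config.bmu.w:
        raise RuntimeError(
            f"site {spec.label!r} failed to reach a stationary state within "
            f"{settle_days} days: {diagnostics}"
        )
    return initialize_site(spec, config), diagnostics


def _scenario_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = config.t_years
    kfbio = np.asarray(config.menopause.kappa_fbio_at(t), dtype=float)
    kfbb = np.asarray(config.menopause.kappa_fbb_at(t), dtype=float)
    factor = np.asarray(scenario_factor(t, config.load_schedule), dtype=float)
    return kfbio, kfbb, factor


def _run_site_kernel(spec: SiteSpec, config: SimulationConfig):
    loads, zeta_eq, _ = _solved_loads(spec, config)
    kfbio, kfbb, factor = _scenario_arrays(config)
    return simulate_site(
        config.n_days,
        spec.initial_vb,
        config.initial_tissue_age_years * DAYS_PER_YEAR,
        zeta_eq,
        config.tissue.rho_m,
        config.tissue.rho_o,
        config.tissue.rho_w,
        config.tissue.v_o,
        np.asarray(config.sv_coeffs, dtype=float),
        int(config.bmu.T_R),
        int(config.bmu.T_I),
        int(config.bmu.T_F),
        config.bmu.A_BMU,
        config.bmu.v_BMU,
        config.bmu.f_bio,
        config.bmu.f_bb_min,
        config.bmu.f_bb_max,
        config.bmu.w,
        config.bmu.v,
        config.mineralization.alpha_0,
        config.mineralization.alpha_max,
        config.mineralization.tau_days,
        config.stimulus.m,
        config.stimulus.phi,
        np.array([lc.cycles_per_day for lc in loads], dtype=float),
        np.array([lc.stress_amplitude for lc in loads], dtype=float),
        kfbio,
        kfbb,
        factor,
        config.coalesce_gap_days,
    )


def _site_series(out: np.ndarray, config: SimulationConfig) -> dict[str, np.ndarray]:
    c = config.tissue
    v_b = out[:, COL_VB]
    v_m = out[:, COL_VM]
    v_w = np.clip(1.0 - c.v_o - v_m, 0.0, None)
    rho_mat = c.rho_m * v_m + c.rho_o * c.v_o + c.rho_w * v_w
    alive = v_b > 0
    return {
        "v_b": v_b,
        "v_m": v_m,
        "alpha": out[:, COL_ALPHA],
        "porosity": np.where(alive, 1.0 - v_b, 1.0),
        "bmd": c.rho_m * v_m * v_b,
        "rho_mat": np.where(alive, rho_mat, 0.0),
        "rho_app": np.where(alive, rho_mat * v_b, 0.0),
        "zeta": out[:, COL_ZETA],
        "zeta_ref": out[:, COL_ZETA_REF],
        "f_or": out[:, COL_FOR],
        "n_dot": out[:, COL_NDOT],
        "v_f_dot": out[:, COL_VFDOT],
        "v_r_dot": out[:, COL_VRDOT],
    }


def femur_average(series: list[np.ndarray], weights: list[float]) -> np.ndarray:
    """Weighted mean of aligned per-site series."""
    if len(series) != len(weights):
        raise ValueError("one weight per series is required")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    lengths = {len(s) for s in series}
    if len(lengths) > 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    stacked = np.vstack(series)
    return w @ stacked / w.sum()


_FEMUR_VARS = ("v_b", "v_m", "alpha", "porosity", "bmd", "rho_mat", "rho_app", "zeta", "zeta_ref", "f_or")


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the daily multi-site simulation over [t_start, t_end]."""
    sites: dict[str, dict[str, np.ndarray]] = {}
    weights: dict[str, float] = {}
    warn: dict[str, int] = {}
    for spec in config.sites:
        try:
            out, flags = _run_site_kernel(spec, config)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"site {spec.label!r} failed: {exc}") from exc
        sites[spec.label] = _site_series(out, config)
        weights[spec.label] = spec.weight
        if flags[0] or flags[1]:
            warn[spec.label] = int(flags[0])

    femur = {
        var: femur_average([s[var] for s in sites.values()], list(weights.values()))
        for var in _FEMUR_VARS
    }
    femur["bmd_norm"] = femur["bmd"] / femur["bmd"][0]
    return SimulationResult(
        t_years=config.t_years,
        sites=sites,
        femur=femur,
        weights=weights,
        config=config,
        warnings=warn,
    )
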