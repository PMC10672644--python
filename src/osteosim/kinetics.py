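"""Basic multicellular unit (BMU) population kinetics and layered mineralization.

Remodeling is carried out by BMUs that originate on the free bone surface,
resorb a packet of tissue over a period T_R, rest over a reversal period
T_I, and refill the packet over a formation period T_F scaled by the focal
bone balance f_bb (ratio of volume formed to volume resorbed).

The origination rate per unit volume is ``Ṅ_BMU = f_or · S_v`` where f_or
is the mechanically inhibited activation frequency and S_v the specific
surface.  The density of *active* BMUs at time τ is the origination rate
integrated over the BMU lifespan T_R + T_I + T_F; the daily resorption and
formation rates are windowed averages of that density,

    v̇_r(t) = (A_BMU · v_BMU / T_R) · Σ_{τ ∈ [t-T_R, t)}           N_BMU(τ) Δτ
    v̇_f(t) = (A_BMU · v_BMU / T_F) · Σ_{τ ∈ [t-T_R-T_I-T_F,
                                           t-T_R-T_I)}  N_BMU(τ) · f_bb(τ) Δτ

with Δτ = 1 day, so formation lags resorption by the reversal pipeline and
an activation-frequency transient transiently depletes bone (the
"remodeling space").  f_bb is evaluated at the historical day τ: formation
reflects the balance prevailing when that BMU was refilling.

Mineralization is tracked in discrete tissue layers: formation pushes a
young layer (primary mineralization level α_0) onto the surface of a LIFO
stack, resorption strips volume youngest-first, and each layer's ash
fraction matures exponentially toward α_max.  Higher turnover therefore
keeps mean tissue age down (less mineral) while net resorption digs into
old, highly mineralized tissue — the two dissociated routes to BMD loss.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .tissue import DEFAULT_CONSTANTS, TissueConstants, mineral_fraction_from_ash

__all__ = [
    "BMUParams",
    "MineralizationLaw",
    "Layer",
    "LayerStack",
    "BMUHistory",
    "activation_frequency",
    "origination_rate",
    "focal_balance",
    "formation_rate",
    "resorption_rate",
    "net_rate",
    "layer_mineral",
    "apply_turnover",
    "stack_summary",
]


@dataclass(frozen=True)
class BMUParams:
    """BMU timing, geometry and focal-balance curve parameters.

    T_R, T_I, T_F are the resorption / reversal / formation periods in days;
    A_BMU the remodeling cross-section in mm²; v_BMU the BMU progression
    speed in mm/day; f_bio the maximum (biological) activation frequency in
    1/(mm²·day); f_bb_min/f_bb_max the focal-balance bounds, and w and v the
    dead-zone half-width and linear-zone width in stimulus units.
    """

    T_R: int = 24
    T_I: int = 18
    T_F: int = 64
    A_BMU: float = 2.84e-2
    v_BMU: float = 0.04
    f_bio: float = 5.0e-3
    f_bb_min: float = 0.85
    f_bb_max: float = 1.15
    w: float = 1.5e-3
    v: float = 1.5e-3

    def __post_init__(self) -> None:
        for name in ("T_R", "T_I", "T_F", "A_BMU", "v_BMU", "f_bio", "w", "v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.f_bb_min <= 1.0 <= self.f_bb_max):
            raise ValueError("focal balance bounds must bracket 1")

    @property
    def lifespan(self) -> int:
        """Total BMU lifespan T_R + T_I + T_F in days."""
        return int(self.T_R + self.T_I + self.T_F)


@dataclass(frozen=True)
class MineralizationLaw:
    """Exponential secondary-mineralization law for layer ash fraction.

    α(age) = α_max − (α_max − α_0)·exp(−age/τ): fresh osteoid carries the
    primary mineral level α_0 and matures toward α_max with time constant
    τ (days).  Defaults: α_0 = 0.45, α_max = 0.72, τ = 1500 days.
    """

    alpha_0: float = 0.45
    alpha_max: float = 0.72
    tau_days: float = 1500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_0 <= self.alpha_max < 1.0):
            raise ValueError("require 0 <= alpha_0 <= alpha_max < 1")
        if self.tau_days <= 0:
            raise ValueError("tau_days must be positive")

    def __call__(self, age_days):
        return layer_mineral(age_days, self)


def layer_mineral(age_days, law: MineralizationLaw):
    """Ash fraction of a tissue layer as a function of its age in days."""
    age = np.asarray(age_days, dtype=float)
    if np.any(age < 0):
        raise ValueError("layer age must be non-negative")
    out = law.alpha_max - (law.alpha_max - law.alpha_0) * np.exp(-age / law.tau_days)
    return out if out.ndim else float(out)


@dataclass
class Layer:
    """One deposited tissue layer: volume-fraction thickness and age (days)."""

    thickness_vb: float
    age: float

    def __post_init__(self) -> None:
        if self.thickness_vb <= 0:
            raise ValueError("layer thickness must be positive")
        if self.age < 0:
            raise ValueError("layer age must be non-negative")


class LayerStack:
    """LIFO stack of tissue layers, youngest on top (end of the list).

    Ages are non-decreasing from top to bottom; the total thickness is the
    bone volume fraction v_b of the material point.  Adjacent layers whose
    ages differ by less than ``coalesce_gap_days`` are merged
    (thickness-weighted age) to bound memory over multi-decade runs.
    """

    def __init__(self, layers=(), coalesce_gap_days: float = 30.0):
        self.layers: list[Layer] = [Layer(l.thickness_vb, l.age) for l in layers]
        self.coalesce_gap_days = float(coalesce_gap_days)
        self._validate()

    def _validate(self) -> None:
        ages = [l.age for l in self.layers]
        if any(a2 > a1 + 1e-9 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError("layer ages must be non-increasing from bottom to top")
        if not 0.0 <= self.total_vb <= 1.0 + 1e-9:
            raise ValueError("total volume fraction outside [0, 1]")

    @property
    def total_vb(self) -> float:
        return float(sum(l.thickness_vb for l in self.layers))

    def __len__(self) -> int:
        return len(self.layers)

    def advance_age(self, dt: float) -> None:
        for l in self.layers:
            l.age += dt

    def resorb(self, volume: float) -> None:
        """Strip ``volume`` from the top (youngest first), splitting layers."""
        remaining = volume
        while remaining > 0 and self.layers:
            top = self.layers[-1]
            if top.thickness_vb <= remaining + 1e-15:
                remaining -= top.thickness_vb
                self.layers.pop()
            else:
                top.thickness_vb -= remaining
                remaining = 0.0
        if remaining > 1e-12:
            warnings.warn(
                "resorption exceeded available bone volume; stack clamped to empty "
                "(degenerate tissue)",
                RuntimeWarning,
                stacklevel=2,
            )

    def push(self, thickness: float, age: float = 0.0) -> None:
        if thickness <= 0:
            return
        if self.layers:
            top = self.layers[-1]
            if top.age - age < self.coalesce_gap_days:
                total = top.thickness_vb + thickness
                top.age = (top.age * top.thickness_vb + age * thickness) / total
                top.thickness_vb = total
                return
        self.layers.append(Layer(thickness, age))


def activation_frequency(zeta: float, zeta_ref: float, f_bio_eff: float):
    """Mechanically inhibited BMU activation frequency, 1/(mm²·day).

    f_or = f_bio_eff · (1 − ζ/(ζ+ζ_ref)) = f_bio_eff · ζ_ref/(ζ+ζ_ref):
    the habitual stimulus suppresses activation toward zero, while disuse
    releases it up to the biological ceiling f_bio_eff.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0):
        raise ValueError("zeta must be non-negative")
    if zeta_ref <= 0:
        raise ValueError("zeta_ref must be positive")
    if f_bio_eff < 0:
        raise ValueError("f_bio_eff must be non-negative")
    out = f_bio_eff * zeta_ref / (zeta + zeta_ref)
    return out if out.ndim else float(out)


def origination_rate(f_or: float, s_v: float):
    """BMU origination rate per unit volume, Ṅ_BMU = f_or · S_v (1/(mm³·day))."""
    f_or = np.asarray(f_or, dtype=float)
    s_v = np.asarray(s_v, dtype=float)
    if np.any(f_or < 0) or np.any(s_v < 0):
        raise ValueError("f_or and S_v must be non-negative")
    out = f_or * s_v
    return out if out.ndim else float(out)


def focal_balance(x, kappa_fbb: float = 1.0, params: BMUParams = BMUParams()):
    """Focal bone balance as a function of the stimulus error x = ζ − ζ_ref.

    Piecewise mechanostat curve scaled by the menopause/ageing multiplier κ:
    κ·f_bb_min in deep disuse, a linear rise across the width-v zone, κ·1
    inside the ±w dead zone, a linear rise to κ·f_bb_max across the upper
    linear zone, and κ·f_bb_max in sustained overload.  κ < 1 shifts the
    whole curve down, so even the dead zone yields net resorption.
    """
    if kappa_fbb < 0:
        raise ValueError("kappa_fbb must be non-negative")
    x = np.asarray(x, dtype=float)
    w, v = params.w, params.v
    lo, hi = params.f_bb_min, params.f_bb_max
    out = np.where(
        x <= -(w + v),
        lo,
        np.where(
            x < -w,
            1.0 + (1.0 - lo) * (x + w) / v,
            np.where(
                x <= w,
                1.0,
                np.where(x < w + v, 1.0 + (hi - 1.0) * (x - w) / v, hi),
            ),
        ),
    )
    out = kappa_fbb * out
    return out if out.ndim else float(out)


class BMUHistory:
    """Ring buffers of origination rate and focal balance for the rate integrals.

    Stores 2·(T_R+T_I+T_F) days of origination rates Ṅ_BMU (the active BMU
    density at τ needs the preceding lifespan of originations) and one
    lifespan of focal-balance values.  ``prefill_equilibrium`` pads the
    buffers with a constant origination rate and f_bb = 1 so a run starts at
    steady state.
    """

    def __init__(self, params: BMUParams):
        self.params = params
        W = params.lifespan
        self._ndot: deque[float] = deque(maxlen=2 * W)
        self._fbb: deque[float] = deque(maxlen=W)
        self._nactive: deque[float] = deque(maxlen=W)

    @classmethod
    def equilibrium(cls, n_dot: float, params: BMUParams) -> "BMUHistory":
        h = cls(params)
        h.prefill_equilibrium(n_dot)
        return h

    def prefill_equilibrium(self, n_dot: float) -> None:
        W = self.params.lifespan
        self._ndot.extend([n_dot] * (2 * W))
        self._fbb.extend([1.0] * W)
        self._nactive.extend([n_dot * W] * W)

    @property
    def is_warm(self) -> bool:
        return len(self._ndot) == 2 * self.params.lifespan

    def push(self, n_dot: float, f_bb: float) -> None:
        """Record one day: origination rate Ṅ_BMU and prevailing f_bb."""
        if n_dot < 0:
            raise ValueError("origination rate must be non-negative")
        if not 0.0 <= f_bb <= self.params.f_bb_max:
            raise ValueError("f_bb outside [0, f_bb_max]")
        if self.is_warm:
            n_active = self._nactive[-1] + n_dot - self._ndot[-self.params.lifespan]
        else:
            n_active = sum(list(self._ndot)[-(self.params.lifespan - 1):]) + n_dot
        self._ndot.append(n_dot)
        self._fbb.append(f_bb)
        self._nactive.append(max(n_active, 0.0))

    def _require_warm(self) -> None:
        if not self.is_warm:
            raise ValueError(
                "history warm-up incomplete: need "
                f"{2 * self.params.lifespan} recorded days, have {len(self._ndot)}"
            )

    def n_active_series(self) -> np.ndarray:
        """Active BMU density for the most recent lifespan of days."""
        self._require_warm()
        return np.asarray(self._nactive, dtype=float)

    def fbb_series(self) -> np.ndarray:
        self._require_warm()
        return np.asarray(self._fbb, dtype=float)


def resorption_rate(history: BMUHistory, params: BMUParams) -> float:
    """Daily bone resorption rate v̇_r (volume fraction per day)."""
    nact = history.n_active_series()
    window = nact[-params.T_R:]
    return params.A_BMU * params.v_BMU / params.T_R * float(np.sum(window))

def formation_rate(history: BMUHistory, params: BMUParams) -> float:
    """Daily bone formation rate v̇_f (volume fraction per day).

    Averages N_BMU(τ)·f_bb(τ) over the window [t−T_R−T_I−T_F, t−T_R−T_I):
    the packets being closed today were activated a reversal pipeline ago.
    """
    nact = history.n_active_series()
    fbb = history.fbb_series()
    window = nact[: params.T_F] * fbb[: params.T_F]
    return params.A_BMU * params.v_BMU / params.T_F * float(np.sum(window))


def net_rate(v_f_dot: float, v_r_dot: float) -> float:
    """Net remodeling rate v̇_b = v̇_f − v̇_r (may be negative)."""
    if v_f_dot < 0 or v_r_dot < 0:
        raise ValueError("formation and resorption rates must be non-negative")
    return v_f_dot - v_r_dot


def apply_turnover(stack: LayerStack, v_f_dot: float, v_r_dot: float, dt: float = 1.0) -> LayerStack:
    """Advance the layer stack one step: age, resorb youngest-first, deposit.

    Removes v̇_r·dt from the top of the stack, then pushes a fresh layer of
    thickness v̇_f·dt at age 0; total volume changes by exactly
    (v̇_f − v̇_r)·dt unless resorption empties the stack (clamped, warned).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stack.advance_age(dt)
    stack.resorb(v_r_dot * dt)
    stack.push(v_f_dot * dt, age=0.0)
    return stack


def stack_summary(
    stack: LayerStack,
    law: MineralizationLaw,
    constants: TissueConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """Aggregate a layer stack into (v_b, mean v_m, mean α).

    α is averaged thickness-weighted; v_m is computed per layer from its own
    ash fraction and then thickness-averaged, so total mineral volume is
    conserved under the aggregation.  An empty stack returns zeros.
    """
    if not stack.layers:
        return 0.0, 0.0, 0.0
    th = np.array([l.thickness_vb for l in stack.layers])
    ages = np.array([l.age for l in stack.layers])
    alphas = layer_mineral(ages, law)
    v_b = float(th.sum())
    alpha_mean = float(np.dot(th, alphas) / v_b)
    v_m_mean = float(np.dot(th, mineral_fraction_from_ash(alphas, constants)) / v_b)
    return v_b, v_m_mean, alpha_mean
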