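"""Menopause and ageing modifiers κ(t) for BMU activity and focal balance.

Hormonal change around the last menses (t = 0) is modeled as permanent
multiplicative drifts of two remodeling parameters: the biological
activation frequency f_bio (κ ≥ 1, turnover rises) and the focal bone
balance f_bb (κ ≤ 1, each BMU refills less than it resorbs).  Each κ(t) is
1 before perimenopause onset t1, ramps linearly to a permanent level
κ_perm at postmenopause onset t2, and thereafter drifts linearly with a
long-term per-day slope representing ageing.  κ is floored at zero: once
the balance modifier vanishes, no formation occurs at any stimulus.

Named presets carry the fitted parameter sets for the three fitting
scenarios (turnover-only, balance-only, and simultaneous changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KappaParams",
    "MenopauseSchedule",
    "kappa",
    "effective_parameters",
    "PRESETS",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.0

_SCENARIOS = ("none", "fbio_only", "fbb_only", "combined")


@dataclass(frozen=True)
class KappaParams:
    """One κ(t) ramp: onset t1 < 0 < t2 (years), permanent level, per-day slope."""

    kappa_perm: float = 1.0
    slope_per_day: float = 0.0
    t1: float = -4.0
    t2: float = 4.0

    def __post_init__(self) -> None:
        if not (self.t1 < 0.0 < self.t2):
            raise ValueError("require t1 < 0 < t2 (years relative to last menses)")
        if self.kappa_perm <= 0:
            raise ValueError("kappa_perm must be positive")


IDENTITY_KAPPA = KappaParams()


def kappa(t_years, p: KappaParams):
    """Evaluate κ at time t (years relative to last menses), floored at 0."""
    t = np.asarray(t_years, dtype=float)
    ramp = 1.0 + (p.kappa_perm - 1.0) * (t - p.t1) / (p.t2 - p.t1)
    drift = p.kappa_perm + p.slope_per_day * (t - p.t2) * DAYS_PER_YEAR
    out = np.where(t <= p.t1, 1.0, np.where(t <= p.t2, ramp, drift))
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MenopauseSchedule:
    """κ parameter pair plus the scenario tag that masks non-varying channels.

    scenario "none" forces both κ ≡ 1; "fbio_only"/"fbb_only" mask the other
    channel to identity; "combined" applies both.
    """

    kappa_fbio: KappaParams = IDENTITY_KAPPA
    kappa_fbb: KappaParams = IDENTITY_KAPPA
    scenario: str = "combined"

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.kappa_fbio.kappa_perm < 1.0:
            raise ValueError("kappa_perm for f_bio must be >= 1 (activity rises)")
        if self.kappa_fbb.kappa_perm > 1.0:
            raise ValueError("kappa_perm for f_bb must be <= 1 (balance falls)")

    def kappa_fbio_at(self, t_years):
        if self.scenario in ("none", "fbb_only"):
            return np.ones_like(np.asarray(t_years, dtype=float)) if np.ndim(t_years) else 1.0
        return kappa(t_years, self.kappa_fbio)

    def kappa_fbb_at(self, t_years):
        if self.scenario in ("none", "fbio_only"):
            return np.ones_like(np.asarray(t_years, dtype=float)) if np.ndim(t_years) else 1.0
        return kappa(t_years, self.kappa_fbb)


def effective_parameters(t_years, schedule: MenopauseSchedule, base_fbio: float):
    """Return (f_bio_eff, κ_fbb) at time t under the schedule's scenario."""
    return (
        base_fbio * schedule.kappa_fbio_at(t_years),
        schedule.kappa_fbb_at(t_years),
    )


def _preset(tag: str, perm_bio: float, slope_bio: float, perm_bb: float, slope_bb: float) -> MenopauseSchedule:
    return MenopauseSchedule(
        kappa_fbio=KappaParams(kappa_perm=perm_bio, slope_per_day=slope_bio),
        kappa_fbb=KappaParams(kappa_perm=perm_bb, slope_per_day=slope_bb),
        scenario=tag,
    )


#: Fitted κ parameter presets for the three calibration scenarios (plus the
#: premenopausal reference with both channels frozen at 1).
PRESETS: dict[str, MenopauseSchedule] = {
    "none": MenopauseSchedule(scenario="none"),
    "fbio_only": _preset("fbio_only", 1.489, 3.654e-4, 1.0, 0.0),
    "fbb_only": _preset("fbb_only", 1.0, 0.0, 0.793, -7.085e-5),
    "combined": _preset("combined", 1.230, 1.610e-4, 0.903, -4.452e-5),
}
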