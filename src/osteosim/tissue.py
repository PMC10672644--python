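"""Bone tissue composition and derived material quantities.

Bone at a material point is described by two state variables: the bone
volume fraction ``v_b`` (bone tissue per unit total volume, the complement
of porosity) and the mineral volume fraction ``v_m`` (mineral per unit
*bone tissue* volume).  The organic fraction of the tissue is constant at
``v_o = 3/7``; secondary mineralization replaces tissue water with mineral,
so the water fraction is ``v_w = 1 - v_o - v_m``.

From these, the module derives the ash fraction α (mineral mass over dry
mass), the isotropic elastic modulus ``E = 84370 · v_b^2.58 · α^2.74`` MPa,
bone mineral density ``BMD = ρ_m · v_m · v_b``, the material density ρ_mat
(tissue mass per tissue volume) and apparent density ρ_app = ρ_mat · v_b,
and the specific surface S_v(porosity) on which remodeling units operate.

Units: densities g/cm³, stresses MPa, lengths mm (S_v in 1/mm).
All fraction-valued inputs are clamped when within 1e-12 of their bounds
and rejected beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueConstants",
    "CompositionPoint",
    "DEFAULT_CONSTANTS",
    "MARTIN_SV_COEFFS",
    "ELASTIC_COEFF_MPA",
    "ELASTIC_EXP_VB",
    "ELASTIC_EXP_ALPHA",
    "water_fraction",
    "ash_fraction",
    "mineral_fraction_from_ash",
    "elastic_modulus",
    "bone_mineral_density",
    "material_density",
    "apparent_density",
    "specific_surface",
]

#: Coefficient and exponents of the volume-fraction / ash-fraction power law
#: for the elastic modulus (Hernandez et al., isotropic form).
ELASTIC_COEFF_MPA = 84370.0
ELASTIC_EXP_VB = 2.58
ELASTIC_EXP_ALPHA = 2.74

#: Martin's quintic for free surface area per unit volume as a function of
#: porosity p, in 1/mm:  S_v = 32.3p - 93.9p^2 + 134p^3 - 101p^4 + 28.8p^5.
#: Stored lowest-order first (constant term included) for np.polynomial use.
MARTIN_SV_COEFFS = (0.0, 32.3, -93.9, 134.0, -101.0, 28.8)

_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class TissueConstants:
    """Densities of the tissue constituents and the fixed organic fraction.

    Attributes
    ----------
    rho_m, rho_o, rho_w:
        Densities of the mineral, organic and water phases in g/cm³.
    v_o:
        Organic volume fraction of bone tissue (dimensionless, constant).
    """

    rho_m: float = 3.2
    rho_o: float = 1.1
    rho_w: float = 1.0
    v_o: float = 3.0 / 7.0

    def __post_init__(self) -> None:
        if not (self.rho_m > self.rho_o > self.rho_w > 0):
            raise ValueError(
                "tissue densities must satisfy rho_m > rho_o > rho_w > 0, got "
                f"({self.rho_m}, {self.rho_o}, {self.rho_w})"
            )
        if not (0.0 < self.v_o < 1.0):
            raise ValueError(f"organic fraction v_o must lie in (0, 1), got {self.v_o}")

    @property
    def v_m_max(self) -> float:
        """Largest attainable mineral fraction (all water replaced)."""
        return 1.0 - self.v_o


DEFAULT_CONSTANTS = TissueConstants()


def _clamped(x, lo: float, hi: float, name: str):
    """Clamp values within ``_CLAMP_TOL`` of [lo, hi]; error beyond."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < lo - _CLAMP_TOL) or np.any(arr > hi + _CLAMP_TOL):
        raise ValueError(f"{name} outside [{lo}, {hi}]: {x!r}")
    out = np.clip(arr, lo, hi)
    return out if arr.ndim else float(out)


def water_fraction(v_m, constants: TissueConstants = DEFAULT_CONSTANTS):
    """Water volume fraction of bone tissue, ``1 - v_o - v_m``.

    Mineral deposition during secondary mineralization displaces tissue
    water one-for-one, so composition closure is exact by construction.
    """
    v_m = _clamped(v_m, 0.0, constants.v_m_max, "v_m")
    return 1.0 - constants.v_o - v_m


def ash_fraction(v_m, constants: TissueConstants = DEFAULT_CONSTANTS):
    """Ash fraction α: mineral mass over dry (mineral + organic) mass."""
    v_m = _clamped(v_m, 0.0, constants.v_m_max, "v_m")
    mineral = constants.rho_m * v_m
    return mineral / (mineral + constants.rho_o * constants.v_o)


def mineral_fraction_from_ash(alpha, constants: TissueConstants = DEFAULT_CONSTANTS):
    """Invert :func:`ash_fraction`: mineral volume fraction at a given α."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < -_CLAMP_TOL) or np.any(alpha >= 1.0):
        raise ValueError(f"ash fraction must lie in [0, 1): {alpha!r}")
    alpha = np.clip(alpha, 0.0, None)
    out = constants.rho_o * constants.v_o * alpha / (constants.rho_m * (1.0 - alpha))
    return out if out.ndim else float(out)


def elastic_modulus(v_b, alpha):
    """Isotropic elastic modulus in MPa from volume fraction and ash fraction."""
    v_b = _clamped(v_b, 0.0, 1.0, "v_b")
    alpha = _clamped(alpha, 0.0, 1.0, "alpha")
    return ELASTIC_COEFF_MPA * v_b**ELASTIC_EXP_VB * alpha**ELASTIC_EXP_ALPHA


def bone_mineral_density(v_b, v_m, constants: TissueConstants = DEFAULT_CONSTANTS):
    """Volumetric bone mineral density ``ρ_m · v_m · v_b`` in g/cm³."""
    v_b = _clamped(v_b, 0.0, 1.0, "v_b")
    v_m = _clamped(v_m, 0.0, 1.0, "v_m")
    return constants.rho_m * v_m * v_b


def material_density(v_m, constants: TissueConstants = DEFAULT_CONSTANTS):
    """Tissue (material) density ρ_mat in g/cm³, excluding pore volume."""
    v_m = _clamped(v_m, 0.0, constants.v_m_max, "v_m")
    v_w = 1.0 - constants.v_o - v_m
    return constants.rho_m * v_m + constants.rho_o * constants.v_o + constants.rho_w * v_w


def apparent_density(rho_mat, v_b):
    """Apparent density ρ_app = ρ_mat · v_b in g/cm³ (pores included)."""
    rho_mat = np.asarray(rho_mat, dtype=float)
    if np.any(rho_mat < 0):
        raise ValueError("rho_mat must be non-negative")
    v_b = _clamped(v_b, 0.0, 1.0, "v_b")
    out = rho_mat * v_b
    return out if np.ndim(out) else float(out)


def specific_surface(porosity, coeffs=MARTIN_SV_COEFFS):
    """Free surface area per unit volume S_v(porosity) in 1/mm.

    The default is Martin's quintic, which vanishes at zero porosity (and,
    to within the rounding of its published coefficients, at full porosity)
    and peaks in the cortical-to-trabecular transition zone (argmax ≈ 0.37),
    so remodeling activity is highest in transitional tissue.  Alternative
    polynomial coefficients (lowest order first) may be supplied.
    """
    porosity = _clamped(porosity, 0.0, 1.0, "porosity")
    out = np.polynomial.polynomial.polyval(porosity, np.asarray(coeffs, dtype=float))
    return out if np.ndim(porosity) else float(out)


@dataclass(frozen=True)
class CompositionPoint:
    """Composition of one material point with its derived quantities."""

    v_b: float
    v_m: float
    constants: TissueConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        _clamped(self.v_b, 0.0, 1.0, "v_b")
        _clamped(self.v_m, 0.0, self.constants.v_m_max, "v_m")

    @property
    def v_w(self) -> float:
        return water_fraction(self.v_m, self.constants)

    @property
    def alpha(self) -> float:
        return ash_fraction(self.v_m, self.constants)

    @property
    def porosity(self) -> float:
        return 1.0 - self.v_b

    @property
    def elastic_modulus(self) -> float:
        return elastic_modulus(self.v_b, self.alpha)

    @property
    def bmd(self) -> float:
        return bone_mineral_density(self.v_b, self.v_m, self.constants)

    @property
    def rho_mat(self) -> float:
        return material_density(self.v_m, self.constants)

    @property
    def rho_app(self) -> float:
        return apparent_density(self.rho_mat, self.v_b)
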