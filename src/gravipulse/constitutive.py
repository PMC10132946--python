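"""Vessel wall mechanics.

Distensibility-based tube law for large arteries.  The reference
distensibility ``Dref`` (at the 100 mmHg reference pressure) follows from an
empirical diameter--wave-speed law through the Bramwell--Hill relation
``D = 1/(rho c^2)``.  Strain stiffening is captured by a bell-shaped
pressure-dependent distensibility ``D_P`` whose exact integral gives a
closed-form area--pressure law ``A(P)``.  A sigmoidal remodeling law maps the
gestational growth stretches of uterine vessels onto a change of reference
distensibility.

All pressures in this module are in kPa and distensibilities in 1/kPa;
diameters in cm; blood density in kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WallLawParams",
    "RemodelingParams",
    "GrowthStretches",
    "reference_distensibility",
    "distensibility_at_pressure",
    "area_from_pressure",
    "pressure_from_area",
    "remodel_reference_distensibility",
]

MMHG_PER_KPA = 7.500617  # 1 kPa = 7.5006 mmHg
KPA_PER_MMHG = 1.0 / MMHG_PER_KPA


@dataclass(frozen=True)
class WallLawParams:
    """Parameters of the strain-stiffening distensibility law.

    ``a1`` and ``b1`` are dimensionless; ``PmaxC`` (pressure of maximal
    compliance) and ``Pwidth`` (width of the compliance bell) are in kPa.
    ``Pref`` is the reference pressure in kPa (100 mmHg).  ``a2``/``b2``
    parameterize the empirical wave-speed law c = a2 / dbar**b2 with c in m/s
    and dbar in cm; they are configuration, chosen so that a nongravid
    ascending aorta (~2.6 cm) has c ~ 5 m/s and an arm artery (~0.5 cm)
    c ~ 9 m/s.
    """

    a1: float = 0.4
    b1: float = 5.0
    PmaxC: float = 2.67
    Pwidth: float = 4.0
    Pref: float = 100.0 * KPA_PER_MMHG
    a2: float = 7.03
    b2: float = 0.3565

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.b1 <= 0 or self.Pwidth <= 0:
            raise ValueError("a1, b1 and Pwidth must be positive")


@dataclass(frozen=True)
class RemodelingParams:
    """Parameters of the sigmoidal gestational remodeling of ``Dref``.

    With the default negative ``kr3`` a growing uterine vessel
    (lam_theta*lam_z > 1) becomes stiffer relative to the nongravid wall.
    ``Ro`` normalizes the law so that it is the identity at
    lam_theta*lam_z = 1.
    """

    kr1: float = 2.2
    kr2: float = 1.7
    kr3: float = -0.85

    @property
    def Ro(self) -> float:
        ro = 1.0 + self.kr3 / (1.0 + np.exp(-self.kr1 * (1.0 - self.kr2)))
        if ro == 0.0:
            raise ValueError("remodeling normalization Ro is zero")
        return ro


@dataclass(frozen=True)
class GrowthStretches:
    """Gestational growth stretches of a uterine-circuit vessel.

    ``lam_theta`` = d(s)/d(0) and ``lam_z`` = l(s)/l(0) are the fractional
    diameter and length increases from the nongravid state at gestational
    age ``s`` (weeks).
    """

    lam_theta: float = 1.0
    lam_z: float = 1.0
    s: float = 0.0


def reference_distensibility(
    dbar_cm: float | np.ndarray,
    rho: float = 1050.0,
    params: WallLawParams = WallLawParams(),
) -> float | np.ndarray:
    """Reference distensibility (1/kPa) of a vessel of diameter ``dbar_cm``.

    Bramwell--Hill form of the empirical wave-speed law:
    Dref = 1 / (rho * (a2 / dbar**b2)**2), with rho in kg/m^3 and the wave
    speed in m/s, converted to 1/kPa.
    """
    dbar = np.asarray(dbar_cm, dtype=float)
    if np.any(dbar <= 0):
        raise ValueError("diameter must be positive")
    c = params.a2 / dbar**params.b2  # m/s
    d_per_pa = 1.0 / (rho * c**2)
    out = d_per_pa * 1e3  # 1/Pa -> 1/kPa
    return float(out) if np.isscalar(dbar_cm) else out


def distensibility_at_pressure(
    P_kpa: float | np.ndarray,
    Dref: float | np.ndarray,
    params: WallLawParams = WallLawParams(),
) -> float | np.ndarray:
    """Strain-stiffening distensibility D_P at pressure ``P_kpa``.

    D_P = [a1 + b1 / (1 + ((P - PmaxC)/Pwidth)^2)] * Dref.  Maximal at
    P = PmaxC, tending to a1*Dref far from it, even-symmetric about PmaxC.
    """
    x = (np.asarray(P_kpa, dtype=float) - params.PmaxC) / params.Pwidth
    out = (params.a1 + params.b1 / (1.0 + x * x)) * Dref
    return float(out) if np.ndim(out) == 0 else out


def area_from_pressure(
    P_kpa: float | np.ndarray,
    Aref_cm2: float | np.ndarray,
    Dref: float | np.ndarray,
    params: WallLawParams = WallLawParams(),
) -> float | np.ndarray:
    """Lumen area (cm^2) at pressure ``P_kpa``; exact integral of D_P.

    A(P) = Aref * exp[a1 Dref (P - Pref)
                      + b1 Dref Pwidth (atan((P-PmaxC)/Pwidth)
                                        - atan((Pref-PmaxC)/Pwidth))]
    Strictly increasing in P; equals Aref at P = Pref.
    """
    P = np.asarray(P_kpa, dtype=float)
    atan_ref = np.arctan((params.Pref - params.PmaxC) / params.Pwidth)
    expo = params.a1 * Dref * (P - params.Pref) + params.b1 * Dref * params.Pwidth * (
        np.arctan((P - params.PmaxC) / params.Pwidth) - atan_ref
    )
    out = Aref_cm2 * np.exp(expo)
    return float(out) if np.ndim(out) == 0 else out


def pressure_from_area(
    A_cm2: float,
    Aref_cm2: float,
    Dref: float,
    params: WallLawParams = WallLawParams(),
    tol: float = 1e-12,
    max_iter: int = 100,
) -> float:
    """Invert the area--pressure law (safeguarded Newton on the monotone map).

    Returns P in kPa such that ``area_from_pressure(P) == A_cm2`` to within
    ``tol`` relative.  Raises ``RuntimeError`` on non-convergence.
    """
    if A_cm2 <= 0:
        raise ValueError("area must be positive")
    # ln(A/Aref) is monotone in P with derivative D_P > 0
    target = np.log(A_cm2 / Aref_cm2)

    def g(P: float) -> float:
        return float(np.log(area_from_pressure(P, Aref_cm2, Dref, params) / Aref_cm2))

    # bracket around Pref
    lo, hi = params.Pref - 1.0, params.Pref + 1.0
    for _ in range(200):
        if g(lo) <= target:
            break
        lo -= max(1.0, abs(lo))
    for _ in range(200):
        if g(hi) >= target:
            break
        hi += max(1.0, abs(hi))
    P = 0.5 * (lo + hi)
    for _ in range(max_iter):
        gP = g(P)
        if gP > target:
            hi = P
        else:
            lo = P
        dP = distensibility_at_pressure(P, Dref, params)
        step = (target - gP) / dP
        P_new = P + step
        if not (lo < P_new < hi):
            P_new = 0.5 * (lo + hi)  # bisection safeguard
        if abs(P_new - P) <= tol * max(1.0, abs(P)):
            return P_new
        P = P_new
    raise RuntimeError(
        f"pressure_from_area failed to converge: A={A_cm2}, bracket=({lo},{hi})"
    )


def remodel_reference_distensibility(
    Dref0: float | np.ndarray,
    growth: GrowthStretches,
    params: RemodelingParams = RemodelingParams(),
) -> float | np.ndarray:
    """Gestationally remodeled reference distensibility.

    Dref(s) = (Dref0 / Ro) * [1 + kr3 / (1 + exp(-kr1 (lam_theta lam_z - kr2)))]
    where Ro is the bracket at lam_theta*lam_z = 1, so the map is the identity
    for a nongravid vessel.  Monotone (decreasing for kr3 < 0) in the stretch
    product.
    """
    lam = growth.lam_theta * growth.lam_z
    if lam < 0:
        raise ValueError("growth stretch product must be non-negative")
    bracket = 1.0 + params.kr3 / (1.0 + np.exp(-params.kr1 * (lam - params.kr2)))
    return Dref0 * bracket / params.Ro
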