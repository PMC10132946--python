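"""Gestational input/target trajectories for the three pregnancy scenarios.

Each scenario (normal pregnancy, early preeclampsia, late preeclampsia) is a
set of gestational curves -- anchor points joined by monotone piecewise-cubic
(PCHIP) interpolation -- for cardiac output, heart rate, mean arterial
pressure, uterine-artery pulsatility index, uterine flow fraction and uterine
vessel lengthening.  The preeclampsia scenarios are expressed as
multiples-of-the-mean (MoM) multiplier curves on the normal scenario; the
MAP multiplier is constructed as TPR MoM x CO MoM so that the prescribed
total-peripheral-resistance trajectories hold identically.

Anchor values: normal CO rises 30% conception to term; early preeclampsia
runs at ~82% of normal CO at 12 weeks and 80% beyond 20 weeks with TPR
1.10/1.24/1.70-fold at 0/12/32 weeks and UA-PI 1.4-fold at 12 weeks rising
to 2.0-fold in the third trimester; late preeclampsia runs at ~7% higher CO
at 12 weeks and ~5% beyond 20 weeks with near-normal TPR until 32 weeks
rising to 1.14-fold at 36 weeks and UA-PI ~1.1-fold at 12 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constitutive import GrowthStretches

__all__ = [
    "GestationalCurve",
    "ScenarioSpec",
    "TargetSet",
    "SCENARIOS",
    "scenario",
    "targets_for",
    "uterine_growth",
    "mom",
]

GESTATION_WEEKS = 40.0


class GestationalCurve:
    """Anchor points joined by monotone (shape-preserving) cubic interpolation.

    Evaluation at an anchor returns the anchor value exactly; between anchors
    PCHIP introduces no overshoot.
    """

    def __init__(self, anchors: list[tuple[float, float]]):
        s = np.array([a[0] for a in anchors], dtype=float)
        v = np.array([a[1] for a in anchors], dtype=float)
        if np.any(np.diff(s) <= 0):
            raise ValueError("anchors must be strictly increasing in s")
        self.anchors = [(float(a), float(b)) for a, b in anchors]
        if len(s) == 1:
            self._f = lambda x: np.full_like(np.asarray(x, dtype=float), v[0])
        else:
            self._f = PchipInterpolator(s, v, extrapolate=False)
        self._s0, self._s1 = float(s[0]), float(s[-1])
        self._v0, self._v1 = float(v[0]), float(v[-1])

    def __call__(self, s: float | np.ndarray) -> float | np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.where(s <= self._s0, self._v0,
                       np.where(s >= self._s1, self._v1, 0.0))
        inside = (s > self._s0) & (s < self._s1)
        if np.any(inside):
            out = np.where(inside, self._f(np.clip(s, self._s0, self._s1)), out)
        return float(out) if out.ndim == 0 else out


@dataclass
class ScenarioSpec:
    """One pregnancy scenario: absolute curves for normal, MoM curves for PE."""

    name: str
    co_mom: GestationalCurve
    tpr_mom: GestationalCurve
    uapi_mom: GestationalCurve
    hr_mom: GestationalCurve
    uterine_flow_mom: GestationalCurve
    dref_multiplier: float = 1.0     # preexisting arterial stiffness (<1 stiffer)

    @property
    def is_normal(self) -> bool:
        return self.name == "normal"


@dataclass
class TargetSet:
    """Calibration inputs/targets at one gestational age for one scenario."""

    s: float
    CO: float                  # L/min (prescribed input)
    HR: float                  # bpm (prescribed input)
    MAP: float                 # mmHg target
    SBP: float                 # mmHg target
    UA_PI: float               # dimensionless target
    flow_fractions: dict[str, float]  # region group -> fraction of CO
    lam_z: float               # uterine-circuit axial growth stretch
    dref_multiplier: float
    tolerance: float = 0.02


# normal-pregnancy absolute baselines (configurable via `baseline` argument)
_NORMAL_BASE = {
    "CO": GestationalCurve([(0, 5.0), (12, 5.9), (20, 6.3), (32, 6.5), (40, 6.5)]),
    "HR": GestationalCurve([(0, 70), (12, 75), (24, 80), (40, 85)]),
    "MAP": GestationalCurve([(0, 85), (12, 82), (20, 81), (32, 84), (40, 86)]),
    "UA_PI": GestationalCurve([(0, 3.0), (12, 1.8), (20, 1.0), (28, 0.85), (40, 0.75)]),
    # nongravid bilateral uterine flow ~30 mL/min (0.6% of CO): mid-range of
    # reported values and jointly consistent with the ~2 mm lumped uterine
    # supply and a nongravid time-averaged velocity of ~8-12 cm/s
    "uterine_fraction": GestationalCurve(
        [(0, 0.006), (12, 0.035), (20, 0.06), (32, 0.09), (40, 0.10)]),
    "lam_z": GestationalCurve([(0, 1.0), (12, 1.15), (20, 1.3), (32, 1.5), (40, 1.6)]),
    # systemic (whole-tree) distensibility multiplier: global arterial
    # compliance rises ~30% by mid-pregnancy (PWV falls), partly reversing
    # toward term
    "distensibility": GestationalCurve(
        [(0, 1.0), (12, 1.2), (20, 1.3), (32, 1.3), (40, 1.25)]),
}

PULSE_PRESSURE_FACTOR = 1.35       # SBP target = MAP target x this
FLOW_FRACTIONS = {"cerebral": 0.12, "limb": 0.25, "renal": 0.18}

_UNIT = GestationalCurve([(0, 1.0), (40, 1.0)])

SCENARIOS: dict[str, ScenarioSpec] = {
    "normal": ScenarioSpec(
        name="normal", co_mom=_UNIT, tpr_mom=_UNIT, uapi_mom=_UNIT,
        hr_mom=_UNIT, uterine_flow_mom=_UNIT, dref_multiplier=1.0),
    "early_pe": ScenarioSpec(
        name="early_pe",
        co_mom=GestationalCurve([(0, 0.97), (12, 0.82), (20, 0.80), (40, 0.80)]),
        tpr_mom=GestationalCurve(
            [(0, 1.10), (12, 1.24), (20, 1.35), (32, 1.70), (40, 1.85)]),
        uapi_mom=GestationalCurve(
            [(0, 1.0), (12, 1.4), (24, 1.85), (28, 2.0), (40, 2.0)]),
        hr_mom=GestationalCurve([(0, 1.0), (12, 0.97), (20, 0.95), (40, 0.95)]),
        uterine_flow_mom=GestationalCurve(
            [(0, 1.0), (12, 0.7), (20, 0.55), (32, 0.47), (40, 0.45)]),
        dref_multiplier=0.88),
    "late_pe": ScenarioSpec(
        name="late_pe",
        co_mom=GestationalCurve([(0, 1.0), (12, 1.07), (20, 1.05), (40, 1.05)]),
        tpr_mom=GestationalCurve(
            [(0, 1.0), (12, 0.98), (32, 1.0), (36, 1.14), (40, 1.20)]),
        uapi_mom=GestationalCurve([(0, 1.0), (12, 1.10), (32, 1.15), (40, 1.30)]),
        hr_mom=GestationalCurve([(0, 1.0), (12, 1.03), (40, 1.05)]),
        uterine_flow_mom=GestationalCurve(
            [(0, 1.0), (12, 0.95), (32, 0.90), (40, 0.85)]),
        dref_multiplier=0.88),
}


def scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {sorted(SCENARIOS)}") from None


def mom(value: float, normal_value: float) -> float:
    """Multiples of the mean: value / matched normal-pregnancy value."""
    if normal_value == 0:
        raise ValueError("normal value must be nonzero")
    return value / normal_value


def targets_for(
    s: float,
    spec: ScenarioSpec | str,
    baseline: dict[str, GestationalCurve] | None = None,
) -> TargetSet:
    """Evaluate all scenario curves at gestational age ``s`` (weeks).

    PE scenarios apply their MoM multipliers to the normal curves; the MAP
    multiplier is TPR MoM x CO MoM.  The uterine flow-fraction target is the
    normal fraction times the uterine-flow MoM divided by the CO MoM (the
    MoM is a ratio of absolute flows, the fraction refers to the scenario's
    own CO).
    """
    if not (0.0 <= s <= GESTATION_WEEKS):
        raise ValueError(f"gestational age {s} outside [0, {GESTATION_WEEKS}] weeks")
    if isinstance(spec, str):
        spec = scenario(spec)
    base = baseline or _NORMAL_BASE
    co_m = spec.co_mom(s)
    tpr_m = spec.tpr_mom(s)
    map_m = tpr_m * co_m
    CO = base["CO"](s) * co_m
    HR = base["HR"](s) * spec.hr_mom(s)
    MAP = base["MAP"](s) * map_m
    UA_PI = base["UA_PI"](s) * spec.uapi_mom(s)
    ut_frac = base["uterine_fraction"](s) * spec.uterine_flow_mom(s) / co_m
    fractions = dict(FLOW_FRACTIONS)
    fractions["uterine"] = float(ut_frac)
    fractions["trunk"] = 1.0 - sum(fractions.values())
    return TargetSet(
        s=float(s), CO=float(CO), HR=float(HR), MAP=float(MAP),
        SBP=float(MAP * PULSE_PRESSURE_FACTOR), UA_PI=float(UA_PI),
        flow_fractions=fractions, lam_z=float(uterine_growth(s, spec).lam_z),
        dref_multiplier=float(base["distensibility"](s) * spec.dref_multiplier))


def uterine_growth(
    s: float,
    spec: ScenarioSpec | str,
    diameter_ratio: float = 1.0,
    baseline: dict[str, GestationalCurve] | None = None,
) -> GrowthStretches:
    """Growth stretches of a uterine-circuit vessel at age ``s``.

    ``lam_theta`` is the current-to-nongravid diameter ratio (an outcome of
    shear-driven growth, passed in by the caller); ``lam_z`` follows the
    prescribed lengthening curve, attenuated in preeclampsia in proportion to
    the cube root of the uterine-flow MoM (less flow-driven remodeling).
    Nongravid vessels have both stretches equal to 1.
    """
    if isinstance(spec, str):
        spec = scenario(spec)
    base = baseline or _NORMAL_BASE
    lam_z_n = base["lam_z"](s)
    atten = spec.uterine_flow_mom(s) ** (1.0 / 3.0)
    lam_z = 1.0 + (lam_z_n - 1.0) * atten
    return GrowthStretches(lam_theta=float(diameter_ratio), lam_z=float(lam_z), s=float(s))
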