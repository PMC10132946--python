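"""Hemodynamic summary metrics from simulated waveforms.

Pulsatility index (Gosling), SBP/DBP/MAP, total peripheral resistance, mean
wall shear stress, foot-to-foot pulse wave velocity (intersecting-tangent
method), augmentation index (AIx and its heart-rate-normalized AIx75), and
RMSE goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveformSummary",
    "StiffnessSummary",
    "pulsatility_index",
    "mean_wall_shear",
    "total_peripheral_resistance",
    "pwv_foot_to_foot",
    "augmentation_index",
    "rmse",
    "summarize_pressure",
    "mom",
]


@dataclass
class WaveformSummary:
    SBP: float                  # mmHg
    DBP: float
    MAP: float
    PP: float                   # SBP - DBP
    mean_velocity: float = float("nan")   # cm/s
    peak_velocity: float = float("nan")
    min_velocity: float = float("nan")
    PI: float = float("nan")
    mean_flow: float = float("nan")       # mL/s


@dataclass
class StiffnessSummary:
    AIx: float                  # % of pulse pressure
    AIx75: float                # %
    AP: float                   # augmentation pressure P2 - P1, mmHg
    P1: float
    P2: float
    cf_PWV: float = float("nan")   # m/s
    cr_PWV: float = float("nan")


def summarize_pressure(P_mmHg: np.ndarray) -> WaveformSummary:
    """SBP/DBP/MAP/PP of one cycle of a pressure waveform (time mean = MAP)."""
    P = np.asarray(P_mmHg, dtype=float)
    sbp, dbp = float(np.max(P)), float(np.min(P))
    return WaveformSummary(SBP=sbp, DBP=dbp, MAP=float(np.mean(P)), PP=sbp - dbp)


def pulsatility_index(v: np.ndarray) -> float:
    """Gosling pulsatility index (vmax - vmin)/vmean of one velocity cycle.

    The standard obstetric-Doppler definition; scale invariant.  Raises
    ``ValueError`` for nonpositive mean velocity (reversed mean flow).
    """
    v = np.asarray(v, dtype=float)
    vmean = float(np.mean(v))
    if vmean <= 0:
        raise ValueError("nonpositive mean velocity: PI undefined (reversed mean flow)")
    return float((np.max(v) - np.min(v)) / vmean)


def mean_wall_shear(Q_ml_s: float, d_cm: float, mu_mpa_s: float = 4.0) -> float:
    """Poiseuille mean wall shear stress tau = 32 mu Qbar / (pi d^3), in Pa."""
    if d_cm <= 0:
        raise ValueError("diameter must be positive")
    mu = mu_mpa_s * 1e-3            # Pa.s
    Q = Q_ml_s * 1e-6               # m^3/s
    d = d_cm * 1e-2                 # m
    return 32.0 * mu * Q / (np.pi * d**3)


def total_peripheral_resistance(MAP_mmHg: float, CO_lpm: float) -> float:
    """TPR = MAP/CO in mmHg.min/L (venous pressure neglected)."""
    if CO_lpm <= 0:
        raise ValueError("CO must be positive")
    return MAP_mmHg / CO_lpm


def mom(value: float, normal_value: float) -> float:
    """Multiples of the mean: ratio of a value to its normal-pregnancy match."""
    if normal_value == 0:
        raise ValueError("normal value must be nonzero")
    return value / normal_value


def _foot_time(t: np.ndarray, P: np.ndarray) -> float:
    """Wave foot by the intersecting-tangent method.

    Intersection of the horizontal tangent at the cycle minimum with the
    tangent at the steepest systolic upstroke.  The waveform is rolled so the
    upstroke does not wrap around the cycle boundary.
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    n = len(P)
    dt = t[1] - t[0]
    # roll so that the global minimum sits at index n//4
    imin = int(np.argmin(P))
    shift = n // 4 - imin
    P = np.roll(P, shift)
    dP = np.gradient(P, dt)
    i0 = n // 4
    iup = i0 + int(np.argmax(dP[i0:i0 + n // 2]))
    Pmin = float(np.min(P))
    slope = float(dP[iup])
    if slope <= 0:
        raise ValueError("no systolic upstroke found")
    t_cross = t[iup] - (P[iup] - Pmin) / slope
    return float((t_cross - shift * dt) % (n * dt))


def pwv_foot_to_foot(
    t: np.ndarray,
    P_site1: np.ndarray,
    P_site2: np.ndarray,
    path_length_cm: float,
) -> float:
    """Foot-to-foot pulse wave velocity between two sites, in m/s.

    ``path_length_cm`` is the effective path; for carotid-femoral PWV use the
    clinical subtraction convention (inlet-to-femoral distance minus
    inlet-to-carotid distance).  Transit time is the difference of the
    intersecting-tangent feet, taken modulo the cycle.
    """
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    tc = float(t[-1] - t[0] + (t[1] - t[0]))
    dt_f = (_foot_time(t, P_site2) - _foot_time(t, P_site1)) % tc
    if dt_f <= 0 or dt_f > 0.5 * tc:
        raise ValueError(
            f"transit time {dt_f:.4f} s not in (0, tc/2]: sites mis-ordered?")
    return path_length_cm * 1e-2 / dt_f


def augmentation_index(
    t: np.ndarray,
    P_aorta_mmHg: np.ndarray,
    HR: float,
) -> StiffnessSummary | None:
    """Pulse-wave-analysis augmentation index of an aortic pressure cycle.

    P1 is the shoulder of the advancing wave (first zero crossing of the 4th
    derivative after the steepest upstroke), P2 the systolic peak of the
    composite wave; AP = P2 - P1, AIx = 100*AP/PP, and
    AIx75 = 0.39*(HR - 75) + AIx.  Returns None when no inflection can be
    found (flagged undefined rather than an error).
    """
    P = np.asarray(P_aorta_mmHg, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(P)
    dt = t[1] - t[0]
    summ = summarize_pressure(P)
    if summ.PP <= 0:
        return None
    # roll the minimum to the front quarter
    imin = int(np.argmin(P))
    P = np.roll(P, n // 4 - imin)
    ipk = int(np.argmax(P))
    dP = np.gradient(P, dt)
    iup = n // 4 + int(np.argmax(dP[n // 4:n // 4 + n // 2]))
    # smooth before the 4th derivative (finite differences amplify noise)
    kernel = np.ones(max(3, n // 100)) / max(3, n // 100)
    Ps = np.convolve(P, kernel, mode="same")
    d4 = Ps
    for _ in range(4):
        d4 = np.gradient(d4, dt)
    # shoulder: first zero crossing of the 4th derivative between the
    # upstroke and shortly after the peak.  The advancing-wave shoulder sits
    # in the upper half of the pulse; crossings below half the pulse height
    # are derivative ringing from the upstroke, not a systolic shoulder.
    lo = min(iup + 1, n - 2)
    hi = min(ipk + n // 20 + 1, n - 1)
    floor = summ.DBP + 0.5 * summ.PP
    shoulder = None
    for i in range(lo, hi):
        if (d4[i] == 0 or d4[i] * d4[i + 1] < 0) and P[i] >= floor:
            shoulder = i
            break
    if shoulder is None or shoulder == ipk:
        # single-peak waveform with no discernible reflection
        P1 = P2 = float(P[ipk])
    else:
        sh_val = float(P[shoulder])
        pk_val = float(P[ipk])
        if shoulder < ipk:
            P1, P2 = sh_val, pk_val       # late-systolic augmentation
        else:
            P1, P2 = pk_val, sh_val       # early peak, shoulder after
    AP = P2 - P1
    AIx = 100.0 * AP / summ.PP
    return StiffnessSummary(AIx=AIx, AIx75=0.39 * (HR - 75.0) + AIx,
                            AP=AP, P1=P1, P2=P2)


def rmse(data: np.ndarray, model: np.ndarray) -> float:
    """Root mean square error sqrt(sum((data-model)^2)/n)."""
    data = np.atleast_1d(np.asarray(data, dtype=float))
    model = np.atleast_1d(np.asarray(model, dtype=float))
    if data.size == 0:
        raise ValueError("empty data")
    return float(np.sqrt(np.mean((data - model) ** 2)))
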