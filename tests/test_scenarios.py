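"""Gestational curves and scenario target tables."""

import numpy as np
import pytest

from gravipulse.scenarios import (
    GestationalCurve,
    SCENARIOS,
    scenario,
    targets_for,
    uterine_growth,
)


def test_curve_is_exact_at_anchors():
    anchors = [(0, 1.0), (12, 1.24), (32, 1.7), (40, 1.85)]
    c = GestationalCurve(anchors)
    for s, v in anchors:
        assert c(s) == pytest.approx(v, rel=1e-14)


def test_curve_is_monotone_between_monotone_anchors():
    c = GestationalCurve([(0, 1.0), (12, 2.0), (40, 5.0)])
    s = np.linspace(0, 40, 401)
    assert np.all(np.diff(c(s)) >= 0)


def test_curve_clamps_outside_anchor_range():
    c = GestationalCurve([(10, 2.0), (30, 4.0)])
    assert c(0.0) == 2.0 and c(40.0) == 4.0


def test_curve_rejects_unsorted_anchors():
    with pytest.raises(ValueError):
        GestationalCurve([(10, 1.0), (5, 2.0)])


def test_unknown_scenario_raises():
    with pytest.raises(ValueError, match="unknown scenario"):
        scenario("mystery")


def test_age_outside_gestation_raises():
    with pytest.raises(ValueError):
        targets_for(-1.0, "normal")
    with pytest.raises(ValueError):
        targets_for(41.0, "normal")


def test_normal_baseline_values():
    t = targets_for(0.0, "normal")
    assert t.CO == pytest.approx(5.0)
    assert t.HR == pytest.approx(70.0)
    assert t.MAP == pytest.approx(85.0)
    assert t.flow_fractions["uterine"] == pytest.approx(0.006)


def test_flow_fractions_sum_to_one():
    for name in SCENARIOS:
        for s in (0.0, 12.0, 24.0, 40.0):
            t = targets_for(s, name)
            assert sum(t.flow_fractions.values()) == pytest.approx(1.0)
            assert all(f > 0 for f in t.flow_fractions.values())


def test_early_pe_tpr_mom_anchor_values():
    """Prescribed TPR MoM = (MAP MoM)/(CO MoM) holds by construction."""
    for s, expected in ((0.0, 1.10), (12.0, 1.24), (32.0, 1.70)):
        e, n = targets_for(s, "early_pe"), targets_for(s, "normal")
        tpr_mom = (e.MAP / e.CO) / (n.MAP / n.CO)
        assert tpr_mom == pytest.approx(expected, rel=1e-12)


def test_late_pe_tpr_mom_at_36_weeks():
    e, n = targets_for(36.0, "late_pe"), targets_for(36.0, "normal")
    assert (e.MAP / e.CO) / (n.MAP / n.CO) == pytest.approx(1.14, rel=1e-12)


def test_early_pe_co_runs_low_late_pe_high():
    for s in (24.0, 32.0, 40.0):
        n = targets_for(s, "normal").CO
        assert targets_for(s, "early_pe").CO / n == pytest.approx(0.80, rel=1e-9)
        assert targets_for(s, "late_pe").CO / n == pytest.approx(1.05, rel=1e-9)
    n12 = targets_for(12.0, "normal").CO
    assert targets_for(12.0, "late_pe").CO / n12 == pytest.approx(1.07, rel=1e-9)


def test_normal_co_rises_at_least_20_percent_to_term():
    t0, t40 = targets_for(0.0, "normal"), targets_for(40.0, "normal")
    assert t40.CO / t0.CO >= 1.20


def test_uapi_mom_anchors():
    e12, n12 = targets_for(12.0, "early_pe"), targets_for(12.0, "normal")
    assert e12.UA_PI / n12.UA_PI == pytest.approx(1.4, rel=1e-12)
    e32, n32 = targets_for(32.0, "early_pe"), targets_for(32.0, "normal")
    assert e32.UA_PI / n32.UA_PI == pytest.approx(2.0, rel=1e-12)
    l12 = targets_for(12.0, "late_pe")
    assert l12.UA_PI / n12.UA_PI == pytest.approx(1.10, rel=1e-12)


def test_normal_uterine_flow_fold_change_exceeds_8():
    t0, t40 = targets_for(0.0, "normal"), targets_for(40.0, "normal")
    fold = (t40.flow_fractions["uterine"] * t40.CO) / (
        t0.flow_fractions["uterine"] * t0.CO)
    assert fold >= 8.0


def test_pe_scenarios_are_stiffer():
    for s in (0.0, 24.0):
        n = targets_for(s, "normal")
        for name in ("early_pe", "late_pe"):
            assert targets_for(s, name).dref_multiplier < n.dref_multiplier


def test_uterine_growth_stretches():
    g0 = uterine_growth(0.0, "normal")
    assert (g0.lam_theta, g0.lam_z) == (1.0, 1.0)
    g40 = uterine_growth(40.0, "normal", diameter_ratio=2.0)
    assert g40.lam_theta == 2.0
    assert g40.lam_z == pytest.approx(1.6, rel=1e-12)
    # impaired lengthening in early PE (reduced flow-driven remodeling)
    assert uterine_growth(40.0, "early_pe").lam_z < g40.lam_z
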