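"""Metric oracles on constructed waveforms."""

import numpy as np
import pytest

from gravipulse.metrics import (
    augmentation_index,
    mean_wall_shear,
    mom,
    pulsatility_index,
    pwv_foot_to_foot,
    rmse,
    summarize_pressure,
    total_peripheral_resistance,
)


def test_pulsatility_index_on_offset_sine():
    t = np.linspace(0, 1, 500, endpoint=False)
    v = 10.0 + 4.0 * np.sin(2 * np.pi * t)
    # (14 - 6)/10
    assert pulsatility_index(v) == pytest.approx(0.8, rel=1e-3)


def test_pulsatility_index_rejects_reversed_mean_flow():
    with pytest.raises(ValueError):
        pulsatility_index(np.array([-1.0, -2.0, 0.5]))


def test_mean_wall_shear_hand_value():
    # tau = 32 mu Q / (pi d^3): mu = 4 mPa.s, Q = 1 mL/s, d = 0.4 cm
    expected = 32 * 4e-3 * 1e-6 / (np.pi * 0.4e-2**3)
    assert mean_wall_shear(1.0, 0.4) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.637, rel=1e-2)  # Pa


def test_mean_wall_shear_rejects_nonpositive_diameter():
    with pytest.raises(ValueError):
        mean_wall_shear(1.0, 0.0)


def test_tpr_is_map_over_co():
    assert total_peripheral_resistance(85.0, 5.0) == pytest.approx(17.0)
    with pytest.raises(ValueError):
        total_peripheral_resistance(85.0, 0.0)


def test_mom_ratio_and_zero_guard():
    assert mom(1.24, 1.0) == pytest.approx(1.24)
    with pytest.raises(ValueError):
        mom(1.0, 0.0)


def test_summarize_pressure():
    p = np.array([60.0, 80.0, 120.0, 90.0])
    s = summarize_pressure(p)
    assert (s.SBP, s.DBP, s.PP) == (120.0, 60.0, 60.0)
    assert s.MAP == pytest.approx(87.5)


def _pulse(t, foot=0.15):
    """Smooth pulse with a sharp upstroke at `foot` (cycle length 1 s)."""
    x = (t - foot) % 1.0
    up = 1.0 / (1.0 + np.exp(-(x - 0.03) / 0.012))
    decay = np.exp(-x / 0.35)
    return 70.0 + 45.0 * up * decay


def test_pwv_exact_on_constructed_shift():
    t = np.arange(2000) / 2000.0
    p1 = _pulse(t, foot=0.10)
    p2 = _pulse(t, foot=0.15)  # 50 ms later
    # 40 cm path, 0.05 s delay -> 8 m/s
    v = pwv_foot_to_foot(t, p1, p2, 40.0)
    assert v == pytest.approx(8.0, rel=0.02)


def test_pwv_handles_feet_wrapping_cycle_boundary():
    t = np.arange(2000) / 2000.0
    p1 = _pulse(t, foot=0.98)
    p2 = _pulse(t, foot=0.03)  # wraps to the next cycle
    v = pwv_foot_to_foot(t, p1, p2, 40.0)
    assert v == pytest.approx(8.0, rel=0.05)


def test_pwv_rejects_bad_path_and_ordering():
    t = np.arange(2000) / 2000.0
    p1 = _pulse(t, foot=0.10)
    p2 = _pulse(t, foot=0.15)
    with pytest.raises(ValueError):
        pwv_foot_to_foot(t, p1, p2, -1.0)
    with pytest.raises(ValueError):
        pwv_foot_to_foot(t, p2, p1, 40.0)  # sites swapped


def test_augmentation_index_on_two_wave_composite():
    """P1 = incident shoulder, P2 = late-systolic augmented peak."""
    t = np.arange(1000) / 1000.0
    incident = 40.0 * np.exp(-0.5 * ((t - 0.12) / 0.045) ** 2)
    reflected = 24.0 * np.exp(-0.5 * ((t - 0.30) / 0.085) ** 2)
    p = 75.0 + incident + reflected
    s = augmentation_index(t, p, HR=75.0)
    assert s is not None
    assert s.P2 > s.P1
    pp = p.max() - p.min()
    assert s.AIx == pytest.approx(100.0 * (s.P2 - s.P1) / pp, rel=1e-9)
    assert 5.0 < s.AIx < 60.0
    assert s.AIx75 == pytest.approx(s.AIx)  # HR = 75 -> no correction


def test_aix75_heart_rate_correction():
    t = np.arange(1000) / 1000.0
    p = 80.0 + 40.0 * np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)
    s = augmentation_index(t, p, HR=90.0)
    assert s is not None
    assert s.AIx75 == pytest.approx(0.39 * 15.0 + s.AIx)


def test_rmse_hand_value_and_empty_guard():
    assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 5.0]) == pytest.approx(
        np.sqrt(4.0 / 3.0))
    with pytest.raises(ValueError):
        rmse([], [])
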