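"""Shared fixtures for the test suite."""

from __future__ import annotations

import pytest

from gravipulse.network import (
    Blood,
    Network,
    VesselSegment,
    WK3Terminal,
    characteristic_impedance,
    clamp_r1,
    generate_reduced_tree,
)


@pytest.fixture(scope="session")
def net0() -> Network:
    """Default nongravid reduced tree (shared, treated as read-only)."""
    return generate_reduced_tree()


def make_single_tube(
    length: float = 20.0,
    dbar: float = 1.0,
    Dref: float = 0.02,
    RT: float = 1.0,
    aRTC: float = 1.0,
    blood: Blood | None = None,
) -> Network:
    """One straight vessel with a WK3 terminal -- analytic-check fixture."""
    blood = blood or Blood()
    seg = VesselSegment(id="tube", name="tube", region="other",
                        length=length, dbar=dbar, Dref=Dref)
    zc = characteristic_impedance(seg.Aref, Dref, blood.rho)
    r1 = clamp_r1(zc, RT)
    term = WK3Terminal(segment_id="tube", R1=r1, R2=RT - r1, C=aRTC / RT)
    return Network(segments={"tube": seg}, junctions=[],
                   terminals={"tube": term}, inlet_segment="tube", blood=blood)


@pytest.fixture()
def single_tube() -> Network:
    return make_single_tube()


@pytest.fixture(scope="session")
def calib(net0):
    """Memoized calibrations keyed by (scenario, gestational age).

    The acceptance criteria reuse the same 13 scenario/age calibrations in
    many ratios; caching keeps the suite within its time budget.
    """
    from gravipulse.calibration import calibrate
    from gravipulse.scenarios import targets_for

    cache: dict[tuple[str, float], object] = {}

    def get(scenario_name: str, s: float):
        key = (scenario_name, float(s))
        if key not in cache:
            cache[key] = calibrate(net0, targets_for(float(s), scenario_name))
        return cache[key]

    return get
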