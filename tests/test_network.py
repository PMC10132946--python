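"""Network model: generation, invariants, serialization."""

import json

import pytest

from gravipulse.network import (
    TreeConfig,
    characteristic_impedance,
    generate_reduced_tree,
    read_network,
    validate_network,
    write_network,
)


def test_default_tree_is_valid(net0):
    assert validate_network(net0) == []


def test_every_leaf_has_a_wk3_terminal(net0):
    assert set(net0.leaves()) == set(net0.terminals)


def test_r1_fraction_invariant(net0):
    for t in net0.terminals.values():
        assert 0.05 * t.RT - 1e-12 <= t.R1 <= 0.40 * t.RT + 1e-12


def test_generation_is_deterministic():
    a = generate_reduced_tree(seed=7)
    b = generate_reduced_tree(seed=7)
    assert [s.dbar for s in a.segments.values()] == \
           [s.dbar for s in b.segments.values()]


def test_jitter_perturbs_geometry():
    a = generate_reduced_tree(TreeConfig(jitter=0.05), seed=3)
    b = generate_reduced_tree(seed=3)
    assert any(a.segments[k].dbar != b.segments[k].dbar for k in a.segments)
    assert validate_network(a) == []


def test_placental_radials_split_across_sides(net0):
    plac = [s for s in net0.segments.values() if s.placental_engaged]
    sides = {s.id.split("_")[1][0] for s in plac}
    assert sides == {"L", "R"}


def test_grid_rule(net0):
    for s in net0.segments.values():
        assert s.n_nodes >= 3  # at least two elements
        assert s.dz * (s.n_nodes - 1) == pytest.approx(s.length, rel=1e-12)
        if s.length >= 0.75:
            assert s.dz <= 0.5 + 1e-12


def test_path_length_from_inlet(net0):
    asc = net0.segments["aorta_asc"]
    car = net0.segments["carotid"]
    assert net0.path_length_from_inlet("carotid", 0.5) == pytest.approx(
        asc.length + 0.5 * car.length)


def test_characteristic_impedance_hand_value():
    # A = 1 cm^2, Dref = 0.01 /kPa: c = 1/sqrt(1050*1e-5) ~ 9.759 m/s
    # Zc = rho c / A = 1050*9.759/1e-4 Pa.s/m^3 -> mmHg.s/mL
    import math
    c = 1.0 / math.sqrt(1050 * 0.01 * 1e-3)
    expected = 1050 * c / 1e-4 / 1.33322e8
    assert characteristic_impedance(1.0, 0.01) == pytest.approx(expected, rel=1e-9)


def test_serialization_roundtrip(tmp_path, net0):
    f = tmp_path / "net.json"
    write_network(net0, f)
    net2 = read_network(f)
    assert set(net2.segments) == set(net0.segments)
    assert set(net2.terminals) == set(net0.terminals)
    for k in net0.segments:
        assert net2.segments[k].dbar == pytest.approx(net0.segments[k].dbar)
        assert net2.segments[k].Dref == pytest.approx(net0.segments[k].Dref)
    assert validate_network(net2) == []


def test_read_network_names_missing_field(tmp_path, net0):
    f = tmp_path / "net.json"
    write_network(net0, f)
    doc = json.loads(f.read_text())
    del doc["segments"][0]["Dref"]
    f.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="Dref"):
        read_network(f)


def test_read_network_rejects_unknown_region(tmp_path, net0):
    f = tmp_path / "net.json"
    write_network(net0, f)
    doc = json.loads(f.read_text())
    doc["segments"][0]["region"] = "gills"
    f.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="gills"):
        read_network(f)


def test_read_network_rejects_terminal_on_unknown_segment(tmp_path, net0):
    f = tmp_path / "net.json"
    write_network(net0, f)
    doc = json.loads(f.read_text())
    doc["terminals"][0]["segment_id"] = "nope"
    f.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="nope"):
        read_network(f)


def test_validate_flags_leaf_without_terminal(net0):
    net = net0.copy()
    leaf = net.leaves()[0]
    del net.terminals[leaf]
    assert any("without WK3 terminal" in v for v in validate_network(net))


def test_validate_flags_multiple_parents(net0):
    net = net0.copy()
    net.junctions[0].child_segments.append(net.junctions[1].child_segments[0])
    assert any("multiple parents" in v for v in validate_network(net))
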