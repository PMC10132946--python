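"""Arterial tree data model, validation, serialization and fixture generation.

The network is a rooted tree of tapered elastic segments.  Every leaf carries
a three-element Windkessel (WK3) terminal; the root (ascending aorta) is the
inlet.  A compact synthetic tree stands in for a full anatomical maternal
arterial network: a short aortic trunk with carotid (cerebral), arm (limb),
renal, mesenteric (trunk) and iliac branches, each iliac feeding a femoral
(limb) terminal and a uterine circuit of uterine -> arcuate -> radial vessels
whose radial arteries are the uterine terminals.

Units in files and in this module: lengths/diameters cm, areas cm^2,
distensibility 1/kPa, resistances mmHg.s/mL, compliances mL/mmHg,
pressures mmHg, density kg/m^3, viscosity mPa.s.
"""

from __future__ import annotations

import copy
import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constitutive import WallLawParams, reference_distensibility

__all__ = [
    "REGIONS",
    "VesselSegment",
    "WK3Terminal",
    "Junction",
    "Blood",
    "Network",
    "TreeConfig",
    "generate_reduced_tree",
    "validate_network",
    "read_network",
    "write_network",
    "characteristic_impedance",
]

REGIONS = (
    "cerebral",
    "limb",
    "trunk",
    "uterine",
    "arcuate",
    "radial_ut",
    "aorta",
    "carotid",
    "iliac",
    "renal",
    "other",
)

UTERINE_CIRCUIT = ("uterine", "arcuate", "radial_ut")

DZ_DEFAULT = 0.5  # cm; short segments use length/2 to keep >= 2 elements


def _grid(length: float) -> tuple[float, int]:
    """Axial step and node count: dz = 0.5 cm, or length/2 if length < 0.75 cm."""
    if length < 0.75:
        dz = length / 2.0
    else:
        dz = DZ_DEFAULT
    n_el = max(2, int(round(length / dz)))
    dz = length / n_el
    return dz, n_el + 1


@dataclass
class VesselSegment:
    id: str
    name: str
    region: str
    length: float            # cm
    dbar: float              # reference diameter at Pref, cm
    Dref: float              # reference distensibility, 1/kPa
    dbar_distal: float | None = None   # optional linear taper
    placental_engaged: bool = False    # meaningful for radial_ut only
    dz: float = field(default=0.0)
    n_nodes: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.dz or not self.n_nodes:
            self.dz, self.n_nodes = _grid(self.length)

    @property
    def Aref(self) -> float:
        """Reference lumen area pi*dbar^2/4, cm^2."""
        return math.pi * self.dbar**2 / 4.0

    def diameters(self) -> np.ndarray:
        """Per-node reference diameter (linear taper if dbar_distal given)."""
        d1 = self.dbar_distal if self.dbar_distal is not None else self.dbar
        return np.linspace(self.dbar, d1, self.n_nodes)


@dataclass
class WK3Terminal:
    segment_id: str
    R1: float               # mmHg.s/mL
    R2: float
    C: float                # mL/mmHg
    Pout: float = 0.0       # mmHg; venous pressure neglected

    @property
    def RT(self) -> float:
        return self.R1 + self.R2

    @property
    def aRTC(self) -> float:
        """Terminal time constant RT*C in seconds."""
        return self.RT * self.C


@dataclass
class Junction:
    parent_segment: str
    child_segments: list[str]

    @property
    def N(self) -> int:
        """Total branches at the junction (parent + children)."""
        return 1 + len(self.child_segments)


@dataclass
class Blood:
    rho: float = 1050.0     # kg/m^3
    mu: float = 4.0         # mPa.s; all diameters > 250 um so a constant
                            # apparent viscosity is adequate
    zeta: float = 9.0       # velocity-profile constant (blunt profile)


@dataclass
class Network:
    segments: dict[str, VesselSegment]
    junctions: list[Junction]
    terminals: dict[str, WK3Terminal]
    inlet_segment: str
    blood: Blood = field(default_factory=Blood)

    def copy(self) -> "Network":
        return copy.deepcopy(self)

    def children_of(self, seg_id: str) -> list[str]:
        for j in self.junctions:
            if j.parent_segment == seg_id:
                return list(j.child_segments)
        return []

    def leaves(self) -> list[str]:
        return [s for s in self.segments if not self.children_of(s)]

    def path_length_from_inlet(self, seg_id: str, fraction: float = 0.5) -> float:
        """Centerline distance from the inlet to a point along a segment."""
        parent = {}
        for j in self.junctions:
            for c in j.child_segments:
                parent[c] = j.parent_segment
        dist = self.segments[seg_id].length * fraction
        cur = seg_id
        while cur != self.inlet_segment:
            cur = parent[cur]
            dist += self.segments[cur].length
        return dist


def characteristic_impedance(Aref_cm2: float, Dref_per_kpa: float, rho: float = 1050.0) -> float:
    """Water-hammer impedance Zc = rho*c/Aref = sqrt(rho/(Aref^2 * Dref)).

    Inputs in cm^2 / (1/kPa) / (kg/m^3); result in mmHg.s/mL.
    """
    if Aref_cm2 <= 0 or Dref_per_kpa <= 0:
        raise ValueError("Aref and Dref must be positive")
    c = 1.0 / math.sqrt(rho * Dref_per_kpa * 1e-3)  # m/s (Dref -> 1/Pa)
    zc_si = rho * c / (Aref_cm2 * 1e-4)             # Pa.s/m^3
    return zc_si / 1.33322e8                        # -> mmHg.s/mL


def clamp_r1(zc: float, RT: float) -> float:
    """Proximal WK3 resistance: R1 = Zc constrained to 5-40% of RT."""
    return min(max(zc, 0.05 * RT), 0.40 * RT)


# ---------------------------------------------------------------------------
# Validation

def validate_network(net: Network) -> list[str]:
    """Return a list of invariant violations (empty iff the network is valid)."""
    v: list[str] = []
    for sid, s in net.segments.items():
        if s.id != sid:
            v.append(f"{sid}: key/id mismatch")
        if s.region not in REGIONS:
            v.append(f"{sid}: unknown region {s.region!r}")
        if s.length <= 0:
            v.append(f"{sid}: nonpositive length")
        if s.dbar <= 0:
            v.append(f"{sid}: nonpositive diameter")
        if s.Dref <= 0:
            v.append(f"{sid}: nonpositive Dref")
        if s.n_nodes < 3:
            v.append(f"{sid}: fewer than two elements")
        if s.length > 0 and abs(s.dz * (s.n_nodes - 1) - s.length) > 1e-9 * s.length:
            v.append(f"{sid}: dz*(n_nodes-1) != length")
    for t_id, t in net.terminals.items():
        if t.segment_id not in net.segments:
            v.append(f"terminal {t_id}: unknown segment")
            continue
        if t.R1 <= 0 or t.R2 <= 0 or t.C <= 0:
            v.append(f"terminal {t_id}: nonpositive WK3 element")
        if not (0.05 * t.RT - 1e-12 <= t.R1 <= 0.40 * t.RT + 1e-12):
            v.append(f"terminal {t_id}: Zc fraction outside 5-40% of RT")
    if net.inlet_segment not in net.segments:
        v.append("inlet segment not in network")
    # tree checks: acyclic, connected, single parent
    parent: dict[str, str] = {}
    for j in net.junctions:
        if j.parent_segment not in net.segments:
            v.append(f"junction parent {j.parent_segment!r} unknown")
        if j.N < 2:
            v.append(f"junction at {j.parent_segment}: fewer than 2 branches")
        for c in j.child_segments:
            if c not in net.segments:
                v.append(f"junction child {c!r} unknown")
            elif c in parent:
                v.append(f"{c}: not a tree (multiple parents)")
            else:
                parent[c] = j.parent_segment
    seen = set()
    stack = [net.inlet_segment] if net.inlet_segment in net.segments else []
    while stack:
        cur = stack.pop()
        if cur in seen:
            v.append(f"{cur}: not a tree (cycle reached from inlet)")
            break
        seen.add(cur)
        stack.extend(net.children_of(cur))
    unreachable = set(net.segments) - seen
    if unreachable and not any("cycle" in x for x in v):
        v.append(f"not a tree: unreachable segments {sorted(unreachable)}")
    for leaf in net.leaves():
        if leaf not in net.terminals:
            v.append(f"{leaf}: leaf segment without WK3 terminal")
    for t in net.terminals.values():
        if net.children_of(t.segment_id):
            v.append(f"{t.segment_id}: terminal attached to a non-leaf segment")
    return v


# ---------------------------------------------------------------------------
# Serialization

_SEG_REQUIRED = ("id", "name", "region", "length", "dbar", "Dref")
_TERM_REQUIRED = ("segment_id", "R1", "R2", "C")


def write_network(net: Network, path: str | Path) -> None:
    """Write the network as JSON; a flat CSV is written next to it."""
    path = Path(path)
    doc = {
        "units": {"length": "cm", "Dref": "1/kPa", "R": "mmHg.s/mL",
                  "C": "mL/mmHg", "P": "mmHg"},
        "inlet_segment": net.inlet_segment,
        "blood": asdict(net.blood),
        "segments": [asdict(s) for s in net.segments.values()],
        "junctions": [asdict(j) for j in net.junctions],
        "terminals": [asdict(t) for t in net.terminals.values()],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    with open(path.with_suffix(".csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "id", "region", "length_cm", "dbar_cm", "Dref_per_kPa",
                    "R1", "R2", "C", "placental"])
        for s in net.segments.values():
            t = net.terminals.get(s.id)
            w.writerow(["segment", s.id, s.region, s.length, s.dbar, s.Dref,
                        t.R1 if t else "", t.R2 if t else "", t.C if t else "",
                        int(s.placental_engaged)])


def read_network(path: str | Path) -> Network:
    """Read a network JSON file; raises ``ValueError`` naming the offender."""
    doc = json.loads(Path(path).read_text())
    segments: dict[str, VesselSegment] = {}
    for rec in doc.get("segments", []):
        for key in _SEG_REQUIRED:
            if key not in rec or rec[key] is None:
                raise ValueError(f"segment record {rec.get('id', '?')}: {key} required")
        if rec["region"] not in REGIONS:
            raise ValueError(f"segment {rec['id']}: unknown region {rec['region']!r}")
        if rec["id"] in segments:
            raise ValueError(f"duplicate segment id {rec['id']!r}")
        segments[rec["id"]] = VesselSegment(**rec)
    terminals: dict[str, WK3Terminal] = {}
    for rec in doc.get("terminals", []):
        for key in _TERM_REQUIRED:
            if key not in rec or rec[key] is None:
                raise ValueError(f"terminal record: {key} required")
        if rec["segment_id"] not in segments:
            raise ValueError(f"terminal references unknown segment {rec['segment_id']!r}")
        terminals[rec["segment_id"]] = WK3Terminal(**rec)
    junctions = [Junction(**rec) for rec in doc.get("junctions", [])]
    if "inlet_segment" not in doc:
        raise ValueError("inlet_segment required")
    blood = Blood(**doc.get("blood", {}))
    return Network(segments=segments, junctions=junctions, terminals=terminals,
                   inlet_segment=doc["inlet_segment"], blood=blood)


# ---------------------------------------------------------------------------
# Synthetic fixture generator

@dataclass
class TreeConfig:
    """Configuration of the reduced synthetic tree and its nongravid baseline.

    Baseline hemodynamics: nongravid CO 5.0 L/min, HR 70 bpm, MAP 85 mmHg,
    bilateral uterine flow 0.6% of CO (~30 mL/min).  Geometry keeps
    physiological lengths for the compliance- and wave-carrying conduits
    (aorta, carotid, limb arteries) -- conduit volume sets the conduit
    compliance that shunts pulsatile flow, and the carotid-to-femoral path
    carries the cf-PWV measurement -- while the short distributing branches
    stand in for whole vascular beds.  Arcuate and radial baseline
    diameters are set so their nongravid wall shear sits at 1.05x / 1.10x the
    uterine-artery value given the equal flow split of the circuit.
    """

    n_uterine: int = 2
    n_arcuate_per_uterine: int = 2
    n_radial_per_arcuate: int = 2
    placental_fraction: float = 0.5   # fraction of radials engaged by placenta
    co_lpm: float = 5.0
    hr_bpm: float = 70.0
    map_mmhg: float = 85.0
    uterine_flow_fraction: float = 0.006
    cerebral_fraction: float = 0.12
    limb_fraction: float = 0.25
    renal_fraction: float = 0.18
    d_uterine: float = 0.20           # nongravid uterine artery diameter, cm
    jitter: float = 0.0               # optional relative geometry jitter
    wall: WallLawParams = field(default_factory=WallLawParams)
    blood: Blood = field(default_factory=Blood)


# (name, region, length cm, d_prox cm, d_dist cm or None)
# Branches that stand in for several parallel vessels use the
# equal-characteristic-impedance equivalent diameter
# d_eq = (sum d_i^(2+b2))^(1/(2+b2)) (Zc ~ d^-(2+b2)): "carotid" merges both
# carotids and vertebrals (~2x0.6 + 2x0.35 cm), "arm" both subclavians
# (~2x0.55), "renal" both renal arteries (~2x0.6), "mesenteric" the
# splanchnic trio celiac+SMA+IMA (~0.8+0.9+0.45).
_TRUNK_GEOMETRY = [
    ("aorta_asc", "aorta", 5.0, 2.6, 2.4),
    ("carotid", "carotid", 16.0, 0.90, 0.80),
    ("arm", "limb", 20.0, 0.75, 0.65),
    ("aorta_desc", "aorta", 16.0, 2.2, 1.8),
    ("renal", "renal", 3.0, 0.80, None),
    ("mesenteric", "trunk", 4.0, 1.20, None),
    ("aorta_abd", "aorta", 12.0, 1.6, 1.3),
]


def generate_reduced_tree(config: TreeConfig | None = None, seed: int = 1) -> Network:
    """Build the default reduced maternal arterial tree.

    Deterministic for a fixed (config, seed); ``seed`` only drives the
    optional geometry jitter.  Terminal WK3 parameters are initialized from
    the DC split of the nongravid baseline (flow-fraction targets at the
    baseline MAP) with aRTC = 1.5 s; the calibration loop refines them.
    """
    cfg = config or TreeConfig()
    if cfg.n_uterine < 1:
        raise ValueError("at least one uterine artery is required")
    rng = np.random.default_rng(seed)
    wall, blood = cfg.wall, cfg.blood

    def jit(x: float) -> float:
        if cfg.jitter <= 0:
            return x
        return x * float(1.0 + cfg.jitter * rng.uniform(-1, 1))

    segments: dict[str, VesselSegment] = {}
    junctions: list[Junction] = []

    def add(name: str, region: str, length: float, d0: float, d1: float | None,
            placental: bool = False) -> str:
        dref = float(reference_distensibility(d0, blood.rho, wall))
        segments[name] = VesselSegment(
            id=name, name=name, region=region, length=jit(length), dbar=jit(d0),
            dbar_distal=jit(d1) if d1 is not None else None, Dref=dref,
            placental_engaged=placental)
        return name

    for name, region, L, d0, d1 in _TRUNK_GEOMETRY:
        add(name, region, L, d0, d1)
    junctions.append(Junction("aorta_asc", ["carotid", "arm", "aorta_desc"]))
    junctions.append(Junction("aorta_desc", ["renal", "mesenteric", "aorta_abd"]))

    # nongravid shear-ratio-consistent uterine circuit diameters
    n_arc = cfg.n_arcuate_per_uterine
    n_rad = cfg.n_radial_per_arcuate
    d_ut = cfg.d_uterine
    d_arc = d_ut * (1.0 / (n_arc * 1.05)) ** (1.0 / 3.0)
    d_rad = d_ut * (1.0 / (n_arc * n_rad * 1.10)) ** (1.0 / 3.0)

    # iliacs: one per side; uterine arteries distributed over the two sides
    add("iliac_L", "iliac", 6.0, 1.0, 0.9)
    add("iliac_R", "iliac", 6.0, 1.0, 0.9)
    junctions.append(Junction("aorta_abd", ["iliac_L", "iliac_R"]))
    placental_ids: list[str] = []
    radial_ids: list[str] = []

    def add_uterine_circuit(tag: str) -> str:
        ut = add(f"uterine_{tag}", "uterine", 10.0, d_ut, None)
        arcs = []
        for a in range(n_arc):
            arc = add(f"arcuate_{tag}{a}", "arcuate", 3.0, d_arc, None)
            arcs.append(arc)
            rads = []
            for r in range(n_rad):
                rad = add(f"radial_{tag}{a}{r}", "radial_ut", 1.5, d_rad, None)
                rads.append(rad)
                radial_ids.append(rad)
            junctions.append(Junction(arc, rads))
        junctions.append(Junction(ut, arcs))
        return ut

    for i, side in enumerate(["L", "R"]):
        fem = add(f"femoral_{side}", "limb", 20.0, 0.8, 0.7)
        kids = [fem]
        for k in range(i, cfg.n_uterine, 2):
            tag = side if cfg.n_uterine <= 2 else f"{side}{k}"
            kids.append(add_uterine_circuit(tag))
        junctions.append(Junction(f"iliac_{side}", kids))
    # engage radials symmetrically across the tree (evenly spaced in order)
    n_plac = int(round(cfg.placental_fraction * len(radial_ids)))
    if n_plac:
        pick = np.round(np.linspace(0, len(radial_ids) - 1, n_plac)).astype(int)
        for i in sorted(set(int(i) for i in pick)):
            segments[radial_ids[i]].placental_engaged = True
            placental_ids.append(radial_ids[i])

    net = Network(segments=segments, junctions=junctions, terminals={},
                  inlet_segment="aorta_asc", blood=blood)

    # initial WK3 split from nongravid flow-fraction targets at baseline MAP
    co_mls = cfg.co_lpm * 1000.0 / 60.0
    groups = {
        "cerebral": (["carotid"], cfg.cerebral_fraction),
        "limb": (["arm"] + [s for s in net.leaves() if s.startswith("femoral")],
                 cfg.limb_fraction),
        "renal": (["renal"], cfg.renal_fraction),
        "uterine": (radial_ids, cfg.uterine_flow_fraction),
    }
    trunk_frac = 1.0 - sum(frac for _, frac in groups.values())
    groups["trunk"] = (["mesenteric"], trunk_frac)
    aRTC = 1.5  # s, initial guess; step 3 tunes it
    for _, (leaves, frac) in groups.items():
        q_each = frac * co_mls / len(leaves)
        RT = cfg.map_mmhg / q_each
        for leaf in leaves:
            s = net.segments[leaf]
            zc = characteristic_impedance(s.Aref, s.Dref, blood.rho)
            r1 = clamp_r1(zc, RT)
            net.terminals[leaf] = WK3Terminal(
                segment_id=leaf, R1=r1, R2=RT - r1, C=aRTC / RT)
    return net
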