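"""1D pulsatile blood-flow solver on a branching arterial tree.

Governing equations per segment: continuity C_A dP/dt + dQ/dz = 0 with the
area slaved to pressure through the strain-stiffening tube law, and momentum
dQ/dt + d/dz(Q^2/A) + (A/rho) dP/dz = f/rho with the friction of the
prescribed power-law velocity profile, f = -2(zeta+2) pi mu Q/A.

Discretization: implicit (backward-Euler) in time on a staggered grid -- P
and A at nodes, Q at faces, including the segment-end boundary faces.  The
boundary faces carry the coupling constraints as algebraic equations: the
prescribed inlet flow, the WK3 terminal relation (with the lumped capacitor
pressure eliminated analytically), and at each junction conservation of flow
(sum Q_i = 0) plus equality of total pressure P + rho*u^2/2 across branches.
Each time step solves the full nonlinear system by a Newton iteration with a
once-per-step factorized Jacobian and exact residual evaluation.

Internal units are CGS: cm, cm^2, mL/s, dyn/cm^2 (barye), g/cm^3, poise.
Results are reported in clinical units (mmHg, mL/s, cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .constitutive import WallLawParams, reference_distensibility
from .network import Network, characteristic_impedance  # noqa: F401  (re-export)

__all__ = [
    "InletWaveform",
    "SimulationResult",
    "build_inlet",
    "friction_term",
    "run_simulation",
    "characteristic_impedance",
]

BARYE_PER_MMHG = 1333.22
BARYE_PER_KPA = 1e4


def friction_term(Q, A, zeta: float = 9.0, mu: float = 0.04):
    """Frictional force per unit length, f = -2(zeta+2) pi mu Q / A.

    Any consistent unit system; zeta=2 recovers the Poiseuille value
    -8 pi mu Q/A for a parabolic profile.
    """
    return -2.0 * (zeta + 2.0) * np.pi * mu * np.asarray(Q) / np.asarray(A)


@dataclass
class InletWaveform:
    """Prescribed periodic inlet flow at the ascending aorta.

    ``q`` is the normalized shape (1/s) sampled on ``nt`` uniform points of
    the cycle with unit integral; ``Q`` = stroke-volume * q is the flow in
    mL/s whose time mean equals CO.
    """

    CO: float               # L/min
    HR: float               # bpm
    nt: int
    q: np.ndarray           # (nt,), 1/s
    Q: np.ndarray           # (nt,), mL/s

    @property
    def tc(self) -> float:
        return 60.0 / self.HR

    @property
    def dt(self) -> float:
        return 60.0 / (self.HR * self.nt)


def build_inlet(
    CO: float,
    HR: float,
    nt: int = 500,
    systole_fraction: float = 0.35,
    dicrotic_dip: float = 0.03,
    shape: str = "half_sine",
) -> InletWaveform:
    """Synthesize the inlet waveform shape and scale it to the prescribed CO.

    ``half_sine``: systolic half-sine over ``systole_fraction`` of the cycle
    followed by a small negative dicrotic lobe of relative amplitude
    ``dicrotic_dip`` (of the systolic peak) and zero diastolic flow;
    ``constant`` gives steady flow (for analytic checks).  The shape is
    normalized so its integral over the cycle is exactly 1.
    """
    if CO <= 0 or HR <= 0:
        raise ValueError("CO and HR must be positive")
    tc = 60.0 / HR
    t = np.arange(nt) * tc / nt
    if shape == "constant":
        q = np.full(nt, 1.0)
    elif shape == "half_sine":
        te = systole_fraction * tc
        q = np.where(t < te, np.sin(np.pi * t / np.clip(te, 1e-9, None)), 0.0)
        if dicrotic_dip > 0:
            td = 0.10 * tc
            mask = (t >= te) & (t < te + td)
            q = q - np.where(mask, dicrotic_dip * np.sin(np.pi * (t - te) / td), 0.0)
    else:
        raise ValueError(f"unknown inlet shape {shape!r}")
    dt = tc / nt
    q = q / (np.sum(q) * dt)  # unit integral on the periodic grid
    co_mls = CO * 1000.0 / 60.0
    Q = co_mls * tc * q       # mean(Q) == co_mls exactly
    return InletWaveform(CO=CO, HR=HR, nt=nt, q=q, Q=Q)


# ---------------------------------------------------------------------------
# Mesh: flattened arrays over the whole tree

class _Mesh:
    """Static discretization of a Network in CGS units."""

    def __init__(self, net: Network, wall: WallLawParams | None = None):
        self.net = net
        wall = wall or WallLawParams()
        self.wall = wall
        self.rho = net.blood.rho / 1000.0          # g/cm^3
        self.mu = net.blood.mu * 0.01              # mPa.s -> poise
        self.zeta = net.blood.zeta
        self.kfric = 2.0 * (self.zeta + 2.0) * np.pi * self.mu / self.rho

        seg_ids = list(net.segments)
        self.seg_ids = seg_ids
        self.seg_index = {s: i for i, s in enumerate(seg_ids)}

        node_seg, node_w, Aref, Dref_b = [], [], [], []
        self.seg_nodes: dict[str, tuple[int, int]] = {}
        self.seg_faces: dict[str, tuple[int, int]] = {}
        face_count = 0
        node_count = 0
        for sid in seg_ids:
            s = net.segments[sid]
            n = s.n_nodes
            d = s.diameters()
            aref = np.pi * d**2 / 4.0
            # taper: scale the segment Dref by the diameter-law ratio
            ratio = reference_distensibility(d, net.blood.rho, wall) / \
                reference_distensibility(s.dbar, net.blood.rho, wall)
            dref = s.Dref * ratio * 1e-4           # 1/kPa -> 1/barye
            w = np.full(n, s.dz)
            w[0] = w[-1] = s.dz / 2.0
            self.seg_nodes[sid] = (node_count, node_count + n)
            self.seg_faces[sid] = (face_count, face_count + n + 1)
            node_seg += [sid] * n
            node_w.append(w)
            Aref.append(aref)
            Dref_b.append(dref)
            node_count += n
            face_count += n + 1
        self.Nn = node_count
        self.Nf = face_count
        self.w = np.concatenate(node_w)
        self.Aref = np.concatenate(Aref)
        self.D = np.concatenate(Dref_b)

        # per-node adjacent faces (every node has both: boundary faces exist)
        self.lf = np.empty(self.Nn, dtype=np.int64)
        self.rf = np.empty(self.Nn, dtype=np.int64)
        # interior faces
        int_f, int_na, int_nb, int_dz = [], [], [], []
        for sid in seg_ids:
            n0, n1 = self.seg_nodes[sid]
            f0, f1 = self.seg_faces[sid]
            n = n1 - n0
            idx = np.arange(n)
            self.lf[n0:n1] = f0 + idx
            self.rf[n0:n1] = f0 + idx + 1
            s = net.segments[sid]
            int_f.append(np.arange(f0 + 1, f1 - 1))
            int_na.append(np.arange(n0, n1 - 1))
            int_nb.append(np.arange(n0 + 1, n1))
            int_dz.append(np.full(n - 1, s.dz))
        self.int_f = np.concatenate(int_f)
        self.int_na = np.concatenate(int_na)
        self.int_nb = np.concatenate(int_nb)
        self.int_dz = np.concatenate(int_dz)

        # boundary faces
        self.inlet_face = self.seg_faces[net.inlet_segment][0]
        self.inlet_node = self.seg_nodes[net.inlet_segment][0]
        term_ids = list(net.terminals)
        self.term_ids = term_ids
        self.term_face = np.array(
            [self.seg_faces[t][1] - 1 for t in term_ids], dtype=np.int64)
        self.term_node = np.array(
            [self.seg_nodes[t][1] - 1 for t in term_ids], dtype=np.int64)
        b = BARYE_PER_MMHG
        self.term_R1 = np.array([net.terminals[t].R1 * b for t in term_ids])
        self.term_R2 = np.array([net.terminals[t].R2 * b for t in term_ids])
        self.term_C = np.array([net.terminals[t].C / b for t in term_ids])
        self.term_Pout = np.array([net.terminals[t].Pout * b for t in term_ids])

        # junctions: parent end face/node, child start faces/nodes
        self.j_pf, self.j_pn = [], []
        ch_f, ch_n, ch_j = [], [], []
        for jidx, j in enumerate(net.junctions):
            self.j_pf.append(self.seg_faces[j.parent_segment][1] - 1)
            self.j_pn.append(self.seg_nodes[j.parent_segment][1] - 1)
            for c in j.child_segments:
                ch_f.append(self.seg_faces[c][0])
                ch_n.append(self.seg_nodes[c][0])
                ch_j.append(jidx)
        self.j_pf = np.array(self.j_pf, dtype=np.int64)
        self.j_pn = np.array(self.j_pn, dtype=np.int64)
        self.ch_f = np.array(ch_f, dtype=np.int64)
        self.ch_n = np.array(ch_n, dtype=np.int64)
        self.ch_j = np.array(ch_j, dtype=np.int64)
        self.nj = len(net.junctions)

        # tube-law constants in barye
        p = wall
        self.a1, self.b1 = p.a1, p.b1
        self.Pmax = p.PmaxC * BARYE_PER_KPA
        self.Pw = p.Pwidth * BARYE_PER_KPA
        self.Pref = p.Pref * BARYE_PER_KPA
        self.atan_ref = np.arctan((self.Pref - self.Pmax) / self.Pw)

    # tube law -------------------------------------------------------------
    def area(self, P: np.ndarray) -> np.ndarray:
        expo = self.a1 * self.D * (P - self.Pref) + self.b1 * self.D * self.Pw * (
            np.arctan((P - self.Pmax) / self.Pw) - self.atan_ref)
        return self.Aref * np.exp(expo)

    def compliance(self, P: np.ndarray, A: np.ndarray) -> np.ndarray:
        x = (P - self.Pmax) / self.Pw
        return (self.a1 + self.b1 / (1.0 + x * x)) * self.D * A


def _dc_state(mesh: "_Mesh", net: Network, q_in: float):
    """Steady resistive solution of the tree at mean inflow ``q_in``.

    Bottom-up pass reduces each subtree to an equivalent resistance (viscous
    segment resistance at the reference area plus terminal or parallel-child
    resistance); top-down pass distributes flows by conductance and
    integrates the viscous pressure drop node by node.  Returns (P, Q, Pc)
    in CGS units.
    """
    children: dict[str, list[str]] = {s: [] for s in net.segments}
    for j in net.junctions:
        children[j.parent_segment] = list(j.child_segments)
    term_index = {t: i for i, t in enumerate(mesh.term_ids)}

    # viscous resistance of each element (dP = r * Q), at the reference area
    def seg_element_r(sid: str) -> np.ndarray:
        n0, n1 = mesh.seg_nodes[sid]
        A = mesh.Aref[n0:n1]
        Af = 0.5 * (A[:-1] + A[1:])
        dz = net.segments[sid].dz
        return mesh.rho * mesh.kfric * dz / Af**2

    r_elem = {sid: seg_element_r(sid) for sid in net.segments}
    r_eq: dict[str, float] = {}

    def reduce(sid: str) -> float:
        if children[sid]:
            down = 1.0 / sum(1.0 / reduce(c) for c in children[sid])
        else:
            i = term_index[sid]
            down = float(mesh.term_R1[i] + mesh.term_R2[i])
        r_eq[sid] = float(np.sum(r_elem[sid])) + down
        return r_eq[sid]

    reduce(net.inlet_segment)

    P = np.empty(mesh.Nn)
    Q = np.empty(mesh.Nf)
    Pc = np.empty(len(mesh.term_ids))

    def descend(sid: str, p_in: float, q: float) -> None:
        n0, n1 = mesh.seg_nodes[sid]
        f0, f1 = mesh.seg_faces[sid]
        Q[f0:f1] = q
        P[n0] = p_in
        P[n0 + 1:n1] = p_in - np.cumsum(r_elem[sid]) * q
        p_end = float(P[n1 - 1])
        if children[sid]:
            for c in children[sid]:
                descend(c, p_end, q / r_eq[c] / sum(1.0 / r_eq[k] for k in children[sid]))
        else:
            i = term_index[sid]
            Pc[i] = p_end - q * mesh.term_R1[i]

    descend(net.inlet_segment, q_in * r_eq[net.inlet_segment], q_in)
    return P, Q, Pc


# ---------------------------------------------------------------------------
# Result container

@dataclass
class SimulationResult:
    """Converged periodic waveforms at probe sites plus diagnostics."""

    t: np.ndarray                                   # (nt,) s within the cycle
    probes: dict[str, dict[str, np.ndarray]]        # site -> P_mmHg/Q_ml_s/A_cm2/v_cm_s
    terminal_mean_flow: dict[str, float]            # mL/s over reporting cycle
    segment_mean_flow: dict[str, float]             # mL/s
    periodicity: list[float] = field(default_factory=list)
    converged: bool = False
    mass_error: float = float("nan")                # |in-out-storage|/stroke volume
    state: tuple | None = None                      # (P, Q, Pc) for warm starts
    n_cycles: int = 0
    dt: float = 0.0

    def summary_site(self, site: str) -> dict[str, np.ndarray]:
        return self.probes[site]


def _default_probes(net: Network) -> dict[str, tuple[str, float]]:
    """Named probe sites: (segment, fractional position along it)."""
    probes = {"aorta_root": (net.inlet_segment, 0.0)}
    for sid in net.segments:
        if sid.startswith("carotid"):
            probes["carotid"] = (sid, 0.5)
        if sid == "femoral_L":
            probes["femoral"] = (sid, 0.5)
        if sid == "arm":
            probes["arm"] = (sid, 0.5)
        if sid.startswith("uterine"):
            probes[f"{sid}_mid"] = (sid, 0.5)
    return probes


def run_simulation(
    net: Network,
    inlet: InletWaveform,
    n_cycles: int = 10,
    probes: dict[str, tuple[str, float]] | None = None,
    state0: tuple | None = None,
    newton_tol: float = 1e-9,
    max_newton: int = 20,
    periodicity_tol: float = 1e-3,
    adaptive: bool = False,
    min_cycles: int = 3,
    wall: WallLawParams | None = None,
    P0_mmHg: float | None = None,
) -> SimulationResult:
    """Run the pulse-wave simulation and report the final cycle.

    With ``adaptive=True`` the run stops as soon as the cycle-to-cycle
    periodicity metric drops below ``periodicity_tol`` (at least
    ``min_cycles``); otherwise exactly ``n_cycles`` cycles are run, as in the
    reporting convention (10 cycles, results from the 10th).  ``state0`` warm
    starts from a previous run's ``result.state``.
    """
    mesh = _Mesh(net, wall)
    nt = inlet.nt
    dt = inlet.dt
    rho = mesh.rho

    if probes is None:
        probes = _default_probes(net)
    probe_nodes = {}
    for name, (sid, frac) in probes.items():
        n0, n1 = mesh.seg_nodes[sid]
        probe_nodes[name] = n0 + int(round(frac * (n1 - n0 - 1)))

    # state
    if state0 is not None:
        P, Q, Pc = (np.array(a, dtype=float) for a in state0)
    else:
        if P0_mmHg is None:
            # cold start at the exact DC (mean-flow) operating point: a
            # two-pass resistive tree solve sets node pressures, face flows
            # and the WK3 capacitor pressures, so the slow windkessel mode
            # (time constant ~R2*C, several cycles long) is barely excited
            P, Q, Pc = _dc_state(mesh, net, float(np.mean(inlet.Q)))
        else:
            # explicit uniform start with capacitors at the DC-divider value
            p0 = P0_mmHg * BARYE_PER_MMHG
            P = np.full(mesh.Nn, p0)
            Q = np.zeros(mesh.Nf)
            Pc = p0 * mesh.term_R2 / (mesh.term_R1 + mesh.term_R2)

    # WK3 elimination coefficients (constant in time)
    kf = dt / (mesh.term_R2 * mesh.term_C)
    alpha = mesh.term_R1 + (dt / mesh.term_C) / (1.0 + kf)

    Nn, Nf = mesh.Nn, mesh.Nf
    nun = Nn + Nf
    rows_cont = np.arange(Nn)

    # residual row scales for the convergence test
    Qs = max(1.0, float(np.max(np.abs(inlet.Q))))
    Ps = 100.0 * BARYE_PER_MMHG
    scale = np.empty(nun)
    scale[:Nn] = Qs
    scale[Nn:] = Qs / dt            # momentum rows
    scale[Nn + mesh.inlet_face] = Qs
    scale[Nn + mesh.term_face] = Ps
    scale[Nn + mesh.j_pf] = Qs
    scale[Nn + mesh.ch_f] = Ps

    qin_t = 0.0

    def residual(P, Q, Aold, Pc_old):
        A = mesh.area(P)
        Qnode = 0.5 * (Q[mesh.lf] + Q[mesh.rf])
        F = Qnode * Qnode / A
        R = np.empty(nun)
        R[:Nn] = mesh.w * (A - Aold) / dt + Q[mesh.rf] - Q[mesh.lf]
        Rf = np.zeros(Nf)
        na, nb, fi = mesh.int_na, mesh.int_nb, mesh.int_f
        Af = 0.5 * (A[na] + A[nb])
        Rf[fi] = ((Q[fi] - Qold[fi]) / dt
                  + (F[nb] - F[na]) / mesh.int_dz
                  + (Af / rho) * (P[nb] - P[na]) / mesh.int_dz
                  + mesh.kfric * Q[fi] / Af)
        Rf[mesh.inlet_face] = Q[mesh.inlet_face] - qin_t
        beta = (Pc_old + (dt / mesh.term_C) * (mesh.term_Pout / mesh.term_R2)) / (1.0 + kf)
        Rf[mesh.term_face] = P[mesh.term_node] - alpha * Q[mesh.term_face] - beta
        childsum = np.zeros(mesh.nj)
        np.add.at(childsum, mesh.ch_j, Q[mesh.ch_f])
        Rf[mesh.j_pf] = Q[mesh.j_pf] - childsum
        up = Q[mesh.j_pf] / A[mesh.j_pn]
        uc = Q[mesh.ch_f] / A[mesh.ch_n]
        Rf[mesh.ch_f] = (P[mesh.j_pn[mesh.ch_j]] + 0.5 * rho * up[mesh.ch_j] ** 2
                         - P[mesh.ch_n] - 0.5 * rho * uc ** 2)
        R[Nn:] = Rf
        return R, A

    def jacobian(P, Q, A):
        CA = mesh.compliance(P, A)
        rows, cols, vals = [], [], []

        def put(r, c, v):
            rows.append(np.asarray(r, dtype=np.int64))
            cols.append(np.asarray(c, dtype=np.int64))
            vals.append(np.asarray(v, dtype=float))

        put(rows_cont, rows_cont, mesh.w * CA / dt)
        put(rows_cont, Nn + mesh.rf, np.ones(Nn))
        put(rows_cont, Nn + mesh.lf, -np.ones(Nn))
        na, nb, fi = mesh.int_na, mesh.int_nb, mesh.int_f
        Af = 0.5 * (A[na] + A[nb])
        put(Nn + fi, Nn + fi, 1.0 / dt + mesh.kfric / Af)
        put(Nn + fi, na, -Af / (rho * mesh.int_dz))
        put(Nn + fi, nb, Af / (rho * mesh.int_dz))
        put([Nn + mesh.inlet_face], [Nn + mesh.inlet_face], [1.0])
        put(Nn + mesh.term_face, mesh.term_node, np.ones(len(mesh.term_face)))
        put(Nn + mesh.term_face, Nn + mesh.term_face, -alpha)
        put(Nn + mesh.j_pf, Nn + mesh.j_pf, np.ones(mesh.nj))
        # dynamic-pressure rows
        put(Nn + mesh.ch_f, mesh.j_pn[mesh.ch_j], np.ones(len(mesh.ch_f)))
        put(Nn + mesh.ch_f, mesh.ch_n, -np.ones(len(mesh.ch_f)))
        up = Q[mesh.j_pf] / A[mesh.j_pn]
        uc = Q[mesh.ch_f] / A[mesh.ch_n]
        put(Nn + mesh.ch_f, Nn + mesh.j_pf[mesh.ch_j],
            rho * up[mesh.ch_j] / A[mesh.j_pn[mesh.ch_j]])
        put(Nn + mesh.ch_f, Nn + mesh.ch_f, -rho * uc / A[mesh.ch_n])
        # mass row entries for child faces (may duplicate -1 with pressure row? no:
        # mass row index is Nn+j_pf, child entries columns Nn+ch_f)
        put(Nn + mesh.j_pf[mesh.ch_j], Nn + mesh.ch_f, -np.ones(len(mesh.ch_f)))
        J = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nun, nun)).tocsc()
        return J

    # time marching
    probe_hist_prev: dict[str, np.ndarray] = {}
    periodicity: list[float] = []
    rec_P = np.empty((nt, Nn))
    rec_Q = np.empty((nt, Nf))
    Aold = mesh.area(P)
    A_start_cycle = Aold.copy()
    Qold = Q.copy()
    P_prev_step = P.copy()
    Q_prev_step = Q.copy()
    inflow_vol = 0.0
    out_vol = 0.0
    cycles_run = 0
    J_lu = None

    for cyc in range(n_cycles):
        probe_hist = {name: np.empty(nt) for name in probe_nodes}
        A_start_cycle = mesh.area(P)
        inflow_vol = 0.0
        out_vol = 0.0
        for it in range(nt):
            qin_t = inlet.Q[(it + 1) % nt]
            Qold = Q.copy()
            Aold = mesh.area(P)
            Pc_old = Pc.copy()
            # linear extrapolation predictor
            P_pred = 2.0 * P - P_prev_step
            Q_pred = 2.0 * Q - Q_prev_step
            P_prev_step, Q_prev_step = P.copy(), Q.copy()
            P, Q = P_pred, Q_pred
            R, A = residual(P, Q, Aold, Pc_old)
            for k in range(max_newton):
                err = float(np.max(np.abs(R / scale)))
                if err < newton_tol:
                    break
                # reuse the factorization from previous steps (quasi-Newton);
                # refactor only when the iteration struggles
                if J_lu is None or k == 4 or k == 9 or k == 14:
                    J_lu = splu(jacobian(P, Q, A))
                dx = J_lu.solve(R)
                P = P - dx[:Nn]
                Q = Q - dx[Nn:]
                R, A = residual(P, Q, Aold, Pc_old)
                if not np.all(np.isfinite(R)):
                    raise FloatingPointError(
                        f"solver diverged at cycle {cyc}, step {it}")
            else:
                raise RuntimeError(
                    f"Newton failed at cycle {cyc}, step {it}: "
                    f"residual {err:.3e} after {max_newton} iterations")
            # accept: update WK3 capacitor pressures
            Pc = (Pc_old + (dt / mesh.term_C) * (Q[mesh.term_face] + mesh.term_Pout / mesh.term_R2)) / (1.0 + kf)
            rec_P[it] = P
            rec_Q[it] = Q
            inflow_vol += qin_t * dt
            out_vol += float(np.sum(Q[mesh.term_face])) * dt
            for name, node in probe_nodes.items():
                probe_hist[name][it] = P[node]
        cycles_run += 1
        # periodicity metric: relative Linf change of probe pressures
        if probe_hist_prev:
            m = max(
                float(np.max(np.abs(probe_hist[n] - probe_hist_prev[n]))
                      / np.max(np.abs(probe_hist[n])))
                for n in probe_hist)
            periodicity.append(m)
            if len(periodicity) >= 4 and periodicity[-1] > 0.5 and all(
                    periodicity[-i] > periodicity[-i - 1] * (1 + 1e-9)
                    for i in (1, 2, 3)):
                raise RuntimeError(
                    "periodicity metric growing for 3 consecutive cycles: "
                    f"{periodicity[-4:]}")
        probe_hist_prev = probe_hist
        if adaptive and cycles_run >= min_cycles and periodicity and \
                periodicity[-1] < periodicity_tol:
            break

    storage = float(np.sum(mesh.w * (mesh.area(P) - A_start_cycle)))
    stroke = inflow_vol if inflow_vol > 0 else 1.0
    mass_error = abs(inflow_vol - out_vol - storage) / stroke

    t = np.arange(nt) * dt
    out_probes: dict[str, dict[str, np.ndarray]] = {}
    vfac = (mesh.zeta + 2.0) / mesh.zeta
    for name, node in probe_nodes.items():
        Pw = rec_P[:, node]
        Qw = 0.5 * (rec_Q[:, mesh.lf[node]] + rec_Q[:, mesh.rf[node]])
        # area from the tube law at this node
        expo = (mesh.a1 * mesh.D[node] * (Pw - mesh.Pref)
                + mesh.b1 * mesh.D[node] * mesh.Pw
                * (np.arctan((Pw - mesh.Pmax) / mesh.Pw) - mesh.atan_ref))
        Aw = mesh.Aref[node] * np.exp(expo)
        out_probes[name] = {
            "P_mmHg": Pw / BARYE_PER_MMHG,
            "Q_ml_s": Qw,
            "A_cm2": Aw,
            "v_cm_s": vfac * Qw / Aw,
        }
    term_mean = {
        tid: float(np.mean(rec_Q[:, f]))
        for tid, f in zip(mesh.term_ids, mesh.term_face)
    }
    seg_mean = {}
    for sid in mesh.seg_ids:
        f0, f1 = mesh.seg_faces[sid]
        seg_mean[sid] = float(np.mean(rec_Q[:, f0:f1]))
    converged = bool(periodicity and periodicity[-1] < periodicity_tol)
    return SimulationResult(
        t=t, probes=out_probes, terminal_mean_flow=term_mean,
        segment_mean_flow=seg_mean, periodicity=periodicity,
        converged=converged, mass_error=mass_error,
        state=(P.copy(), Q.copy(), Pc.copy()), n_cycles=cycles_run, dt=dt)
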