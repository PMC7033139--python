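"""Coupled intravascular, transvascular and interstitial fluid dynamics.

Blood flow in the vessel graph obeys Hagen-Poiseuille conductances with a
non-Newtonian apparent viscosity (the Pries in-vivo law in vessel diameter
plus a hematocrit correction).  Each segment leaks plasma through its wall
by Starling's law; the leak drives interstitial fluid pressure (IFP)
through a Poisson equation and Darcy's law gives the interstitial velocity.
Hematocrit separates at bifurcations by plasma skimming.

Unit system (project-wide): pressures mmHg, lengths um, time s, dynamic
viscosity Pa*s, flow um^3/s, wall shear stress dyn/cm^2.  Conversions are
centralized in the constants below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .grid import (
    BoundaryCondition,
    ScalarField,
    SolverError,
    VectorField,
    gradient,
    solve_poisson,
)

MMHG_TO_PA = 133.322
PA_TO_DYN_CM2 = 10.0


@dataclass
class FluidParams:
    """Blood/interstitium fluid constants."""

    mu_plasma: float = 1.2e-3   # plasma viscosity, Pa*s
    H_D_n: float = 0.45         # normal (inlet) discharge hematocrit
    r_th: float = 2.5           # bifurcation velocity-ratio threshold
    L_p: float = 2.0e-3         # vessel-wall hydraulic conductivity, um/(mmHg s)
    sigma: float = 0.9          # osmotic reflection coefficient
    pi_lum: float = 20.0        # plasma oncotic pressure, mmHg
    pi_ins: float = 10.0        # interstitial oncotic pressure, mmHg
    K_ins: float = 25.0         # interstitial hydraulic conductivity, um^2/(mmHg s)
    S_over_V: float = 0.02      # vessel surface per unit volume, 1/um
    p_inlet: float = 30.0       # primary-ring inlet pressure, mmHg
    p_drop: float = 10.0        # inlet-to-outlet pressure drop on the ring, mmHg
    p_lum_ref: float = 30.0     # characteristic luminal pressure normalizing
                                # the perfusion laws (fixed across scenarios)
    d_c: float = 40.0           # characteristic neo-vessel diameter, um
    tumor_lp_scaling: bool = True   # L_p grows with d_v/d_c inside the tumor
    flux_weighted_split: bool = False  # optional RBC-flux-conserving variant
    q_ref_mode: str = "max_segment"    # reference flow for the metabolic
                                       # stimulus: "max_segment" | "inlet_sum"

    @property
    def osmotic_jump(self) -> float:
        """Effective oncotic pressure difference sigma*(pi_lum - pi_ins)."""
        return self.sigma * (self.pi_lum - self.pi_ins)


@dataclass
class FlowSolution:
    """Solved network state: node pressures and per-segment flows."""

    node_pressure: dict          # site -> p_lum (mmHg)
    total_inflow: float = 0.0    # um^3/s into the network at fixed nodes
    total_outflow: float = 0.0   # um^3/s out of the network at fixed nodes
    total_leak: float = 0.0      # total transvascular filtration, um^3/s
    residual: float = 0.0        # worst interior mass-balance defect, um^3/s


# ---------------------------------------------------------------------------
# Rheology

def relative_viscosity(d_v: float | np.ndarray) -> float | np.ndarray:
    """Pries in-vivo relative apparent viscosity of normal-hematocrit blood."""
    d = np.asarray(d_v, float)
    if np.any(d <= 0):
        raise ValueError("vessel diameter must be positive")
    out = 3.2 + 6.0 * np.exp(-0.085 * d) - 2.44 * np.exp(-0.06 * d**0.645)
    return float(out) if np.ndim(d_v) == 0 else out


def _shape_exponent(d_v: float | np.ndarray) -> np.ndarray:
    d = np.asarray(d_v, float)
    gate = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + np.exp(-0.075 * d)) * (gate - 1.0) + gate


def hematocrit_factor(H_D: float | np.ndarray, d_v: float | np.ndarray, H_D_n: float = 0.45):
    """Hematocrit dependence of viscosity, normalized to 1 at H_D_n."""
    H = np.asarray(H_D, float)
    if np.any((H < 0) | (H >= 1)):
        raise ValueError("hematocrit must lie in [0, 1)")
    C = _shape_exponent(d_v)
    out = ((1.0 - H) ** C - 1.0) / ((1.0 - H_D_n) ** C - 1.0)
    return float(out) if np.ndim(H_D) == 0 and np.ndim(d_v) == 0 else out


def blood_viscosity(
    d_v: float, H_D: float, params: FluidParams
) -> float:
    """Apparent blood viscosity (Pa*s) for one segment.

    Diameters at or below the 1.1 um pole are treated as collapsed by the
    caller; this function requires d_v > 1.1.
    """
    if d_v <= 1.1:
        raise ValueError("blood_viscosity undefined for d_v <= 1.1 um (collapsed)")
    mu_n = relative_viscosity(d_v)
    f = hematocrit_factor(H_D, d_v, params.H_D_n)
    wall = (d_v / (d_v - 1.1)) ** 2
    return (1.0 + (mu_n - 1.0) * f * wall) * wall * params.mu_plasma


# ---------------------------------------------------------------------------
# Elementary flows

def poiseuille_flow(dp_lum: float, d_v: float, L: float, mu_blood: float) -> float:
    """Hagen-Poiseuille volumetric flow, um^3/s (dp in mmHg)."""
    return (np.pi / 128.0) * (dp_lum * MMHG_TO_PA) * d_v**4 / (L * mu_blood)


def segment_conductance(d_v: float, L: float, mu_blood: float) -> float:
    """Flow per unit pressure difference, um^3/(s mmHg)."""
    return (np.pi / 128.0) * MMHG_TO_PA * d_v**4 / (L * mu_blood)


def starling_flux(d_v: float, L: float, p_trans: float, params: FluidParams,
                  L_p: float | None = None) -> float:
    """Starling transvascular filtration rate, um^3/s."""
    lp = params.L_p if L_p is None else L_p
    return np.pi * d_v * L * lp * (p_trans - params.osmotic_jump)


def wall_shear_stress(mu_blood: float, Q_lum: float, d_v: float) -> float:
    """WSS from the solved flow: 32 mu Q / (pi d^3), in dyn/cm^2."""
    if d_v <= 0:
        return 0.0
    tau_pa = 32.0 * mu_blood * abs(Q_lum) / (np.pi * d_v**3)
    return tau_pa * PA_TO_DYN_CM2


# ---------------------------------------------------------------------------
# Network flow

def _effective_diameter(edge_data: dict) -> float:
    d = edge_data["d_v_def"] if edge_data["d_v_def"] > 0 else 0.0
    return d


def _edge_leak_coefficient(
    a, b, edge_data: dict, params: FluidParams, tumor_mask: np.ndarray | None
) -> float:
    d = _effective_diameter(edge_data)
    lp = params.L_p
    if params.tumor_lp_scaling and tumor_mask is not None and (tumor_mask[a] or tumor_mask[b]):
        lp = params.L_p * max(d / params.d_c, 0.0)
    return np.pi * d * edge_data["L"] * lp


def solve_network_flow(
    network,
    p_ins: ScalarField,
    params: FluidParams,
    tumor_mask: np.ndarray | None = None,
) -> FlowSolution:
    """Solve nodal pressures and segment flows with distributed Starling leak.

    Mass balance at every free node: the Poiseuille flows into the node
    equal half of the Starling leak of each adjacent segment (the leak is
    evaluated at the segment midpoint and split between its endpoints).
    Ring nodes carry fixed (Dirichlet) pressures.  Components containing no
    fixed node are flagged and left flowless.
    """
    g = network.graph
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    fixed = {n: d["fixed_pressure"] for n, d in g.nodes(data=True)
             if d.get("fixed_pressure") is not None}

    # viscosity and conductance per edge from current diameter and hematocrit
    cond = {}
    leak_coef = {}
    for a, b, d in g.edges(data=True):
        dv = _effective_diameter(d)
        if dv <= 1.1:
            d["collapsed"] = True
            cond[(a, b)] = 0.0
            leak_coef[(a, b)] = 0.0
            d["mu_blood"] = params.mu_plasma
            continue
        mu = blood_viscosity(dv, min(d["H_D"], 0.99), params)
        d["mu_blood"] = mu
        cond[(a, b)] = segment_conductance(dv, d["L"], mu)
        leak_coef[(a, b)] = _edge_leak_coefficient(a, b, d, params, tumor_mask)

    # identify solvable nodes: components that reach a fixed-pressure node
    # through segments that actually conduct or leak (collapsed segments
    # with zero conductance and zero leak cannot transmit pressure)
    import networkx as nx

    eff = nx.Graph()
    eff.add_nodes_from(g.nodes)
    for a, b in g.edges:
        key = (a, b) if (a, b) in cond else (b, a)
        if cond[key] > 0.0 or leak_coef[key] > 0.0:
            eff.add_edge(a, b)
    solvable = set()
    for comp in nx.connected_components(eff):
        if any(n in fixed for n in comp):
            solvable |= comp
        elif len(comp) > 1:
            warnings.warn("vessel component with no pressure reference; flows set to 0")

    free = [n for n in nodes if n in solvable and n not in fixed]
    fidx = {n: i for i, n in enumerate(free)}
    rows, cols, vals = [], [], []
    rhs = np.zeros(len(free))
    for a, b, d in g.edges(data=True):
        gab = cond[(a, b)]
        kl = leak_coef[(a, b)]
        pm = 0.5 * (p_ins.values[a] + p_ins.values[b]) + params.osmotic_jump
        for x, y in ((a, b), (b, a)):
            if x not in fidx:
                continue
            i = fidx[x]
            rows.append(i); cols.append(i); vals.append(gab + 0.25 * kl)
            rhs[i] += 0.5 * kl * pm
            if y in fidx:
                rows.append(i); cols.append(fidx[y]); vals.append(-gab + 0.25 * kl)
            else:
                py = fixed.get(y, 0.0)
                rhs[i] += (gab - 0.25 * kl) * py

    pressures = dict(fixed)
    if free:
        A = coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsr()
        try:
            sol = spsolve(A, rhs)
        except Exception as exc:  # singular isolated pieces
            raise SolverError(f"network flow solve failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("network flow solve produced non-finite pressures")
        for n, i in fidx.items():
            pressures[n] = float(sol[i])
    for n in nodes:
        if n not in pressures:
            pressures[n] = None  # pressure-unreferenced: no flow, no perfusion
        g.nodes[n]["p_lum"] = pressures[n]

    # per-segment flows, leak and WSS
    total_leak = 0.0
    residual = np.zeros(len(free))
    for a, b, d in g.edges(data=True):
        gab = cond[(a, b)]
        kl = leak_coef[(a, b)]
        pa, pb = pressures[a], pressures[b]
        if pa is None or pb is None:
            d.update(_a=a, Q_IBF=0.0, Q_TFF=0.0, Q_lum=0.0, tau=0.0,
                     p_trans=0.0)
            continue
        q_ibf = gab * (pa - pb)
        p_mid = 0.5 * (pa + pb)
        p_ins_mid = 0.5 * (p_ins.values[a] + p_ins.values[b])
        q_tff = kl * (p_mid - p_ins_mid - params.osmotic_jump)
        d["_a"] = a
        d["Q_IBF"] = q_ibf
        d["Q_TFF"] = q_tff
        d["Q_lum"] = q_ibf - q_tff
        d["p_trans"] = p_mid - p_ins_mid
        dv = _effective_diameter(d)
        d["tau"] = wall_shear_stress(d["mu_blood"], d["Q_lum"], dv) if dv > 1.1 else 0.0
        if dv > 1.1 and abs(d["Q_lum"]) > 0:
            d["flow_governed"] = True
        total_leak += q_tff
        # mass balance at a free node: net outflow plus its share of the leak
        for x, sign in ((a, 1.0), (b, -1.0)):
            if x in fidx:
                residual[fidx[x]] += sign * q_ibf + 0.5 * q_tff

    inflow = outflow = 0.0
    for n in fixed:
        net = 0.0
        for m in g.neighbors(n):
            if pressures[m] is None:
                continue
            q = cond[(n, m)] if (n, m) in cond else cond[(m, n)]
            net += q * (pressures[n] - pressures[m])
            # half of the adjacent segment's leak is drawn directly at this
            # boundary node; count it so inflow = outflow + total leak holds
            e = g.edges[n, m]
            net += 0.5 * e["Q_TFF"]
        if net > 0:
            inflow += net
        else:
            outflow -= net
    res = float(np.max(np.abs(residual))) if len(free) else 0.0
    return FlowSolution(pressures, inflow, outflow, total_leak, res)


def _components(g):
    import networkx as nx

    return nx.connected_components(g)


# ---------------------------------------------------------------------------
# Hematocrit phase separation

def distribute_hematocrit(network, params: FluidParams) -> dict:
    """Propagate hematocrit from the inlets through the solved flow field.

    Nodes are processed in descending-pressure order, which topologically
    orders the flow directions (blood always runs down-pressure), so a
    single pass handles loops exactly.  At a bifurcation with daughter
    velocities u1 >= u2 the parent hematocrit splits by plasma skimming
    (concentration sums conserved as printed); beyond the velocity-ratio
    threshold the slower daughter receives none.  Junctions with more than
    two outflows are split pairwise in descending-velocity order.  Merging
    inflows mix flux-weighted.  Returns {site: node hematocrit}.
    """
    g = network.graph
    pres = {n: g.nodes[n].get("p_lum") for n in g.nodes}
    pres = {n: (-np.inf if p is None else p) for n, p in pres.items()}
    order = sorted(g.nodes, key=lambda n: -pres[n])
    node_h: dict = {}
    fixed_inlets = {
        n for n, d in g.nodes(data=True)
        if d.get("fixed_pressure") is not None
    }
    for a, b, d in g.edges(data=True):
        d["H_D"] = 0.0

    for n in order:
        inflows = []
        outflows = []
        for m in g.neighbors(n):
            e = g.edges[n, m]
            q = e["Q_IBF"] if _edge_orient(n, m, e) else -e["Q_IBF"]
            # q > 0 means flow n -> m (outflow from n)
            if abs(q) < 1e-300:
                continue
            if q > 0:
                outflows.append((m, e, q))
            else:
                inflows.append((m, e, -q))
        if n in fixed_inlets and not inflows:
            h_node = params.H_D_n if outflows else 0.0
        elif inflows:
            qtot = sum(q for *_, q in inflows)
            h_node = sum(e["H_D"] * q for _, e, q in inflows) / qtot if qtot > 0 else 0.0
        else:
            h_node = 0.0
        node_h[n] = h_node
        if not outflows:
            continue

        def velocity(item):
            m, e, q = item
            dv = max(_effective_diameter(e), 1e-12)
            return q / (np.pi * dv**2 / 4.0)

        outflows.sort(key=velocity, reverse=True)
        h_p = h_node
        while len(outflows) >= 2:
            fast = outflows.pop(0)
            u1 = velocity(fast)
            u2 = velocity(outflows[0])
            if u2 <= 0 or u1 / u2 > params.r_th:
                h1, h2 = h_p, 0.0
            elif params.flux_weighted_split:
                # variant: the printed concentration fractions reinterpreted
                # as RBC-flux fractions, so H*Q is conserved instead of H
                q1, q2 = fast[2], outflows[0][2]
                phi1 = 1.0 / (1.0 + u1 / (2.0 * u2))
                phi2 = 1.0 / (1.0 + 2.0 * u2 / u1)
                qp = q1 + q2
                h1 = min(h_p * qp * phi1 / q1, 0.99)
                h2 = min(h_p * qp * phi2 / q2, 0.99)
            else:
                h1 = h_p / (1.0 + u1 / (2.0 * u2))
                h2 = h_p / (1.0 + 2.0 * u2 / u1)
            fast[1]["H_D"] = min(h1, 0.99)
            h_p = h2
        outflows[0][1]["H_D"] = min(h_p, 0.99)
    return node_h


def _edge_orient(n, m, e) -> bool:
    """True if Q_IBF was computed with n as the first endpoint."""
    a = e.get("_a")
    return a == n if a is not None else n <= m


# ---------------------------------------------------------------------------
# Interstitium

def ifp_source_field(network, p_ins: ScalarField, params: FluidParams,
                     tumor_mask: np.ndarray | None = None) -> ScalarField:
    """Poisson source for IFP: Starling filtration at vessel-wall nodes.

    ``L_p (S/V) / K_ins * (p_trans - sigma (pi_lum - pi_ins))`` at vessel
    nodes, zero elsewhere; mmHg/um^2.
    """
    lat = p_ins.lattice
    src = np.zeros(lat.shape)
    g = network.graph
    for n, d in g.nodes(data=True):
        p_lum = d.get("p_lum", params.p_inlet)
        if p_lum is None:
            continue  # pressure-unreferenced node: no transvascular source
        lp = params.L_p
        if params.tumor_lp_scaling and tumor_mask is not None and tumor_mask[n]:
            dvs = [g.edges[n, m]["d_v_def"] for m in g.neighbors(n)]
            if dvs:
                lp = params.L_p * max(np.mean(dvs) / params.d_c, 0.0)
        src[n] = lp * params.S_over_V / params.K_ins * (
            p_lum - p_ins.values[n] - params.osmotic_jump
        )
    return ScalarField(lat, src, "ifp_source")


def solve_interstitial(
    network,
    params: FluidParams,
    p_ins_prev: ScalarField | None = None,
    tumor_mask: np.ndarray | None = None,
    tol: float = 1e-8,
) -> tuple[ScalarField, VectorField]:
    """IFP from the vascular leak sources and Darcy velocity from its gradient."""
    lat = network.lattice
    if p_ins_prev is None:
        p_ins_prev = ScalarField.uniform(lat, 0.0, "p_ins")
    src = ifp_source_field(network, p_ins_prev, params, tumor_mask)
    bc = BoundaryCondition(0.0)
    p = solve_poisson(src, bc, tol=tol, x0=p_ins_prev.values)
    p.name = "p_ins"
    grad = gradient(p)
    u = VectorField(lat, -params.K_ins * grad.ux, -params.K_ins * grad.uy,
                    -params.K_ins * grad.uz, "u_ins")
    return p, u


def couple_flow_interstitium(
    network,
    params: FluidParams,
    p_ins_init: ScalarField | None = None,
    tumor_mask: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 30,
) -> tuple[FlowSolution, ScalarField, VectorField, int]:
    """Fixed-point coupling of network flow and interstitial pressure.

    Alternates the nodal flow solve (given IFP) with the IFP solve (given
    vascular leaks) until the max change of both pressure sets drops below
    ``tol`` (mmHg).  Returns (flow, p_ins, u_ins, iterations).
    """
    lat = network.lattice
    p_ins = p_ins_init if p_ins_init is not None else ScalarField.uniform(lat, 0.0, "p_ins")
    prev_nodal: dict = {}
    history = []
    for it in range(1, max_iter + 1):
        flow = solve_network_flow(network, p_ins, params, tumor_mask)
        p_new, u = solve_interstitial(network, params, p_ins, tumor_mask)
        dp_field = float(np.max(np.abs(p_new.values - p_ins.values)))
        dp_nodal = max(
            (
                abs(p - prev_nodal.get(n, 0.0))
                for n, p in flow.node_pressure.items()
                if p is not None
            ),
            default=0.0,
        )
        p_ins = p_new
        prev_nodal = dict(flow.node_pressure)
        history.append(max(dp_field, dp_nodal))
        if history[-1] < tol:
            return flow, p_ins, u, it
    raise SolverError(
        f"flow-interstitium coupling did not converge in {max_iter} iterations; "
        f"residual history: {['%.3g' % r for r in history]}"
    )
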