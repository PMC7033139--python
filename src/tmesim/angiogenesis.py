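"""Angiogenic vessel network: sprouting, tip migration, lumenogenesis,
adaptation, deformation and disruption.

The vasculature is a graph whose nodes sit on lattice sites and whose edges
(segments) connect 26-neighbor sites, so segment lengths are 1, sqrt(2) or
sqrt(3) times the lattice spacing.  A fixed *primary ring* of vessel nodes
supplies blood at prescribed pressures; VEGF-activated ring nodes spawn tip
endothelial cells (tECs) that migrate by chemotaxis (saturating in VEGF),
haptotaxis along the ECM, and a solid-stress barrier, laying down stalk
segments behind them.  Stalk segments grow lumens (Michaelis-Menten in a
stalk growth state driven by VEGF and the Ang-1/Ang-2 balance) until they
first carry flow, after which the wall-signal adaptation law takes over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .grid import NEIGHBOR_OFFSETS, ConfigurationError, LatticeSpec, ScalarField
from .tumor_cells import MotilityParams, move_probabilities_batch

Site = tuple[int, int, int]


@dataclass
class LumenParams:
    """Stalk-growth / lumenogenesis constants (rates in 1/s)."""

    G_0: float = 5.0          # Michaelis constant for lumen growth
    alpha_p: float = 3.0e-4   # max sEC proliferation rate
    theta_p: float = 0.02     # VEGF Michaelis constant for proliferation
    omega_m: float = 1.5e-4   # max quiescence-for-maturation rate
    theta_m: float = 0.02     # VEGF Michaelis constant for maturation
    rho_m: float = 1.0        # Ang-1/Ang-2 ratio Michaelis constant
    delta: float = 1.0e-4     # max sEC death rate
    theta_d: float = 0.01     # VEGF Michaelis constant for death
    k_age: float = 2.0e-5     # aging growth constant
    d_c: float = 40.0         # characteristic neo-vessel diameter, um
    d_nascent: float = 2.0    # nascent sprout diameter, um

    @property
    def G_s_nascent(self) -> float:
        """Initial stalk growth state so that d_v(0) = d_nascent."""
        return self.G_0 * self.d_nascent / (self.d_c - self.d_nascent)


@dataclass
class AdaptationParams:
    """Wall-signal diameter adaptation constants.

    WSS in dyn/cm^2 project-wide; the empirical constants of the
    transvascular-pressure stimulus (100, 86, 5000, 5.4) are fixed.
    """

    tau_ref: float = 0.5      # WSS offset avoiding the log singularity
    k_p: float = 0.5          # pressure-stimulus weight
    k_m: float = 0.8          # hematocrit-metabolic stimulus weight
    k_e: float = 0.5          # VEGF-stimulus weight
    k_0: float = 1.0          # wall elasticity constant, dyn/cm^2 per um
    c_v_ch: float = 0.05      # characteristic VEGF concentration
    d_0: float = 10.0         # stress-free diameter, um
    tau_c: float = 10.0       # characteristic elastic stress, dyn/cm^2
    S_Sh: float = 1.0         # shrinkage stimulus
    k_d: float = 1.0 / 3600.0 # diameter rate scale, um/s per unit stimulus
    d_max: float = 60.0       # diameter cap (1.5 x d_c)


@dataclass
class ComplianceParams:
    """Elastic wall deformation under transvascular pressure and stress."""

    E: float = 25.0           # elasticity, mmHg
    cp: float = 0.1           # compliance power
    p_c: float = 5.0          # collapse pressure, mmHg


@dataclass
class DisruptionParams:
    """Removal of chronically under-sheared or VEGF-flooded segments."""

    tau_th: float = 0.01      # WSS threshold, dyn/cm^2
    c_v_th: float = 1.5       # VEGF threshold inside the tumor
    t_s: float = 36_000.0     # survival time, s (10 h)


@dataclass
class SproutingParams:
    """Sprout initiation and branching thresholds."""

    c_v_sprout: float = 0.007 # VEGF level activating ring sprouting
    min_spacing: float = 150.0 # NOTCH-mediated minimum spacing, um
    c_v_branch: float = 0.3   # VEGF level enabling stalk-to-tip branching
    branch_rate: float = 1.0 / 21600.0  # branching rate above threshold, 1/s


@dataclass
class TipCell:
    """Migrating tip endothelial cell leading one sprout."""

    site: Site
    prev_site: Site | None = None
    alive: bool = True
    age: float = 0.0


class VesselNetwork:
    """Graph of vessel nodes (lattice sites) and segments (edges)."""

    def __init__(self, lattice: LatticeSpec):
        self.lattice = lattice
        self.graph = nx.Graph()
        self.tips: list[TipCell] = []

    # -- construction -------------------------------------------------------

    def add_node(self, site: Site, kind: str = "neo", fixed_pressure: float | None = None):
        if site in self.graph:
            return
        if not self.lattice.contains(site):
            raise ConfigurationError(f"vessel node {site} off lattice")
        self.graph.add_node(site, kind=kind, fixed_pressure=fixed_pressure, is_tip=False)

    def add_segment(self, a: Site, b: Site, d_v: float, G_s: float, kind: str = "neo"):
        if a not in self.graph or b not in self.graph:
            raise ConfigurationError("segment endpoints must exist")
        diff = np.abs(np.asarray(a) - np.asarray(b))
        if diff.max() != 1:
            raise ConfigurationError(f"segment {a}-{b} endpoints are not lattice neighbors")
        L = float(np.linalg.norm(diff) * self.lattice.h)
        self.graph.add_edge(
            a, b, L=L, d_v=d_v, d_v_def=d_v, G_s=G_s, H_D=0.0,
            Q_lum=0.0, Q_IBF=0.0, Q_TFF=0.0, tau=0.0, age=0.0,
            low_wss_timer=0.0, high_vegf_timer=0.0, kind=kind,
            flow_governed=False, collapsed=False,
        )

    # -- queries ------------------------------------------------------------

    def ring_sites(self) -> list[Site]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "primary"]

    def neo_segments(self):
        return [(a, b, d) for a, b, d in self.graph.edges(data=True) if d["kind"] == "neo"]

    def segments(self):
        return list(self.graph.edges(data=True))

    def n_neo_segments(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d["kind"] == "neo")

    def ec_mask(self) -> np.ndarray:
        mask = np.zeros(self.lattice.shape, dtype=bool)
        for site in self.graph.nodes:
            mask[site] = True
        return mask

    def validate(self) -> None:
        """Graph-consistency audit: endpoints exist, lengths legal, no dups."""
        for a, b, d in self.graph.edges(data=True):
            ratio = d["L"] / self.lattice.h
            if not any(math.isclose(ratio, r, rel_tol=1e-9) for r in (1.0, math.sqrt(2), math.sqrt(3))):
                raise ConfigurationError(f"segment {a}-{b} has illegal length {d['L']}")
        for tip in self.tips:
            if tip.alive and tip.site not in self.graph:
                raise ConfigurationError(f"tip at {tip.site} lost its node")


# ---------------------------------------------------------------------------
# Sprout initiation

def select_sprout_sites(
    ring_sites: list[Site],
    c_v: ScalarField,
    params: SproutingParams,
    rng: np.random.Generator,
    existing_tips: list[Site] | None = None,
) -> list[Site]:
    """VEGF-activated ring nodes, greedily accepted with NOTCH spacing.

    Candidates (c_v >= activation level) are visited in random order; a
    candidate is accepted only if farther than ``min_spacing`` from every
    previously accepted or existing sprout site.
    """
    lat = c_v.lattice
    candidates = [s for s in ring_sites if c_v.values[s] >= params.c_v_sprout]
    if not candidates:
        return []
    order = rng.permutation(len(candidates))
    accepted: list[Site] = []
    anchors = [lat.coords(s) for s in (existing_tips or [])]
    for idx in order:
        s = candidates[idx]
        x = lat.coords(s)
        if all(np.linalg.norm(x - a) > params.min_spacing for a in anchors):
            accepted.append(s)
            anchors.append(x)
    return accepted


# ---------------------------------------------------------------------------
# Tip migration

def tec_move_probabilities(
    tip: TipCell,
    c_v: ScalarField,
    c_e: ScalarField,
    p_bias: ScalarField,
    motility: MotilityParams,
    dt: float,
) -> np.ndarray:
    """27-vector of move probabilities for one tip EC.

    Chemotaxis up the VEGF gradient with saturating weight
    ``beta_c / (1 + alpha c_v)``, haptotaxis up the ECM gradient, and the
    solid-stress barrier as an exponential down-weighting; the tip's own
    previous node is excluded to prevent immediate backtracking.
    """
    sites = np.asarray([tip.site], int)
    chemo_coef = motility.beta_c / (1.0 + motility.alpha * c_v.values[tip.site])
    forbidden = None
    if tip.prev_site is not None:
        forbidden = np.zeros((1, 26), dtype=bool)
        delta = tuple(np.asarray(tip.prev_site) - np.asarray(tip.site))
        for k, e in enumerate(NEIGHBOR_OFFSETS[1:]):
            if tuple(e) == delta:
                forbidden[0, k] = True
    return move_probabilities_batch(
        sites,
        c_v.lattice,
        motility.D_EC,
        [(np.asarray([chemo_coef]), c_v.values), (motility.beta_h, c_e.values)],
        p_bias.values,
        motility.lambda_p,
        np.zeros(c_v.lattice.shape, dtype=bool),
        dt,
        extra_forbidden=forbidden,
    )[0]


def extend_sprout(
    tip: TipCell, move: Site, network: VesselNetwork, lumen: LumenParams
) -> None:
    """Advance a tip by one lattice move, laying a stalk segment behind it.

    Moving onto an existing vessel node triggers anastomosis and retires the
    tip; otherwise a new neo node and a nascent-diameter segment are created.
    """
    if move == (0, 0, 0) or not tip.alive:
        return
    target = tuple(int(a + m) for a, m in zip(tip.site, move))
    if not network.lattice.contains(target):
        return
    if target in network.graph:
        anastomose(tip, target, network, lumen)
        return
    network.add_node(target, kind="neo")
    network.graph.nodes[target]["is_tip"] = True
    network.graph.nodes[tip.site]["is_tip"] = False
    network.add_segment(tip.site, target, lumen.d_nascent, lumen.G_s_nascent)
    tip.prev_site = tip.site
    tip.site = target


def anastomose(tip: TipCell, target: Site, network: VesselNetwork, lumen: LumenParams) -> None:
    """Fuse a tip into an existing vessel node, closing a loop."""
    if target == tip.prev_site:
        return  # no self-fusion with the immediately preceding node
    if not network.graph.has_edge(tip.site, target):
        network.add_segment(tip.site, target, lumen.d_nascent, lumen.G_s_nascent)
    network.graph.nodes[tip.site]["is_tip"] = False
    other = network.graph.nodes[target]
    if other.get("is_tip"):
        other["is_tip"] = False
        for t in network.tips:
            if t.alive and t.site == target:
                t.alive = False
    tip.alive = False


def maybe_branch(
    network: VesselNetwork,
    c_v: ScalarField,
    params: SproutingParams,
    rng: np.random.Generator,
    dt: float,
) -> list[TipCell]:
    """Stalk-to-tip differentiation: VEGF-driven bifurcation from the wall.

    Degree-2 stalk nodes seeing VEGF above the branching threshold become
    new tips at rate ``branch_rate`` per unit time, subject to the NOTCH
    spacing rule against existing branch points and tips.
    """
    lat = network.lattice
    new_tips: list[TipCell] = []
    anchors = [lat.coords(n) for n, deg in network.graph.degree() if deg >= 3]
    anchors += [lat.coords(t.site) for t in network.tips if t.alive]
    candidates = [
        n for n, d in network.graph.nodes(data=True)
        if d["kind"] == "neo" and not d["is_tip"] and network.graph.degree(n) == 2
        and c_v.values[n] > params.c_v_branch
    ]
    for n in candidates:
        x = lat.coords(n)
        if any(np.linalg.norm(x - a) <= params.min_spacing for a in anchors):
            continue
        if rng.random() < params.branch_rate * dt:
            network.graph.nodes[n]["is_tip"] = True
            tip = TipCell(site=n, prev_site=None)
            network.tips.append(tip)
            new_tips.append(tip)
            anchors.append(x)
    return new_tips


# ---------------------------------------------------------------------------
# Lumenogenesis

def stalk_growth_step(
    G_s: float | np.ndarray,
    c_v: float | np.ndarray,
    c_a1: float | np.ndarray,
    c_a2: float | np.ndarray,
    dt: float,
    params: LumenParams,
) -> float | np.ndarray:
    """Euler step of the stalk-growth state.

    Proliferation (Michaelis-Menten in VEGF) minus quiescence-for-maturation
    (VEGF saturation times an Ang-1/Ang-2-ratio saturation) minus death
    (active at low VEGF) plus aging.  With no Ang-2 the ratio is treated as
    infinite: absence of the destabilizer maximizes the maturation factor.
    """
    cv = np.asarray(c_v, float)
    a1 = np.asarray(c_a1, float)
    a2 = np.asarray(c_a2, float)
    prolif = params.alpha_p * cv / (cv + params.theta_p)
    # Ang-1/Ang-2 ratio saturation, rewritten as 1/(1 + rho_m * a2/a1) so
    # the no-Ang-2 limit is exactly 1 and the no-ligand case is 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_sat = np.where(
            a1 > 0.0,
            1.0 / (1.0 + params.rho_m * np.where(a1 > 0.0, a2 / np.where(a1 > 0, a1, 1.0), 0.0)),
            0.0,
        )
    maturation = params.omega_m * (cv / (cv + params.theta_m)) * ratio_sat
    death = (1.0 - cv / (cv + params.theta_d)) * params.delta
    out = np.asarray(G_s, float) + dt * (prolif - maturation - death + params.k_age)
    out = np.maximum(out, 0.0)
    if np.ndim(G_s) == 0:
        return float(out)
    return out


def lumen_diameter(G_s: float | np.ndarray, params: LumenParams) -> float | np.ndarray:
    """Quasi-static lumen diameter: d_c * G_s / (G_s + G_0), bounded by d_c."""
    return params.d_c * np.asarray(G_s, float) / (np.asarray(G_s, float) + params.G_0)


# ---------------------------------------------------------------------------
# Adaptation / deformation / disruption

#: events logged by the numerical guards below (name -> count)
GUARD_LOG: dict[str, int] = {}


def _log_guard(name: str) -> None:
    GUARD_LOG[name] = GUARD_LOG.get(name, 0) + 1


def adaptation_stimuli(
    tau: float,
    p_trans: float,
    Q_lum: float,
    H_D: float,
    c_v: float,
    d_v: float,
    params: AdaptationParams,
    Q_ref: float,
) -> tuple[float, float, float, float]:
    """The four wall signals controlling neo-vessel dilation/constriction.

    ``S_WSS = log10(tau + tau_ref)``; the transvascular-pressure stimulus
    uses the published empirical fit (valid for p >= 10 mmHg; lower
    pressures are clamped to the 10 mmHg plateau and logged); the metabolic
    stimulus compares hematocrit flow against the network-wide reference
    flow; the VEGF stimulus vanishes at the stress-free diameter.
    """
    S_wss = math.log10(tau + params.tau_ref)

    p_eff = p_trans
    if p_eff < 10.0:
        _log_guard("S_p_pressure_clamp")
        p_eff = 10.0
    loglog = math.log10(math.log10(p_eff)) if p_eff > 10.0 else 0.0
    tau_e = 100.0 - 86.0 * math.exp(-5000.0 * loglog**5.4)
    S_p = -params.k_p * math.log10(tau_e)

    qh = Q_lum * H_D
    if qh <= 0.0:
        _log_guard("S_HM_no_flow_clamp")
        qh = max(Q_ref, 1e-30) * 1e-6
    S_hm = params.k_m * math.log10(Q_ref / qh + 1.0)

    suscept = params.k_0 * (params.c_v_ch / (params.c_v_ch + c_v)) * (d_v - params.d_0)
    arg = suscept / params.tau_c + 1.0
    if arg < 0.1:
        _log_guard("S_vegf_arg_clamp")
        arg = 0.1
    S_vegf = -params.k_e * math.log10(arg)
    return S_wss, S_p, S_hm, S_vegf


def adapt_diameter(
    d_v: float, stimuli: tuple[float, float, float, float], dt: float, params: AdaptationParams
) -> float:
    """Euler diameter update from the summed wall stimuli minus shrinkage,
    floored at 0 and capped at d_max."""
    total = sum(stimuli) - params.S_Sh
    new = d_v + dt * params.k_d * total
    return float(min(max(new, 0.0), params.d_max))


def deform_diameter(
    d_v: float, p_trans: float, p_s: float, params: ComplianceParams
) -> tuple[float, bool]:
    """Elastic deformation; returns (deformed diameter, collapsed flag)."""
    base = (p_trans - p_s + params.p_c) / params.E
    if base <= 0.0:
        return 0.0, True
    return float(d_v * base**params.cp), False


def disrupt_vessels(
    network: VesselNetwork,
    c_v: ScalarField,
    inside_tumor: np.ndarray,
    dt: float,
    params: DisruptionParams,
) -> int:
    """Remove neo segments chronically below the WSS threshold or chronically
    VEGF-flooded inside the tumor; timers reset whenever the condition
    clears.  Orphaned neo nodes are pruned; the primary ring is never
    touched.  Returns the number of removed segments."""
    to_remove = []
    for a, b, d in network.neo_segments():
        if d["tau"] < params.tau_th:
            d["low_wss_timer"] += dt
        else:
            d["low_wss_timer"] = 0.0
        mid_cv = 0.5 * (c_v.values[a] + c_v.values[b])
        if (inside_tumor[a] or inside_tumor[b]) and mid_cv > params.c_v_th:
            d["high_vegf_timer"] += dt
        else:
            d["high_vegf_timer"] = 0.0
        if d["low_wss_timer"] >= params.t_s or d["high_vegf_timer"] >= params.t_s:
            to_remove.append((a, b))
    network.graph.remove_edges_from(to_remove)
    # prune neo nodes no longer connected to the primary ring: a severed
    # fragment can never carry pressure or flow again
    orphan_set: set = set()
    if to_remove:
        import networkx as nx

        for comp in nx.connected_components(network.graph):
            if not any(network.graph.nodes[n]["kind"] == "primary" for n in comp):
                orphan_set |= comp
    orphan_set |= {
        n for n, d in network.graph.nodes(data=True)
        if d["kind"] == "neo" and network.graph.degree(n) == 0
    }
    network.graph.remove_nodes_from(orphan_set)
    for tip in network.tips:
        if tip.alive and tip.site in orphan_set:
            tip.alive = False
    return len(to_remove)
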