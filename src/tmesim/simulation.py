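"""Simulation orchestration: initialization, the macro time step, full runs.

Time hierarchy (all configurable): soluble-species transport runs on the
finest step ``dt_transport``; cellular events (phenotype, energy, division,
migration, sprouting) on ``dt_cell``; and flow, lumenogenesis, adaptation,
deformation and disruption on the coarsest step ``dt_remodel``.  One
:func:`macro_step` advances the state by ``dt_cell``.

The default scenario starts from five active tumor cells at the center of
the cube and a circular primary vessel ring of radius ~ half the domain in
the tumor mid-plane; nutrients are uniform at their characteristic levels
and growth factors are zero.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import biochem, hemodynamics
from .angiogenesis import (
    TipCell,
    VesselNetwork,
    adapt_diameter,
    adaptation_stimuli,
    deform_diameter,
    disrupt_vessels,
    extend_sprout,
    lumen_diameter,
    maybe_branch,
    select_sprout_sites,
    stalk_growth_step,
)
from .biochem import OccupancyMasks, ReceptorState
from .config import ParameterSet, SimulationConfig, apply_scenario
from .grid import (
    BoundaryCondition,
    ClampAudit,
    LatticeSpec,
    ScalarField,
    VectorField,
)
from .metrics import MetricsReport
from .tumor_cells import (
    ACTIVE,
    NECROTIC,
    QUIESCENT,
    CellPopulation,
    energy_step,
    move_probabilities_batch,
    phenotype_transition,
    sample_moves_batch,
    solid_stress_field,
    vitality,
)

SPECIES = ("c_o2", "c_g", "c_co2", "c_v", "c_a1", "c_a2", "c_m")
U_EPS = 1e-2  # um/s; below this the interstitial flow cannot move solute
              # across any meaningful fraction of a lattice spacing
RNG_STREAMS = ("sprouting", "tips", "branching", "proliferation", "migration", "ordering")


@dataclass
class SimulationState:
    """Everything that evolves: fields, agents, network, fluids, clocks."""

    config: SimulationConfig
    params: ParameterSet              # scenario-applied working copy
    fields: dict                      # name -> ScalarField
    bcs: dict                         # name -> BoundaryCondition
    receptors: ReceptorState
    population: CellPopulation
    network: VesselNetwork
    p_ins: ScalarField
    u_ins: VectorField
    p_s: ScalarField
    masks: OccupancyMasks
    rngs: dict
    clamp_audit: ClampAudit = field(default_factory=ClampAudit)
    report: MetricsReport = field(default_factory=MetricsReport)
    t: float = 0.0                    # simulated seconds
    step_count: int = 0
    ec_dv: np.ndarray | None = None   # per-node mean adjacent diameter, um
    ec_plum: np.ndarray | None = None # per-node lumen pressure, mmHg
    flow: object | None = None
    Q_ref: float = 0.0
    initial_centroid: np.ndarray | None = None
    sprout_origins: list = field(default_factory=list)

    @property
    def t_days(self) -> float:
        return self.t / 86400.0


# ---------------------------------------------------------------------------
# Initialization

def _build_primary_ring(network: VesselNetwork, params: ParameterSet) -> None:
    """Rasterize the circular primary vessel in the mid-plane.

    Ring radius is half the domain extent minus one spacing (the circle of
    the full-scale setup scaled with the lattice).  Node pressures vary
    smoothly from the inlet value at angle 0 to inlet - p_drop at angle pi,
    giving the network a driving pressure difference once loops form.
    """
    lat = network.lattice
    cx, cy, cz = lat.center_site()
    r = min(lat.extent[0], lat.extent[1]) / 2.0 - lat.h
    fluid = params.fluid
    n_theta = max(int(2 * np.pi * r / lat.h) * 4, 64)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    sites, site_theta = [], {}
    for th in thetas:
        s = (
            int(round(cx + r * np.cos(th) / lat.h)),
            int(round(cy + r * np.sin(th) / lat.h)),
            cz,
        )
        if not sites or s != sites[-1]:
            if s in site_theta:
                continue
            sites.append(s)
            site_theta[s] = th
    p_out = fluid.p_inlet - fluid.p_drop
    for s in sites:
        p = p_out + (fluid.p_inlet - p_out) * (1.0 + np.cos(site_theta[s])) / 2.0
        network.add_node(s, kind="primary", fixed_pressure=p)
    for a, b in zip(sites, sites[1:] + sites[:1]):
        if a == b:
            continue
        diff = np.abs(np.asarray(a) - np.asarray(b))
        if diff.max() != 1:
            continue  # rasterization duplicate; ring stays connected overall
        network.add_segment(a, b, params.d_primary, G_s=1e6, kind="primary")
        network.graph.edges[a, b]["flow_governed"] = True


def initialize(config: SimulationConfig) -> SimulationState:
    """Build the initial state for a configuration (scenario applied)."""
    params = apply_scenario(config.parameters, config.scenario)
    lat = config.lattice
    cr, gf = params.cr, params.gf

    fields = {
        "c_o2": ScalarField.uniform(lat, cr.c_o2_ch, "c_o2"),
        "c_g": ScalarField.uniform(lat, cr.c_g_ch, "c_g"),
        "c_co2": ScalarField.uniform(lat, cr.c_co2_ch, "c_co2"),
        "c_v": ScalarField.uniform(lat, 0.0, "c_v"),
        "c_a1": ScalarField.uniform(lat, 0.0, "c_a1"),
        "c_a2": ScalarField.uniform(lat, 0.0, "c_a2"),
        "c_m": ScalarField.uniform(lat, 0.0, "c_m"),
        "c_e": ScalarField.uniform(lat, gf.c_e_ch, "c_e"),
    }
    bcs = {
        "c_o2": BoundaryCondition(cr.c_o2_ch),
        "c_g": BoundaryCondition(cr.c_g_ch),
        "c_co2": BoundaryCondition(cr.c_co2_ch),
        "c_v": BoundaryCondition(0.0),
        "c_a1": BoundaryCondition(0.0),
        "c_a2": BoundaryCondition(0.0),
        "c_m": BoundaryCondition(0.0),
    }

    population = CellPopulation(lat)
    cx, cy, cz = lat.center_site()
    seeds = [(cx, cy, cz), (cx + 1, cy, cz), (cx - 1, cy, cz),
             (cx, cy + 1, cz), (cx, cy - 1, cz)]
    for s in seeds:
        population.add(s, ACTIVE, params.phenotype.psi_ch / 2.0)

    network = VesselNetwork(lat)
    _build_primary_ring(network, params)

    receptors = ReceptorState.zeros(lat)
    masks = OccupancyMasks.empty(lat)

    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(RNG_STREAMS, ss.spawn(len(RNG_STREAMS)))}

    state = SimulationState(
        config=config,
        params=params,
        fields=fields,
        bcs=bcs,
        receptors=receptors,
        population=population,
        network=network,
        p_ins=ScalarField.uniform(lat, 0.0, "p_ins"),
        u_ins=VectorField.zeros(lat, "u_ins"),
        p_s=ScalarField.uniform(lat, 0.0, "p_s"),
        masks=masks,
        rngs=rngs,
    )
    state.report.parameter_digest = params.digest()
    _refresh_vessel_caches(state)
    state.p_s = solid_stress_field(population, params.stress)
    state.initial_centroid = population.centroid()
    return state


def _refresh_vessel_caches(state: SimulationState) -> None:
    """Rebuild the lattice-aligned EC mask, diameter and pressure caches."""
    lat = state.config.lattice
    g = state.network.graph
    ec = np.zeros(lat.shape, dtype=bool)
    dv = np.zeros(lat.shape)
    plum = np.zeros(lat.shape)
    p_default = state.params.fluid.p_inlet
    p_ins_vals = state.p_ins.values
    for n, d in g.nodes(data=True):
        ec[n] = True
        adj = [g.edges[n, m]["d_v_def"] for m in g.neighbors(n)]
        dv[n] = float(np.mean(adj)) if adj else 0.0
        if "p_lum" in d:
            # None marks a pressure-unreferenced node: zero transvascular
            # pressure, hence no perfusion through its wall
            plum[n] = p_ins_vals[n] if d["p_lum"] is None else d["p_lum"]
        else:
            plum[n] = d.get("fixed_pressure") or p_default
    state.masks.L_EC = ec
    state.ec_dv = dv
    state.ec_plum = plum
    state.receptors.instantiate_on(ec, state.params.gf.r_total)


# ---------------------------------------------------------------------------
# Transport stage

def _vitality_field(state: SimulationState) -> np.ndarray:
    """Vitality of live tumor cells mapped onto the lattice (0 elsewhere)."""
    pop = state.population
    lat = state.config.lattice
    out = np.zeros(lat.shape)
    live = pop.live_mask()
    if not live.any():
        return out
    s = pop.sites[live]
    o2 = state.fields["c_o2"].values[s[:, 0], s[:, 1], s[:, 2]]
    gl = state.fields["c_g"].values[s[:, 0], s[:, 1], s[:, 2]]
    co2 = state.fields["c_co2"].values[s[:, 0], s[:, 1], s[:, 2]]
    vit = vitality(o2, gl, co2, state.params.phenotype, state.params.cr)
    out[s[:, 0], s[:, 1], s[:, 2]] = vit
    return out


def _transport_substep(state: SimulationState, dt: float) -> None:
    p = state.params
    cr, gf = p.cr, p.gf
    f = state.fields
    masks = state.masks
    ec = masks.L_EC
    live_tc = np.zeros(state.config.lattice.shape, dtype=bool)
    live = state.population.live_mask()
    if live.any():
        s = state.population.sites[live]
        live_tc[s[:, 0], s[:, 1], s[:, 2]] = True
    masks.L_TC = state.population.occupancy

    vit = _vitality_field(state)
    c_g6, c_o2_rate, r_co2 = biochem.cr_rates(vit, cr)

    p_lum = np.where(ec, state.ec_plum, 0.0)
    p_trans = p_lum - state.p_ins.values
    # the perfusion laws are normalized by the characteristic luminal
    # pressure, so transvascular pressure drives supply directly
    p_ref = p.fluid.p_lum_ref
    e_o2 = biochem.perfusion_exchange("o2", state.ec_dv, p_trans, p_ref, 0.0, cr)
    e_g = biochem.perfusion_exchange("g", state.ec_dv, p_trans, p_ref,
                                     f["c_g"].values, cr)
    e_co2 = biochem.perfusion_exchange("co2", state.ec_dv, p_trans, p_ref, 0.0, cr)
    e_v = biochem.perfusion_exchange("vegf", state.ec_dv, 0.0, 1.0, 0.0, cr, gf)

    # receptor kinetics can be stiffer than transport at high ligand levels;
    # subdivide their Euler step to stay inside the stability bound
    rate_v = gf.k_v_on * float(np.max(f["c_v"].values, initial=0.0)) + gf.k_v_off
    n_rec = max(int(np.ceil(dt * rate_v / 0.5)), 1)
    flux_v = np.zeros(state.config.lattice.shape)
    for _ in range(n_rec):
        flux_v += biochem.receptor_step_vegfr2(state.receptors, f["c_v"].values, dt / n_rec, gf)
    flux_v /= n_rec
    rate_t = (
        gf.k_a1_on * float(np.max(f["c_a1"].values, initial=0.0))
        + gf.k_a2_on * float(np.max(f["c_a2"].values, initial=0.0))
        + gf.k_a1_off + gf.k_a2_off
    )
    n_rec = max(int(np.ceil(dt * rate_t / 0.5)), 1)
    flux_a1 = np.zeros(state.config.lattice.shape)
    flux_a2 = np.zeros(state.config.lattice.shape)
    for _ in range(n_rec):
        f1, f2 = biochem.receptor_step_tie2(
            state.receptors, f["c_a1"].values, f["c_a2"].values, dt / n_rec, gf
        )
        flux_a1 += f1
        flux_a2 += f2
    flux_a1 /= n_rec
    flux_a2 /= n_rec

    src = {
        "c_o2": -c_o2_rate + e_o2 * ec,
        "c_g": -c_g6 + e_g * ec,
        "c_co2": r_co2 - e_co2 * ec,
        "c_v": biochem.vegf_production(f["c_o2"].values, live_tc, cr, gf)
        - e_v * ec + flux_v - gf.eps_v * f["c_v"].values,
        "c_a1": biochem.angiopoietin_production(f["c_a1"].values, "ang1", masks, gf)
        + flux_a1 - gf.eps_a1 * f["c_a1"].values,
        "c_a2": biochem.angiopoietin_production(f["c_a2"].values, "ang2", masks, gf)
        + flux_a2 - gf.eps_a2 * f["c_a2"].values,
        "c_m": biochem.mmp_sources(vit, masks, f["c_m"].values, gf),
    }
    D = {
        "c_o2": cr.D_o2, "c_g": cr.D_g, "c_co2": cr.D_co2, "c_v": gf.D_v,
        "c_a1": gf.D_a1, "c_a2": gf.D_a2, "c_m": gf.D_m,
    }
    from .grid import advance_species

    u = state.u_ins
    # convection is dropped while the interstitial speed is physically
    # negligible (< U_EPS um/s moves fluid < 1/100 of a node spacing per
    # simulated hour); it re-engages as soon as vascular leak builds IFP
    if (
        np.max(np.abs(u.ux), initial=0.0) < U_EPS
        and np.max(np.abs(u.uy), initial=0.0) < U_EPS
        and np.max(np.abs(u.uz), initial=0.0) < U_EPS
    ):
        u = None
    for name in SPECIES:
        f[name] = advance_species(
            f[name], D[name], u, src[name], dt, state.bcs[name],
            state.clamp_audit,
        )
    f["c_e"].values = biochem.ecm_step(f["c_e"].values, f["c_m"].values, dt, gf)


# ---------------------------------------------------------------------------
# Cellular stage

def _cell_stage(state: SimulationState, dt: float) -> None:
    pop = state.population
    p = state.params
    if len(pop) == 0:
        return
    s = pop.sites
    o2 = state.fields["c_o2"].values[s[:, 0], s[:, 1], s[:, 2]]
    gl = state.fields["c_g"].values[s[:, 0], s[:, 1], s[:, 2]]
    co2 = state.fields["c_co2"].values[s[:, 0], s[:, 1], s[:, 2]]
    vit = vitality(o2, gl, co2, p.phenotype, p.cr)

    if "first_hypoxia" not in state.report.events and np.any(o2 < p.cr.c_o2_ch):
        state.report.mark_event("first_hypoxia", state.t_days)
    pop.phenotype = phenotype_transition(pop.phenotype, vit, pop.psi, p.phenotype)
    live = pop.live_mask()
    pop.psi[live] = energy_step(pop.psi[live], vit[live], dt, p.phenotype)
    pop.age[live] += dt

    # division: active cells with enough ATP, randomized order
    eligible = np.flatnonzero((pop.phenotype == ACTIVE) & (pop.psi >= p.phenotype.psi_ch))
    if len(eligible):
        order = state.rngs["ordering"].permutation(len(eligible))
        lat = state.config.lattice
        from .grid import NEIGHBOR_OFFSETS

        shape = np.array(lat.shape)
        for i in eligible[order]:
            targets = pop.sites[i] + NEIGHBOR_OFFSETS[1:]
            ok = np.all((targets >= 0) & (targets < shape), axis=1)
            free = targets[ok]
            free = free[~pop.occupancy[free[:, 0], free[:, 1], free[:, 2]]]
            if len(free) == 0:
                continue
            choice = free[state.rngs["proliferation"].integers(len(free))]
            pop.psi[i] = p.phenotype.psi_ch / 2.0
            pop.add(tuple(int(x) for x in choice), ACTIVE, p.phenotype.psi_ch / 2.0)

    # migration: active cells, probabilities vs start-of-sweep occupancy
    active_idx = np.flatnonzero(pop.phenotype == ACTIVE)
    if len(active_idx):
        p_bias = state.p_ins.values + state.p_s.values
        probs = move_probabilities_batch(
            pop.sites[active_idx],
            state.config.lattice,
            p.motility.D_TC,
            [(p.motility.beta_h, state.fields["c_e"].values)],
            p_bias,
            p.motility.lambda_p,
            pop.occupancy,
            dt,
        )
        moves = sample_moves_batch(probs, state.rngs["migration"])
        order = state.rngs["ordering"].permutation(len(active_idx))
        for k in order:
            i = active_idx[k]
            mv = moves[k]
            if not mv.any():
                continue
            target = tuple(int(x) for x in (pop.sites[i] + mv))
            if pop.occupancy[target]:
                continue  # conflict within the sweep: stay
            pop.occupancy[tuple(pop.sites[i])] = False
            pop.occupancy[target] = True
            pop.sites[i] = target


# ---------------------------------------------------------------------------
# Angiogenesis stage

def _angiogenesis_stage(state: SimulationState, dt: float) -> None:
    p = state.params
    net = state.network
    c_v = state.fields["c_v"]
    c_e = state.fields["c_e"]
    p_bias = ScalarField(state.config.lattice,
                         state.p_ins.values + state.p_s.values, "p_bias")

    anchors = [t.site for t in net.tips if t.alive] + state.sprout_origins
    new_sites = select_sprout_sites(net.ring_sites(), c_v, p.sprouting,
                                    state.rngs["sprouting"], anchors)
    for s in new_sites:
        tip = TipCell(site=s)
        net.tips.append(tip)
        net.graph.nodes[s]["is_tip"] = True
        state.sprout_origins.append(s)
        state.report.mark_event("first_sprout", state.t_days)

    # one batched probability evaluation for all live tips (fields frozen at
    # the start of the stage); graph updates then apply sequentially
    live_tips = [t for t in net.tips if t.alive]
    if live_tips:
        from .grid import NEIGHBOR_OFFSETS
        from .tumor_cells import move_probabilities_batch, sample_moves_batch

        sites = np.asarray([t.site for t in live_tips], int)
        cv_here = c_v.values[sites[:, 0], sites[:, 1], sites[:, 2]]
        chemo = p.motility.beta_c / (1.0 + p.motility.alpha * cv_here)
        forbidden = np.zeros((len(live_tips), 26), dtype=bool)
        offset_index = {tuple(e): k for k, e in enumerate(NEIGHBOR_OFFSETS[1:])}
        for i, t in enumerate(live_tips):
            if t.prev_site is not None:
                delta = tuple(np.asarray(t.prev_site) - np.asarray(t.site))
                k = offset_index.get(delta)
                if k is not None:
                    forbidden[i, k] = True
        probs = move_probabilities_batch(
            sites, state.config.lattice, p.motility.D_EC,
            [(chemo, c_v.values), (p.motility.beta_h, c_e.values)],
            p_bias.values, p.motility.lambda_p,
            np.zeros(state.config.lattice.shape, dtype=bool), dt,
            extra_forbidden=forbidden,
        )
        moves = sample_moves_batch(probs, state.rngs["tips"])
        for tip, mv in zip(live_tips, moves):
            if not tip.alive:
                continue  # retired by an earlier anastomosis this step
            n_edges_before = net.graph.number_of_edges()
            extend_sprout(tip, tuple(int(x) for x in mv), net, p.lumen)
            if not tip.alive and net.graph.number_of_edges() > n_edges_before:
                state.report.mark_event("first_anastomosis", state.t_days)
            tip.age += dt

    maybe_branch(net, c_v, p.sprouting, state.rngs["branching"], dt)


# ---------------------------------------------------------------------------
# Remodeling stage

def _segment_midvalue(field_values: np.ndarray, a, b) -> float:
    return 0.5 * (float(field_values[a]) + float(field_values[b]))


def _remodel_stage(state: SimulationState, dt: float) -> None:
    p = state.params
    net = state.network
    g = net.graph
    c_v = state.fields["c_v"]

    state.p_s = solid_stress_field(state.population, p.stress)

    # lumenogenesis: stalk growth drives the diameter until first flow
    for a, b, d in net.neo_segments():
        cv = _segment_midvalue(c_v.values, a, b)
        ca1 = _segment_midvalue(state.fields["c_a1"].values, a, b)
        ca2 = _segment_midvalue(state.fields["c_a2"].values, a, b)
        d["G_s"] = stalk_growth_step(d["G_s"], cv, ca1, ca2, dt, p.lumen)
        if not d["flow_governed"]:
            d["d_v"] = float(lumen_diameter(d["G_s"], p.lumen))
        d["age"] += dt

    # elastic deformation from last-known transvascular pressure + stress
    for a, b, d in net.neo_segments():
        p_trans = d.get("p_trans", p.fluid.p_inlet)
        ps_mid = _segment_midvalue(state.p_s.values, a, b)
        d["d_v_def"], d["collapsed"] = deform_diameter(
            d["d_v"], p_trans, ps_mid, p.compliance
        )

    inside_tumor = ndimage.binary_dilation(
        state.population.occupancy, structure=np.ones((3, 3, 3), dtype=bool)
    )

    flow, p_ins, u_ins, _ = hemodynamics.couple_flow_interstitium(
        net, p.fluid, state.p_ins, inside_tumor, tol=1e-3, max_iter=40
    )
    state.flow = flow
    state.p_ins = p_ins
    state.u_ins = u_ins
    hemodynamics.distribute_hematocrit(net, p.fluid)

    if p.fluid.q_ref_mode == "inlet_sum":
        state.Q_ref = flow.total_inflow
    else:
        neo_flows = [abs(d["Q_lum"]) for *_, d in net.neo_segments()]
        state.Q_ref = max(neo_flows) if neo_flows else 0.0

    for a, b, d in net.neo_segments():
        if not d["flow_governed"]:
            continue
        if not state.report.events.get("first_perfused_neovessel"):
            state.report.mark_event("first_perfused_neovessel", state.t_days)
        cv = _segment_midvalue(c_v.values, a, b)
        stim = adaptation_stimuli(
            d["tau"], d.get("p_trans", p.fluid.p_inlet), abs(d["Q_lum"]),
            d["H_D"], cv, d["d_v"], p.adaptation, state.Q_ref,
        )
        d["d_v"] = adapt_diameter(d["d_v"], stim, dt, p.adaptation)

    disrupt_vessels(net, c_v, inside_tumor, dt, p.disruption)
    _refresh_vessel_caches(state)


# ---------------------------------------------------------------------------
# Macro step and run loop

def macro_step(state: SimulationState) -> SimulationState:
    """Advance the state by one cellular step ``dt_cell`` (in place).

    Stages: transport sub-cycle; cell phenotype/energy/division/migration;
    sprouting, tip migration and branching; then, on remodeling boundaries,
    lumenogenesis, flow + interstitium, hematocrit, adaptation, deformation
    and disruption, followed by a mask/cache refresh.
    """
    cfg = state.config
    stage = "transport"
    try:
        n_sub = int(round(cfg.dt_cell / cfg.dt_transport))
        for _ in range(n_sub):
            _transport_substep(state, cfg.dt_transport)
        stage = "cells"
        _cell_stage(state, cfg.dt_cell)
        stage = "angiogenesis"
        _angiogenesis_stage(state, cfg.dt_cell)

        state.step_count += 1
        state.t += cfg.dt_cell
        per_remodel = int(round(cfg.dt_remodel / cfg.dt_cell))
        if state.step_count % per_remodel == 0:
            stage = "remodeling"
            _remodel_stage(state, cfg.dt_remodel)
    except Exception as exc:
        dump = None
        if cfg.output_dir:
            dump = Path(cfg.output_dir) / f"crash_step{state.step_count}.pkl"
            dump.parent.mkdir(parents=True, exist_ok=True)
            save_checkpoint(state, dump)
        raise RuntimeError(
            f"macro_step failed in stage {stage!r} at t={state.t_days:.3f} days"
            + (f"; restartable state dumped to {dump}" if dump else "")
        ) from exc

    if (state.population.phenotype == NECROTIC).any():
        state.report.mark_event("first_necrotic", state.t_days)
    return state


def _centroid_drift(state: SimulationState) -> float:
    c = state.population.centroid()
    if c is None or state.initial_centroid is None:
        return 0.0
    return float(np.linalg.norm(c - state.initial_centroid))


def snapshot(state: SimulationState) -> dict:
    return state.report.snapshot(
        state.t_days,
        state.population,
        state.network,
        state.config.lattice,
        peak_ifp=float(np.max(state.p_ins.values)),
        centroid_drift_um=_centroid_drift(state),
    )


def run(config: SimulationConfig, progress: bool = False) -> SimulationState:
    """Run a configuration to its time horizon, collecting snapshots."""
    state = initialize(config)
    snapshot(state)
    n_steps = int(round(config.t_end_days * 86400.0 / config.dt_cell))
    snap_every = max(int(round(config.snapshot_every / config.dt_cell)), 1)
    for i in range(1, n_steps + 1):
        macro_step(state)
        if i % snap_every == 0 or i == n_steps:
            row = snapshot(state)
            if progress:
                print(
                    f"day {row['t_days']:6.2f}  total={row['total']:5d} "
                    f"A/Q/N={row['active']}/{row['quiescent']}/{row['necrotic']} "
                    f"neo={row['n_neo_segments']}"
                )
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        from . import io as tio

        tio.write_run_outputs(state, outdir)
    return state


# ---------------------------------------------------------------------------
# Checkpointing and determinism helpers

def save_checkpoint(state: SimulationState, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_checkpoint(path) -> SimulationState:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def state_hash(state: SimulationState) -> str:
    """Deterministic digest of fields, cells and network for replay checks."""
    h = hashlib.sha256()
    for name in sorted(state.fields):
        h.update(np.ascontiguousarray(state.fields[name].values).tobytes())
    h.update(np.ascontiguousarray(state.population.sites).tobytes())
    h.update(np.ascontiguousarray(state.population.phenotype).tobytes())
    h.update(np.ascontiguousarray(state.population.psi).tobytes())
    for a, b, d in sorted(state.network.graph.edges(data=True)):
        h.update(repr((a, b, round(d["d_v"], 12), round(d["H_D"], 12))).encode())
    h.update(np.ascontiguousarray(state.p_ins.values).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Fixtures

def make_fixture(name: str, seed: int = 0, scenario=None, **overrides) -> SimulationConfig:
    """Preset configurations.

    ``toy21``: 21^3 nodes, 1 mm cube, 2 simulated days — minute-scale runs.
    ``small41``: 41^3 nodes, 2 mm cube, 4 simulated days — property suites.
    ``paperlike201``: 201^3 nodes, 10 mm cube, 35 days — full-scale setup.
    """
    from .config import SCENARIO_PRESETS, ScenarioSpec

    if isinstance(scenario, str):
        scenario = SCENARIO_PRESETS[scenario]
    scenario = scenario or ScenarioSpec()
    presets = {
        "toy21": dict(lattice=LatticeSpec(21, 21, 21, 50.0), t_end_days=2.0,
                      snapshot_every=3600.0 * 3),
        "small41": dict(lattice=LatticeSpec(41, 41, 41, 50.0), t_end_days=4.0,
                        snapshot_every=3600.0 * 6),
        "paperlike201": dict(lattice=LatticeSpec(201, 201, 201, 50.0), t_end_days=35.0,
                             snapshot_every=86400.0),
    }
    if name not in presets:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(presets)}")
    kwargs = presets[name]
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, scenario=scenario, name=name, **kwargs)
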