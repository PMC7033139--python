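"""Reaction terms and receptor kinetics for the nine biochemical agents.

Species: the cellular-respiration (CR) agents oxygen, glucose and carbon
dioxide; VEGF with its endothelial receptor VEGFR-2; angiopoietin-1 and -2
competing for Tie-2; MMP; and ECM (fibronectin).  Transport of the soluble
species is handled by :mod:`tmesim.grid`; this module provides the local
source/sink rates that are composed with it, working throughout in
normalized concentration units (characteristic concentrations = 1).

Receptors exist only on vessel-wall (endothelial) lattice nodes and are
instantiated when a node first becomes part of a vessel wall.  Their
per-node totals (free + active) are conserved exactly by construction: each
binding flux is added to one pool and subtracted from the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ConfigurationError, LatticeSpec


@dataclass
class CRParams:
    """Cellular-respiration transport/reaction constants.

    Diffusivities in um^2/s, rates in 1/s, concentrations normalized by the
    characteristic value of each species.
    """

    D_o2: float = 6.0
    D_g: float = 4.0
    D_co2: float = 6.0
    gamma0: float = 2.2e-3      # max CR consumption/production rate, 1/s
    f_o2: float = 2.0e-3        # O2 perfusion rate constant, 1/s
    f_g: float = 2.0e-3         # max glucose perfusion rate, 1/s
    km_g: float = 1.0           # Michaelis constant of glucose efflux
    f_co2: float = 2.0e-3       # CO2 clearance rate constant, 1/s
    d_c: float = 40.0           # characteristic neo-vessel diameter, um
    c_o2_ch: float = 1.0        # characteristic concentrations (normalized)
    c_g_ch: float = 1.0
    c_co2_ch: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gamma0, self.km_g, self.d_c) <= 0:
            raise ConfigurationError("CR parameters must be positive")


@dataclass
class GrowthFactorParams:
    """VEGF / angiopoietin / MMP / ECM constants (normalized units)."""

    D_v: float = 3.0
    D_a1: float = 2.0
    D_a2: float = 2.0
    D_m: float = 2.0
    R_v: float = 5.0e-3         # VEGF secretion by hypoxic tumor cells, 1/s
    f_v: float = 3.0e-4         # VEGF washout into perfused vessels, 1/s
    eps_v: float = 2.0e-5       # VEGF natural decay, 1/s
    R_a1: float = 1.0e-4        # Ang-1 secretion by endothelium
    R_a2: float = 1.0e-4        # Ang-2 secretion by tumor-associated endothelium
    eps_a1: float = 1.0e-5
    eps_a2: float = 1.0e-5
    R_mT: float = 5.0e-5        # MMP secretion by tumor cells (vitality-scaled)
    R_mE: float = 5.0e-5        # MMP secretion by endothelium
    eps_m: float = 1.0e-4
    eps_e: float = 1.0e-4       # ECM proteolysis rate per unit MMP, 1/s
    k_v_on: float = 1.0e-3      # VEGF-VEGFR-2 binding, 1/(conc s)
    k_v_off: float = 1.0e-4
    k_a1_on: float = 1.0e-3
    k_a1_off: float = 1.0e-4
    k_a2_on: float = 1.0e-3
    k_a2_off: float = 1.0e-4
    e_0: float = 1.0            # characteristic EC concentration
    K_a: float = 1.0            # angiopoietin carrying-capacity coefficient
    c_v_ch: float = 0.05        # characteristic VEGF concentration (adaptation)
    r_total: float = 1.0        # receptor surface density per EC node
    c_e_ch: float = 1.0         # initial/boundary ECM level


@dataclass
class OccupancyMasks:
    """Binary indicator fields: tumor-cell and vessel-wall occupancy."""

    L_TC: np.ndarray
    L_EC: np.ndarray

    @classmethod
    def empty(cls, lattice: LatticeSpec) -> "OccupancyMasks":
        return cls(np.zeros(lattice.shape, bool), np.zeros(lattice.shape, bool))


@dataclass
class ReceptorState:
    """Per-node receptor pools (zero away from vessel walls).

    ``r_v_f``/``r_v_a``: free and VEGF-bound VEGFR-2; ``r_a_f``, ``r_a1_a``,
    ``r_a2_a``: free Tie-2 and Tie-2 bound to Ang-1 / Ang-2.
    """

    r_v_f: np.ndarray
    r_v_a: np.ndarray
    r_a_f: np.ndarray
    r_a1_a: np.ndarray
    r_a2_a: np.ndarray

    @classmethod
    def zeros(cls, lattice: LatticeSpec) -> "ReceptorState":
        z = lambda: np.zeros(lattice.shape)
        return cls(z(), z(), z(), z(), z())

    def instantiate_on(self, new_ec: np.ndarray, r_total: float) -> None:
        """Express fresh (all-free) receptors on nodes that just became EC."""
        fresh = new_ec & (self.r_v_f + self.r_v_a == 0.0)
        self.r_v_f[fresh] = r_total
        fresh_t = new_ec & (self.r_a_f + self.r_a1_a + self.r_a2_a == 0.0)
        self.r_a_f[fresh_t] = r_total

    def vegfr2_total(self) -> np.ndarray:
        return self.r_v_f + self.r_v_a

    def tie2_total(self) -> np.ndarray:
        return self.r_a_f + self.r_a1_a + self.r_a2_a


# ---------------------------------------------------------------------------
# CR agents

def perfusion_exchange(
    species: str,
    d_v: np.ndarray | float,
    p_trans: np.ndarray | float,
    p_lum: np.ndarray | float,
    c_local: np.ndarray | float,
    params: CRParams,
    gf: GrowthFactorParams | None = None,
) -> np.ndarray | float:
    """Transvascular exchange rate at a vessel-wall node.

    Oxygen/CO2: ``f * (d_v/d_c) * (p_trans/p_lum)``; glucose carries an
    additional Michaelis-Menten factor in the local concentration.  The VEGF
    washout term is pressure-independent, proportional to ``d_v/d_c`` only
    (the caller applies the sink sign for CO2 and VEGF).
    """
    ratio_d = np.asarray(d_v, float) / params.d_c
    if species == "vegf":
        if gf is None:
            raise ConfigurationError("vegf perfusion needs GrowthFactorParams")
        return gf.f_v * ratio_d
    ratio_p = np.asarray(p_trans, float) / np.asarray(p_lum, float)
    if species == "o2":
        return params.f_o2 * ratio_d * ratio_p
    if species == "g":
        mm = np.asarray(c_local, float) / (np.asarray(c_local, float) + params.km_g)
        return params.f_g * mm * ratio_d * ratio_p
    if species == "co2":
        return params.f_co2 * ratio_d * ratio_p
    raise ConfigurationError(f"unknown species {species!r}")


def cr_rates(vitality: np.ndarray | float, params: CRParams):
    """Stoichiometric CR rates: O2 consumption = CO2 production = 6 x glucose.

    Returns ``(C_g, C_o2, R_co2)`` for C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O + ATP.
    """
    c_o2 = params.gamma0 * np.asarray(vitality, float)
    return c_o2 / 6.0, c_o2, c_o2


def vegf_production(
    c_o2: np.ndarray | float, at_tc: np.ndarray | float, params: CRParams, gf: GrowthFactorParams
) -> np.ndarray | float:
    """Hypoxia-gated VEGF secretion by tumor cells.

    Secretion switches on strictly below the characteristic oxygen level
    (Heaviside with H(0) = 0) and ramps linearly to the full rate at zero
    oxygen.
    """
    c = np.asarray(c_o2, float)
    gate = (c < params.c_o2_ch).astype(float)
    return gf.R_v * gate * (1.0 - c / params.c_o2_ch) * np.asarray(at_tc, float)


# ---------------------------------------------------------------------------
# Receptor kinetics

def receptor_step_vegfr2(state: ReceptorState, c_v: np.ndarray, dt: float, gf: GrowthFactorParams):
    """Forward-Euler VEGFR-2 binding step; returns the net VEGF binding flux.

    The returned field (1/s units, per node) is the sink that the VEGF
    transport equation must apply: ``-k_on r_f c_v + k_off r_a``.
    """
    rate_scale = gf.k_v_on * float(np.max(c_v, initial=0.0)) + gf.k_v_off
    if dt * rate_scale >= 1.0:
        raise ConfigurationError(
            f"receptor step unstable: dt*(k_on*c_v + k_off) = {dt * rate_scale:.3g} >= 1"
        )
    bind = gf.k_v_on * state.r_v_f * c_v
    unbind = gf.k_v_off * state.r_v_a
    state.r_v_f += dt * (unbind - bind)
    state.r_v_a += dt * (bind - unbind)
    return unbind - bind


def receptor_step_tie2(
    state: ReceptorState, c_a1: np.ndarray, c_a2: np.ndarray, dt: float, gf: GrowthFactorParams
):
    """Tie-2 step with Ang-1/Ang-2 competition; returns both ligand fluxes."""
    rate_scale = (
        gf.k_a1_on * float(np.max(c_a1, initial=0.0))
        + gf.k_a2_on * float(np.max(c_a2, initial=0.0))
        + gf.k_a1_off + gf.k_a2_off
    )
    if dt * rate_scale >= 1.0:
        raise ConfigurationError(
            f"Tie-2 step unstable: dt*rates = {dt * rate_scale:.3g} >= 1"
        )
    bind1 = gf.k_a1_on * state.r_a_f * c_a1
    unbind1 = gf.k_a1_off * state.r_a1_a
    bind2 = gf.k_a2_on * state.r_a_f * c_a2
    unbind2 = gf.k_a2_off * state.r_a2_a
    state.r_a_f += dt * (unbind1 - bind1 + unbind2 - bind2)
    state.r_a1_a += dt * (bind1 - unbind1)
    state.r_a2_a += dt * (bind2 - unbind2)
    return unbind1 - bind1, unbind2 - bind2


# ---------------------------------------------------------------------------
# Angiopoietins, MMP, ECM

def angiopoietin_production(
    c_a: np.ndarray | float, which: str, masks: OccupancyMasks, gf: GrowthFactorParams
) -> np.ndarray | float:
    """Logistic-like angiopoietin secretion by endothelium.

    ``(e_0 K_a - c_a^2)/K_a`` times the rate constant; Ang-1 at every
    vessel-wall node, Ang-2 only at vessel-wall nodes inside tumor tissue.
    May go negative above the carrying level (the transport shell clamps the
    field itself at zero).
    """
    c = np.asarray(c_a, float)
    logistic = (gf.e_0 * gf.K_a - c**2) / gf.K_a
    if which == "ang1":
        return gf.R_a1 * logistic * masks.L_EC
    if which == "ang2":
        return gf.R_a2 * logistic * (masks.L_EC & masks.L_TC)
    raise ConfigurationError(f"unknown angiopoietin {which!r}")


def mmp_sources(
    vitality: np.ndarray | float, masks: OccupancyMasks, c_m: np.ndarray | float,
    gf: GrowthFactorParams,
) -> np.ndarray | float:
    """MMP secretion by tumor cells (vitality-scaled) and endothelium, minus decay."""
    return (
        gf.R_mT * np.asarray(vitality, float) * masks.L_TC
        + gf.R_mE * masks.L_EC
        - gf.eps_m * np.asarray(c_m, float)
    )


def ecm_step(c_e: np.ndarray, c_m: np.ndarray, dt: float, gf: GrowthFactorParams) -> np.ndarray:
    """Pointwise proteolytic ECM decay (no transport): dc_e/dt = -eps_e c_m c_e."""
    if dt * gf.eps_e * float(np.max(c_m, initial=0.0)) >= 1.0:
        raise ConfigurationError("ECM step unstable: dt*eps_e*max(c_m) >= 1")
    return c_e * (1.0 - dt * gf.eps_e * c_m)
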