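"""Tumor-cell agents: vitality, ATP energy, phenotypes, division, migration.

Each tumor cell (TC) occupies exactly one lattice site.  A scalar *vitality*
combining oxygen/glucose saturation with carbon-dioxide toxicity gates an
ATP energy budget; energy drives the phenotype machine
(active <-> quiescent -> necrotic, necrosis absorbing) and division.
Active cells move on the lattice with hybrid continuous-discrete
probabilities read off the finite-difference discretization of the
random-walk + haptotaxis density equation, biased away from high fluid
pressure / solid stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biochem import CRParams
from .grid import (
    NEIGHBOR_OFFSETS,
    LatticeSpec,
    ScalarField,
)

ACTIVE, QUIESCENT, NECROTIC = 0, 1, 2
PHENOTYPE_NAMES = {ACTIVE: "active", QUIESCENT: "quiescent", NECROTIC: "necrotic"}


@dataclass
class PhenotypeParams:
    """Vitality/energy constants.

    ``phi``: vitality ceiling; ``vitality_ch``: active/quiescent threshold;
    ``psi_ch``: division energy (ATP units); production/consumption rates in
    ATP units per second.
    """

    phi: float = 1.0
    vitality_ch: float = 0.20
    psi_ch: float = 1.0
    k_a_p: float = 1.33e-3  # active ATP production per unit vitality
    k_a_c: float = 1.53e-3  # active ATP consumption (Michaelis-Menten max)
    k_q_c: float = 6.0e-6   # quiescent maintenance consumption


@dataclass
class SolidStressParams:
    """Gaussian growth-induced solid-stress bump centred on the tumor."""

    p_s0: float = 0.005     # peak stress per N_ref live cells, mmHg
    sigma_s: float = 200.0  # Gaussian width, um
    n_ref: float = 5.0      # reference (initial) cell count


@dataclass
class MotilityParams:
    """Random-walk / taxis weights for TC and tip-EC migration."""

    D_TC: float = 3.0e-4    # TC random-walk diffusivity, um^2/s
    D_EC: float = 0.01      # tip-EC random-walk diffusivity, um^2/s
    beta_c: float = 300.0   # chemotaxis weight (tip ECs), um^2/(s conc)
    beta_h: float = 0.3     # haptotaxis weight, um^2/(s conc)
    alpha: float = 5.0      # chemotaxis saturation, 1/conc
    lambda_p: float = 0.693 # pressure/stress bias: 1 mmHg uphill halves a weight


@dataclass
class TumorCell:
    """View of one tumor cell (site, phenotype, ATP energy, age)."""

    site: tuple[int, int, int]
    phenotype: int
    psi: float
    age: float = 0.0


class CellPopulation:
    """Array-backed collection of tumor cells with site exclusivity."""

    def __init__(self, lattice: LatticeSpec):
        self.lattice = lattice
        self.sites = np.zeros((0, 3), dtype=int)
        self.phenotype = np.zeros(0, dtype=np.int8)
        self.psi = np.zeros(0)
        self.age = np.zeros(0)
        self.occupancy = np.zeros(lattice.shape, dtype=bool)

    def __len__(self) -> int:
        return len(self.sites)

    def add(self, site: tuple[int, int, int], phenotype: int, psi: float, age: float = 0.0):
        if self.occupancy[site]:
            raise ValueError(f"site {site} already occupied")
        self.sites = np.vstack([self.sites, np.asarray(site, int)])
        self.phenotype = np.append(self.phenotype, np.int8(phenotype))
        self.psi = np.append(self.psi, psi)
        self.age = np.append(self.age, age)
        self.occupancy[site] = True

    def cells(self):
        for i in range(len(self)):
            yield TumorCell(tuple(self.sites[i]), int(self.phenotype[i]),
                            float(self.psi[i]), float(self.age[i]))

    def counts(self) -> dict[str, int]:
        return {
            "active": int(np.sum(self.phenotype == ACTIVE)),
            "quiescent": int(np.sum(self.phenotype == QUIESCENT)),
            "necrotic": int(np.sum(self.phenotype == NECROTIC)),
            "total": len(self),
        }

    def live_mask(self) -> np.ndarray:
        return self.phenotype != NECROTIC

    def centroid(self) -> np.ndarray | None:
        """Physical centroid (um) of live cells; None if no live cells."""
        live = self.live_mask()
        if not live.any():
            return None
        return (np.asarray(self.lattice.origin)
                + self.lattice.h * self.sites[live].mean(axis=0))


# ---------------------------------------------------------------------------
# Vitality and energy

def vitality(
    c_o2: np.ndarray | float,
    c_g: np.ndarray | float,
    c_co2: np.ndarray | float,
    params: PhenotypeParams,
    cr: CRParams,
) -> np.ndarray | float:
    """CR-based cellular vitality in [0, phi].

    Michaelis-Menten saturation in oxygen and glucose, multiplied by a
    quartic-exponential CO2 toxicity gate that engages strictly above the
    characteristic CO2 level (Heaviside, H(0) = 0).
    """
    o2 = np.asarray(c_o2, float)
    g = np.asarray(c_g, float)
    co2 = np.asarray(c_co2, float)
    sat = (o2 / (o2 + cr.c_o2_ch)) * (g / (g + cr.c_g_ch))
    excess = co2 / cr.c_co2_ch - 1.0
    gate = (co2 > cr.c_co2_ch).astype(float)
    return params.phi * sat * np.exp(-5.0 * excess**4 * gate)


def energy_step(
    psi: np.ndarray | float, vit: np.ndarray | float, dt: float, params: PhenotypeParams
) -> np.ndarray | float:
    """One Euler step of the ATP budget.

    Active branch (vitality above threshold): linear production minus
    Michaelis-Menten consumption (constant 1); quiescent branch: constant
    maintenance drain.  Ties (vitality exactly at threshold) fall to the
    quiescent branch (H(0) = 0).
    """
    v = np.asarray(vit, float)
    active = (v > params.vitality_ch).astype(float)
    slope = active * (params.k_a_p * v - params.k_a_c * v / (v + 1.0)) \
        - (1.0 - active) * params.k_q_c
    return np.asarray(psi, float) + dt * slope


def phenotype_transition(
    phenotype: np.ndarray | int, vit: np.ndarray | float, psi: np.ndarray | float,
    params: PhenotypeParams,
) -> np.ndarray | int:
    """Phenotype machine: necrosis absorbing, energy exhaustion first.

    A quiescent cell whose energy has gone negative becomes necrotic; this
    takes precedence over reactivation.  Otherwise vitality above the
    threshold makes a cell active, at-or-below makes it quiescent.
    """
    ph = np.asarray(phenotype, dtype=np.int8)
    v = np.asarray(vit, float)
    p = np.asarray(psi, float)
    out = np.where(v > params.vitality_ch, ACTIVE, QUIESCENT).astype(np.int8)
    out = np.where((ph == QUIESCENT) & (p < 0.0), NECROTIC, out)
    out = np.where(ph == NECROTIC, NECROTIC, out)
    if np.isscalar(phenotype) or np.ndim(phenotype) == 0:
        return int(out)
    return out


# ---------------------------------------------------------------------------
# Division

def try_proliferate(
    cell: TumorCell,
    occupancy: np.ndarray,
    rng: np.random.Generator,
    params: PhenotypeParams,
    lattice: LatticeSpec,
) -> TumorCell | None:
    """Attempt division of an active cell with enough ATP.

    Requires psi >= psi_ch and at least one free 26-neighbor site; the
    daughter is placed on a uniformly chosen free neighbor and both cells
    restart at psi_ch / 2.  Division is deferred (energy retained) under
    contact inhibition.
    """
    if cell.phenotype != ACTIVE or cell.psi < params.psi_ch:
        return None
    targets = np.asarray(cell.site) + NEIGHBOR_OFFSETS[1:]
    ok = np.all((targets >= 0) & (targets < np.array(lattice.shape)), axis=1)
    free = [t for t, o in zip(targets, ok) if o and not occupancy[tuple(t)]]
    if not free:
        return None
    choice = free[rng.integers(len(free))]
    cell.psi = params.psi_ch / 2.0
    return TumorCell(tuple(int(x) for x in choice), ACTIVE, params.psi_ch / 2.0)


# ---------------------------------------------------------------------------
# Solid stress

def solid_stress_field(
    population: CellPopulation, params: SolidStressParams
) -> ScalarField:
    """Gaussian solid-stress bump at the live-cell centroid, amplitude
    proportional to the live-cell count."""
    lat = population.lattice
    center = population.centroid()
    if center is None:
        return ScalarField.uniform(lat, 0.0, "p_s")
    n_live = int(population.live_mask().sum())
    x = np.asarray(lat.origin)[0] + lat.h * np.arange(lat.n_x)
    y = np.asarray(lat.origin)[1] + lat.h * np.arange(lat.n_y)
    z = np.asarray(lat.origin)[2] + lat.h * np.arange(lat.n_z)
    r2 = (
        (x[:, None, None] - center[0]) ** 2
        + (y[None, :, None] - center[1]) ** 2
        + (z[None, None, :] - center[2]) ** 2
    )
    amp = params.p_s0 * n_live / params.n_ref
    return ScalarField(lat, amp * np.exp(-r2 / (2.0 * params.sigma_s**2)), "p_s")


# ---------------------------------------------------------------------------
# Hybrid continuous-discrete movement probabilities

def _directional_differences(field: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """(n, 26) array of f(x+e) - f(x-e) with one-sided clipping at faces."""
    shape = np.array(field.shape)
    n = len(sites)
    out = np.zeros((n, 26))
    for k, e in enumerate(NEIGHBOR_OFFSETS[1:]):
        fwd = np.clip(sites + e, 0, shape - 1)
        bwd = np.clip(sites - e, 0, shape - 1)
        out[:, k] = field[fwd[:, 0], fwd[:, 1], fwd[:, 2]] - field[bwd[:, 0], bwd[:, 1], bwd[:, 2]]
    return out


def move_probabilities_batch(
    sites: np.ndarray,
    lattice: LatticeSpec,
    D: float,
    taxis_terms: list[tuple[np.ndarray | float, np.ndarray]],
    p_bias: np.ndarray | None,
    lambda_p: float,
    blocked: np.ndarray,
    dt: float,
    extra_forbidden: np.ndarray | None = None,
) -> np.ndarray:
    """(n, 27) move distributions over {stay} + 26 neighbors for n agents.

    Transition rates come from the explicit finite-difference discretization
    of the density equation: every neighbor carries the random-walk rate
    ``D/h^2`` plus, per taxis term ``(coef, field)``, the directional
    derivative of the field projected on the move direction,
    ``coef * (f(x+e) - f(x-e)) / (2 (|e| h)^2)``.  Negative rates are
    clipped.  An uphill step of the bias field (interstitial pressure plus
    solid stress) multiplies the rate by ``exp(-lambda_p * dp)``.
    Probabilities are ``dt * rate`` with the remainder assigned to *stay*;
    if the rates exceed 1/dt they are renormalized.  Blocked (occupied or
    off-lattice) targets get zero; an all-zero row degenerates to stay=1.
    """
    n = len(sites)
    h = lattice.h
    shape = np.array(lattice.shape)
    offs = NEIGHBOR_OFFSETS[1:]
    norms2 = (np.linalg.norm(offs.astype(float), axis=1) * h) ** 2

    rates = np.full((n, 26), D / h**2)
    for coef, fld in taxis_terms:
        diffs = _directional_differences(fld, sites)
        coef_arr = np.asarray(coef, float)
        if coef_arr.ndim == 0:
            rates += coef_arr * diffs / (2.0 * norms2)
        else:
            rates += coef_arr[:, None] * diffs / (2.0 * norms2)
    rates = np.maximum(rates, 0.0)

    if p_bias is not None and lambda_p > 0.0:
        dp = _directional_differences_one_sided(p_bias, sites)
        rates *= np.exp(-lambda_p * dp)

    # forbid off-lattice and blocked targets
    targets = sites[:, None, :] + offs[None, :, :]
    on = np.all((targets >= 0) & (targets < shape), axis=2)
    t = np.clip(targets, 0, shape - 1)
    occ = blocked[t[..., 0], t[..., 1], t[..., 2]]
    allowed = on & ~occ
    if extra_forbidden is not None:
        allowed &= ~extra_forbidden
    rates[~allowed] = 0.0

    p_move = dt * rates
    total = p_move.sum(axis=1)
    over = total > 1.0
    if over.any():
        p_move[over] /= total[over, None]
        total[over] = 1.0
    probs = np.empty((n, 27))
    probs[:, 0] = 1.0 - total
    probs[:, 1:] = p_move
    return probs


def _directional_differences_one_sided(field: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """(n, 26) array of f(x+e) - f(x): the cost of stepping to each target."""
    shape = np.array(field.shape)
    here = field[sites[:, 0], sites[:, 1], sites[:, 2]]
    out = np.zeros((len(sites), 26))
    for k, e in enumerate(NEIGHBOR_OFFSETS[1:]):
        t = np.clip(sites + e, 0, shape - 1)
        out[:, k] = field[t[:, 0], t[:, 1], t[:, 2]] - here
    return out


def tc_move_probabilities(
    cell: TumorCell,
    c_e: ScalarField,
    p_bias: ScalarField,
    occupancy: np.ndarray,
    motility: MotilityParams,
    dt: float,
) -> np.ndarray:
    """27-vector of move probabilities for one active tumor cell.

    Random walk plus haptotaxis up the ECM gradient, exponentially biased
    toward lower interstitial pressure + solid stress.
    """
    sites = np.asarray([cell.site], int)
    return move_probabilities_batch(
        sites,
        c_e.lattice,
        motility.D_TC,
        [(motility.beta_h, c_e.values)],
        p_bias.values,
        motility.lambda_p,
        occupancy,
        dt,
    )[0]


def sample_move(probabilities: np.ndarray, rng: np.random.Generator) -> tuple[int, int, int]:
    """Draw one displacement (index 0 = stay) from a 27-vector."""
    idx = rng.choice(27, p=probabilities)
    return tuple(int(v) for v in NEIGHBOR_OFFSETS[idx])


def sample_moves_batch(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized inverse-CDF sampling of one displacement per row."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random((len(probs), 1))
    idx = (u > cdf).sum(axis=1)
    idx = np.minimum(idx, 26)
    return NEIGHBOR_OFFSETS[idx]
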