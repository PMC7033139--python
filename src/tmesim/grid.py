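"""Regular 3-D lattice, finite-difference operators and field solvers.

All continuum quantities of the model (nutrient and growth-factor
concentrations, interstitial fluid pressure and velocity) live on a single
regular lattice with spacing ``h`` (micrometres).  Discrete agents (tumor
cells, vessel nodes) occupy the same lattice sites, so one geometry object
serves the whole simulation.

Numerics: 7-point central Laplacian, first-order upwind convection, forward
Euler in time with a per-species stability check, and a sparse direct /
conjugate-gradient Poisson solver with Dirichlet boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix, identity, kron
from scipy.sparse.linalg import cg, factorized


class ConfigurationError(ValueError):
    """Raised for invalid lattice/time-step/parameter combinations."""


class SolverError(RuntimeError):
    """Raised when an iterative solver fails to reach its tolerance."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the regular simulation lattice.

    Parameters
    ----------
    n_x, n_y, n_z
        Node counts per axis (>= 3).
    h
        Node spacing in micrometres; one lattice site corresponds to one
        cell-sized volume element (h**3).
    origin
        Physical coordinate of node (0, 0, 0), micrometres.
    """

    n_x: int
    n_y: int
    n_z: int
    h: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) < 3:
            raise ConfigurationError("lattice needs at least 3 nodes per axis")
        if self.h <= 0:
            raise ConfigurationError("lattice spacing h must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_nodes(self) -> int:
        return self.n_x * self.n_y * self.n_z

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent per axis, (n - 1) * h, micrometres."""
        return ((self.n_x - 1) * self.h, (self.n_y - 1) * self.h, (self.n_z - 1) * self.h)

    def contains(self, site: tuple[int, int, int]) -> bool:
        i, j, k = site
        return 0 <= i < self.n_x and 0 <= j < self.n_y and 0 <= k < self.n_z

    def coords(self, site: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + self.h * np.asarray(site, dtype=float)

    def center_site(self) -> tuple[int, int, int]:
        return (self.n_x // 2, self.n_y // 2, self.n_z // 2)


@dataclass
class BoundaryCondition:
    """Dirichlet condition applied on all six faces of the box."""

    value: float
    kind: str = "dirichlet"


@dataclass
class ScalarField:
    """One real value per lattice node (a concentration, pressure, ...)."""

    lattice: LatticeSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.lattice.shape:
            raise ConfigurationError(
                f"field {self.name!r}: values shape {self.values.shape} "
                f"does not match lattice {self.lattice.shape}"
            )

    @classmethod
    def uniform(cls, lattice: LatticeSpec, value: float, name: str = "") -> "ScalarField":
        return cls(lattice, np.full(lattice.shape, float(value)), name)

    def copy(self) -> "ScalarField":
        return ScalarField(self.lattice, self.values.copy(), self.name)


@dataclass
class VectorField:
    """Three real components per lattice node (e.g. interstitial velocity)."""

    lattice: LatticeSpec
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    name: str = ""

    @classmethod
    def zeros(cls, lattice: LatticeSpec, name: str = "") -> "VectorField":
        z = np.zeros(lattice.shape)
        return cls(lattice, z.copy(), z.copy(), z.copy(), name)


def _check_same_lattice(*objs) -> LatticeSpec:
    lat = objs[0].lattice
    for o in objs[1:]:
        if o.lattice.shape != lat.shape or o.lattice.h != lat.h:
            raise ConfigurationError("lattice mismatch between fields")
    return lat


def _pad_dirichlet(values: np.ndarray, bc_value: float) -> np.ndarray:
    return np.pad(values, 1, mode="constant", constant_values=bc_value)


def laplacian(f: ScalarField, bc: BoundaryCondition) -> ScalarField:
    """7-point central-difference Laplacian with Dirichlet ghost values."""
    lat = f.lattice
    g = _pad_dirichlet(f.values, bc.value)
    c = g[1:-1, 1:-1, 1:-1]
    out = (
        g[2:, 1:-1, 1:-1] + g[:-2, 1:-1, 1:-1]
        + g[1:-1, 2:, 1:-1] + g[1:-1, :-2, 1:-1]
        + g[1:-1, 1:-1, 2:] + g[1:-1, 1:-1, :-2]
        - 6.0 * c
    ) / lat.h**2
    return ScalarField(lat, out, f"lap({f.name})")


def convective_divergence(u: VectorField, f: ScalarField) -> ScalarField:
    """First-order upwind discretization of div(u * f).

    The upwind direction is chosen per component from the sign of u at the
    node.  Ghost values replicate the edge (one-sided at the boundary).
    """
    lat = _check_same_lattice(u, f)
    h = lat.h
    out = np.zeros(lat.shape)
    for comp, axis in ((u.ux, 0), (u.uy, 1), (u.uz, 2)):
        g = comp * f.values
        gp = np.pad(g, 1, mode="edge")[
            tuple(slice(1, -1) if a != axis else slice(None) for a in range(3))
        ]
        fwd = (np.take(gp, range(2, gp.shape[axis]), axis=axis)
               - np.take(gp, range(1, gp.shape[axis] - 1), axis=axis)) / h
        bwd = (np.take(gp, range(1, gp.shape[axis] - 1), axis=axis)
               - np.take(gp, range(0, gp.shape[axis] - 2), axis=axis)) / h
        out += np.where(comp > 0, bwd, fwd)
    return ScalarField(lat, out, f"div(u*{f.name})")


# One cached Poisson operator (and factorization for small lattices) per
# lattice shape; the matrix depends only on geometry.
_POISSON_CACHE: dict[tuple, tuple] = {}
_DIRECT_LIMIT = 50_000  # unknowns; above this fall back to CG


def _poisson_operator(lat: LatticeSpec):
    key = (lat.shape, lat.h)
    if key not in _POISSON_CACHE:
        def lap1d(n):
            d = np.full(n, -2.0)
            o = np.ones(n - 1)
            return csr_matrix(np.diag(d) + np.diag(o, 1) + np.diag(o, -1))

        nx, ny, nz = (lat.n_x - 2, lat.n_y - 2, lat.n_z - 2)
        ix, iy, iz = identity(nx), identity(ny), identity(nz)
        A = (
            kron(kron(lap1d(nx), iy), iz)
            + kron(kron(ix, lap1d(ny)), iz)
            + kron(kron(ix, iy), lap1d(nz))
        ).tocsr() / lat.h**2
        solve = factorized((-A).tocsc()) if A.shape[0] <= _DIRECT_LIMIT else None
        _POISSON_CACHE[key] = (A, solve)
    return _POISSON_CACHE[key]


def solve_poisson(
    source: ScalarField,
    bc: BoundaryCondition,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
) -> ScalarField:
    """Solve -lap(p) = source with Dirichlet boundaries.

    Deterministic; the residual max-norm of the interior equations is
    checked against ``tol`` on return.
    """
    if tol <= 0:
        raise ConfigurationError("tol must be positive")
    lat = source.lattice
    A, direct = _poisson_operator(lat)
    rhs = source.values[1:-1, 1:-1, 1:-1].ravel().copy()
    # Dirichlet boundary contribution: interior nodes adjacent to a face see
    # the bc value through the stencil (-lap moves it to the right side).
    inner = np.zeros((lat.n_x - 2, lat.n_y - 2, lat.n_z - 2))
    inner[0, :, :] += bc.value
    inner[-1, :, :] += bc.value
    inner[:, 0, :] += bc.value
    inner[:, -1, :] += bc.value
    inner[:, :, 0] += bc.value
    inner[:, :, -1] += bc.value
    rhs = rhs + inner.ravel() / lat.h**2

    if direct is not None:
        x = direct(rhs)
    else:
        x_init = None
        if x0 is not None:
            x_init = x0[1:-1, 1:-1, 1:-1].ravel()
        # l2 residual below tol/2 guarantees the max-norm check below passes
        x, info = cg(-A, rhs, x0=x_init, rtol=0.0, atol=tol * 0.5, maxiter=20_000)
        if info != 0:
            res = np.max(np.abs(-A @ x - rhs))
            raise SolverError(f"Poisson CG did not converge (info={info}, residual={res:.3e})")

    residual = np.max(np.abs(-A @ x - rhs))
    if residual > tol:
        raise SolverError(f"Poisson residual {residual:.3e} exceeds tol {tol:.3e}")

    p = np.full(lat.shape, bc.value, dtype=float)
    p[1:-1, 1:-1, 1:-1] = x.reshape((lat.n_x - 2, lat.n_y - 2, lat.n_z - 2))
    return ScalarField(lat, p, f"poisson({source.name})")


@dataclass
class ClampAudit:
    """Cumulative record of negative-concentration clamping per species."""

    total_clamped: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, magnitude: float) -> None:
        if magnitude > 0.0:
            self.total_clamped[name] = self.total_clamped.get(name, 0.0) + magnitude


def stability_dt(D: float, h: float) -> float:
    """Largest explicit-Euler time step for diffusivity D: h^2 / (6 D)."""
    if D <= 0:
        return np.inf
    return h**2 / (6.0 * D)


def advance_species(
    f: ScalarField,
    D: float,
    u: VectorField | None,
    net_source: ScalarField | np.ndarray | None,
    dt: float,
    bc: BoundaryCondition,
    clamp_audit: ClampAudit | None = None,
) -> ScalarField:
    """One forward-Euler reaction-convection-diffusion step, clamped at 0.

    ``dt`` must satisfy the explicit diffusion stability bound
    ``dt <= h^2 / (6 D)``; violating it raises a :class:`ConfigurationError`
    naming the species.  Boundary faces are reset to the Dirichlet value.
    """
    lat = f.lattice
    if dt > stability_dt(D, lat.h) * (1 + 1e-12):
        raise ConfigurationError(
            f"dt={dt:g}s violates stability bound {stability_dt(D, lat.h):g}s "
            f"for species {f.name!r} (D={D:g} um^2/s, h={lat.h:g} um)"
        )
    rhs = np.zeros(lat.shape)
    if D > 0:
        rhs += D * laplacian(f, bc).values
    if u is not None:
        rhs -= convective_divergence(u, f).values
    if net_source is not None:
        src = net_source.values if isinstance(net_source, ScalarField) else net_source
        rhs += src
    new = f.values + dt * rhs
    neg = np.minimum(new, 0.0)
    if clamp_audit is not None:
        clamp_audit.record(f.name, float(-neg.sum()))
    new = np.maximum(new, 0.0)
    new[0, :, :] = new[-1, :, :] = bc.value
    new[:, 0, :] = new[:, -1, :] = bc.value
    new[:, :, 0] = new[:, :, -1] = bc.value
    return ScalarField(lat, new, f.name)


def gradient(f: ScalarField) -> VectorField:
    """Central-difference gradient (one-sided at the boundary faces)."""
    h = f.lattice.h
    gx, gy, gz = np.gradient(f.values, h)
    return VectorField(f.lattice, gx, gy, gz, f"grad({f.name})")


# 26-neighbourhood displacement table shared by cells, tips and the vessel
# graph; index 0 is "stay".
NEIGHBOR_OFFSETS: np.ndarray = np.array(
    [(0, 0, 0)]
    + [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)
OFFSET_NORMS: np.ndarray = np.linalg.norm(NEIGHBOR_OFFSETS.astype(float), axis=1)
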