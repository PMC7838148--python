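"""Structured grids and first-order finite-element operators.

Grids are axis-aligned with uniform spacing per axis; solution values live
on nodes, diffusion tensors and drift vectors live on cells (the dual
grid).  The spatial operators of the tumor model,

    L(u) = div(D grad u) + div((div D) u),

are assembled in weak form with multilinear (Q1) trial and test functions
and 2-point Gauss quadrature per axis, which is exact for cell-constant
tensors.  Zero-Neumann outer boundaries arise naturally from the weak
form.  The imaging-visibility constraint (an *internal* Dirichlet
condition on the discrete shell of the visible region) is represented by
a :class:`ConstraintSet` and enforced by identity rows.

Indexing conventions (fixed so operators are reproducible bit-for-bit):

* node ``(i_0, ..., i_{d-1})`` sits at ``(i_0 h_0, ..., i_{d-1} h_{d-1})``;
* flat node/cell indices are C-order (last axis fastest);
* cells are half-open boxes indexed by their lower corner; point queries
  on a cell face resolve to the lower-index cell.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from functools import reduce

import numpy as np
from scipy import sparse

__all__ = [
    "StructuredGrid",
    "ScalarField",
    "ConstraintSet",
    "AssembledSystem",
    "build_grid",
    "assemble",
    "extract_constraints",
    "apply_constraints",
    "constrain_matrix",
    "constrain_vector",
]


@dataclasses.dataclass(frozen=True)
class StructuredGrid:
    """Axis-aligned grid with uniform spacing per axis."""

    extents: tuple[float, ...]
    cells: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.extents) != len(self.cells):
            raise ValueError("extents and cells must have equal length")
        if not 1 <= len(self.cells) <= 3:
            raise ValueError("only 1-, 2- and 3-dimensional grids are supported")
        if any(e <= 0 for e in self.extents):
            raise ValueError(f"extents must be positive, got {self.extents}")
        if any(c < 1 for c in self.cells):
            raise ValueError(f"cell counts must be >= 1, got {self.cells}")
        object.__setattr__(self, "extents", tuple(float(e) for e in self.extents))
        object.__setattr__(self, "cells", tuple(int(c) for c in self.cells))

    @property
    def dim(self) -> int:
        return len(self.cells)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(e / c for e, c in zip(self.extents, self.cells))

    @property
    def node_shape(self) -> tuple[int, ...]:
        return tuple(c + 1 for c in self.cells)

    @property
    def cell_shape(self) -> tuple[int, ...]:
        return self.cells

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.cells))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def node_positions(self, axis: int) -> np.ndarray:
        """Node coordinates along one axis."""
        return np.linspace(0.0, self.extents[axis], self.cells[axis] + 1)

    def cell_centers(self, axis: int) -> np.ndarray:
        h = self.spacing[axis]
        return (np.arange(self.cells[axis]) + 0.5) * h

    def node_mesh(self) -> tuple[np.ndarray, ...]:
        """Meshgrid (ij-indexed) of node coordinates."""
        axes = [self.node_positions(k) for k in range(self.dim)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def locate_cell(self, point) -> tuple[int, ...]:
        """Cell owning ``point`` under half-open ownership.

        A point exactly on a shared cell face belongs to the lower-index
        cell; the far domain boundary belongs to the last cell.
        """
        point = np.atleast_1d(np.asarray(point, dtype=float))
        idx = []
        for k in range(self.dim):
            h = self.spacing[k]
            if not 0.0 <= point[k] <= self.extents[k]:
                raise ValueError(f"point {point} outside the domain")
            i = int(np.ceil(point[k] / h)) - 1  # face at i*h -> cell i-1
            idx.append(min(max(i, 0), self.cells[k] - 1))
        return tuple(idx)


def build_grid(extents, cells) -> StructuredGrid:
    """Construct a :class:`StructuredGrid` from per-axis lengths and counts."""
    extents = tuple(np.atleast_1d(np.asarray(extents, dtype=float)))
    cells = tuple(int(c) for c in np.atleast_1d(cells))
    return StructuredGrid(extents, cells)


@dataclasses.dataclass
class ScalarField:
    """Node-valued field (tumor volume fraction) on a structured grid."""

    grid: StructuredGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.node_shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match node shape "
                f"{self.grid.node_shape}"
            )

    @classmethod
    def constant(cls, grid: StructuredGrid, value: float) -> "ScalarField":
        return cls(grid, np.full(grid.node_shape, float(value)))

    @classmethod
    def from_flat(cls, grid: StructuredGrid, flat: np.ndarray) -> "ScalarField":
        return cls(grid, np.asarray(flat, dtype=float).reshape(grid.node_shape))

    def flat(self) -> np.ndarray:
        return self.values.ravel(order="C")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


@dataclasses.dataclass(frozen=True)
class ConstraintSet:
    """Pinned node indices (flat, C-order) with a single Dirichlet value.

    Represents the discrete internal boundary of the imaging-visible
    region; the default pinned value is the visibility threshold 0.16.
    ``interior`` optionally records every node of the visible region
    (shell included) — not pinned, but available to solvers for
    branch-selecting initial guesses: inside the segmentation the density
    is known to exceed the threshold.
    """

    indices: np.ndarray
    value: float = 0.16
    interior: np.ndarray | None = None

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)
        if self.interior is not None:
            object.__setattr__(
                self,
                "interior",
                np.unique(np.asarray(self.interior, dtype=np.int64)),
            )
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"pinned value must lie in (0, 1), got {self.value}")

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate(self, grid: StructuredGrid) -> None:
        if len(self) and (self.indices.min() < 0 or self.indices.max() >= grid.n_nodes):
            raise ValueError("constraint indices outside the grid")


@dataclasses.dataclass
class AssembledSystem:
    """Assembled weak-form operators on a structured grid.

    ``stiffness`` applies ``-int grad(phi_i) . D grad(phi_j)`` (symmetric
    negative semidefinite for SPD tensors), ``drift`` the once-integrated
    ``div((div D) u)`` term, ``mass`` the consistent Q1 mass matrix.
    """

    grid: StructuredGrid
    mass: sparse.csr_matrix
    stiffness: sparse.csr_matrix
    drift: sparse.csr_matrix
    constraints: ConstraintSet | None = None

    @property
    def lumped_mass(self) -> np.ndarray:
        return np.asarray(self.mass.sum(axis=1)).ravel()

    def spatial_operator(self) -> sparse.csr_matrix:
        return (self.stiffness + self.drift).tocsr()


def _axis_matrices(h: float):
    """1D Q1 element matrices on a cell of length ``h``.

    ``m``: mass, ``s``: stiffness ``int phi_a' phi_b'``, ``g``: convection
    factor ``int phi_a' phi_b`` (h-independent).
    """
    m = h * np.array([[1.0 / 3.0, 1.0 / 6.0], [1.0 / 6.0, 1.0 / 3.0]])
    s = (1.0 / h) * np.array([[1.0, -1.0], [-1.0, 1.0]])
    g = np.array([[-0.5, -0.5], [0.5, 0.5]])
    return m, s, g


def _kron_chain(mats):
    return reduce(np.kron, mats)


def element_matrices(spacing):
    """Reference Q1 element matrices for one cell.

    Returns ``(M, K, G)`` where ``M`` is the ``(2^d, 2^d)`` mass matrix,
    ``K[i, j]`` the matrix of ``int d_i phi_a d_j phi_b`` and ``G[i]``
    the matrix of ``int d_i phi_a phi_b``.  Local node ordering matches
    C-order node offsets (last axis fastest), consistent with Kronecker
    products in axis order.
    """
    d = len(spacing)
    axis = [_axis_matrices(h) for h in spacing]
    M = _kron_chain([axis[k][0] for k in range(d)])
    K = np.empty((d, d, 2**d, 2**d))
    G = np.empty((d, 2**d, 2**d))
    for i in range(d):
        G[i] = _kron_chain(
            [axis[k][2] if k == i else axis[k][0] for k in range(d)]
        )
        for j in range(d):
            factors = []
            for k in range(d):
                if k == i and k == j:
                    factors.append(axis[k][1])
                elif k == i:
                    factors.append(axis[k][2])
                elif k == j:
                    factors.append(axis[k][2].T)
                else:
                    factors.append(axis[k][0])
            K[i, j] = _kron_chain(factors)
    return M, K, G


def _connectivity(grid: StructuredGrid) -> np.ndarray:
    """Global node indices of each cell's corners, shape (n_cells, 2^d)."""
    d = grid.dim
    cell_idx = np.indices(grid.cell_shape).reshape(d, -1)
    conn = np.empty((grid.n_cells, 2**d), dtype=np.int64)
    for l, bits in enumerate(itertools.product((0, 1), repeat=d)):
        node_multi = cell_idx + np.asarray(bits, dtype=np.int64)[:, None]
        conn[:, l] = np.ravel_multi_index(tuple(node_multi), grid.node_shape)
    return conn


def assemble(grid: StructuredGrid, field=None, drift=None) -> AssembledSystem:
    """Assemble mass, stiffness and drift operators.

    Parameters
    ----------
    grid:
        The structured grid.
    field:
        A ``TensorField`` of cell-wise SPD diffusion tensors; ``None``
        means the unit tensor in every cell.
    drift:
        A ``DriftField`` of cell-wise drift vectors ``b = div D``;
        ``None`` assembles a zero drift operator (exact for spatially
        constant tensor fields).
    """
    d = grid.dim
    n = grid.n_nodes
    if field is not None and field.grid is not grid and field.grid != grid:
        raise ValueError("tensor field lives on a different grid")
    if drift is not None and drift.grid is not grid and drift.grid != grid:
        raise ValueError("drift field lives on a different grid")

    M_ref, K_ref, G_ref = element_matrices(grid.spacing)
    conn = _connectivity(grid)
    nc = grid.n_cells
    nl = 2**d

    rows = np.repeat(conn, nl, axis=1).ravel()
    cols = np.tile(conn, (1, nl)).ravel()

    def _scatter(per_cell: np.ndarray) -> sparse.csr_matrix:
        mat = sparse.coo_matrix(
            (per_cell.ravel(), (rows, cols)), shape=(n, n)
        ).tocsr()
        mat.sum_duplicates()
        return mat

    mass = _scatter(np.broadcast_to(M_ref, (nc, nl, nl)))

    if field is None:
        tensors = np.broadcast_to(np.eye(d), (nc, d, d))
    else:
        tensors = field.tensors.reshape(nc, d, d)
    stiff_cells = -np.einsum("cij,ijab->cab", tensors, K_ref)
    stiffness = _scatter(stiff_cells)

    if drift is None:
        drift_mat = sparse.csr_matrix((n, n))
    else:
        b = drift.vectors.reshape(nc, d)
        drift_cells = -np.einsum("ci,iab->cab", b, G_ref)
        drift_mat = _scatter(drift_cells)

    return AssembledSystem(grid, mass, stiffness, drift_mat)


def extract_constraints(
    u_visible: ScalarField, theta: float = 0.16, fill_interior: bool = False
) -> ConstraintSet:
    """Discrete internal Dirichlet boundary of the visible region.

    Returns the one-node-thick shell of the super-threshold set: all nodes
    with ``u >= theta`` that have at least one face-neighbor node with
    ``u < theta``, pinned at value ``theta``.  With ``fill_interior=True``
    every super-threshold node is pinned instead (the estimate outside the
    visible region is identical either way).

    A field entirely above or below the threshold yields an empty
    constraint set and a warning.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {theta}")
    mask = u_visible.values >= theta
    if mask.all() or not mask.any():
        warnings.warn(
            "visible-region shell is empty: field does not cross the threshold",
            stacklevel=2,
        )
        return ConstraintSet(
            np.empty(0, dtype=np.int64),
            value=theta,
            interior=np.empty(0, dtype=np.int64),
        )

    if fill_interior:
        shell = mask
    else:
        below = ~mask
        neighbor_below = np.zeros_like(mask)
        d = mask.ndim
        for axis in range(d):
            lo = [slice(None)] * d
            hi = [slice(None)] * d
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            neighbor_below[lo] |= below[hi]
            neighbor_below[hi] |= below[lo]
        shell = mask & neighbor_below

    idx = np.flatnonzero(shell.ravel(order="C"))
    interior = np.flatnonzero(mask.ravel(order="C"))
    return ConstraintSet(idx, value=theta, interior=interior)


def constrain_matrix(A: sparse.spmatrix, indices: np.ndarray) -> sparse.csr_matrix:
    """Replace the given rows of ``A`` by identity rows."""
    n = A.shape[0]
    if len(indices) == 0:
        return A.tocsr()
    free = np.ones(n)
    free[indices] = 0.0
    pinned = 1.0 - free
    return (sparse.diags(free) @ A + sparse.diags(pinned)).tocsr()


def constrain_vector(b: np.ndarray, indices: np.ndarray, value: float) -> np.ndarray:
    """Set constrained entries of a right-hand side / residual vector."""
    out = np.array(b, dtype=float, copy=True)
    out[indices] = value
    return out


def constrained_solve(A: sparse.spmatrix, b: np.ndarray, constraints: ConstraintSet) -> np.ndarray:
    """Solve a linear system with identity-row Dirichlet constraints.

    Pinned entries of the solution are assigned the constraint value
    exactly (not just to solver round-off).
    """
    from scipy.sparse import linalg as spla

    Ac = constrain_matrix(A, constraints.indices)
    bc = constrain_vector(b, constraints.indices, constraints.value)
    u = spla.spsolve(Ac.tocsc(), bc)
    if len(constraints):
        u[constraints.indices] = constraints.value
    return u


def apply_constraints(
    system: AssembledSystem, constraints: ConstraintSet
) -> AssembledSystem:
    """Attach an internal Dirichlet constraint set to an assembled system.

    The operators are kept intact; solvers replace constrained rows by
    identity rows (see :func:`constrain_matrix`) so the solution is exactly
    the pinned value at pinned nodes while unconstrained equations see the
    pinned values as data.
    """
    constraints.validate(system.grid)
    return AssembledSystem(
        grid=system.grid,
        mass=system.mass,
        stiffness=system.stiffness,
        drift=system.drift,
        constraints=constraints,
    )
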