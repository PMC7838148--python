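"""Diffusion tensor fields: synthetic generators, DTI scaling, diagnostics.

Tumor diffusivity enters the growth model as a cell-wise (dual-grid)
symmetric positive definite tensor ``D(x)``.  This module builds the
synthetic fields used in the validation studies — randomly perturbed
isotropic fields with unit mean determinant, the three-band "butterfly"
field, and banded anisotropic 3D volumes — scales water-diffusion (DTI)
tensors to tumor diffusivity, and computes the derived quantities the
solvers and screening diagnostics need: the matrix divergence drift
``b = div D``, fractional anisotropy, and the grid-scale Peclet number
``tau = |b| L / |D|_F``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .discretization import StructuredGrid

__all__ = [
    "TensorField",
    "DriftField",
    "homogeneous_field",
    "random_isotropic_field",
    "butterfly_profile",
    "butterfly_field",
    "banded_anisotropic_field",
    "scale_dti",
    "tensor_divergence",
    "fractional_anisotropy",
    "peclet_field",
]


@dataclasses.dataclass
class TensorField:
    """Cell-wise symmetric positive definite diffusion tensors.

    ``tensors`` has shape ``grid.cell_shape + (d, d)`` and is piecewise
    constant on the dual (cell) grid.  Symmetry is enforced on
    construction; positive definiteness can be checked with
    :meth:`check_spd` (an eigenvalue sweep, so it is opt-in for large
    volumes).
    """

    grid: StructuredGrid
    tensors: np.ndarray

    def __post_init__(self) -> None:
        d = self.grid.dim
        self.tensors = np.asarray(self.tensors, dtype=float)
        expected = self.grid.cell_shape + (d, d)
        if self.tensors.shape != expected:
            raise ValueError(
                f"tensor array shape {self.tensors.shape}, expected {expected}"
            )
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2)):
            raise ValueError("tensors must be symmetric")

    @property
    def dim(self) -> int:
        return self.grid.dim

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.tensors)

    def check_spd(self, tol: float = 0.0) -> None:
        """Raise with the offending cell indices if any tensor is not SPD."""
        lam = self.eigenvalues()
        bad = ~np.all(lam > tol, axis=-1) | ~np.all(np.isfinite(lam), axis=-1)
        if bad.any():
            cells = np.argwhere(bad)
            raise ValueError(
                f"{len(cells)} non-SPD tensor cell(s), first at {tuple(int(i) for i in cells[0])}"
            )

    def determinants(self) -> np.ndarray:
        return np.linalg.det(self.tensors)

    def frobenius_norm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.tensors**2, axis=(-2, -1)))


@dataclasses.dataclass
class DriftField:
    """Cell-wise drift vectors ``b = div D`` (units length/time)."""

    grid: StructuredGrid
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        expected = self.grid.cell_shape + (self.grid.dim,)
        if self.vectors.shape != expected:
            raise ValueError(
                f"drift array shape {self.vectors.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("drift vectors must be finite")

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def homogeneous_field(grid: StructuredGrid, diffusivity=1.0) -> TensorField:
    """Spatially constant tensor field.

    ``diffusivity`` may be a scalar (isotropic) or a ``(d, d)`` symmetric
    matrix.
    """
    d = grid.dim
    diffusivity = np.asarray(diffusivity, dtype=float)
    if diffusivity.ndim == 0:
        tensor = np.eye(d) * float(diffusivity)
    else:
        tensor = diffusivity
    tensors = np.broadcast_to(tensor, grid.cell_shape + (d, d)).copy()
    return TensorField(grid, tensors)


def random_isotropic_field(
    grid: StructuredGrid, beta: float, seed: int
) -> TensorField:
    """Randomly perturbed isotropic field ``D = 1_d * delta**(1/d)``.

    ``delta`` is drawn uniformly from ``(1 - beta, 1 + beta)``, one
    independent draw per cell, so the determinant of every cell tensor
    equals its draw and the field-average determinant is close to 1 for
    every realisation.  Draws come from a counter-based (Philox) generator
    keyed by the seed, consumed in C-order cell-index order, so a field is
    reproducible for a fixed seed and grid.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError(
            f"perturbation amplitude must lie in [0, 1) to keep tensors "
            f"positive definite, got {beta}"
        )
    d = grid.dim
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    delta = rng.uniform(1.0 - beta, 1.0 + beta, size=grid.n_cells)
    scale = delta ** (1.0 / d)
    tensors = np.einsum("c,ij->cij", scale, np.eye(d))
    return TensorField(grid, tensors.reshape(grid.cell_shape + (d, d)))


def butterfly_profile(x1, length, amplitude: float = 0.9, modes: int = 3):
    """Scalar diffusivity of the banded 2D test field at position ``x1``:
    ``1 + amplitude * sin(modes * pi * x1 / length)``."""
    return 1.0 + amplitude * np.sin(modes * np.pi * np.asarray(x1, dtype=float) / length)


def butterfly_field(
    grid: StructuredGrid, amplitude: float = 0.9, modes: int = 3
) -> TensorField:
    """Isotropic, inhomogeneous 2D field with alternating diffusivity bands.

    The unit tensor is scaled by ``1 + sin(modes pi x_1 / L_x) * amplitude``
    evaluated at cell centers, splitting the domain into ``modes`` vertical
    bands of alternating high and low diffusivity (the left and right
    thirds fast, the middle slow, for the default three bands).
    """
    if grid.dim != 2:
        raise ValueError("butterfly field is a 2D construction")
    if not 0.0 <= amplitude < 1.0:
        raise ValueError(
            f"amplitude must lie in [0, 1) to keep tensors positive, got {amplitude}"
        )
    x1 = grid.cell_centers(0)
    scale = butterfly_profile(x1, grid.extents[0], amplitude, modes)
    tensors = np.zeros(grid.cell_shape + (2, 2))
    tensors[..., 0, 0] = scale[:, None]
    tensors[..., 1, 1] = scale[:, None]
    return TensorField(grid, tensors)


def banded_anisotropic_field(
    grid: StructuredGrid, fa_amplitude: float = 0.6, bands: int = 2
) -> TensorField:
    """Synthetic 3D SPD tensor volume with band-structured anisotropy.

    Eigenvalues are ``(1 + a, 1, 1/(1 + a))`` along the coordinate axes
    with ``a(z) = fa_amplitude * (1 + sin(2 pi bands z / L_z)) / 2``
    evaluated at cell centers, so fractional anisotropy varies smoothly
    in bands along the last axis while every tensor stays SPD with unit
    determinant.
    """
    if grid.dim != 3:
        raise ValueError("banded anisotropic field is a 3D construction")
    if fa_amplitude < 0:
        raise ValueError("fa_amplitude must be non-negative")
    z = grid.cell_centers(2)
    a = fa_amplitude * 0.5 * (1.0 + np.sin(2.0 * np.pi * bands * z / grid.extents[2]))
    tensors = np.zeros(grid.cell_shape + (3, 3))
    tensors[..., 0, 0] = 1.0 + a[None, None, :]
    tensors[..., 1, 1] = 1.0
    tensors[..., 2, 2] = 1.0 / (1.0 + a[None, None, :])
    return TensorField(grid, tensors)


def scale_dti(
    water_tensors: TensorField, alpha: float, repair: bool = False
) -> TensorField:
    """Tumor diffusivity from water diffusivity by scalar scaling
    ``D = alpha * D_w``.

    Eigenvectors are unchanged and fractional anisotropy is invariant.
    Non-SPD input cells (possible in real DTI exports) are rejected with
    the offending cell index by default; with ``repair=True`` their
    eigenvalues are clamped to ``1e-6`` times the cell's largest
    eigenvalue before scaling, a common DTI hygiene step.
    """
    if not alpha > 0.0:
        raise ValueError(f"scaling factor must be positive, got {alpha}")
    tensors = water_tensors.tensors
    lam = np.linalg.eigvalsh(tensors)
    bad = ~np.all(lam > 0.0, axis=-1)
    if bad.any():
        if not repair:
            cells = np.argwhere(bad)
            raise ValueError(
                f"{len(cells)} non-SPD input cell(s), first at {tuple(int(i) for i in cells[0])}; "
                "pass repair=True to clamp eigenvalues"
            )
        lam_full, vec = np.linalg.eigh(tensors)
        floor = 1e-6 * lam_full[..., -1:]
        lam_rep = np.maximum(lam_full, floor)
        tensors = np.einsum("...ik,...k,...jk->...ij", vec, lam_rep, vec)
    return TensorField(water_tensors.grid, alpha * tensors)


def tensor_divergence(field: TensorField) -> DriftField:
    """Row-wise matrix divergence ``b_j = sum_i dD_ij/dx_i`` per cell.

    First-order finite differences of neighboring cell tensors: central in
    the interior, one-sided at the field boundary (``numpy.gradient``
    semantics).  Constant fields yield zero drift; with symmetric tensors
    the row and column conventions coincide.
    """
    grid = field.grid
    d = grid.dim
    if any(c < 2 for c in grid.cells):
        raise ValueError(
            "matrix divergence needs at least 2 cells per axis, "
            f"got {grid.cells}"
        )
    vectors = np.zeros(grid.cell_shape + (d,))
    for j in range(d):
        for i in range(d):
            vectors[..., j] += np.gradient(
                field.tensors[..., i, j], grid.spacing[i], axis=i
            )
    return DriftField(grid, vectors)


def fractional_anisotropy(field: TensorField) -> np.ndarray:
    """Per-cell fractional anisotropy in [0, 1].

    ``FA = sqrt(d/(d-1)) * ||lam - mean(lam)|| / ||lam||`` over the
    eigenvalue tuple; 0 for isotropic tensors and approaching 1 in the
    rank-deficient limit.  The same formula is applied to eigenvalue
    pairs in 2D.
    """
    lam = field.eigenvalues()
    if not np.all(np.isfinite(lam)):
        bad = np.argwhere(~np.all(np.isfinite(lam), axis=-1))
        raise ValueError(f"non-finite eigenvalues, first at cell {tuple(bad[0])}")
    d = field.dim
    if d < 2:
        return np.zeros(field.grid.cell_shape)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(d / (d - 1.0)) * num / den
    return np.where(den > 0.0, fa, 0.0)


def peclet_field(
    field: TensorField, drift: DriftField, spacing: float | None = None
) -> np.ndarray:
    """Grid-scale Peclet number ``tau = |b| L / |D|_F`` per cell.

    ``L`` defaults to the grid's first-axis cell edge length.  ``tau``
    screens whether drift induced by tensor inhomogeneity stays small
    against diffusion, the regime in which the stationalization remains
    applicable.  Cells with zero tensor norm are undefined and raise.
    """
    if drift.grid != field.grid:
        raise ValueError("drift and tensor field live on different grids")
    if spacing is None:
        spacing = field.grid.spacing[0]
    norm = field.frobenius_norm()
    if np.any(norm == 0.0):
        bad = np.argwhere(norm == 0.0)
        raise ValueError(f"zero tensor norm, first at cell {tuple(bad[0])}")
    return drift.magnitudes() * float(spacing) / norm
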