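"""File containers for fields: legacy-VTK, NIfTI and HDF5.

Scalar node fields and per-cell scalars go to legacy ASCII VTK
``STRUCTURED_POINTS`` files (deterministic text, convenient for
ParaView), to NIfTI-1 volumes via nibabel, or to HDF5 groups carrying the
grid metadata (extents, cells, origin).  Tensor volumes round-trip
through NIfTI in the usual 6-component upper-triangle-per-voxel dialect
(a lower-triangle flag is accepted) or through HDF5 with shape
``cells + (d, d)``.
"""

from __future__ import annotations

import numpy as np

from .discretization import ScalarField, StructuredGrid, build_grid
from .fields import TensorField

__all__ = [
    "write_vtk",
    "write_nifti",
    "read_nifti",
    "write_hdf5_field",
    "read_hdf5_field",
    "write_hdf5_tensors",
    "read_hdf5_tensors",
    "read_nifti_tensors",
    "write_nifti_tensors",
]

_UPPER_PAIRS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
_LOWER_PAIRS = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


def _vtk_dims(shape) -> tuple[int, int, int]:
    return tuple(list(shape) + [1] * (3 - len(shape)))


def write_vtk(path, grid: StructuredGrid, point_data=None, cell_data=None) -> None:
    """Write node and/or cell scalars to a legacy ASCII VTK file.

    ``point_data`` / ``cell_data`` map names to arrays of node/cell shape.
    VTK expects the x index fastest, so arrays are emitted in Fortran
    order of the grid axes.  Output is deterministic text.
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    spacing = _vtk_dims_spacing(grid)
    lines = [
        "# vtk DataFile Version 3.0",
        "glioextent structured field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        "DIMENSIONS {} {} {}".format(*_vtk_dims(grid.node_shape)),
        "ORIGIN 0 0 0",
        "SPACING {:.17g} {:.17g} {:.17g}".format(*spacing),
    ]

    def _emit(section: str, count: int, data: dict) -> None:
        lines.append(f"{section} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.ravel(order="F")
            lines.extend(f"{v:.17g}" for v in flat)

    if point_data:
        _emit("POINT_DATA", grid.n_nodes, point_data)
    if cell_data:
        _emit("CELL_DATA", grid.n_cells, cell_data)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _vtk_dims_spacing(grid: StructuredGrid) -> tuple[float, float, float]:
    return tuple(list(grid.spacing) + [1.0] * (3 - grid.dim))


def write_nifti(path, field: ScalarField) -> None:
    """Write a nodal scalar field as a NIfTI-1 volume (affine = spacing)."""
    import nibabel as nib

    grid = field.grid
    vals = field.values
    shape3 = _vtk_dims(grid.node_shape)
    affine = np.eye(4)
    for k in range(grid.dim):
        affine[k, k] = grid.spacing[k]
    img = nib.Nifti1Image(vals.reshape(shape3).astype(np.float64), affine)
    nib.save(img, str(path))


def read_nifti(path, extents=None) -> ScalarField:
    """Read a NIfTI scalar volume back onto a structured grid.

    Grid spacing is taken from the affine diagonal unless ``extents``
    overrides the physical lengths.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    shape = data.shape
    cells = tuple(s - 1 for s in shape)
    if extents is None:
        zooms = img.header.get_zooms()[: len(shape)]
        extents = tuple(z * c for z, c in zip(zooms, cells))
    grid = build_grid(extents, cells)
    return ScalarField(grid, data)


def write_hdf5_field(path, field: ScalarField, name: str = "u") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        ds = fh.create_dataset(name, data=field.values, track_times=False)
        ds.attrs["extents"] = field.grid.extents
        ds.attrs["cells"] = field.grid.cells
        ds.attrs["origin"] = (0.0,) * field.grid.dim


def read_hdf5_field(path, name: str = "u") -> ScalarField:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh[name]
        grid = build_grid(tuple(ds.attrs["extents"]), tuple(int(c) for c in ds.attrs["cells"]))
        return ScalarField(grid, ds[...])


def write_hdf5_tensors(path, field: TensorField, name: str = "D") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        ds = fh.create_dataset(name, data=field.tensors, track_times=False)
        ds.attrs["extents"] = field.grid.extents
        ds.attrs["cells"] = field.grid.cells


def read_hdf5_tensors(path, name: str = "D") -> TensorField:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh[name]
        grid = build_grid(tuple(ds.attrs["extents"]), tuple(int(c) for c in ds.attrs["cells"]))
        return TensorField(grid, ds[...])


def write_nifti_tensors(path, field: TensorField, order: str = "upper") -> None:
    """Write a 3D tensor field as a 6-component-per-voxel NIfTI volume."""
    import nibabel as nib

    if field.grid.dim != 3:
        raise ValueError("NIfTI tensor export is defined for 3D volumes")
    pairs = _UPPER_PAIRS if order == "upper" else _LOWER_PAIRS
    comps = np.stack([field.tensors[..., i, j] for i, j in pairs], axis=-1)
    affine = np.eye(4)
    for k in range(3):
        affine[k, k] = field.grid.spacing[k]
    nib.save(nib.Nifti1Image(comps.astype(np.float64), affine), str(path))


def read_nifti_tensors(path, extents=None, order: str = "upper") -> TensorField:
    """Read a per-voxel symmetric tensor volume from NIfTI.

    Expects 6 components per voxel in upper-triangle order (xx, xy, xz,
    yy, yz, zz); pass ``order="lower"`` for the lower-triangle dialect.
    """
    import nibabel as nib

    img = nib.load(str(path))
    comps = np.asarray(img.dataobj, dtype=float)
    comps = np.squeeze(comps)
    if comps.ndim != 4 or comps.shape[-1] != 6:
        raise ValueError(
            f"expected a (nx, ny, nz, 6) tensor volume, got shape {comps.shape}"
        )
    pairs = _UPPER_PAIRS if order == "upper" else _LOWER_PAIRS
    cells = comps.shape[:3]
    tensors = np.zeros(cells + (3, 3))
    for c, (i, j) in enumerate(pairs):
        tensors[..., i, j] = comps[..., c]
        tensors[..., j, i] = comps[..., c]
    if extents is None:
        zooms = img.header.get_zooms()[:3]
        extents = tuple(z * c for z, c in zip(zooms, cells))
    grid = build_grid(extents, cells)
    return TensorField(grid, tensors)
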