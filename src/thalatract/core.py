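"""Shared spatial containers for the thalamic-targeting pipeline.

All world coordinates are millimetres in a RAS-oriented frame; voxel indices
are 0-based and map to world space through a 4x4 affine whose columns follow
the NIfTI convention (``world = affine @ [i, j, k, 1]``).  Voxel *centers*
sit at integer indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine

log = logging.getLogger("thalatract")

_Vec3 = np.ndarray  # shape (3,), float64, millimetres


def as_vec3(x) -> _Vec3:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass
class VoxelGrid:
    """A 3D scalar/label volume with its grid-to-world affine.

    Carrier for probability maps, visitation counts, integer labels and
    binary masks.  ``data`` is any numeric dtype; geometry lives in
    ``affine`` (mm).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and different data."""
        if data.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return VoxelGrid(data, self.affine.copy())

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    # --- coordinate transforms -------------------------------------------------

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        return apply_affine(np.linalg.inv(self.affine), np.asarray(xyz, dtype=float))

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel integer indices (may fall outside the grid)."""
        return np.rint(self.world_to_voxel(xyz)).astype(np.int64)

    def contains_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        shape = np.asarray(self.shape)
        return np.all((ijk >= 0) & (ijk < shape), axis=-1)

    def world_coordinates(self) -> np.ndarray:
        """World mm coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(*self.shape, 3)


def require_binary(grid: VoxelGrid, name: str = "mask") -> np.ndarray:
    """Validate a mask grid and return it as boolean."""
    vals = np.unique(grid.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must contain only 0/1 values, found {vals[:10]}")
    return grid.data.astype(bool)


@dataclass
class OrientationField:
    """Per-voxel fiber orientation samples driving streamline propagation.

    Each voxel stores 0, 1 or 2 unit direction vectors (0 = isotropic,
    non-propagating; 2 = crossing-fiber voxel) plus an angular dispersion in
    degrees — the per-axis SD of the Gaussian perturbation applied on the
    tangent plane when a direction is sampled.
    """

    directions: np.ndarray  # (X, Y, Z, 2, 3) float, unused slots arbitrary
    n_directions: np.ndarray  # (X, Y, Z) uint8 in {0, 1, 2}
    dispersion_deg: np.ndarray  # (X, Y, Z) float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.n_directions = np.asarray(self.n_directions, dtype=np.uint8)
        self.dispersion_deg = np.asarray(self.dispersion_deg, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.directions.ndim != 5 or self.directions.shape[3:] != (2, 3):
            raise ValueError("directions must have shape (X, Y, Z, 2, 3)")
        if self.n_directions.shape != self.directions.shape[:3]:
            raise ValueError("n_directions shape mismatch")
        self.validate_units()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.n_directions.shape  # type: ignore[return-value]

    def validate_units(self, tol: float = 1e-6) -> None:
        """Every stored direction must be unit-norm."""
        for k in (0, 1):
            sel = self.n_directions > k
            if np.any(sel):
                norms = np.linalg.norm(self.directions[sel, k, :], axis=-1)
                if np.any(np.abs(norms - 1.0) >= tol):
                    raise ValueError("orientation vectors must be unit-norm")

    @classmethod
    def empty(cls, shape, affine) -> "OrientationField":
        return cls(
            directions=np.zeros((*shape, 2, 3)),
            n_directions=np.zeros(shape, dtype=np.uint8),
            dispersion_deg=np.zeros(shape),
            affine=affine,
        )


@dataclass
class LandmarkSet:
    """AC, PC and an interhemispheric point (mm) defining the AC-PC frame.

    IH is any midsagittal point off the AC-PC line, e.g. the apex of the
    corpus callosum; it fixes the midsagittal plane.
    """

    AC: _Vec3
    PC: _Vec3
    IH: _Vec3

    #: triangle-area tolerance below which the landmarks count as collinear
    collinearity_tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.AC = as_vec3(self.AC)
        self.PC = as_vec3(self.PC)
        self.IH = as_vec3(self.IH)
        self.validate()

    def validate(self) -> None:
        if np.linalg.norm(self.PC - self.AC) <= self.collinearity_tol:
            raise ValueError("AC and PC coincide")
        area = 0.5 * np.linalg.norm(np.cross(self.PC - self.AC, self.IH - self.AC))
        if area <= self.collinearity_tol:
            raise ValueError("IH is collinear with the AC-PC line")

    def as_dict(self) -> dict[str, list[float]]:
        return {k: getattr(self, k).tolist() for k in ("AC", "PC", "IH")}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(AC=d["AC"], PC=d["PC"], IH=d["IH"])
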