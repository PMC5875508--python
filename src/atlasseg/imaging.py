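"""Geometric image model: grids, volumes, masks, and the shared raster ops.

A :class:`VolumeGrid` fixes the affine map between 0-based voxel indices and
physical millimetre coordinates (voxel centres at
``origin + direction @ (spacing * index)``).  :class:`ScalarVolume` carries CT
intensities in Hounsfield units (HU) on such a grid; :class:`BinaryMask`
carries one organ's {0,1} segmentation.  All physical quantities are in mm.

The resampling convention throughout the package: a spatial transform maps
points of the *target* (fixed/patient) grid into the *source* (moving/atlas)
space, so warped atlas labels land directly on the patient grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, GridMismatchError

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "LevelSetField",
    "resample",
    "dilate_mask",
    "gradient_magnitude",
    "signed_distance",
]

#: out-of-field fill values: air for CT, background for masks
CT_FILL_HU = -1000.0
MASK_FILL = 0


@dataclass(frozen=True)
class VolumeGrid:
    """Physical geometry of a 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis.
    spacing : tuple of float
        Voxel size per axis in mm; all components > 0.
    origin : tuple of float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    direction : 3x3 ndarray
        Orthonormal axis-direction matrix (columns are the physical
        directions of the index axes).
    """

    shape: tuple
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", d)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"non-positive spacing {self.spacing}")
        if abs(abs(np.linalg.det(d)) - 1.0) > 1e-8 or not np.allclose(
            d.T @ d, np.eye(3), atol=1e-8
        ):
            raise GeometryError("direction matrix is not orthonormal")

    # -- index <-> physical -------------------------------------------------

    @property
    def index_to_physical_matrix(self) -> np.ndarray:
        """3x3 linear part of the index->physical affine."""
        return self.direction @ np.diag(self.spacing)

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to physical mm."""
        idx = np.asarray(index, dtype=float)
        return idx @ self.index_to_physical_matrix.T + np.asarray(self.origin)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical mm points, shape (..., 3), to continuous indices."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.origin)
        inv = np.linalg.inv(self.index_to_physical_matrix)
        return pts @ inv.T

    def physical_points(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class ScalarVolume:
    """A scalar (HU) image on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("non-finite intensity values")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    """A {0,1} organ segmentation on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray
    organ_label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def bool(self) -> np.ndarray:
        return self.values.astype(np.bool_)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.values.copy(), self.organ_label)


@dataclass
class LevelSetField:
    """Signed scalar field (mm) whose zero level set is a closed surface.

    Convention: negative inside, positive outside.
    """

    grid: VolumeGrid
    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.phi.shape != self.grid.shape:
            raise GeometryError("phi shape mismatch")

    def to_mask(self, organ_label: str = "") -> BinaryMask:
        return BinaryMask(self.grid, (self.phi < 0).astype(np.uint8), organ_label)


# ---------------------------------------------------------------------------
# raster operations
# ---------------------------------------------------------------------------


def resample(volume, target: VolumeGrid, transform=None, interpolation: str = "linear"):
    """Resample a volume or mask onto ``target``.

    ``transform`` maps target physical points into the source physical space
    (identity if None).  Masks must use nearest-neighbour to remain binary.
    Out-of-field voxels take -1000 HU for scalar volumes and 0 for masks.
    """
    is_mask = isinstance(volume, BinaryMask)
    if is_mask and interpolation == "linear":
        interpolation = "nearest"
    order = {"linear": 1, "nearest": 0}[interpolation]
    cval = MASK_FILL if is_mask else CT_FILL_HU

    pts = target.physical_points().reshape(-1, 3)
    if transform is not None:
        pts = transform.apply_points(pts)
    idx = volume.grid.physical_to_index(pts)  # (N, 3) continuous source indices

    src = volume.values.astype(np.float64)
    out = ndimage.map_coordinates(
        src, idx.T, order=order, mode="constant", cval=cval, prefilter=False
    ).reshape(target.shape)
    if is_mask:
        return BinaryMask(target, (out > 0.5).astype(np.uint8), volume.organ_label)
    return ScalarVolume(target, out)


def dilate_mask(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Dilate by a true Euclidean margin in mm (anisotropy honoured).

    Every voxel whose physical (centre-to-centre) distance to the input
    foreground is <= ``margin_mm`` becomes foreground.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    fg = mask.bool
    if not fg.any():
        warnings.warn("dilate_mask: empty input mask returned unchanged")
        return mask.copy()
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~fg, sampling=mask.grid.spacing)
    out = dist <= margin_mm * (1 + 1e-12)
    return BinaryMask(mask.grid, out.astype(np.uint8), mask.organ_label)


def gradient_magnitude(volume: ScalarVolume, smoothing_sigma_mm: float = 0.0) -> ScalarVolume:
    """|∇I| in HU/mm, after optional Gaussian smoothing at a physical sigma."""
    if smoothing_sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    vals = volume.values
    sp = volume.grid.spacing
    if smoothing_sigma_mm > 0:
        vals = ndimage.gaussian_filter(
            vals, sigma=[smoothing_sigma_mm / s for s in sp], mode="nearest"
        )
    grads = np.gradient(vals, *sp)
    return ScalarVolume(volume.grid, np.sqrt(sum(g * g for g in grads)))


def signed_distance(mask: BinaryMask) -> LevelSetField:
    """Signed Euclidean distance to the mask boundary in mm, negative inside."""
    fg = mask.bool
    if not fg.any() or fg.all():
        raise GeometryError("signed_distance requires both foreground and background")
    sp = mask.grid.spacing
    dist_out = ndimage.distance_transform_edt(~fg, sampling=sp)
    dist_in = ndimage.distance_transform_edt(fg, sampling=sp)
    return LevelSetField(mask.grid, dist_out - dist_in)


def require_same_grid(a, b) -> None:
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError("operands are defined on different grids")
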