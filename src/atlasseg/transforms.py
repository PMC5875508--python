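"""Spatial transforms mapping fixed (patient) physical points into moving
(atlas) physical space — the resampling convention.

Three families: :class:`Affine3D` (pure numpy), :class:`BSplineFFD` (a cubic
free-form deformation backed by a SimpleITK B-spline transform), and
:class:`CompositeTransform` (applied right-to-left, so ``[affine, ffd]``
means the FFD acts first).  :class:`DisplacementTransform` carries a dense
displacement field sampled on a grid; the phantom generator uses it for
analytically known ground-truth warps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .imaging import VolumeGrid

__all__ = [
    "SpatialTransform",
    "IdentityTransform",
    "Affine3D",
    "BSplineFFD",
    "DisplacementTransform",
    "CompositeTransform",
    "write_transform",
    "read_transform",
]


class SpatialTransform:
    """Interface: vectorized point mapping plus SimpleITK interop."""

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def as_sitk(self) -> sitk.Transform:
        raise NotImplementedError

    def displacement_on_grid(self, grid: VolumeGrid) -> np.ndarray:
        """Dense displacement (mm), shape ``grid.shape + (3,)``."""
        pts = grid.physical_points().reshape(-1, 3)
        return (self.apply_points(pts) - pts).reshape(grid.shape + (3,))


class IdentityTransform(SpatialTransform):
    def apply_points(self, points):
        return np.asarray(points, dtype=float)

    def as_sitk(self):
        return sitk.Transform(3, sitk.sitkIdentity)


@dataclass
class Affine3D(SpatialTransform):
    """y = M (x - c) + c + t with invertible 3x3 matrix M."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-10:
            raise ValueError("affine matrix is singular")

    def apply_points(self, points):
        pts = np.asarray(points, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "Affine3D":
        inv = np.linalg.inv(self.matrix)
        # y = M(x-c)+c+t  =>  x = M^-1 (y - c - t) + c
        return Affine3D(inv, -inv @ self.translation, self.center)

    def as_sitk(self):
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.matrix.flatten()))
        t.SetTranslation(tuple(self.translation))
        t.SetCenter(tuple(self.center))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "Affine3D":
        t = sitk.AffineTransform(t)
        return cls(
            np.array(t.GetMatrix()).reshape(3, 3),
            np.array(t.GetTranslation()),
            np.array(t.GetCenter()),
        )

    @classmethod
    def translation_only(cls, t) -> "Affine3D":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def rotation_z(cls, degrees: float, center=(0.0, 0.0, 0.0)) -> "Affine3D":
        a = np.deg2rad(degrees)
        m = np.array(
            [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
        )
        return cls(m, np.zeros(3), np.asarray(center, dtype=float))

    def to_dict(self) -> dict:
        return {
            "type": "affine",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Affine3D":
        return cls(np.array(d["matrix"]), np.array(d["translation"]), np.array(d["center"]))


class BSplineFFD(SpatialTransform):
    """Cubic B-spline free-form deformation over the fixed-image domain.

    Displacement at any physical point is the order-3 B-spline interpolation
    of per-node mm coefficients on a coarse control lattice covering the
    fixed image extent plus the spline support pad.
    """

    def __init__(self, sitk_bspline: sitk.BSplineTransform):
        self._t = sitk.BSplineTransform(sitk_bspline)

    @classmethod
    def initialize(cls, fixed_image: sitk.Image, node_spacing_mm: float) -> "BSplineFFD":
        extent = [
            (sz - 1) * sp for sz, sp in zip(fixed_image.GetSize(), fixed_image.GetSpacing())
        ]
        mesh = [max(1, int(np.ceil(e / node_spacing_mm))) for e in extent]
        return cls(sitk.BSplineTransformInitializer(fixed_image, mesh, order=3))

    @property
    def coefficients(self) -> np.ndarray:
        """Node displacements, shape (n_nodes, 3)."""
        return np.array(self._t.GetParameters()).reshape(3, -1).T

    @property
    def n_parameters(self) -> int:
        return len(self._t.GetParameters())

    def apply_points(self, points):
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.empty_like(pts)
        for i, p in enumerate(pts):
            out[i] = self._t.TransformPoint(tuple(p))
        return out

    def as_sitk(self):
        return self._t

    def max_displacement_mm(self, grid: VolumeGrid) -> float:
        disp = dense_sitk_displacement(self._t, grid)
        return float(np.linalg.norm(disp, axis=-1).max())


@dataclass
class DisplacementTransform(SpatialTransform):
    """y = x + D(x), D a dense per-voxel displacement field (mm) on ``grid``,
    linearly interpolated between voxel centres and zero outside."""

    grid: VolumeGrid
    field: np.ndarray  # shape grid.shape + (3,)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.shape != self.grid.shape + (3,):
            raise ValueError("displacement field shape mismatch")

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        idx = self.grid.physical_to_index(np.asarray(points, dtype=float)).T
        return np.stack(
            [
                ndimage.map_coordinates(
                    self.field[..., k], idx, order=1, mode="constant", cval=0.0, prefilter=False
                )
                for k in range(3)
            ],
            axis=-1,
        )

    def apply_points(self, points):
        pts = np.asarray(points, dtype=float)
        return pts + self.displacement_at(pts)

    def inverse(self, n_iter: int = 30) -> "DisplacementTransform":
        """Fixed-point inversion: Dinv(y) = -D(y + Dinv(y)); valid while the
        field is a contraction (max |∇D| < 1), which the phantom guarantees."""
        pts = self.grid.physical_points()
        dinv = np.zeros_like(self.field)
        flat = pts.reshape(-1, 3)
        for _ in range(n_iter):
            dinv_flat = dinv.reshape(-1, 3)
            dinv = -self.displacement_at(flat + dinv_flat).reshape(self.field.shape)
        return DisplacementTransform(self.grid, dinv)

    def as_sitk(self):
        # sitk displacement image is indexed (x, y, z) with vector pixels
        arr = np.ascontiguousarray(self.field.transpose(2, 1, 0, 3))
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(tuple(self.grid.spacing))
        img.SetOrigin(tuple(self.grid.origin))
        img.SetDirection(tuple(self.grid.direction.flatten()))
        return sitk.DisplacementFieldTransform(sitk.Cast(img, sitk.sitkVectorFloat64))


@dataclass
class CompositeTransform(SpatialTransform):
    """Ordered transform stack applied right-to-left on fixed-space points:
    ``CompositeTransform([affine, ffd])`` computes ``affine(ffd(x))``."""

    transforms: list

    def apply_points(self, points):
        pts = np.asarray(points, dtype=float)
        for t in reversed(self.transforms):
            pts = t.apply_points(pts)
        return pts

    def as_sitk(self):
        # sitk composite applies the last-added transform first
        comp = sitk.CompositeTransform(3)
        for t in self.transforms:
            comp.AddTransform(t.as_sitk())
        return comp

    @property
    def affine(self):
        return self.transforms[0]

    @property
    def ffd_stages(self):
        return self.transforms[1:]


def dense_sitk_displacement(transform: sitk.Transform, grid: VolumeGrid) -> np.ndarray:
    """Displacement of a sitk transform sampled on ``grid``, shape + (3,)."""
    f = sitk.TransformToDisplacementFieldFilter()
    f.SetSize([int(s) for s in grid.shape])
    f.SetOutputSpacing(tuple(grid.spacing))
    f.SetOutputOrigin(tuple(grid.origin))
    f.SetOutputDirection(tuple(grid.direction.flatten()))
    img = f.Execute(transform)
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0, 3).astype(np.float64)


def write_transform(transform: SpatialTransform, path: str) -> None:
    """Serialize a transform: JSON sidecar for affines, ITK text .tfm
    otherwise (both plain-text formats)."""
    if isinstance(transform, Affine3D) and path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(transform.to_dict(), fh, indent=2)
    else:
        sitk.WriteTransform(transform.as_sitk(), path)


def read_transform(path: str) -> SpatialTransform:
    if path.endswith(".json"):
        with open(path) as fh:
            return Affine3D.from_dict(json.load(fh))

    class _SitkWrapped(SpatialTransform):
        def __init__(self, t):
            self._t = t

        def apply_points(self, points):
            pts = np.asarray(points, dtype=float).reshape(-1, 3)
            return np.array([self._t.TransformPoint(tuple(p)) for p in pts])

        def as_sitk(self):
            return self._t

    return _SitkWrapped(sitk.ReadTransform(path))
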