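"""Synthetic CT-like phantoms with known ground truth.

The generator rasterizes a stylized thoraco-abdominal anatomy on a 64^3,
2.5 mm grid: an elliptical body of soft tissue, two low-HU lungs, a high-HU
vertebral column, a bowel-gas pocket, and soft-tissue target organs (liver,
spleen, kidneys) of similar HU wrapped in thin fat capsules.  The layout
mirrors the statistical structure of clinical abdominal CT rather than its
anatomy: organs of similar intensity are adjacent, and every target organ
neighbours both low-HU (fat, gas, lung) and the soft-tissue background, so
local intensity histograms are multimodal the way real scans are — the
regime the refinement stage's histogram classification assumes.

The "patient" is the base anatomy plus noise; each "atlas" is the base
warped by an invertible random smooth displacement (coarse 55 mm lattice,
cubic interpolation, bounded magnitude) composed with a rigid posture
change, under a monotone intensity remap a*v + b emulating calibration
differences.  The exact patient->atlas transform is recorded per atlas, and
atlas organ masks are rasterized analytically through its inverse, so
known-transform recovery and self-consistency have well-defined ground
truth.  All randomness derives from the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .imaging import BinaryMask, ScalarVolume, VolumeGrid
from .transforms import Affine3D, CompositeTransform, DisplacementTransform

__all__ = [
    "Ellipsoid",
    "Capsule",
    "Structure",
    "PhantomSpec",
    "AtlasCase",
    "PhantomCase",
    "generate_phantom",
    "add_confounder",
    "default_spec",
]


# ---------------------------------------------------------------------------
# implicit shape primitives (inside where implicit < 0)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple
    semi_axes: tuple

    def implicit(self, points: np.ndarray) -> np.ndarray:
        r = (np.asarray(points, dtype=float) - np.asarray(self.center)) / np.asarray(
            self.semi_axes
        )
        return np.sum(r * r, axis=-1) - 1.0

    def expand(self, margin_mm: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(s + margin_mm for s in self.semi_axes))

    @property
    def min_radius_mm(self) -> float:
        return float(min(self.semi_axes))


@dataclass(frozen=True)
class Capsule:
    p0: tuple
    p1: tuple
    radius: float

    def implicit(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        a, b = np.asarray(self.p0, dtype=float), np.asarray(self.p1, dtype=float)
        ab = b - a
        t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
        d = p - (a + t[..., None] * ab)
        return np.sum(d * d, axis=-1) / self.radius**2 - 1.0

    def expand(self, margin_mm: float) -> "Capsule":
        return Capsule(self.p0, self.p1, self.radius + margin_mm)

    @property
    def min_radius_mm(self) -> float:
        return float(self.radius)


@dataclass(frozen=True)
class Structure:
    """One painted anatomy element (painted in list order, later wins)."""

    label: str
    shape: object
    hu: float
    hu_jitter: float = 0.0
    target: bool = False    # segmentation target (gets a truth/atlas mask)
    textured: bool = False  # carries the smooth background-heterogeneity field


def _default_structures() -> list:
    fat = -90.0
    structures = [
        Structure("body", Ellipsoid((80, 80, 80), (76, 70, 78)), 10.0, textured=True),
        # thin fat capsules painted under their organs; fat and soft-tissue
        # background are heterogeneous (textured) the way real tissue is,
        # while each organ parenchyma is a tight intensity mode
        Structure("fat_liver", Ellipsoid((108, 76, 62), (30.5, 24.5, 26.5)), fat, textured=True),
        Structure("fat_spleen", Ellipsoid((40, 84, 60), (17.5, 15.5, 19.5)), fat, textured=True),
        Structure("fat_kidney_left", Ellipsoid((60, 112, 56), (13.5, 12.5, 17.5)), fat, textured=True),
        Structure("fat_kidney_right", Ellipsoid((100, 112, 56), (13.5, 12.5, 17.5)), fat, textured=True),
        Structure("bowel_gas", Ellipsoid((70, 56, 78), (10, 9, 11)), -600.0),
        Structure("vertebrae", Capsule((80, 118, 24), (80, 118, 136), 9.0), 700.0),
        Structure("lung_right", Ellipsoid((114, 72, 118), (21, 19, 26)), -800.0),
        Structure("lung_left", Ellipsoid((46, 72, 118), (21, 19, 26)), -800.0, 4.0, True),
        Structure("liver", Ellipsoid((108, 76, 62), (28, 22, 24)), 75.0, 4.0, True),
        Structure("spleen", Ellipsoid((40, 84, 60), (15, 13, 17)), 62.0, 4.0, True),
        Structure("kidney_left", Ellipsoid((60, 112, 56), (11, 10, 15)), 52.0, 4.0, True),
        Structure("kidney_right", Ellipsoid((100, 112, 56), (11, 10, 15)), 52.0, 4.0, True),
    ]
    return structures


@dataclass
class PhantomSpec:
    """Study conditions for one phantom family."""

    grid: VolumeGrid = field(
        default_factory=lambda: VolumeGrid((64, 64, 64), (2.5, 2.5, 2.5))
    )
    structures: list = field(default_factory=_default_structures)
    air_hu: float = -1000.0
    noise_sigma_hu: float = 3.0
    texture_amp_hu: float = 12.0
    texture_lattice_mm: float = 40.0
    n_atlases: int = 3
    deformation_max_mm: float = 8.0
    deformation_lattice_mm: float = 55.0
    rotation_range_deg: float = 6.0
    translation_range_mm: float = 7.0
    remap_scale_range: tuple = (0.92, 1.08)
    remap_offset_range: tuple = (-25.0, 25.0)
    seed: int = 0

    @property
    def targets(self) -> list:
        return [s for s in self.structures if s.target]

    def validate(self) -> None:
        targets = self.targets
        if not targets:
            raise PhantomSpecError("no target organs defined")
        min_r = min(t.shape.min_radius_mm for t in targets)
        if self.deformation_max_mm >= min_r:
            raise PhantomSpecError(
                f"deformation max {self.deformation_max_mm} mm >= smallest organ "
                f"radius {min_r} mm: true transforms would not be invertible"
            )
        pts = self.grid.physical_points().reshape(-1, 3)
        inside = {t.label: t.shape.implicit(pts) < 0 for t in targets}
        labels = list(inside)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if np.any(inside[a] & inside[b]):
                    raise PhantomSpecError(f"target organs '{a}' and '{b}' overlap")


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    return replace(PhantomSpec(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


@dataclass
class AtlasCase:
    volume: ScalarVolume
    masks: list
    true_transform: CompositeTransform     # patient -> atlas space
    inverse_transform: CompositeTransform  # atlas -> patient space


@dataclass
class PhantomCase:
    patient: ScalarVolume
    truth: list
    atlases: list
    spec: PhantomSpec
    seed: int
    confounders: dict = field(default_factory=dict)

    def truth_for(self, label: str) -> BinaryMask:
        for m in self.truth:
            if m.organ_label == label:
                return m
        raise KeyError(label)

    def exact_warped_truth(self, atlas_index: int, label: str) -> BinaryMask:
        """Atlas mask pulled back onto the patient grid analytically:
        the organ's implicit function evaluated at Tinv(T(x))."""
        atlas = self.atlases[atlas_index]
        shape = next(s.shape for s in self.spec.targets if s.label == label)
        pts = self.patient.grid.physical_points().reshape(-1, 3)
        mapped = atlas.inverse_transform.apply_points(atlas.true_transform.apply_points(pts))
        inside = (shape.implicit(mapped) < 0).reshape(self.patient.grid.shape)
        return BinaryMask(self.patient.grid, inside.astype(np.uint8), label)


@dataclass
class _SmoothField:
    """Scalar field on the phantom grid, sampled at arbitrary mm points."""

    grid: VolumeGrid
    values: np.ndarray

    def at(self, points: np.ndarray) -> np.ndarray:
        idx = self.grid.physical_to_index(np.asarray(points, dtype=float)).T
        return ndimage.map_coordinates(
            self.values, idx, order=1, mode="nearest", prefilter=False
        )


def _rasterize(
    spec: PhantomSpec,
    points: np.ndarray,
    jitter: dict | None = None,
    texture: _SmoothField | None = None,
) -> np.ndarray:
    """Paint structures in order; textured ones carry the heterogeneity
    field (evaluated at the same, possibly warped, physical points so it
    travels consistently with each atlas's deformation)."""
    vals = np.full(points.shape[:-1], spec.air_hu)
    tex = texture.at(points) if texture is not None else None
    for s in spec.structures:
        inside = s.shape.implicit(points) < 0
        hu = s.hu + (jitter or {}).get(s.label, 0.0)
        vals[inside] = hu
        if s.textured and tex is not None:
            vals[inside] += tex[inside]
    return vals


def _texture_field(spec: PhantomSpec, rng: np.random.RandomState) -> _SmoothField:
    """Smooth random tissue-heterogeneity field in HU."""
    shape = spec.grid.shape
    extent = [(n - 1) * h for n, h in zip(shape, spec.grid.spacing)]
    coarse = [max(2, int(np.ceil(e / spec.texture_lattice_mm)) + 1) for e in extent]
    field_c = rng.normal(size=tuple(coarse))
    dense = ndimage.zoom(field_c, [n / c for n, c in zip(shape, coarse)], order=3)
    dense *= spec.texture_amp_hu / max(np.abs(dense).max(), 1e-9)
    return _SmoothField(spec.grid, dense)


def _random_displacement(spec: PhantomSpec, rng: np.random.RandomState) -> np.ndarray:
    """Smooth random field (mm) on the phantom grid, max-norm bounded."""
    shape = spec.grid.shape
    extent = [(n - 1) * h for n, h in zip(shape, spec.grid.spacing)]
    coarse = [max(2, int(np.ceil(e / spec.deformation_lattice_mm)) + 1) for e in extent]
    field_c = rng.normal(size=tuple(coarse) + (3,))
    dense = np.stack(
        [
            ndimage.zoom(field_c[..., k], [n / c for n, c in zip(shape, coarse)], order=3)
            for k in range(3)
        ],
        axis=-1,
    )
    mag = np.linalg.norm(dense, axis=-1).max()
    # comparable deformation magnitude across atlases: the reference setting
    # this emulates shows near-identical per-atlas agreement, and label
    # fusion of a few raters presumes raters of similar reliability
    amp = spec.deformation_max_mm * rng.uniform(0.85, 1.0)
    return dense * (amp / max(mag, 1e-9))


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomCase:
    """Build one patient plus ``n_atlases`` deformed, reposed atlas variants."""
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.RandomState(spec.seed & 0x7FFFFFFF)
    grid = spec.grid
    pts = grid.physical_points().reshape(-1, 3)
    center = grid.index_to_physical((np.asarray(grid.shape, dtype=float) - 1) / 2.0)

    texture = _texture_field(spec, rng)
    base = _rasterize(spec, pts, texture=texture).reshape(grid.shape)
    patient = ScalarVolume(grid, base + rng.normal(0.0, spec.noise_sigma_hu, grid.shape))
    truth = [
        BinaryMask(grid, (t.shape.implicit(pts) < 0).reshape(grid.shape).astype(np.uint8), t.label)
        for t in spec.targets
    ]

    atlases = []
    for _ in range(spec.n_atlases):
        disp = DisplacementTransform(grid, _random_displacement(spec, rng))
        angle = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg)
        shift = rng.uniform(-spec.translation_range_mm, spec.translation_range_mm, 3)
        rigid = Affine3D.rotation_z(angle, center)
        rigid = Affine3D(rigid.matrix, shift, rigid.center)
        fwd = CompositeTransform([rigid, disp])                       # patient -> atlas
        inv = CompositeTransform([disp.inverse(), rigid.inverse()])   # atlas -> patient

        jitter = {
            t.label: rng.uniform(-t.hu_jitter, t.hu_jitter) for t in spec.targets
        }
        a, b = (
            rng.uniform(*spec.remap_scale_range),
            rng.uniform(*spec.remap_offset_range),
        )
        noise = rng.normal(0.0, spec.noise_sigma_hu, grid.shape)

        mapped = inv.apply_points(pts)
        jittered = _rasterize(spec, mapped, jitter, texture=texture)
        outside = np.any(
            (grid.physical_to_index(mapped) < -0.5)
            | (grid.physical_to_index(mapped) > np.asarray(grid.shape) - 0.5),
            axis=-1,
        )
        jittered[outside] = spec.air_hu
        vol = ScalarVolume(grid, (a * jittered.reshape(grid.shape) + b) + noise)
        masks = [
            BinaryMask(
                grid,
                (t.shape.implicit(mapped) < 0).reshape(grid.shape).astype(np.uint8),
                t.label,
            )
            for t in spec.targets
        ]
        atlases.append(AtlasCase(vol, masks, fwd, inv))
    return PhantomCase(patient, truth, atlases, spec, spec.seed)


# ---------------------------------------------------------------------------
# confounders (patient-side perturbations with recorded regions)
# ---------------------------------------------------------------------------


def add_confounder(case: PhantomCase, kind: str, organ: str | None = None) -> PhantomCase:
    """Insert a named confounder into the patient volume only.

    The affected region is recorded in ``confounders[kind]`` for targeted
    assertions.  Atlases are untouched: the confounder exists only in the
    patient, as implants, gas and motion artifacts do.
    """
    out = copy.deepcopy(case)
    grid = case.patient.grid
    pts = grid.physical_points().reshape(-1, 3)
    vals = out.patient.values

    if kind == "artifact_blob":
        blob = Ellipsoid((80, 44, 64), (6, 6, 6))
        region = (blob.implicit(pts) < 0).reshape(grid.shape)
        for t in case.spec.targets:
            if np.any(region & out.truth_for(t.label).bool):
                raise PhantomSpecError("artifact blob intersects a target organ")
        vals[region] = 1500.0
    elif kind == "blurred_pole":
        # motion blur flattens the HU of the organ's superior border layer
        # toward the background: outside the organ's intensity envelope but
        # with only a soft internal gradient, over a wide shallow dome
        organ = organ or "kidney_left"
        tr = out.truth_for(organ).bool
        shape = next(s.shape for s in case.spec.targets if s.label == organ)
        organ_hu = next(s.hu for s in case.spec.structures if s.label == organ)
        depth = ndimage.distance_transform_edt(tr, sampling=grid.spacing)
        z_phys = grid.physical_points()[..., 2]
        z_split = shape.center[2] + 0.45 * shape.semi_axes[2]
        cap = tr & (depth <= 1.05 * max(grid.spacing)) & (z_phys >= z_split)
        noise = vals[cap] - organ_hu  # keep a trace of the original noise
        vals[cap] = (organ_hu - 14.0) + 0.3 * noise
        region = cap
    elif kind == "attached_blob":
        organ = organ or "spleen"
        shape = next(s.shape for s in case.spec.targets if s.label == organ)
        c = np.asarray(shape.center, dtype=float)
        blob = Ellipsoid(tuple(c + np.array([0.0, -shape.semi_axes[1], 0.0])), (9, 8, 9))
        tr = out.truth_for(organ).bool
        region = (blob.implicit(pts) < 0).reshape(grid.shape) & ~tr
        vals[region] = 110.0
    elif kind == "missing_organ":
        organ = organ or "lung_left"
        tr = out.truth_for(organ).bool
        body_hu = next(s.hu for s in case.spec.structures if s.label == "body")
        rng = np.random.RandomState((case.seed + 7919) & 0x7FFFFFFF)
        vals[tr] = body_hu + rng.normal(0.0, case.spec.noise_sigma_hu, int(tr.sum()))
        region = tr
    else:
        raise ValueError(f"unknown confounder kind '{kind}'")

    out.patient = ScalarVolume(grid, vals)
    out.confounders[kind] = region
    return out
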