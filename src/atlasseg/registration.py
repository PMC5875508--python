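"""Atlas-to-patient registration: two-phase affine then masked
multi-resolution B-spline deformable alignment, both driven by Mattes
mutual information (MI).

The affine stage is initialized by matching intensity centres of mass and
optimized by a regular-step gradient descent in two 30-iteration phases:
translations only first (posture/couch shifts dominate), then the full
12-parameter affine.  The deformable stage refines a cubic B-spline
free-form deformation over four control-lattice resolutions (100 -> 20 mm
node spacing) with LBFGS, evaluating the metric only at fixed-image samples
whose mapped point falls inside the union of atlas organ masks dilated by a
10 mm margin — irrelevant high-contrast regions (implants, bowel gas) are
thereby excluded from the match.

:func:`mattes_mi` is a self-contained numpy estimator of the (negated)
Mattes MI — zero-order Parzen window on the fixed intensities, cubic
B-spline window on the moving — exposed for diagnostics and testing; the
optimizers use SimpleITK's implementation of the same metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import MaskCoverageError, MetricDegenerateError
from .imaging import BinaryMask, ScalarVolume, VolumeGrid, dilate_mask, resample
from .io import to_sitk, to_sitk_mask
from .transforms import Affine3D, BSplineFFD, CompositeTransform

__all__ = [
    "MIMetricConfig",
    "RegistrationConfig",
    "mattes_mi",
    "register_affine",
    "register_bspline",
    "warp_atlas_labels",
]


@dataclass
class MIMetricConfig:
    """Sampling and binning of the MI metric.

    20 histogram bins and a 0.5 sampling fraction are the affine-stage
    defaults; the deformable stage densifies to 32 bins at full sampling
    since far more parameters are optimized.
    """

    histogram_bins: int = 20
    sampling_fraction: float = 0.5
    fixed_mask: BinaryMask | None = None
    moving_mask: BinaryMask | None = None
    seed: int = 0

    def __post_init__(self):
        if self.histogram_bins < 2:
            raise ValueError("need >= 2 histogram bins")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling fraction must be in (0, 1]")


@dataclass
class RegistrationConfig:
    """Numeric knobs of both registration stages (defaults as documented)."""

    affine_bins: int = 20
    affine_sampling: float = 0.5
    affine_iterations: int = 30          # per phase and resolution level
    affine_max_step_mm: float = 10.0     # trust region per optimizer step
    affine_min_step: float = 1e-5
    affine_relaxation: float = 0.7
    affine_shrink_factors: tuple = (4, 2, 1)
    affine_smoothing_sigmas: tuple = (2.0, 1.0, 0.0)  # in voxels per level
    affine_use_mask: bool = False        # whole-image affine by default
    bspline_bins: int = 32
    bspline_sampling: float = 1.0
    stage_spacings_mm: tuple = (100.0, 73.0, 40.0, 20.0)
    # per-stage image shrink and Gaussian smoothing (voxels): quasi-Newton
    # line searches fail on the noise-rough MI surface of the raw images
    bspline_shrink_factors: tuple = (2, 2, 1, 1)
    bspline_smoothing_sigmas: tuple = (2.0, 1.0, 1.0, 1.0)
    stage_iterations: int = 100
    lbfgs_memory: int = 5
    lbfgs_gradient_tol: float = 1e-7
    mask_margin_mm: float = 10.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Mattes mutual information (numpy estimator)
# ---------------------------------------------------------------------------


def _cubic_bspline_kernel(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline Parzen window, support |u| < 2, integral 1."""
    au = np.abs(u)
    w = np.zeros_like(au)
    m1 = au < 1
    m2 = (au >= 1) & (au < 2)
    w[m1] = (4.0 - 6.0 * au[m1] ** 2 + 3.0 * au[m1] ** 3) / 6.0
    w[m2] = (2.0 - au[m2]) ** 3 / 6.0
    return w


def mattes_mi(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    transform=None,
    cfg: MIMetricConfig | None = None,
) -> float:
    """Negated Mattes mutual information (lower = better match), in nats.

    Fixed-image voxels are sampled uniformly at random (seeded, fixed per
    call), mapped through ``transform`` into moving space, and samples whose
    mapped point falls outside the moving image domain (or outside
    ``cfg.moving_mask``) are ignored.  The joint histogram uses a zero-order
    window on fixed intensities and a cubic B-spline window on linearly
    interpolated moving intensities.
    """
    cfg = cfg or MIMetricConfig()
    bins = cfg.histogram_bins
    rng = np.random.RandomState(cfg.seed)

    fixed_idx = np.argwhere(
        cfg.fixed_mask.bool if cfg.fixed_mask is not None else np.ones(fixed.grid.shape, bool)
    )
    n = len(fixed_idx)
    if cfg.sampling_fraction < 1.0:
        take = max(1, int(round(n * cfg.sampling_fraction)))
        fixed_idx = fixed_idx[rng.choice(n, size=take, replace=False)]

    pts = fixed.grid.index_to_physical(fixed_idx)
    if transform is not None:
        pts = transform.apply_points(pts)
    midx = moving.grid.physical_to_index(pts)

    # discard samples mapped outside the moving domain
    inside = np.all((midx >= 0) & (midx <= np.array(moving.grid.shape) - 1), axis=1)
    if cfg.moving_mask is not None:
        from scipy import ndimage as _ndi

        inmask = (
            _ndi.map_coordinates(
                cfg.moving_mask.values.astype(np.float64),
                midx.T, order=0, mode="constant", cval=0.0,
            )
            > 0.5
        )
        inside &= inmask
    if inside.sum() < bins * bins:
        raise MetricDegenerateError(
            f"only {int(inside.sum())} valid metric samples for {bins}^2 joint bins"
        )
    fixed_idx, midx = fixed_idx[inside], midx[inside]

    from scipy import ndimage as _ndi

    fvals = fixed.values[tuple(fixed_idx.T)]
    mvals = _ndi.map_coordinates(moving.values, midx.T, order=1, prefilter=False)

    fmin, fmax = fixed.values.min(), fixed.values.max()
    mmin, mmax = moving.values.min(), moving.values.max()
    fwidth = (fmax - fmin) / bins or 1.0
    mwidth = (mmax - mmin) / bins or 1.0

    fbin = np.clip(((fvals - fmin) / fwidth).astype(int), 0, bins - 1)
    mpos = (mvals - mmin) / mwidth - 0.5  # continuous bin coordinate

    joint = np.zeros((bins, bins))
    base = np.floor(mpos).astype(int)
    for off in (-1, 0, 1, 2):
        b = base + off
        w = _cubic_bspline_kernel(mpos - b)
        np.add.at(joint, (fbin, np.clip(b, 0, bins - 1)), w)
    joint /= joint.sum()

    pf = joint.sum(axis=1, keepdims=True)
    pm = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (pf @ pm)[nz])))
    return -mi


# ---------------------------------------------------------------------------
# registration drivers (SimpleITK backend)
# ---------------------------------------------------------------------------


def _base_method(bins, sampling, seed) -> sitk.ImageRegistrationMethod:
    R = sitk.ImageRegistrationMethod()
    R.SetMetricAsMattesMutualInformation(bins)
    if sampling < 1.0:
        # REGULAR keeps the sample set fixed for the whole run: a
        # re-drawn random subset per iteration makes the regular-step
        # optimizer relax its step on every noisy gradient flip
        R.SetMetricSamplingStrategy(R.REGULAR)
        # seed 0 means wall-clock in sitk: keep runs reproducible
        R.SetMetricSamplingPercentage(sampling, int(seed) + 1)
    else:
        R.SetMetricSamplingStrategy(R.NONE)
    R.SetInterpolator(sitk.sitkLinear)
    return R


def register_affine(
    fixed: ScalarVolume, moving: ScalarVolume, cfg: RegistrationConfig | None = None
) -> Affine3D:
    """Two-phase affine alignment.

    Initialization matches grey-value centres of mass; phase 1 optimizes
    translations only (30 iterations of regular-step gradient descent),
    phase 2 releases all 12 parameters (shear, scale, rotation, translation)
    for another 30 iterations with physical-shift parameter scales.
    """
    cfg = cfg or RegistrationConfig()
    if fixed.values.std() == 0 or moving.values.std() == 0:
        raise MetricDegenerateError("constant image cannot drive MI registration")
    f_img = to_sitk(fixed, sitk.sitkFloat32)
    m_img = to_sitk(moving, sitk.sitkFloat32)

    tx = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    tx = sitk.AffineTransform(tx)

    for phase in (1, 2):
        R = _base_method(cfg.affine_bins, cfg.affine_sampling, cfg.seed)
        R.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0,
            minStep=cfg.affine_min_step,
            numberOfIterations=cfg.affine_iterations,
            relaxationFactor=cfg.affine_relaxation,
            gradientMagnitudeTolerance=1e-10,
            estimateLearningRate=R.EachIteration,
            maximumStepSizeInPhysicalUnits=cfg.affine_max_step_mm,
        )
        R.SetOptimizerScalesFromPhysicalShift()
        R.SetShrinkFactorsPerLevel(list(cfg.affine_shrink_factors))
        R.SetSmoothingSigmasPerLevel(list(cfg.affine_smoothing_sigmas))
        R.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        R.SetInitialTransform(tx, inPlace=True)
        if phase == 1:
            # 9 matrix parameters frozen, 3 translations active
            R.SetOptimizerWeights([0.0] * 9 + [1.0] * 3)
        try:
            R.Execute(f_img, m_img)
        except RuntimeError as exc:  # pragma: no cover - optimizer pathologies
            warnings.warn(f"affine phase {phase} stopped early: {exc}")
    return Affine3D.from_sitk(tx)


def register_bspline(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    init: Affine3D,
    moving_organ_masks: list,
    cfg: RegistrationConfig | None = None,
) -> CompositeTransform:
    """Masked multi-resolution B-spline registration on top of ``init``.

    Four stages refine the control lattice from 100 mm to 20 mm node
    spacing; each stage optimizes a fresh zero-initialized FFD composed
    under the frozen transforms of earlier stages (exact preservation of the
    current displacement field), using LBFGS against Mattes MI restricted to
    the dilated union of the atlas organ masks in moving space.
    """
    cfg = cfg or RegistrationConfig()
    if not moving_organ_masks:
        raise MaskCoverageError("no organ masks supplied for the metric mask")
    union = np.zeros(moving.grid.shape, np.uint8)
    labels = []
    for m in moving_organ_masks:
        union |= m.values
        labels.append(m.organ_label)
    if not union.any():
        raise MaskCoverageError(f"all organ masks empty: {labels}")
    mask = dilate_mask(BinaryMask(moving.grid, union, "union"), cfg.mask_margin_mm)

    f_img = to_sitk(fixed, sitk.sitkFloat32)
    m_img = to_sitk(moving, sitk.sitkFloat32)
    mask_img = to_sitk_mask(mask)

    shrinks = cfg.bspline_shrink_factors or (1,) * len(cfg.stage_spacings_mm)
    smooths = cfg.bspline_smoothing_sigmas or (0.0,) * len(cfg.stage_spacings_mm)
    stages = [init]
    for stage_index, spacing in enumerate(cfg.stage_spacings_mm):
        ffd = BSplineFFD.initialize(f_img, spacing)
        R = _base_method(cfg.bspline_bins, cfg.bspline_sampling, cfg.seed)
        R.SetMetricMovingMask(mask_img)
        R.SetOptimizerAsLBFGSB(
            gradientConvergenceTolerance=cfg.lbfgs_gradient_tol,
            numberOfIterations=cfg.stage_iterations,
            maximumNumberOfCorrections=cfg.lbfgs_memory,
        )
        R.SetShrinkFactorsPerLevel([int(shrinks[min(stage_index, len(shrinks) - 1)])])
        R.SetSmoothingSigmasPerLevel([float(smooths[min(stage_index, len(smooths) - 1)])])
        R.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        if stage_index == 0:
            frozen = init.as_sitk()
        else:
            # prior FFD stages are frozen into a dense displacement field for
            # the metric: ITK has no position Jacobian for B-spline transforms
            # inside the initial-transform chain.  The returned composite
            # keeps the exact B-spline stages; only the gradient computation
            # sees the (voxel-sampled) field, whose interpolation error on
            # these smooth fields is far below the lattice resolution.
            from .transforms import dense_sitk_displacement

            field = dense_sitk_displacement(
                CompositeTransform(stages).as_sitk(), fixed.grid
            )
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(field.transpose(2, 1, 0, 3)), isVector=True
            )
            img.SetSpacing(tuple(fixed.grid.spacing))
            img.SetOrigin(tuple(fixed.grid.origin))
            img.SetDirection(tuple(fixed.grid.direction.flatten()))
            frozen = sitk.DisplacementFieldTransform(
                sitk.Cast(img, sitk.sitkVectorFloat64)
            )
        R.SetMovingInitialTransform(frozen)
        R.SetInitialTransform(ffd.as_sitk(), inPlace=True)
        try:
            R.Execute(f_img, m_img)
        except RuntimeError as exc:
            msg = str(exc)
            if "samples map inside" in msg or "sample" in msg.lower():
                raise MaskCoverageError(
                    f"no valid metric samples inside the mask for organs {labels} "
                    f"at stage spacing {spacing} mm"
                ) from exc
            raise
        stages.append(ffd)
    return CompositeTransform(stages)


def warp_atlas_labels(
    atlas_masks: list, transform, patient_grid: VolumeGrid
) -> list:
    """Resample atlas organ masks onto the patient grid (nearest neighbour)."""
    ref = sitk.Image([int(s) for s in patient_grid.shape], sitk.sitkUInt8)
    ref.SetSpacing(tuple(patient_grid.spacing))
    ref.SetOrigin(tuple(patient_grid.origin))
    ref.SetDirection(tuple(patient_grid.direction.flatten()))
    out = []
    for m in atlas_masks:
        res = sitk.Resample(
            to_sitk_mask(m), ref, transform.as_sitk(), sitk.sitkNearestNeighbor, 0.0
        )
        arr = sitk.GetArrayFromImage(res).transpose(2, 1, 0)
        out.append(BinaryMask(patient_grid, arr, m.organ_label))
    return out
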