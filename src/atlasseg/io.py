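"""Volume I/O: NIfTI-1 read/write (nibabel), SimpleITK interop, DICOM series.

Grid geometry round-trips losslessly through the NIfTI affine: the affine's
3x3 block is ``direction @ diag(spacing)`` and its translation column is the
origin, in the package's own physical frame.  Masks are stored as uint8
label volumes, one file per organ (canonical) — a multi-label volume can be
split with :func:`split_labels`.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .imaging import BinaryMask, ScalarVolume, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dicom_series",
    "split_labels",
    "grid_from_affine",
    "affine_from_grid",
    "to_sitk",
    "from_sitk",
]


def affine_from_grid(grid: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = grid.index_to_physical_matrix
    aff[:3, 3] = grid.origin
    return aff


def grid_from_affine(shape, affine: np.ndarray) -> VolumeGrid:
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    direction = lin / spacing
    return VolumeGrid(tuple(shape), tuple(spacing), tuple(affine[:3, 3]), direction)


def read_volume(path: str) -> ScalarVolume:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return ScalarVolume(grid_from_affine(data.shape, img.affine), data)


def write_volume(vol, path: str, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), affine_from_grid(vol.grid))
    nib.save(img, path)


def read_mask(path: str, organ_label: str = "") -> BinaryMask:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if not organ_label:
        organ_label = os.path.basename(path).split(".")[0]
    return BinaryMask(
        grid_from_affine(data.shape, img.affine), (data > 0).astype(np.uint8), organ_label
    )


def write_mask(mask: BinaryMask, path: str) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine_from_grid(mask.grid))
    nib.save(img, path)


def split_labels(path: str, label_names: dict) -> list:
    """Split a multi-label uint volume into per-organ binary masks.

    ``label_names`` maps integer label value -> organ name.
    """
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    grid = grid_from_affine(data.shape, img.affine)
    return [
        BinaryMask(grid, (data == lab).astype(np.uint8), name)
        for lab, name in sorted(label_names.items())
    ]


def read_dicom_series(directory: str) -> ScalarVolume:
    """Read a single-series DICOM CT directory via SimpleITK."""
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(directory)
    if not files:
        raise FileNotFoundError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    return from_sitk(reader.Execute())


# ---------------------------------------------------------------------------
# SimpleITK interop.  sitk indexes (x, y, z) with arrays returned as
# [z, y, x]; the package's index axis 0 is mapped to sitk's x axis.
# ---------------------------------------------------------------------------


def to_sitk(vol, dtype=sitk.sitkFloat64) -> sitk.Image:
    arr = np.ascontiguousarray(np.asarray(vol.values, dtype=np.float64).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(vol.grid.spacing))
    img.SetOrigin(tuple(vol.grid.origin))
    img.SetDirection(tuple(vol.grid.direction.flatten()))
    if dtype is not None:
        img = sitk.Cast(img, dtype)
    return img


def to_sitk_mask(mask: BinaryMask) -> sitk.Image:
    return sitk.Cast(to_sitk(mask), sitk.sitkUInt8)


def sitk_grid(img: sitk.Image) -> VolumeGrid:
    return VolumeGrid(
        tuple(img.GetSize()),
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
        np.array(img.GetDirection()).reshape(3, 3),
    )


def from_sitk(img: sitk.Image) -> ScalarVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return ScalarVolume(sitk_grid(img), arr)
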