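import numpy as np
import pytest
import SimpleITK as sitk

from atlasseg.imaging import BinaryMask, ScalarVolume, VolumeGrid
from atlasseg.phantom import PhantomSpec, generate_phantom

# single-threaded ITK keeps runs bit-reproducible and mirrors deployment
sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)

ORGANS = ["liver", "spleen", "kidney_left", "kidney_right", "lung_left"]


@pytest.fixture(scope="session")
def standard_case():
    """The standard 3-atlas phantom used across the suite (seed 7)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def segment_run(standard_case):
    """One full pipeline run on the standard phantom, shared by the
    end-to-end tests (registration is the expensive step)."""
    from atlasseg.pipeline import AtlasLibrary, SegmentationConfig, segment

    library = AtlasLibrary.from_phantom(standard_case)
    config = SegmentationConfig(seed=7)
    masks, report, intermediates = segment(
        standard_case.patient, library, None, config, return_intermediates=True
    )
    return {
        "case": standard_case,
        "masks": {m.organ_label: m for m in masks},
        "report": report,
        "intermediates": intermediates,
        "config": config,
    }


@pytest.fixture
def unit_grid():
    return VolumeGrid((16, 16, 16), (1.0, 1.0, 1.0))


@pytest.fixture
def ball_volume():
    """HU-60 ball of radius 25 mm in a -100 background on a 48^3 grid."""
    grid = VolumeGrid((48, 48, 48), (2.5, 2.5, 2.5))
    pts = grid.physical_points()
    c = np.array([58.75] * 3)
    r = np.linalg.norm(pts - c, axis=-1)
    vol = ScalarVolume(grid, np.where(r < 25, 60.0, -100.0))
    truth = BinaryMask(grid, (r < 25).astype(np.uint8), "ball")
    return vol, truth


def random_blob(shape, spacing, seed, p=0.5, smooth=1):
    """Random connected-ish blob mask for oracle comparisons."""
    from scipy import ndimage

    rng = np.random.RandomState(seed)
    raw = rng.rand(*shape) < p
    blob = ndimage.binary_closing(raw, iterations=smooth)
    blob = ndimage.binary_opening(blob, iterations=smooth)
    if not blob.any():
        blob[tuple(s // 2 for s in shape)] = True
    return blob
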