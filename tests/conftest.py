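import nibabel as nib
import numpy as np
import pytest

from dynparc.io import BoldRun


def make_run(data, shape=None, affine=None, tr=2.2, run_id="run"):
    """BoldRun over a full-grid mask whose voxel count matches ``data`` rows."""
    data = np.asarray(data, dtype=float)
    if shape is None:
        shape = (data.shape[0], 1, 1)
    mask = np.ones(shape, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    return BoldRun(data=data, affine=affine, mask=mask, tr_seconds=tr,
                   run_id=run_id)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_bold_files(tmp_path):
    """A (10, 10, 10, 50) BOLD NIfTI plus a 400-voxel mask on disk."""
    rng = np.random.default_rng(0)
    vol = rng.standard_normal((10, 10, 10, 50))
    mask = np.zeros((10, 10, 10), dtype=np.uint8)
    mask.ravel()[:400] = 1
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    bold_path = tmp_path / "bold.nii.gz"
    mask_path = tmp_path / "mask.nii.gz"
    nib.save(nib.Nifti1Image(vol, affine), str(bold_path))
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))
    return bold_path, mask_path, vol, mask.astype(bool), affine
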