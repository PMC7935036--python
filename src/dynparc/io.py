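"""NIfTI input/output and signal conditioning for masked BOLD runs.

A run is held as a dense ``voxels x frames`` matrix whose rows follow a
fixed C-order linearization of the in-mask voxels (iterate i, then j, then
k; numpy's default ravel order).  Every downstream module — window
parcellation, seed binarization, stability maps — indexes voxels through
this same linearization, so map vectors are comparable across modules and
across runs sharing a mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from nilearn.image import smooth_img


class GridMismatchError(ValueError):
    """Volumes do not share shape/affine."""


class DataError(ValueError):
    """Non-finite or otherwise unusable voxel data."""


@dataclass
class BoldRun:
    """Masked BOLD time series with spatial metadata.

    Attributes
    ----------
    data : ndarray, shape (n_voxels, n_frames)
        One row per in-mask voxel (C-order linearization of the mask),
        one column per time frame.
    affine : ndarray, shape (4, 4)
        Voxel-index to MNI-millimetre transform.
    mask : ndarray of bool, 3D
        Brain mask on the acquisition grid.
    tr_seconds : float
        Repetition time in seconds.
    run_id : str
        Opaque label used in reports.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    tr_seconds: float
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D voxels x frames matrix")
        n_mask = int(self.mask.sum())
        if self.data.shape[0] != n_mask:
            raise GridMismatchError(
                f"data has {self.data.shape[0]} rows but mask has {n_mask} voxels"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("non-finite values inside the mask")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class PreprocParams:
    """Light preprocessing applied on load: smoothing, standardization, censoring."""

    standardize: bool = True
    smoothing_fwhm_mm: float = 6.0
    censor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")


@dataclass
class SeedSpec:
    """A named seed: MNI mm coordinates resolved to a masked-row index."""

    mni_mm: tuple[float, float, float]
    voxel_index: int
    name: str = "seed"
    snapped: bool = False  # True when the point fell outside the mask


# ---------------------------------------------------------------------------
# masking / unmasking


def mask_volume(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract in-mask values in C-order. 4-D input yields voxels x frames."""
    mask = np.asarray(mask).astype(bool)
    if vol.shape[: mask.ndim] != mask.shape:
        raise GridMismatchError("volume and mask shapes differ")
    return np.asarray(vol)[mask]


def unmask_vector(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Place a per-voxel vector back onto the 3-D grid (``fill`` elsewhere)."""
    mask = np.asarray(mask).astype(bool)
    values = np.asarray(values)
    if values.shape[0] != int(mask.sum()):
        raise ValueError("one value per in-mask voxel required")
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = values
    return out


# ---------------------------------------------------------------------------
# loading


def load_run(
    bold_path: str | Path,
    mask_path: str | Path,
    tr_seconds: float = 2.2,
    preproc: PreprocParams | None = None,
    run_id: str | None = None,
) -> BoldRun:
    """Load a 4-D BOLD NIfTI, mask it, and optionally smooth/standardize/censor.

    Raises
    ------
    GridMismatchError
        If the BOLD and mask grids or affines disagree.
    DataError
        If the mask is empty or in-mask voxels contain non-finite values.
    """
    img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    if img.shape[:3] != mask.shape:
        raise GridMismatchError(
            f"BOLD grid {img.shape[:3]} != mask grid {mask.shape}"
        )
    if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
        raise GridMismatchError("BOLD and mask affines disagree")
    if mask.sum() == 0:
        raise DataError("mask contains no voxels")

    preproc = preproc or PreprocParams(standardize=False, smoothing_fwhm_mm=0.0)
    if preproc.smoothing_fwhm_mm > 0:
        img = smooth_img(img, fwhm=preproc.smoothing_fwhm_mm)
    vol = np.asanyarray(img.dataobj)
    if vol.ndim == 3:
        vol = vol[..., np.newaxis]
    data = mask_volume(vol, mask).astype(float)
    run = BoldRun(
        data=data,
        affine=np.asarray(img.affine, dtype=float),
        mask=mask,
        tr_seconds=tr_seconds,
        run_id=run_id or Path(bold_path).name,
    )
    if preproc.censor_mask is not None:
        run = apply_censor(run, preproc.censor_mask)
    if preproc.standardize:
        run = standardize(run)
    return run


# ---------------------------------------------------------------------------
# signal conditioning


def standardize(run: BoldRun) -> BoldRun:
    """Scale each voxel's time series to zero mean, unit sample variance.

    Zero-variance (constant) voxels map to all-zero rows rather than NaN, so
    downstream k-means sees finite features everywhere.
    """
    if run.n_frames < 2:
        raise DataError("standardization needs at least 2 frames")
    data = run.data
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    # sample (ddof=1) variance, matching the unit-variance convention
    sd = centered.std(axis=1, ddof=1, keepdims=True)
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return replace(run, data=out)


def smooth(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Gaussian-smooth each frame on the full grid, then re-mask.

    Smoothing happens on the unmasked volume (out-of-mask voxels are zero),
    with a truncated kernel and no renormalization at boundaries.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return run
    vol = np.zeros(run.mask.shape + (run.n_frames,), dtype=float)
    vol[run.mask] = run.data
    img = nib.Nifti1Image(vol, run.affine)
    sm = np.asanyarray(smooth_img(img, fwhm=fwhm_mm).dataobj)
    return replace(run, data=sm[run.mask])


def apply_censor(run: BoldRun, censor_mask: Sequence[int] | np.ndarray) -> BoldRun:
    """Drop frames flagged 0 in the censor (scrubbing) mask, keeping order."""
    keep = np.asarray(censor_mask).astype(bool)
    if keep.shape != (run.n_frames,):
        raise ValueError(
            f"censor mask has {keep.size} entries for {run.n_frames} frames"
        )
    if not keep.any():
        raise DataError("censor mask drops every frame")
    return replace(run, data=run.data[:, keep])


def concatenate_runs(runs: Sequence[BoldRun]) -> BoldRun:
    """Concatenate runs along time. Masks, affines and TR must agree."""
    if not runs:
        raise ValueError("no runs to concatenate")
    first = runs[0]
    for r in runs[1:]:
        if r.mask.shape != first.mask.shape or not np.array_equal(r.mask, first.mask):
            raise GridMismatchError("masks differ across runs")
        if not np.allclose(r.affine, first.affine, atol=1e-4):
            raise GridMismatchError("affines differ across runs")
        if not np.isclose(r.tr_seconds, first.tr_seconds):
            raise GridMismatchError("TR differs across runs")
    data = np.concatenate([r.data for r in runs], axis=1)
    return replace(first, data=data, run_id="+".join(r.run_id for r in runs))


# ---------------------------------------------------------------------------
# coordinates


def run_boundaries(runs: Sequence[BoldRun]) -> list[int]:
    """Frame indices at which a new run starts within the concatenation."""
    bounds, offset = [], 0
    for r in runs[:-1]:
        offset += r.n_frames
        bounds.append(offset)
    return bounds


def mni_to_voxel(
    affine: np.ndarray,
    mask: np.ndarray,
    mni_mm: Sequence[float],
    max_snap_mm: float = 10.0,
) -> tuple[tuple[int, int, int], bool]:
    """Resolve an MNI mm point to a 3-D in-mask voxel index.

    Returns ``((i, j, k), snapped)`` where ``snapped`` is True when the
    nearest voxel center was outside the mask and the nearest in-mask voxel
    (Euclidean mm distance, ties toward the smaller linear index) was used
    instead.

    Raises
    ------
    ValueError
        If the point lies farther than ``max_snap_mm`` from any in-mask voxel.
    """
    mask = np.asarray(mask).astype(bool)
    inv = np.linalg.inv(affine)
    pt = np.asarray(mni_mm, dtype=float)
    ijk = inv @ np.append(pt, 1.0)
    # round half toward the lower index for deterministic tie-breaking
    vox = np.ceil(ijk[:3] - 0.5).astype(int)
    in_grid = np.all((vox >= 0) & (vox < np.array(mask.shape)))
    if in_grid and mask[tuple(vox)]:
        return tuple(int(v) for v in vox), False
    # snap to the nearest in-mask voxel center in mm
    idx = np.argwhere(mask)
    centers = (affine @ np.c_[idx, np.ones(len(idx))].T)[:3].T
    d = np.linalg.norm(centers - pt, axis=1)
    best = int(np.argmin(d))  # argmin takes the first = lowest linear index
    if d[best] > max_snap_mm:
        raise ValueError(
            f"point {tuple(pt)} is {d[best]:.1f} mm from the nearest in-mask "
            f"voxel (limit {max_snap_mm} mm)"
        )
    return tuple(int(v) for v in idx[best]), True


def _grid_to_row(vox: tuple[int, int, int], mask: np.ndarray) -> int:
    """Map a 3-D in-mask voxel index to its row in the masked matrix."""
    if not mask[vox]:
        raise ValueError(f"voxel {vox} is outside the mask")
    flat = np.ravel_multi_index(vox, mask.shape)
    return int(np.cumsum(mask.ravel())[flat] - 1)


def resolve_seed(
    affine: np.ndarray,
    mask: np.ndarray,
    mni_mm: Sequence[float],
    name: str = "seed",
    max_snap_mm: float = 10.0,
) -> SeedSpec:
    vox, snapped = mni_to_voxel(affine, mask, mni_mm, max_snap_mm=max_snap_mm)
    return SeedSpec(mni_mm=tuple(float(x) for x in mni_mm),
                    voxel_index=_grid_to_row(vox, np.asarray(mask).astype(bool)),
                    name=name, snapped=snapped)


# ---------------------------------------------------------------------------
# writing


def save_map(
    values: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
) -> Path:
    """Write a per-voxel vector as a 3-D NIfTI (zeros outside the mask)."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise DataError("cannot write a map for an empty mask")
    vol = unmask_vector(np.asarray(values, dtype=float), mask)
    img = nib.Nifti1Image(vol, np.asarray(affine, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_censor_tsv(path: str | Path) -> np.ndarray:
    """Read a one-column TSV of 0/1 keep flags, one row per frame."""
    flags = np.loadtxt(str(path), dtype=int, ndmin=1)
    if flags.ndim != 1 or not np.isin(flags, (0, 1)).all():
        raise ValueError("censor TSV must be a single column of 0/1")
    return flags


def load_seeds_json(path: str | Path) -> list[dict]:
    """Read a JSON list of ``{"name": ..., "mni_mm": [x, y, z]}`` seeds."""
    with open(path) as fh:
        seeds = json.load(fh)
    if not isinstance(seeds, list):
        raise ValueError("seeds file must contain a JSON list")
    for s in seeds:
        if "name" not in s or "mni_mm" not in s or len(s["mni_mm"]) != 3:
            raise ValueError("each seed needs 'name' and a 3-vector 'mni_mm'")
    return seeds
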