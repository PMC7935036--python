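"""Synthetic 4-D BOLD-like data with planted, switching parcellations.

The generator emulates the statistical structure the state-detection
pipeline assumes: voxels on a regular grid group into k contiguous parcels
(random Voronoi cells) that share a latent smooth time course, and the
active partition switches between a small number of recurring spatial
configurations ("states") in contiguous segments.  A subject is identified
by its set of partitions; independent replication sets reuse the partitions
but resample the state sequence and latent courses.  Gaussian noise is
added relative to the unit-variance parcel signals.

Planted seed parcels of different states are required to have pairwise Dice
below a separation bound (default 0.3, the state-clustering threshold), by
rejection sampling, so that recovering the planted states is well-posed.

No hemodynamic convolution or physiological confounds are modeled: the
target is the clustering structure of preprocessed signals, not biophysics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linear_sum_assignment

from .io import BoldRun
from .states import dice
from .stability import StabilityMap


@dataclass
class SyntheticSpec:
    """Parameters of the planted-state simulation.

    Defaults mirror the regime the pipeline targets: a 12x12x12 grid at
    3 mm, two states with 60/40 dwell, 12 parcels per state, segments of
    about 200 frames (~7 min at TR 2.2 s), a 4050-frame series (the length
    of five 810-frame sessions, ~2.5 h), and noise at 0.3 of the
    unit-variance parcel signal.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    n_states: int = 2
    k_true: int = 12
    dwell_targets: tuple[float, ...] = (0.6, 0.4)
    segment_length_frames: int = 200
    n_frames: int = 4050
    n_subjects: int = 1
    n_sets_per_subject: int = 1
    noise_sigma: float = 0.3
    rng_seed: int = 0
    tr_seconds: float = 2.2
    seed_voxel_ijk: tuple[int, int, int] | None = None  # default: grid center
    dice_separation: float = 0.3
    latent_smooth_frames: float = 2.0
    max_partition_retries: int = 500

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if len(self.dwell_targets) != self.n_states:
            raise ValueError("one dwell target per state required")
        if abs(sum(self.dwell_targets) - 1.0) > 1e-9:
            raise ValueError("dwell_targets must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def seed_ijk(self) -> tuple[int, int, int]:
        if self.seed_voxel_ijk is not None:
            return self.seed_voxel_ijk
        return tuple(s // 2 for s in self.grid_shape)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def mask(self) -> np.ndarray:
        return np.ones(self.grid_shape, dtype=bool)

    @property
    def seed_row(self) -> int:
        """Masked-row index of the seed voxel (full-grid mask, C-order)."""
        return int(np.ravel_multi_index(self.seed_ijk, self.grid_shape))


@dataclass
class GroundTruth:
    """Planted partitions, seed parcels, and the per-frame state sequence."""

    partitions: np.ndarray  # (n_states, n_voxels) parcel label per voxel
    seed_parcels: np.ndarray  # (n_states, n_voxels) binary seed-parcel maps
    state_sequence: np.ndarray  # (n_frames,) active state id per frame
    subject_id: str = "sub-01"

    @property
    def n_states(self) -> int:
        return self.partitions.shape[0]

    def realized_dwell(self) -> np.ndarray:
        counts = np.bincount(self.state_sequence, minlength=self.n_states)
        return counts / len(self.state_sequence)


def _voronoi_partition(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Contiguous k-parcel labeling: nearest of k distinct random centers."""
    n_vox = int(np.prod(spec.grid_shape))
    centers_flat = rng.choice(n_vox, size=spec.k_true, replace=False)
    centers = np.array(np.unravel_index(centers_flat, spec.grid_shape)).T
    coords = np.indices(spec.grid_shape).reshape(3, -1).T
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(np.int32)


def _seed_parcel(partition: np.ndarray, seed_row: int) -> np.ndarray:
    return (partition == partition[seed_row]).astype(np.uint8)


def make_ground_truth(spec: SyntheticSpec, subject_id: str = "sub-01",
                      rng: np.random.Generator | None = None) -> GroundTruth:
    """Sample partitions (rejection-sampled for seed-parcel separation) and
    a state sequence honoring the dwell targets.

    Raises
    ------
    RuntimeError
        If seed-parcel Dice separation cannot be achieved within the retry
        budget.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    partitions, seed_parcels = [], []
    for s in range(spec.n_states):
        for attempt in range(spec.max_partition_retries):
            part = _voronoi_partition(spec, rng)
            sp = _seed_parcel(part, spec.seed_row)
            if all(dice(sp, prev) < spec.dice_separation for prev in seed_parcels):
                partitions.append(part)
                seed_parcels.append(sp)
                break
        else:
            raise RuntimeError(
                f"could not separate seed parcels below Dice "
                f"{spec.dice_separation} in {spec.max_partition_retries} tries"
            )
    seq = sample_state_sequence(spec, rng)
    return GroundTruth(
        partitions=np.stack(partitions),
        seed_parcels=np.stack(seed_parcels),
        state_sequence=seq,
        subject_id=subject_id,
    )


def sample_state_sequence(spec: SyntheticSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """Contiguous same-state segments whose totals hit the dwell targets.

    Each state's frame budget (dwell target x n_frames, rounded) is split
    into segments of roughly ``segment_length_frames`` (uniform +/- 50%
    jitter), and the segments are interleaved in random order.  Realized
    dwell therefore matches the targets up to rounding.
    """
    budgets = np.round(np.asarray(spec.dwell_targets) * spec.n_frames).astype(int)
    budgets[-1] = spec.n_frames - budgets[:-1].sum()
    segments: list[tuple[int, int]] = []  # (state, length)
    for state, budget in enumerate(budgets):
        remaining = budget
        while remaining > 0:
            lo = max(1, spec.segment_length_frames // 2)
            hi = spec.segment_length_frames * 3 // 2
            length = int(rng.integers(lo, hi + 1))
            length = min(length, remaining)
            # avoid a tiny trailing remnant: absorb it into this segment
            if 0 < remaining - length < lo:
                length = remaining
            segments.append((state, length))
            remaining -= length
    rng.shuffle(segments)
    seq = np.concatenate([np.full(ln, st, dtype=np.int32) for st, ln in segments])
    return seq


def resample_sequence(gt: GroundTruth, spec: SyntheticSpec,
                      rng: np.random.Generator) -> GroundTruth:
    """New replication set: same partitions, fresh state sequence."""
    return replace(gt, state_sequence=sample_state_sequence(spec, rng))


def simulate_bold(spec: SyntheticSpec, gt: GroundTruth,
                  rng: np.random.Generator | None = None,
                  run_id: str = "sim") -> BoldRun:
    """Voxel signals from latent parcel courses plus Gaussian noise.

    Within each contiguous state segment every parcel of the active
    partition gets an independent smooth unit-variance latent course
    (white noise smoothed along time); courses are resampled at each
    segment, so windows straddling a state change are genuinely mixed.
    The output is standardized per voxel.
    """
    rng = rng or np.random.default_rng(spec.rng_seed + 1)
    seq = gt.state_sequence
    n_frames = len(seq)
    n_vox = gt.partitions.shape[1]
    data = np.empty((n_vox, n_frames))
    # iterate contiguous segments of the state sequence
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n_frames]))
    for a, b in zip(starts, ends):
        state = int(seq[a])
        ln = b - a
        courses = rng.standard_normal((spec.k_true, ln))
        if spec.latent_smooth_frames > 0 and ln > 1:
            courses = gaussian_filter1d(courses, spec.latent_smooth_frames, axis=1)
        sd = courses.std(axis=1, keepdims=True)
        mu = courses.mean(axis=1, keepdims=True)
        courses = np.divide(courses - mu, sd, out=np.zeros_like(courses),
                            where=sd > 0)
        data[:, a:b] = courses[gt.partitions[state]]
    if spec.noise_sigma > 0:
        data += spec.noise_sigma * rng.standard_normal(data.shape)
    # standardize per voxel
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1, keepdims=True)
    data = np.divide(data - mu, sd, out=np.zeros_like(data), where=sd > 0)
    return BoldRun(data=data, affine=spec.affine, mask=spec.mask,
                   tr_seconds=spec.tr_seconds, run_id=run_id)


def simulate_dataset(
    spec: SyntheticSpec,
) -> dict[str, dict[str, tuple[BoldRun, GroundTruth]]]:
    """Full design: ``{subject: {set: (run, ground_truth)}}``.

    Partitions are shared across a subject's sets; state sequences and
    latent courses are freshly sampled per set.  All randomness descends
    from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    out: dict[str, dict[str, tuple[BoldRun, GroundTruth]]] = {}
    for s in range(spec.n_subjects):
        subject = f"sub-{s + 1:02d}"
        gt0 = make_ground_truth(spec, subject_id=subject, rng=rng)
        sets = {}
        for t in range(spec.n_sets_per_subject):
            gt = gt0 if t == 0 else resample_sequence(gt0, spec, rng)
            run = simulate_bold(spec, gt, rng=rng,
                                run_id=f"{subject}_set-{t + 1}")
            sets[f"set-{t + 1}"] = (run, gt)
        out[subject] = sets
    return out


# ---------------------------------------------------------------------------
# recovery scoring against the planted truth


def majority_planted_state(seq: np.ndarray, start: int, length: int) -> int:
    """Majority active state in the frame window [start, start+length)."""
    counts = np.bincount(seq[start : start + length])
    return int(np.argmax(counts))  # ties toward the lower state id


def evaluate_recovery(
    state_maps: list[StabilityMap],
    assignment_df,
    gt: GroundTruth,
    window_length: int,
    stability_cut: float = 0.5,
) -> dict:
    """Score detected states against the planted truth.

    Detected stability maps are binarized at ``stability_cut`` and paired
    with planted seed parcels by Hungarian matching on the Dice matrix.
    Reports the detected state count, matched Dice scores, absolute dwell
    errors (detected dwell vs the planted per-window-majority dwell), and
    window-assignment accuracy against the majority planted state per
    window (maps left unassigned count as incorrect).
    """
    n_detected = len(state_maps)
    windows = assignment_df[["window_index", "window_start_frame"]].drop_duplicates()
    majority = {
        int(row.window_index): majority_planted_state(
            gt.state_sequence, int(row.window_start_frame), window_length
        )
        for row in windows.itertuples()
    }
    planted_instance_dwell = np.zeros(gt.n_states)
    for _, row in assignment_df.iterrows():
        planted_instance_dwell[majority[int(row.window_index)]] += 1
    planted_instance_dwell /= len(assignment_df)

    result = {
        "n_detected": n_detected,
        "matched_dice": [],
        "dwell_abs_error": [],
        "assignment_accuracy": float("nan"),
        "planted_dwell": planted_instance_dwell.tolist(),
        "detected_dwell": [m.dwell_fraction for m in state_maps],
    }
    if n_detected == 0:
        return result

    binarized = [(m.values > stability_cut).astype(np.uint8) for m in state_maps]
    dmat = np.array([[dice(b, sp) if (b.sum() + sp.sum()) else 0.0
                      for sp in gt.seed_parcels] for b in binarized])
    rows, cols = linear_sum_assignment(-dmat)
    detected_to_planted = {int(i): int(j) for i, j in zip(rows, cols)}
    result["matched_dice"] = [float(dmat[i, j]) for i, j in zip(rows, cols)]
    result["dwell_abs_error"] = [
        abs(state_maps[i].dwell_fraction - planted_instance_dwell[j])
        for i, j in zip(rows, cols)
    ]

    # window-assignment accuracy: detected rank -> planted state via the match
    rank_of_state_id = {m.state_id: r for r, m in enumerate(state_maps)}
    correct = 0
    for _, row in assignment_df.iterrows():
        sid = int(row.state_id)
        if sid in rank_of_state_id:
            det = rank_of_state_id[sid]
            if detected_to_planted.get(det) == majority[int(row.window_index)]:
                correct += 1
    result["assignment_accuracy"] = correct / len(assignment_df)
    return result


# ---------------------------------------------------------------------------
# file output so the CLI pipeline runs on simulated data


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write NIfTI runs, the mask, and JSON ground truth for every
    subject x set of the design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_img = nib.Nifti1Image(spec.mask.astype(np.uint8), spec.affine)
    nib.save(mask_img, str(out_dir / "mask.nii.gz"))
    dataset = simulate_dataset(spec)
    for subject, sets in dataset.items():
        for set_name, (run, gt) in sets.items():
            base = out_dir / subject / set_name
            base.mkdir(parents=True, exist_ok=True)
            vol = np.zeros(spec.grid_shape + (run.n_frames,), dtype=np.float32)
            vol[spec.mask] = run.data
            nib.save(nib.Nifti1Image(vol, spec.affine), str(base / "bold.nii.gz"))
            truth = {
                "subject_id": gt.subject_id,
                "seed_voxel_ijk": list(spec.seed_ijk),
                "state_sequence": gt.state_sequence.tolist(),
                "partitions": gt.partitions.tolist(),
                "seed_parcels": gt.seed_parcels.tolist(),
                "dwell_targets": list(spec.dwell_targets),
            }
            (base / "ground_truth.json").write_text(json.dumps(truth))
    return out_dir
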