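"""End-to-end drivers: configuration, fit, split-half evaluation, fingerprint.

``RunConfig`` gathers every tunable of the pipeline with the reference
defaults (window length 100 frames, overlap 10, k = 12 parcels,
5 k-means replications per window, Dice threshold 0.3, dwell threshold
10%, 6 mm smoothing, stability cut 0.5, 50-voxel minimum region).  A single
base seed determines every random draw — session shuffling, per-replication
k-means seeds, outer algorithm replications — through documented offsets,
so any output is reproducible from its configuration alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import evaluation, io, stability, states, windows

logger = logging.getLogger("dynparc")


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the reference settings."""

    window_length: int = 100
    window_overlap: int = 10
    k: int = 12
    n_replications: int = 5
    dice_threshold: float = 0.3
    dwell_threshold: float = 0.10
    linkage: str = "average"
    smoothing_fwhm_mm: float = 6.0
    standardize: bool = True
    stability_cut: float = 0.5
    min_region_voxels: int = 50
    connectivity: str = "face"
    n_algorithm_replications: int = 15
    base_seed: int = 0
    shuffle_sessions: bool = False
    forbid_boundary_spanning: bool = False
    tr_seconds: float = 2.2
    max_seed_snap_mm: float = 10.0

    def __post_init__(self) -> None:
        # delegate range checks to the parameter dataclasses they feed
        self.parcellation_params()
        self.state_params()
        stability.RegionParams(self.stability_cut, self.min_region_voxels,
                               self.connectivity)
        if not 0 <= self.window_overlap < self.window_length:
            raise ValueError("need 0 <= overlap < window length")

    def parcellation_params(self, base_seed: int | None = None) -> windows.ParcellationParams:
        return windows.ParcellationParams(
            k=self.k, n_replications=self.n_replications,
            base_seed=self.base_seed if base_seed is None else base_seed,
        )

    def state_params(self) -> states.StateParams:
        return states.StateParams(
            dice_threshold=self.dice_threshold,
            dwell_threshold=self.dwell_threshold,
            linkage=self.linkage,
        )

    def region_params(self) -> stability.RegionParams:
        return stability.RegionParams(
            stability_cut=self.stability_cut,
            min_region_voxels=self.min_region_voxels,
            connectivity=self.connectivity,
        )

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a JSON file; keyword overrides win over file values."""
        cfg = json.loads(Path(path).read_text())
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


@dataclass
class FitResult:
    """Everything the fit stage produces for one subject x seed x set."""

    state_maps: list[stability.StabilityMap]
    assignment: pd.DataFrame
    seed_maps: list[states.SeedParcelMap]
    dice_mat: np.ndarray
    within_dice: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray
    seed: io.SeedSpec
    config: RunConfig
    subject: str = "sub"

    @property
    def dwell_fractions(self) -> list[float]:
        return [m.dwell_fraction for m in self.state_maps]


def fit_states(
    runs: list[io.BoldRun],
    seed: io.SeedSpec,
    config: RunConfig | None = None,
    subject: str = "sub",
    base_seed: int | None = None,
) -> FitResult:
    """Run the full state-detection pipeline on one set of sessions.

    Sessions are concatenated (optionally shuffled by the base seed),
    sliding windows are parcellated with replicated k-means, the seed's
    parcel is binarized per parcellation, and states are detected on the
    Dice matrix and summarized as ranked stability maps.
    """
    config = config or RunConfig()
    seed_int = config.base_seed if base_seed is None else base_seed
    order = list(range(len(runs)))
    if config.shuffle_sessions and len(runs) > 1:
        rng = np.random.default_rng(seed_int)
        rng.shuffle(order)
    ordered = [runs[i] for i in order]
    run = io.concatenate_runs(ordered)
    boundaries = io.run_boundaries(ordered)

    spec = windows.enumerate_windows(run.n_frames, config.window_length,
                                     config.window_overlap)
    parcs = windows.run_sliding_parcellation(
        run, spec, config.parcellation_params(base_seed=seed_int),
        forbid_boundary_spanning=config.forbid_boundary_spanning,
        run_boundaries=boundaries,
    )
    logger.info("fit %s: %d windows x %d replications = %d parcellations",
                subject, spec.n_windows, config.n_replications, len(parcs))
    seed_maps = [states.binarize_seed_parcel(p, seed.voxel_index) for p in parcs]
    detected, assignment, dmat = states.detect_states(seed_maps,
                                                      config.state_params())
    state_maps = stability.build_state_maps(seed_maps, detected, dmat,
                                            seed_name=seed.name)
    logger.info("fit %s: %d states retained, dwell %s", subject,
                len(state_maps), [round(m.dwell_fraction, 3) for m in state_maps])
    return FitResult(
        state_maps=state_maps,
        assignment=states.assignment_table(seed_maps, assignment),
        seed_maps=seed_maps,
        dice_mat=dmat,
        within_dice=states.within_state_dice(dmat, detected),
        mask=run.mask,
        affine=run.affine,
        seed=seed,
        config=config,
        subject=subject,
    )


# ---------------------------------------------------------------------------
# persistence


def write_fit(result: FitResult, out_dir: str | Path) -> Path:
    """Write state maps (NIfTI + JSON sidecars), assignments (TSV) and a
    summary (JSON) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecars = []
    for m in result.state_maps:
        stem = f"{result.subject}_{m.seed_name}_state-{m.state_rank}"
        io.save_map(m.values, result.mask, result.affine,
                    out_dir / f"{stem}.nii.gz")
        sidecars.append({
            "rank": m.state_rank, "dwell_fraction": m.dwell_fraction,
            "n_members": int(round(m.dwell_fraction * len(result.seed_maps))),
            "state_id": m.state_id, "mean_within_dice": m.mean_within_dice,
        })
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecars[-1]))
    result.assignment.to_csv(out_dir / "assignments.tsv", sep="\t", index=False)
    summary = {
        "subject": result.subject,
        "seed": {"name": result.seed.name, "mni_mm": list(result.seed.mni_mm),
                 "voxel_index": result.seed.voxel_index},
        "n_maps": len(result.seed_maps),
        "n_states": len(result.state_maps),
        "states": sidecars,
        "within_state_dice": result.within_dice.to_dict(orient="records"),
        "config": asdict(result.config),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
    return out_dir


def load_fit_maps(fit_dir: str | Path) -> tuple[list[np.ndarray], list[dict]]:
    """Read back stability-map vectors and sidecars, ordered by state rank."""
    fit_dir = Path(fit_dir)
    summary = json.loads((fit_dir / "summary.json").read_text())
    files = sorted(fit_dir.glob("*_state-*.nii.gz"),
                   key=lambda p: int(p.name.rsplit("state-", 1)[1].split(".")[0]))
    if not files:
        return [], summary.get("states", [])
    # reconstruct the mask from any nonzero extent is unsafe; the seed map is
    # stored dense, so correlate over the full grid (zeros outside the mask
    # are shared structure and identical across maps from the same fit)
    vectors = [np.asanyarray(nib.load(str(f)).dataobj).ravel() for f in files]
    return vectors, summary["states"]


# ---------------------------------------------------------------------------
# split-half evaluation and fingerprinting over fitted outputs


def evaluate_sets(maps1: list[np.ndarray], maps2: list[np.ndarray],
                  dwell1: list[float], dwell2: list[float]) -> dict:
    """Hungarian matching + per-state reproducibility + dwell comparison."""
    if not maps1 or not maps2:
        logger.warning("empty state set: reporting zero matches")
        return {"n_pairs": 0, "scores": [0.0] * len(maps1),
                "dwell_table": pd.DataFrame(), "match": None}
    match = evaluation.hungarian_match(maps1, maps2)
    return {
        "n_pairs": len(match.pairs),
        "scores": evaluation.reproducibility_scores(match).tolist(),
        "dwell_table": evaluation.compare_dwell_times(match, dwell1, dwell2),
        "match": match,
    }


def fingerprint_fits(
    fits: dict[str, dict[str, list[np.ndarray]]],
    n_iter: int = 1000,
    rng_seed: int = 0,
) -> dict:
    """Deterministic + chance fingerprinting over ``{subject: {set: maps}}``."""
    pooled, subjects, set_tags = [], [], []
    for subject, sets in sorted(fits.items()):
        for set_name, maps in sorted(sets.items()):
            for m in maps:
                pooled.append(m)
                subjects.append(subject)
                set_tags.append(set_name)
    if len(set(subjects)) < 2:
        raise ValueError("deterministic fingerprinting needs >= 2 subjects")
    det = evaluation.deterministic_fingerprint(pooled, subjects, set_tags)
    chance = evaluation.chance_fingerprint(subjects, n_iter=n_iter,
                                           rng_seed=rng_seed)
    return {"deterministic": det, "chance_accuracy": chance,
            "n_maps": len(pooled), "n_subjects": len(set(subjects))}
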