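"""Dynamic state detection from window parcellations.

Each window parcellation is binarized at the seed (voxels sharing the
seed's parcel), pairwise Dice similarity is computed between all seed-parcel
maps, and average-linkage hierarchical clustering on distance 1 - Dice is
cut at 1 - dice_threshold to group maps into dynamic states.  States whose
membership does not exceed the dwell threshold (a fraction of all
window x replication instances, strict inequality) are dropped; their maps
are reported as unassigned with state id -1.

The similarity threshold is interpreted as a dendrogram cut level rather
than a hard minimum pairwise Dice; ``within_state_dice`` reports the
realized minimum and mean within-state Dice so both readings can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .windows import WindowParcellation

UNASSIGNED = -1


@dataclass
class SeedParcelMap:
    """Binary map of the seed's parcel for one window x replication."""

    binary: np.ndarray
    window_index: int
    replication_index: int
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary).astype(np.uint8)
        if self.binary.sum() < 1:
            raise ValueError("a seed-parcel map must mark at least one voxel")


@dataclass
class StateParams:
    """State-detection thresholds: linkage cut on Dice and dwell filter."""

    dice_threshold: float = 0.3
    dwell_threshold: float = 0.10
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0 < self.dice_threshold <= 1:
            raise ValueError("dice_threshold must be in (0, 1]")
        if not 0 <= self.dwell_threshold < 1:
            raise ValueError("dwell_threshold must be in [0, 1)")


@dataclass
class DynamicState:
    """A retained cluster of seed-parcel maps and its dwell-time fraction."""

    state_id: int
    member_indices: list[int]
    dwell_fraction: float


def binarize_seed_parcel(parcellation: WindowParcellation,
                         seed_voxel: int) -> SeedParcelMap:
    """1 where a voxel shares the seed's k-means label, else 0."""
    labels = parcellation.labels
    return SeedParcelMap(
        binary=(labels == labels[seed_voxel]),
        window_index=parcellation.window_index,
        replication_index=parcellation.replication_index,
        start_frame=parcellation.start_frame,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A ∩ B| / (|A| + |B|) between binary vectors."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("maps differ in length")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise ValueError("Dice undefined for two empty maps")
    return 2.0 * int((a & b).sum()) / total


def dice_matrix(maps: list[SeedParcelMap]) -> np.ndarray:
    """Symmetric pairwise Dice with unit diagonal; one computation per pair."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    # vectorized: intersections via the Gram matrix of the 0/1 stack
    stack = np.stack([m.binary for m in maps]).astype(float)
    sizes = stack.sum(axis=1)
    inter = stack @ stack.T
    mat = 2.0 * inter / (sizes[:, None] + sizes[None, :])
    # exact symmetry and unit diagonal regardless of float round-off
    mat = np.triu(mat, 1)
    mat = mat + mat.T
    np.fill_diagonal(mat, 1.0)
    return mat


def cluster_states(dice_mat: np.ndarray, params: StateParams) -> np.ndarray:
    """Average-linkage clustering on 1 - Dice, cut at 1 - dice_threshold.

    Returns one 0-based state label per map (labels are arbitrary ids at
    this stage; dwell filtering and ranking happen downstream).
    """
    dist = 1.0 - np.asarray(dice_mat, dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=params.linkage)
    labels = fcluster(z, t=1.0 - params.dice_threshold, criterion="distance")
    return labels.astype(int) - 1


def filter_states(labels: np.ndarray, total_n: int,
                  params: StateParams) -> tuple[list[DynamicState], np.ndarray]:
    """Keep states with strictly more than dwell_threshold * total_n members.

    Returns the retained states (arbitrary original ids preserved) and the
    per-map assignment with dropped-state members set to ``UNASSIGNED``.
    """
    labels = np.asarray(labels)
    assignment = np.full(labels.shape, UNASSIGNED, dtype=int)
    states: list[DynamicState] = []
    for sid in np.unique(labels):
        members = np.flatnonzero(labels == sid)
        if len(members) > params.dwell_threshold * total_n:
            states.append(
                DynamicState(
                    state_id=int(sid),
                    member_indices=[int(i) for i in members],
                    dwell_fraction=len(members) / total_n,
                )
            )
            assignment[members] = sid
    return states, assignment


def within_state_dice(dice_mat: np.ndarray,
                      states: list[DynamicState]) -> pd.DataFrame:
    """Realized min and mean pairwise Dice inside each retained state."""
    rows = []
    for st in states:
        idx = np.asarray(st.member_indices)
        if len(idx) == 1:
            lo = mean = 1.0
        else:
            sub = dice_mat[np.ix_(idx, idx)]
            off = sub[np.triu_indices(len(idx), 1)]
            lo, mean = float(off.min()), float(off.mean())
        rows.append({"state_id": st.state_id, "n_members": len(idx),
                     "min_dice": lo, "mean_dice": mean})
    return pd.DataFrame(rows, columns=["state_id", "n_members",
                                       "min_dice", "mean_dice"])


def detect_states(
    maps: list[SeedParcelMap], params: StateParams | None = None
) -> tuple[list[DynamicState], np.ndarray, np.ndarray]:
    """Full state-detection stage: Dice matrix -> linkage cut -> dwell filter.

    Returns ``(states, assignment, dice_mat)`` where ``assignment`` holds one
    state id (or -1) per input map.
    """
    params = params or StateParams()
    mat = dice_matrix(maps)
    labels = cluster_states(mat, params)
    states, assignment = filter_states(labels, len(maps), params)
    return states, assignment, mat


def assignment_table(maps: list[SeedParcelMap],
                     assignment: np.ndarray) -> pd.DataFrame:
    """Tidy per-map state assignment (window, replication, start, state)."""
    return pd.DataFrame(
        {
            "window_index": [m.window_index for m in maps],
            "replication_index": [m.replication_index for m in maps],
            "window_start_frame": [m.start_frame for m in maps],
            "state_id": np.asarray(assignment, dtype=int),
        }
    )
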