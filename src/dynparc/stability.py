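"""Stability maps, state ordering, and contiguous-region extraction.

A state's stability map is the voxelwise mean of its binary seed-parcel
maps: the probability that a voxel belongs to the seed's parcel while the
state is active.  States are ranked by decreasing dwell fraction (primary,
secondary, ...).  A stability map can be split into spatially contiguous
regions by thresholding and connected-component labeling, dropping
components below a minimum voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import unmask_vector
from .states import DynamicState, SeedParcelMap


@dataclass
class StabilityMap:
    """Per-voxel probability of belonging to the seed's parcel in one state."""

    values: np.ndarray
    state_rank: int = 0  # 1 = primary, 2 = secondary, ...
    dwell_fraction: float = 0.0
    seed_name: str = "seed"
    state_id: int = 0
    mean_within_dice: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("stability values must lie in [0, 1]")


@dataclass
class RegionParams:
    """Threshold/size/connectivity rules for splitting maps into regions."""

    stability_cut: float = 0.5
    min_region_voxels: int = 50
    connectivity: str = "face"  # or "full" = face+edge+corner

    def __post_init__(self) -> None:
        if not 0 < self.stability_cut < 1:
            raise ValueError("stability_cut must be in (0, 1)")
        if self.min_region_voxels < 1:
            raise ValueError("min_region_voxels must be >= 1")
        if self.connectivity not in ("face", "full"):
            raise ValueError("connectivity must be 'face' or 'full'")


def compute_stability_map(member_maps: list[SeedParcelMap]) -> np.ndarray:
    """Voxelwise arithmetic mean of the binary member maps."""
    if not member_maps:
        raise ValueError("a state needs at least one member map")
    return np.mean([m.binary for m in member_maps], axis=0)


def build_state_maps(
    maps: list[SeedParcelMap],
    states: list[DynamicState],
    dice_mat: np.ndarray | None = None,
    seed_name: str = "seed",
) -> list[StabilityMap]:
    """Stability map per retained state, sorted and ranked by dwell time."""
    out = []
    for st in states:
        members = [maps[i] for i in st.member_indices]
        mean_d = 1.0
        if dice_mat is not None and len(st.member_indices) > 1:
            idx = np.asarray(st.member_indices)
            sub = dice_mat[np.ix_(idx, idx)]
            mean_d = float(sub[np.triu_indices(len(idx), 1)].mean())
        out.append(
            StabilityMap(
                values=compute_stability_map(members),
                dwell_fraction=st.dwell_fraction,
                seed_name=seed_name,
                state_id=st.state_id,
                mean_within_dice=mean_d,
            )
        )
    return sort_and_label_states(out)


def sort_and_label_states(stability_maps: list[StabilityMap]) -> list[StabilityMap]:
    """Order by decreasing dwell; rank 1..n (primary, secondary, ...).

    Ties broken by larger mean within-state Dice, then lower original id.
    """
    order = sorted(
        stability_maps,
        key=lambda m: (-m.dwell_fraction, -m.mean_within_dice, m.state_id),
    )
    for rank, m in enumerate(order, start=1):
        m.state_rank = rank
    return order


def extract_regions(
    stability_values: np.ndarray,
    params: RegionParams,
    mask: np.ndarray,
) -> np.ndarray:
    """Split a stability map into contiguous supra-threshold regions.

    Binarize at ``stability_cut``, label connected components (6-neighbor
    face connectivity by default), drop components smaller than
    ``min_region_voxels``, and relabel survivors 1..m by decreasing size
    (size ties broken by lower original component label).  Returns an
    integer-valued 3-D volume; 0 is background.
    """
    mask = np.asarray(mask).astype(bool)
    vol = unmask_vector(np.asarray(stability_values, dtype=float), mask)
    binary = vol > params.stability_cut
    structure = ndimage.generate_binary_structure(
        3, 1 if params.connectivity == "face" else 3
    )
    labeled, n = ndimage.label(binary, structure=structure)
    out = np.zeros_like(labeled)
    if n == 0:
        return out
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    keep = [(int(sz), lab) for lab, sz in zip(range(1, n + 1), sizes)
            if sz >= params.min_region_voxels]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, old_label) in enumerate(keep, start=1):
        out[labeled == old_label] = new_label
    return out


def combined_region_atlas(
    state_maps: list[StabilityMap],
    params: RegionParams,
    mask: np.ndarray,
) -> np.ndarray:
    """Multi-state atlas with disjoint label ranges per state rank.

    State of rank r contributes labels in (r-1)*offset + 1 .. ; later-ranked
    states never overwrite voxels already claimed by a higher-ranked state.
    """
    mask = np.asarray(mask).astype(bool)
    atlas = np.zeros(mask.shape, dtype=int)
    offset = 0
    for m in sorted(state_maps, key=lambda s: s.state_rank):
        regions = extract_regions(m.values, params, mask)
        free = atlas == 0
        atlas[free] = np.where(regions[free] > 0, regions[free] + offset, 0)
        offset += int(regions.max())
    return atlas
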