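"""Sliding-window enumeration and replicated k-means window parcellation.

Windows of length W with overlap O are cut from the concatenated time
series, starting at frame 0 and stepping by W - O; a trailing window that
would run past the end is dropped.  Each window is clustered n_replications
times with k-means (k-means++ initialization, one start per replication —
replication over random seeds is the multi-start mechanism), yielding
``n_windows * n_replications`` whole-volume parcellations per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .io import BoldRun


@dataclass
class WindowSpec:
    """Sliding-window layout: length, overlap and the resulting start frames."""

    length_W: int
    overlap_O: int
    starts: list[int]

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass
class ParcellationParams:
    """k-means controls for the window parcellation stage."""

    k: int = 12
    n_replications: int = 5
    base_seed: int = 0
    max_iter: int = 300
    tol: float = 1e-4
    n_init: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")


@dataclass
class WindowParcellation:
    """One replicated k-means labeling of all in-mask voxels for one window."""

    window_index: int
    replication_index: int
    labels: np.ndarray  # one id in [0, k) per in-mask voxel
    rng_seed: int
    start_frame: int = 0


def enumerate_windows(n_frames: int, length_W: int, overlap_O: int) -> WindowSpec:
    """List window start frames: 0, W-O, 2(W-O), ... while start + W <= n_frames.

    >>> enumerate_windows(190, 100, 10).starts
    [0, 90]
    """
    if overlap_O < 0 or overlap_O >= length_W:
        raise ValueError("overlap must satisfy 0 <= O < W")
    if n_frames < length_W:
        raise ValueError(f"need at least W={length_W} frames, got {n_frames}")
    step = length_W - overlap_O
    starts = list(range(0, n_frames - length_W + 1, step))
    return WindowSpec(length_W=length_W, overlap_O=overlap_O, starts=starts)


def extract_window(run: BoldRun, start: int, length_W: int) -> np.ndarray:
    """Columns [start, start + W) of the masked matrix."""
    if start < 0 or start + length_W > run.n_frames:
        raise ValueError(
            f"window [{start}, {start + length_W}) out of range for "
            f"{run.n_frames} frames"
        )
    return run.data[:, start : start + length_W]


def parcellate_window(
    window_matrix: np.ndarray,
    params: ParcellationParams,
    rng_seed: int,
    window_index: int = 0,
    replication_index: int = 0,
    start_frame: int = 0,
) -> WindowParcellation:
    """Cluster voxels by their within-window time courses.

    Observations are voxels, features are the W frames of the window;
    k-means++ seeding makes the solution deterministic given ``rng_seed``.
    Empty clusters are permitted: labels are not re-compacted, only the
    bound ``distinct labels <= k`` is guaranteed.
    """
    x = np.asarray(window_matrix, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("window must hold at least 2 frames")
    if params.k > x.shape[0]:
        raise ValueError(f"k={params.k} exceeds {x.shape[0]} voxels")
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=params.n_init,
        max_iter=params.max_iter,
        tol=params.tol,
        random_state=int(rng_seed) % (2**32),
    )
    labels = km.fit_predict(x)
    return WindowParcellation(
        window_index=window_index,
        replication_index=replication_index,
        labels=labels.astype(np.int32),
        rng_seed=int(rng_seed),
        start_frame=start_frame,
    )


def replication_seed(base_seed: int, window_index: int, n_replications: int,
                     replication_index: int) -> int:
    """Deterministic per-replication seed: base + window * n_reps + rep."""
    return int(base_seed) + window_index * n_replications + replication_index


def run_sliding_parcellation(
    run: BoldRun,
    window_spec: WindowSpec,
    params: ParcellationParams,
    forbid_boundary_spanning: bool = False,
    run_boundaries: Sequence[int] = (),
) -> list[WindowParcellation]:
    """All window x replication parcellations for one concatenated run.

    Windows may span session boundaries by default; with
    ``forbid_boundary_spanning`` windows containing any frame index in
    ``run_boundaries`` strictly inside them are skipped.
    """
    out: list[WindowParcellation] = []
    for w_idx, start in enumerate(window_spec.starts):
        if forbid_boundary_spanning and any(
            start < b < start + window_spec.length_W for b in run_boundaries
        ):
            continue
        window = extract_window(run, start, window_spec.length_W)
        for r_idx in range(params.n_replications):
            seed = replication_seed(params.base_seed, w_idx,
                                    params.n_replications, r_idx)
            out.append(
                parcellate_window(
                    window, params, seed,
                    window_index=w_idx, replication_index=r_idx,
                    start_frame=start,
                )
            )
    return out
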