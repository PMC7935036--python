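"""Evaluation battery: split-half matching, reproducibility, fingerprinting.

States detected on two independent replication sets (e.g., split-half
sessions) are paired one-to-one by the Hungarian method, maximizing total
Pearson correlation between their stability maps.  Per-state
reproducibility is the paired correlation, with 0 for set-1 states left
unmatched.  Fingerprinting pools the maps of all subjects and sets and asks
whether each map's nearest neighbor (by Pearson r, excluding itself)
belongs to the same subject; a chance baseline repeats random pairings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class MatchResult:
    """One-to-one state pairing between two replication sets."""

    pairs: list[tuple[int, int]]  # (index in set 1, index in set 2)
    correlations: list[float]  # Pearson r per pair
    unmatched_set1: list[int]  # set-1 states with no counterpart (score 0)
    n_set1: int = 0
    n_set2: int = 0


@dataclass
class FingerprintOutcome:
    query: int
    match: int
    query_subject: str
    match_subject: str
    success: bool
    best_r: float


@dataclass
class FingerprintResult:
    outcomes: list[FingerprintOutcome]
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.outcomes])


def pearson(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation over in-mask voxels; errors on constant input."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson undefined for a constant map")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def correlation_matrix(maps_set1: list[np.ndarray],
                       maps_set2: list[np.ndarray]) -> np.ndarray:
    return np.array([[pearson(a, b) for b in maps_set2] for a in maps_set1])


def hungarian_match(maps_set1: list[np.ndarray],
                    maps_set2: list[np.ndarray]) -> MatchResult:
    """Pair states across sets maximizing total Pearson r.

    Rectangular assignment when set sizes differ: min(n1, n2) pairs are
    formed and leftover set-1 states are reported unmatched (score 0 by
    convention downstream).
    """
    if not maps_set1 or not maps_set2:
        raise ValueError("both sets must be nonempty")
    corr = correlation_matrix(maps_set1, maps_set2)
    rows, cols = linear_sum_assignment(-corr)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols)]
    matched1 = {i for i, _ in pairs}
    return MatchResult(
        pairs=pairs,
        correlations=[float(corr[i, j]) for i, j in pairs],
        unmatched_set1=[i for i in range(len(maps_set1)) if i not in matched1],
        n_set1=len(maps_set1),
        n_set2=len(maps_set2),
    )


def reproducibility_scores(match: MatchResult) -> np.ndarray:
    """Per-set-1-state score: paired Pearson r, or 0 when unmatched."""
    scores = np.zeros(match.n_set1)
    for (i, _), r in zip(match.pairs, match.correlations):
        scores[i] = r
    return scores


def between_subject_scores(maps_by_subject: dict[str, list[np.ndarray]]) -> np.ndarray:
    """Pearson r for every cross-subject map pair, pooled over state ranks."""
    subjects = sorted(maps_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    out = []
    for i, s in enumerate(subjects):
        for s2 in subjects[i + 1:]:
            for a in maps_by_subject[s]:
                for b in maps_by_subject[s2]:
                    out.append(pearson(a, b))
    return np.asarray(out)


def deterministic_fingerprint(
    pooled_maps: list[np.ndarray],
    subjects: list[str],
    sets: list[str] | None = None,
    exclude_same_set: bool = False,
) -> FingerprintResult:
    """Nearest-neighbor subject identification over the pooled maps.

    For each query map the best match is the most correlated map in the
    pool excluding the query itself (and, optionally, all maps from the
    query's own replication set); success means the subjects agree.
    Correlation ties break toward the lowest map index.
    """
    n = len(pooled_maps)
    if n < 2:
        raise ValueError("pool must hold at least 2 maps")
    if len(subjects) != n or (sets is not None and len(sets) != n):
        raise ValueError("one subject (and set) tag per map required")
    if exclude_same_set and sets is None:
        raise ValueError("set tags required to exclude same-set maps")
    corr = correlation_matrix(pooled_maps, pooled_maps)
    outcomes = []
    for q in range(n):
        row = corr[q].copy()
        row[q] = -np.inf
        if exclude_same_set:
            for j in range(n):
                if j != q and subjects[j] == subjects[q] and sets[j] == sets[q]:
                    row[j] = -np.inf
        best = int(np.argmax(row))  # argmax -> lowest index on ties
        outcomes.append(
            FingerprintOutcome(
                query=q, match=best,
                query_subject=subjects[q], match_subject=subjects[best],
                success=subjects[best] == subjects[q],
                best_r=float(row[best]),
            )
        )
    acc = float(np.mean([o.success for o in outcomes]))
    return FingerprintResult(outcomes=outcomes, accuracy=acc)


def chance_fingerprint(
    subjects: list[str],
    n_iter: int = 1000,
    rng_seed: int = 0,
) -> float:
    """Chance baseline for fingerprinting accuracy.

    Per iteration, for each subject: draw one of their maps uniformly, then
    draw a second map uniformly from the whole pool excluding the first;
    success when both belong to that subject.  With S subjects of m maps
    each the expectation is (m - 1) / (S*m - 1).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    subjects = list(subjects)
    rng = np.random.default_rng(rng_seed)
    uniq = sorted(set(subjects))
    by_subject = {s: [i for i, x in enumerate(subjects) if x == s] for s in uniq}
    n = len(subjects)
    successes = 0
    for _ in range(n_iter):
        for s in uniq:
            first = by_subject[s][rng.integers(len(by_subject[s]))]
            second = rng.integers(n - 1)
            if second >= first:
                second += 1
            successes += subjects[second] == s
    return successes / (n_iter * len(uniq))


def expected_chance_accuracy(n_subjects: int, maps_per_subject: int) -> float:
    """Closed form for the chance baseline with equal-size map sets."""
    return (maps_per_subject - 1) / (n_subjects * maps_per_subject - 1)


def compare_dwell_times(
    match: MatchResult,
    dwell_set1: list[float],
    dwell_set2: list[float],
) -> pd.DataFrame:
    """Dwell fractions of matched states, side by side; unmatched excluded."""
    rows = [
        {"state_rank_set1": i + 1, "state_rank_set2": j + 1,
         "dwell_set1": dwell_set1[i], "dwell_set2": dwell_set2[j],
         "pearson_r": r}
        for (i, j), r in zip(match.pairs, match.correlations)
    ]
    return pd.DataFrame(
        rows, columns=["state_rank_set1", "state_rank_set2",
                       "dwell_set1", "dwell_set2", "pearson_r"]
    )
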