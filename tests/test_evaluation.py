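import itertools

import numpy as np
import pytest

from dynparc import evaluation


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal(50)
        assert evaluation.pearson(a, a) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        a = rng.random(30)
        assert evaluation.pearson(a, 1 - a) == pytest.approx(-1.0)

    def test_orthogonal_binary_patterns(self):
        a = np.array([0, 1, 0, 1], dtype=float)
        b = np.array([0, 1, 1, 0], dtype=float)
        assert evaluation.pearson(a, b) == pytest.approx(0.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            evaluation.pearson(np.ones(5), np.arange(5.0))


def brute_force_match(corr):
    """Enumerate every injection of the smaller set into the larger."""
    n1, n2 = corr.shape
    best, best_total = None, -np.inf
    if n1 <= n2:
        for perm in itertools.permutations(range(n2), n1):
            total = sum(corr[i, j] for i, j in enumerate(perm))
            if total > best_total:
                best_total, best = total, [(i, j) for i, j in enumerate(perm)]
    else:
        for perm in itertools.permutations(range(n1), n2):
            total = sum(corr[i, j] for j, i in enumerate(perm))
            if total > best_total:
                best_total, best = total, [(i, j) for j, i in enumerate(perm)]
    return best_total


class TestHungarianMatch:
    def test_identical_sets_identity_pairing(self, rng):
        maps = [rng.standard_normal(40) for _ in range(3)]
        match = evaluation.hungarian_match(maps, maps)
        assert sorted(match.pairs) == [(0, 0), (1, 1), (2, 2)]
        assert all(r == pytest.approx(1.0) for r in match.correlations)

    def test_two_by_two_hand_case(self):
        # cross-correlations ((0.9, 0.1), (0.2, 0.8)) built exactly from an
        # orthonormal zero-mean basis: the diagonal pairing wins, total 1.7
        rng = np.random.default_rng(5)
        x = rng.standard_normal((60, 4))
        x -= x.mean(axis=0)
        u, _ = np.linalg.qr(x)  # orthonormal, still zero-mean columns
        a, b = u[:, 0], u[:, 1]
        c = 0.9 * u[:, 0] + 0.2 * u[:, 1] + np.sqrt(1 - 0.85) * u[:, 2]
        d = 0.1 * u[:, 0] + 0.8 * u[:, 1] + np.sqrt(1 - 0.65) * u[:, 3]
        match = evaluation.hungarian_match([a, b], [c, d])
        assert sorted(match.pairs) == [(0, 0), (1, 1)]
        assert sum(match.correlations) == pytest.approx(1.7, abs=1e-9)

    def test_rectangular_three_vs_two(self, rng):
        maps1 = [rng.standard_normal(30) for _ in range(3)]
        maps2 = [rng.standard_normal(30) for _ in range(2)]
        match = evaluation.hungarian_match(maps1, maps2)
        assert len(match.pairs) == 2
        assert len(match.unmatched_set1) == 1
        scores = evaluation.reproducibility_scores(match)
        assert scores[match.unmatched_set1[0]] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        maps1 = [rng.standard_normal(25) for _ in range(n1)]
        maps2 = [rng.standard_normal(25) for _ in range(n2)]
        corr = evaluation.correlation_matrix(maps1, maps2)
        match = evaluation.hungarian_match(maps1, maps2)
        assert sum(match.correlations) == pytest.approx(brute_force_match(corr))

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluation.hungarian_match([], [rng.standard_normal(5)])


class TestReproducibilityScores:
    def test_passthrough_when_all_matched(self, rng):
        a = [rng.standard_normal(20) for _ in range(2)]
        match = evaluation.hungarian_match(a, a)
        scores = evaluation.reproducibility_scores(match)
        assert scores.shape == (2,)
        np.testing.assert_allclose(scores, 1.0)

    def test_score_length_equals_set1_size(self, rng):
        maps1 = [rng.standard_normal(15) for _ in range(4)]
        maps2 = [rng.standard_normal(15) for _ in range(2)]
        match = evaluation.hungarian_match(maps1, maps2)
        assert evaluation.reproducibility_scores(match).shape == (4,)


class TestBetweenSubjectScores:
    def test_identical_subjects_all_one(self, rng):
        m = rng.standard_normal(30)
        out = evaluation.between_subject_scores(
            {"a": [m.copy(), m.copy()], "b": [m.copy(), m.copy()]})
        np.testing.assert_allclose(out, 1.0)

    def test_pair_count_combinatorics(self, rng):
        maps = {s: [rng.standard_normal(10) for _ in range(n)]
                for s, n in [("a", 2), ("b", 3), ("c", 1)]}
        out = evaluation.between_subject_scores(maps)
        assert len(out) == 2 * 3 + 2 * 1 + 3 * 1

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluation.between_subject_scores({"a": [rng.standard_normal(5)]})


class TestDeterministicFingerprint:
    def _subject_pool(self, rng, n_subjects=2, within_r=0.95):
        """Subject templates plus small per-map jitter: within-subject maps
        correlate strongly, between weakly."""
        pooled, subjects, sets = [], [], []
        for s in range(n_subjects):
            template = rng.standard_normal(200)
            for t in range(2):
                pooled.append(template + 0.3 * rng.standard_normal(200))
                subjects.append(f"sub-{s}")
                sets.append(f"set-{t}")
        return pooled, subjects, sets

    def test_well_separated_subjects_accuracy_one(self, rng):
        pooled, subjects, sets = self._subject_pool(rng)
        out = evaluation.deterministic_fingerprint(pooled, subjects, sets)
        assert out.accuracy == 1.0

    def test_query_never_matches_itself(self, rng):
        pooled, subjects, sets = self._subject_pool(rng, n_subjects=3)
        out = evaluation.deterministic_fingerprint(pooled, subjects, sets)
        assert all(o.query != o.match for o in out.outcomes)

    def test_identical_maps_deterministic_tiebreak(self):
        m = np.arange(10.0)
        pooled = [m.copy() for _ in range(3)]
        out = evaluation.deterministic_fingerprint(pooled, ["a", "b", "c"])
        # ties break toward the lowest map index
        assert [o.match for o in out.outcomes] == [1, 0, 0]

    def test_scale_and_shift_invariance(self, rng):
        pooled, subjects, sets = self._subject_pool(rng)
        out1 = evaluation.deterministic_fingerprint(pooled, subjects, sets)
        shifted = [5.0 + 2.0 * m for m in pooled]
        out2 = evaluation.deterministic_fingerprint(shifted, subjects, sets)
        assert out1.accuracy == out2.accuracy
        assert [o.match for o in out1.outcomes] == [o.match for o in out2.outcomes]

    def test_small_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluation.deterministic_fingerprint([rng.standard_normal(5)], ["a"])


class TestChanceFingerprint:
    def test_single_subject_always_succeeds(self):
        acc = evaluation.chance_fingerprint(["a"] * 4, n_iter=50, rng_seed=0)
        assert acc == 1.0

    def test_matches_analytic_expectation(self):
        S, m, n_iter = 5, 4, 1000
        subjects = [f"s{i}" for i in range(S) for _ in range(m)]
        acc = evaluation.chance_fingerprint(subjects, n_iter=n_iter, rng_seed=7)
        p = evaluation.expected_chance_accuracy(S, m)
        se = np.sqrt(p * (1 - p) / (n_iter * S))
        assert abs(acc - p) < 3 * se

    def test_deterministic_given_seed(self):
        subjects = ["a", "a", "b", "b"]
        a1 = evaluation.chance_fingerprint(subjects, n_iter=200, rng_seed=3)
        a2 = evaluation.chance_fingerprint(subjects, n_iter=200, rng_seed=3)
        assert a1 == a2


class TestCompareDwellTimes:
    def test_identical_runs_equal_columns(self, rng):
        maps = [rng.standard_normal(20) for _ in range(2)]
        match = evaluation.hungarian_match(maps, maps)
        table = evaluation.compare_dwell_times(match, [0.6, 0.3], [0.6, 0.3])
        np.testing.assert_array_equal(table["dwell_set1"], table["dwell_set2"])

    def test_unmatched_states_excluded(self, rng):
        maps1 = [rng.standard_normal(20) for _ in range(3)]
        maps2 = [rng.standard_normal(20) for _ in range(2)]
        match = evaluation.hungarian_match(maps1, maps2)
        table = evaluation.compare_dwell_times(match, [0.5, 0.3, 0.15],
                                               [0.6, 0.25])
        assert len(table) == 2
        assert table["dwell_set1"].between(0, 1).all()
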