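"""Splits, metrics, baseline, statistical comparisons, embedding analyses."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import average_precision_score

from epistate.evaluation import (
    average_precision,
    compare_to_baseline,
    indirect_clustering_count,
    mean_average_precision,
    narrow_vs_broad,
    per_locus_baseline,
    per_track_ap,
    quant_to_qual,
    r_squared,
    split_unseen_celltype,
    split_unseen_sequence,
    tissue_cosine_test,
    validation_pairs,
)
from epistate.track_graph import MeasurementMatrix

CHROMS = [f"chr{i}" for i in range(1, 21)] + ["chrX", "chrY"]


class TestSplits:
    def test_chry_never_included(self):
        spec = split_unseen_sequence(CHROMS, seed=0)
        everything = spec.train_chroms + spec.val_chroms + spec.eval_chroms
        assert "chrY" not in everything

    def test_partitions_disjoint_and_cover(self):
        spec = split_unseen_sequence(CHROMS, seed=1)
        parts = [set(spec.train_chroms), set(spec.val_chroms), set(spec.eval_chroms)]
        assert sum(len(p) for p in parts) == 21  # all but chrY
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert len(spec.val_chroms) == 2 and len(spec.eval_chroms) == 2

    def test_deterministic(self):
        a = split_unseen_sequence(CHROMS, seed=5)
        b = split_unseen_sequence(CHROMS, seed=5)
        assert a.val_chroms == b.val_chroms and a.eval_chroms == b.eval_chroms

    def test_too_few_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            split_unseen_sequence(["chr1", "chr2", "chrY"], seed=0)

    @pytest.mark.parametrize("k", [3, 5, 10])
    def test_celltype_split_has_k_diagonal_pairs(self, k):
        cells = [f"cell{i}" for i in range(30)]
        spec = split_unseen_celltype(CHROMS, cells, k, seed=2)
        assert len(validation_pairs(spec)) == k
        assert len(spec.chrom_folds) == k and len(spec.cell_folds) == k

    def test_every_cell_present_in_training(self):
        cells = [f"cell{i}" for i in range(12)]
        spec = split_unseen_celltype(CHROMS, cells, 3, seed=3)
        held = set(validation_pairs(spec))
        for ci, fold in enumerate(spec.cell_folds):
            train_seq_folds = [si for si in range(3) if (si, ci) not in held]
            assert train_seq_folds  # each cell set trains on other sequence folds

    @pytest.mark.parametrize("seed", range(10))
    def test_no_leakage_between_train_and_validation(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.choice([3, 5, 10]))
        cells = [f"cell{i}" for i in range(int(rng.integers(k, 25)))]
        spec = split_unseen_celltype(CHROMS, cells, k, seed=seed)
        held = set(validation_pairs(spec))
        train_pairs = {
            (si, ci)
            for si in range(k)
            for ci in range(k)
            if (si, ci) not in held
        }
        assert not (held & train_pairs)
        # chromosome folds are disjoint
        seen = set()
        for fold in spec.chrom_folds:
            assert not (seen & set(fold))
            seen |= set(fold)

    def test_rejects_invalid_k(self):
        with pytest.raises(ValueError):
            split_unseen_celltype(CHROMS, ["a", "b", "c", "d"], 4, seed=0)


class TestAveragePrecision:
    def test_worked_example(self):
        ap = average_precision([0.9, 0.8, 0.7], [1, 0, 1])
        assert ap == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)

    def test_perfect_ranking_is_one(self):
        assert average_precision([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.5], [0])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_sklearn_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.3
        if labels.sum() == 0:
            labels[0] = True
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-9
        )

    def test_mean_average_precision_is_macro_mean(self):
        assert mean_average_precision({("a", 0): 0.4, ("b", 1): 0.8}) == pytest.approx(0.6)


class TestRSquared:
    def test_perfect_predictions(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_predictor_is_zero(self):
        assert r_squared([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == pytest.approx(0.0)

    def test_worked_example(self):
        assert r_squared([0.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [3.0, 3.0])


class TestPerLocusBaseline:
    def test_mean_over_training_cells(self):
        scores = per_locus_baseline(
            {"locus1": (np.array([[0.0], [1.0], [1.0]]), np.ones((3, 1), bool))}
        )
        assert scores["locus1"][0] == pytest.approx(2.0 / 3.0)

    def test_single_training_cell(self):
        scores = per_locus_baseline(
            {"x": (np.array([[0.7]]), np.ones((1, 1), bool))}
        )
        assert scores["x"][0] == pytest.approx(0.7)

    def test_locus_without_training_cells_rejected(self):
        with pytest.raises(ValueError):
            per_locus_baseline({"x": (np.zeros((2, 1)), np.zeros((2, 1), bool))})


class TestQuantToQual:
    def test_all_below_threshold(self):
        assert quant_to_qual(np.full(500, 2.0)).sum() == 0

    def test_matches_peak_calls_of_equal_track(self):
        v = np.zeros(2000)
        v[700] = 6.0
        labels = quant_to_qual(v)
        assert labels[625:775].all()
        assert labels.sum() == 150

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(2.0, 1500)
        low = quant_to_qual(v, 3.0).sum()
        high = quant_to_qual(v, 6.0).sum()
        assert high <= low


def exact_wilcoxon_one_sided(diffs):
    """Enumerate all sign assignments of ranked |differences|."""
    diffs = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.array(signs)).sum())
    ws = np.array(ws)
    return np.mean(ws >= w_obs)


def exact_mannwhitney_one_sided(x, y):
    """Enumerate group assignments for the exact U null."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    us = []
    for combo in itertools.combinations(range(n + m), n):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        us.append(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys))
    us = np.array(us)
    return np.mean(us >= u_obs)


class TestCompareToBaseline:
    def test_uniform_improvement_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.random(20)
        p = compare_to_baseline(base + 0.1, base)
        assert p < 0.001

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            compare_to_baseline(np.full(6, 0.5), np.full(6, 0.5))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exact_signed_rank_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.random(9)
        model = base + rng.normal(0, 0.2, 9)
        p = compare_to_baseline(model, base)
        p_exact = exact_wilcoxon_one_sided(model - base)
        assert p == pytest.approx(p_exact, abs=1e-9)


class TestNarrowVsBroad:
    CAT = {f"n{i}": "narrow" for i in range(8)}
    CAT.update({f"b{i}": "broad" for i in range(8)})
    CAT.update({"e0": "exception", "u0": "unknown"})

    def test_strong_separation_significant(self):
        ap = {f"n{i}": 0.9 for i in range(8)}
        ap.update({f"b{i}": 0.1 for i in range(8)})
        assert narrow_vs_broad(ap, self.CAT) < 0.001

    def test_exception_and_unknown_excluded(self):
        ap = {f"n{i}": 0.9 for i in range(8)}
        ap.update({f"b{i}": 0.1 for i in range(8)})
        with_extras = dict(ap)
        with_extras["e0"] = 0.5
        with_extras["u0"] = 0.5
        assert narrow_vs_broad(ap, self.CAT) == narrow_vs_broad(with_extras, self.CAT)

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError):
            narrow_vs_broad({"n0": 0.5}, self.CAT)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_u_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ap = {f"n{i}": rng.random() for i in range(5)}
        ap.update({f"b{i}": rng.random() for i in range(5)})
        p = narrow_vs_broad(ap, self.CAT)
        narrow = np.array([ap[f"n{i}"] for i in range(5)])
        broad = np.array([ap[f"b{i}"] for i in range(5)])
        p_hi = exact_mannwhitney_one_sided(narrow, broad)
        p_lo = exact_mannwhitney_one_sided(broad, narrow)
        assert p == pytest.approx(2 * min(p_hi, p_lo, 0.5), abs=1e-9)


class TestTissueCosine:
    def test_identical_embeddings_p_near_one(self):
        emb = np.tile(np.array([1.0, 2.0, 0.5]), (6, 1))
        obs, null_mean, _, p = tissue_cosine_test(emb, ["a", "a", "a", "b", "b", "b"],
                                                  n_perm=200, seed=0)
        assert obs == pytest.approx(1.0)
        assert null_mean == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_shuffled_labels_are_self_null(self, rng):
        emb = rng.normal(size=(14, 6))
        labels = ["a"] * 7 + ["b"] * 7
        shuffled = list(rng.permutation(labels))
        obs, null_mean, null_sd, _ = tissue_cosine_test(emb, shuffled, n_perm=500, seed=1)
        assert abs(obs - null_mean) < 2.5 * null_sd

    def test_clustered_embeddings_significant(self, rng):
        centers = {"a": np.array([3.0, 0.0]), "b": np.array([0.0, 3.0])}
        labels = ["a"] * 6 + ["b"] * 6
        emb = np.stack([centers[l] + rng.normal(0, 0.3, 2) for l in labels])
        _, _, _, p = tissue_cosine_test(emb, labels, n_perm=999, seed=2)
        assert p < 0.01

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            tissue_cosine_test(np.eye(3), ["a", "a", "a"], n_perm=10, seed=0)


class TestIndirectClustering:
    def _mask(self, measured):
        measured = np.asarray(measured, bool)
        return MeasurementMatrix(
            [f"c{i}" for i in range(measured.shape[0])],
            [f"f{j}" for j in range(measured.shape[1])],
            measured,
        )

    def test_same_tissue_disjoint_features_counts_all(self, rng):
        emb = rng.normal(size=(4, 3))
        m = self._mask(np.eye(4))
        count, _, _ = indirect_clustering_count(emb, ["t"] * 4, m, n_perm=10, seed=0)
        assert count == 4

    def test_all_distinct_tissues_count_zero(self, rng):
        emb = rng.normal(size=(4, 3))
        m = self._mask(np.eye(4))
        count, _, _ = indirect_clustering_count(
            emb, ["a", "b", "c", "d"], m, n_perm=10, seed=0
        )
        assert count == 0

    def test_permutation_expectation_matches_enumeration(self, rng):
        emb = rng.normal(size=(5, 3))
        measured = np.array(
            [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], bool
        )
        m = self._mask(measured)
        labels = np.array(["a", "a", "b", "b", "c"])
        nn_obs, expected, _ = indirect_clustering_count(
            emb, list(labels), m, n_perm=4000, seed=3
        )
        # exhaustive oracle over all label orderings
        from epistate.evaluation import _nearest_neighbors

        nn = _nearest_neighbors(emb)
        shared = (measured[:, None, :] & measured[None, :, :]).any(axis=2)
        counts = []
        for perm in itertools.permutations(labels):
            counts.append(
                sum(
                    perm[i] == perm[nn[i]] and not shared[i, nn[i]]
                    for i in range(5)
                )
            )
        assert expected == pytest.approx(np.mean(counts), abs=0.15)


class TestPerTrackAp:
    def test_shapes_and_skipping(self, rng):
        scores = rng.random((30, 3, 2))
        labels = (rng.random((30, 3, 2)) < 0.4).astype(int)
        labels[:, 0, 0] = 0  # degenerate track skipped
        ap = per_track_ap(scores, labels)
        assert (0, 0) not in ap
        for v in ap.values():
            assert 0.0 <= v <= 1.0
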