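"""Wrapper CV, distance-matrix score, Dunn, FOM and cluster-external error."""

from itertools import permutations

import numpy as np
import pytest

from sigselect import ExpressionDataset, EvaluatorSpec
from sigselect.evaluation import (
    cluster_external_error,
    distance_matrix_score,
    dunn_index,
    figure_of_merit,
    match_clusters_error,
    run_pool_algorithm,
    sample_distance_matrix,
    wrapper_cv_error,
)


def _two_cluster_dataset(n_per=6, gap=10.0, jitter=0.1, seed=0, n_genes=5):
    rng = np.random.default_rng(seed)
    base = np.concatenate([np.zeros(n_per), np.full(n_per, gap)])
    values = np.vstack([base + rng.normal(0, jitter, size=2 * n_per) for _ in range(n_genes)])
    samples = tuple(f"s{i}" for i in range(2 * n_per))
    labels = {s: ("A" if i < n_per else "B") for i, s in enumerate(samples)}
    return ExpressionDataset(tuple(f"g{i}" for i in range(n_genes)), samples, values, labels)


class TestWrapperCv:
    @pytest.mark.parametrize("clf", ["svm", "nb_gauss", "nb_kde", "bayes_net"])
    def test_perfect_separator_zero_error(self, tiny_two_class, clf):
        spec = EvaluatorSpec(kind="wrapper", classifier_id=clf, k_folds=3, seed=0)
        err = wrapper_cv_error(tiny_two_class, tiny_two_class.label_vector(), ["g0"], spec)
        assert err == 0.0

    def test_permuted_labels_near_half(self):
        errs = []
        for rep in range(30):
            rng = np.random.default_rng(rep)
            ds = _two_cluster_dataset(n_per=8, gap=0.0, jitter=1.0, seed=rep)
            y = np.array(["A"] * 8 + ["B"] * 8)
            rng.shuffle(y)
            spec = EvaluatorSpec(kind="wrapper", classifier_id="svm", k_folds=4, seed=rep)
            errs.append(wrapper_cv_error(ds, y, list(ds.gene_ids), spec))
        assert np.mean(errs) == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_seed(self, planted_dataset):
        spec = EvaluatorSpec(kind="wrapper", classifier_id="svm", k_folds=5, seed=9)
        y = planted_dataset.label_vector()
        sub = list(planted_dataset.gene_ids[:5])
        assert wrapper_cv_error(planted_dataset, y, sub, spec) == wrapper_cv_error(
            planted_dataset, y, sub, spec
        )

    def test_loo_equivalence_when_k_equals_min_class(self, tiny_two_class):
        # k_folds = class size -> every fold holds out one sample per class
        y = tiny_two_class.label_vector()
        spec = EvaluatorSpec(kind="wrapper", classifier_id="nb_gauss", k_folds=3, seed=1)
        err = wrapper_cv_error(tiny_two_class, y, ["g0", "g1"], spec)
        assert 0.0 <= err <= 1.0

    def test_unknown_classifier_rejected(self, tiny_two_class):
        spec = EvaluatorSpec(kind="wrapper", classifier_id="svm", k_folds=3)
        object.__setattr__(spec, "classifier_id", "nope")
        with pytest.raises(ValueError, match="classifier"):
            wrapper_cv_error(tiny_two_class, tiny_two_class.label_vector(), ["g0"], spec)


class TestDistanceScore:
    def test_identical_samples_zero(self):
        values = np.tile(np.array([[1.0], [2.0]]), (1, 6))
        ds = ExpressionDataset(("a", "b"), tuple(f"s{i}" for i in range(6)), values)
        y = ["A", "A", "A", "B", "B", "B"]
        assert distance_matrix_score(ds, y, ["a", "b"], "euclidean") == 0.0

    def test_two_tight_clusters_euclidean_gap(self):
        ds = _two_cluster_dataset(n_per=5, gap=10.0, jitter=0.1, n_genes=1)
        y = ds.label_vector()
        score = distance_matrix_score(ds, y, ["g0"], "euclidean")
        assert score == pytest.approx(10.0, abs=0.5)

    def test_sample_order_invariance(self, planted_dataset):
        y = planted_dataset.label_vector()
        sub = list(planted_dataset.gene_ids[:6])
        a = distance_matrix_score(planted_dataset, y, sub, "pearson")
        rng = np.random.default_rng(4)
        perm = rng.permutation(planted_dataset.n_samples)
        shuffled = planted_dataset.subset_samples(
            [planted_dataset.sample_ids[i] for i in perm]
        )
        b = distance_matrix_score(shuffled, y[perm], sub, "pearson")
        assert a == pytest.approx(b, rel=1e-9)


class TestDunn:
    def test_direct_arithmetic(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0]).reshape(1, -1)
        D = sample_distance_matrix(pts, "euclidean")
        assert dunn_index(D, [0, 0, 1, 1]) == pytest.approx(9.0)

    def test_all_singletons_infinite(self):
        pts = np.array([0.0, 1.0, 2.0]).reshape(1, -1)
        D = sample_distance_matrix(pts, "euclidean")
        assert dunn_index(D, [0, 1, 2]) == np.inf

    def test_scale_invariance(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0]).reshape(1, -1)
        D = sample_distance_matrix(pts, "euclidean")
        assert dunn_index(2 * D, [0, 0, 1, 1]) == pytest.approx(dunn_index(D, [0, 0, 1, 1]))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            dunn_index(np.zeros((3, 3)), [0, 0, 0])


class TestFom:
    def test_all_singletons_zero(self):
        ds = _two_cluster_dataset(n_per=3, n_genes=4)
        fom = figure_of_merit(ds, lambda vals: np.arange(vals.shape[1]))
        assert fom == pytest.approx(0.0)

    def test_single_cluster_equals_mean_population_sd(self):
        ds = _two_cluster_dataset(n_per=4, n_genes=6, seed=3)
        fom = figure_of_merit(ds, lambda vals: np.zeros(vals.shape[1], dtype=int))
        expected = np.mean(ds.values.std(axis=1))  # ddof=0 population SD
        assert fom == pytest.approx(expected, rel=1e-9)

    def test_true_partition_beats_random(self):
        ds = _two_cluster_dataset(n_per=6, gap=5.0, jitter=0.3, n_genes=8, seed=5)
        truth = np.array([0] * 6 + [1] * 6)
        rng = np.random.default_rng(6)
        random_part = rng.permutation(truth)
        fom_true = figure_of_merit(ds, lambda vals: truth)
        fom_rand = figure_of_merit(ds, lambda vals: random_part)
        assert fom_true < fom_rand


class TestClusterExternal:
    def test_matching_equals_exhaustive_permutation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_classes = int(rng.integers(2, 6))
            n = int(rng.integers(n_classes, 15))
            part = rng.integers(0, n_classes, size=n)
            y = rng.integers(0, n_classes, size=n)
            got = match_clusters_error(part, y)
            best = min(
                float(np.mean(np.array([perm[p] for p in part]) != y))
                for perm in permutations(range(n_classes))
            )
            assert got == pytest.approx(best)

    @pytest.mark.parametrize("index", ["dunn", "fom"])
    def test_separated_classes_zero_error(self, index):
        ds = _two_cluster_dataset(n_per=6, gap=8.0, jitter=0.2, n_genes=6, seed=8)
        spec = EvaluatorSpec(
            kind="cluster_external", index=index,
            clustering_pool=("kmeans", "hier_complete", "pam"), distance="euclidean", seed=0,
        )
        err = cluster_external_error(ds, ds.label_vector(), list(ds.gene_ids), spec)
        assert err == 0.0

    def test_error_bounded(self, planted_dataset):
        spec = EvaluatorSpec(
            kind="cluster_external", clustering_pool=("kmeans", "hier_average"), seed=0
        )
        err = cluster_external_error(
            planted_dataset, planted_dataset.label_vector(),
            list(planted_dataset.gene_ids[:8]), spec,
        )
        assert 0.0 <= err <= 1.0


class TestClusteringPool:
    @pytest.mark.parametrize(
        "alg", ["kmeans", "diana", "sota", "pam", "clara",
                "hier_average", "hier_complete", "hier_single", "hier_ward", "agnes"]
    )
    def test_every_pool_member_recovers_two_blocks(self, alg):
        ds = _two_cluster_dataset(n_per=6, gap=8.0, jitter=0.2, n_genes=6, seed=9)
        part = run_pool_algorithm(alg, ds.values, 2, "euclidean", seed=0)
        assert match_clusters_error(part, ds.label_vector()) == 0.0
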