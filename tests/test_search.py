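"""Search strategies: RFE coefficients and schedule, MRMR, forward, GA."""

import numpy as np
import pytest

from sigselect import (
    DiscretizationSpec,
    ExpressionDataset,
    EvaluatorSpec,
    GaSpec,
    RfeSpec,
    ga_search,
    make_evaluator,
    mrmr_search,
    rfe_coefficient,
    rfe_search,
    univariate_forward_search,
)
from sigselect.metrics import discretize_matrix, mutual_information, normalized_mi
from sigselect.search import SelectionTrace, _rfe_coefficients_all, mrmr_coefficients


def _wrapper_ev(seed=0, k=5):
    return make_evaluator(EvaluatorSpec(kind="wrapper", classifier_id="svm", k_folds=k, seed=seed))


def _distance_ev(seed=0):
    return make_evaluator(EvaluatorSpec(kind="distance_matrix", seed=seed))


class TestRfeCoefficient:
    def test_two_samples_one_per_class(self):
        # with one sample per class the only pair is between-class, so the
        # coefficient is exactly the MI of that single sample pair
        values = np.array([[1.0, -1.0], [0.5, 0.5], [2.0, -2.0]])
        ds = ExpressionDataset(("a", "b", "c"), ("s1", "s2"), values)
        disc = DiscretizationSpec(3)
        c = rfe_coefficient(ds, ["X", "Y"], "a", ("a", "b", "c"), disc)
        codes = discretize_matrix(values[[1, 2]], disc)
        assert c == pytest.approx(mutual_information(codes[:, 0], codes[:, 1]))

    def test_invariant_to_class_relabeling(self, planted_dataset):
        y = planted_dataset.label_vector()
        relabeled = np.array([f"class_{v}" for v in y])
        sub = tuple(planted_dataset.gene_ids[:5])
        a = rfe_coefficient(planted_dataset, y, sub[0], sub)
        b = rfe_coefficient(planted_dataset, relabeled, sub[0], sub)
        assert a == pytest.approx(b)

    def test_matches_explicit_pair_enumeration(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=(3, 4))
        ds = ExpressionDataset(("a", "b", "c"), tuple(f"s{i}" for i in range(4)), values)
        y = np.array(["A", "A", "B", "B"])
        disc = DiscretizationSpec(3)
        for excluded in ("a", "b", "c"):
            keep = [g for g in ("a", "b", "c") if g != excluded]
            codes = discretize_matrix(values[ds.gene_index(keep)], disc)
            expected = 0.0
            for i in range(4):
                for j in range(i + 1, 4):
                    mi = mutual_information(codes[:, i], codes[:, j])
                    expected += mi if y[i] != y[j] else -mi
            got = rfe_coefficient(ds, y, excluded, ("a", "b", "c"), disc)
            assert got == pytest.approx(expected)

    def test_vectorized_equals_reference(self, planted_dataset):
        y = planted_dataset.label_vector()
        sub = tuple(planted_dataset.gene_ids[:8])
        disc = DiscretizationSpec(3)
        codes = discretize_matrix(planted_dataset.values[planted_dataset.gene_index(sub)], disc)
        fast = _rfe_coefficients_all(codes, np.asarray(y), 3)
        for k, g in enumerate(sub):
            slow = rfe_coefficient(planted_dataset, y, g, sub, disc)
            assert fast[k] == pytest.approx(slow, rel=1e-9, abs=1e-9)

    def test_subset_of_one_rejected(self, planted_dataset):
        with pytest.raises(ValueError, match=">= 2"):
            rfe_coefficient(
                planted_dataset, planted_dataset.label_vector(), "g0000", ("g0000",)
            )


class TestRfeSearch:
    def test_extreme_m_two_step_schedule(self, tiny_two_class):
        # m = n_genes - 1: the full set and a single surviving gene
        trace = rfe_search(
            tiny_two_class, tiny_two_class.label_vector(), RfeSpec(m=2), _wrapper_ev(k=3)
        )
        assert len(trace.steps) == 2
        assert len(trace.steps[0][0]) == 3
        assert len(trace.steps[1][0]) == 1

    def test_sizes_strictly_decrease_by_m(self, planted_dataset):
        trace = rfe_search(
            planted_dataset, planted_dataset.label_vector(), RfeSpec(m=10), _distance_ev()
        )
        sizes = [len(s) for s, _ in trace.steps]
        assert all(a - b == 10 for a, b in zip(sizes, sizes[1:]))

    def test_planted_recovery(self, planted, ):
        ds, truth = planted
        trace = rfe_search(ds, ds.label_vector(), RfeSpec(m=5), _wrapper_ev())
        recovered = len(set(trace.best_subset) & set(truth)) / len(truth)
        assert recovered >= 0.7

    def test_reproducible_trace(self, planted_dataset):
        y = planted_dataset.label_vector()
        t1 = rfe_search(planted_dataset, y, RfeSpec(m=10), _wrapper_ev(seed=3))
        t2 = rfe_search(planted_dataset, y, RfeSpec(m=10), _wrapper_ev(seed=3))
        assert t1.steps == t2.steps


class TestMrmr:
    def test_first_pick_is_max_relevance(self, planted_dataset):
        y = planted_dataset.label_vector()
        disc = DiscretizationSpec(3)
        trace = mrmr_search(planted_dataset, y, disc, _distance_ev(), max_iter=3)
        codes = discretize_matrix(planted_dataset.values, disc)
        nmis = [normalized_mi(codes[g], y) for g in range(planted_dataset.n_genes)]
        assert trace.steps[0][0][0] == planted_dataset.gene_ids[int(np.argmax(nmis))]

    def test_exact_copy_not_chosen_second(self):
        rng = np.random.default_rng(17)
        strong = np.concatenate([rng.normal(-2, 0.2, 10), rng.normal(2, 0.2, 10)])
        other = np.concatenate([rng.normal(-1, 0.5, 10), rng.normal(1, 0.5, 10)])
        values = np.vstack([strong, strong.copy(), other, rng.normal(size=20)])
        ds = ExpressionDataset(
            ("strong", "copy", "other", "noise"), tuple(f"s{i}" for i in range(20)), values
        )
        y = np.array(["A"] * 10 + ["B"] * 10)
        trace = mrmr_search(ds, y, DiscretizationSpec(3), _distance_ev(), max_iter=2)
        first, second = trace.steps[0][0][0], trace.steps[1][0][1]
        assert first in ("strong", "copy")
        assert second not in ("strong", "copy")  # the duplicate is maximally redundant

    def test_coefficients_match_hand_rolled_loop(self):
        rng = np.random.default_rng(19)
        values = rng.normal(size=(4, 12))
        ds = ExpressionDataset(("a", "b", "c", "d"), tuple(f"s{i}" for i in range(12)), values)
        y = np.array(["A"] * 6 + ["B"] * 6)
        disc = DiscretizationSpec(3)
        codes = discretize_matrix(values, disc)
        selected = ["b"]
        got = mrmr_coefficients(ds, y, selected, disc)
        for i, g in enumerate(("a", "c", "d")):
            gi = {"a": 0, "c": 2, "d": 3}[g]
            rel = normalized_mi(codes[gi], y)
            red = mutual_information(codes[gi], codes[1])
            assert got[g] == pytest.approx(rel / max(red, 1e-6))

    def test_subsets_grow_by_one_no_repeats(self, planted_dataset):
        y = planted_dataset.label_vector()
        trace = mrmr_search(planted_dataset, y, DiscretizationSpec(3), _distance_ev(), 8)
        for k, (sub, _) in enumerate(trace.steps):
            assert len(sub) == k + 1
            assert len(set(sub)) == len(sub)


class TestUnivariateForward:
    def test_planted_gene_ranked_first(self, tiny_two_class):
        trace = univariate_forward_search(
            tiny_two_class, tiny_two_class.label_vector(), "f", _wrapper_ev(k=3), 3
        )
        assert trace.steps[0][0] == ("g0",)

    def test_max_iter_one_single_step(self, planted_dataset):
        trace = univariate_forward_search(
            planted_dataset, planted_dataset.label_vector(), "gs2", _distance_ev(), 1
        )
        assert len(trace.steps) == 1

    def test_prefix_errors_match_direct_evaluator_calls(self, planted_dataset):
        y = planted_dataset.label_vector()
        ev = _distance_ev()
        trace = univariate_forward_search(planted_dataset, y, "f", ev, 5)
        for sub, err in trace.steps:
            assert err == pytest.approx(ev(planted_dataset, y, list(sub)))


class TestGa:
    def test_population_one_no_operators_chromosome_fixed(self, planted_dataset):
        y = planted_dataset.label_vector()
        spec = GaSpec(population_size=1, chromosome_length=5, crossover_prob=0.0,
                      mutation_prob=0.0, elitism_count=1, max_generations=3,
                      slope_threshold=1.0, seed=4)
        trace = ga_search(planted_dataset, y, spec, _distance_ev())
        # a single elitist chromosome with no operators is never replaced,
        # so only one distinct subset is ever evaluated
        assert len(trace.steps) == 1

    def test_best_error_non_increasing_with_elitism(self, planted_dataset):
        y = planted_dataset.label_vector()
        spec = GaSpec(population_size=10, chromosome_length=8, max_generations=8,
                      slope_threshold=1.0, seed=5)
        trace = ga_search(planted_dataset, y, spec, _distance_ev())
        best_so_far = np.minimum.accumulate([e for _, e in trace.steps])
        assert trace.best_error == best_so_far[-1]

    def test_planted_recovery_with_long_enough_chromosome(self, planted):
        ds, truth = planted
        spec = GaSpec(population_size=24, chromosome_length=12, max_generations=60,
                      mutation_prob=0.05, seed=6)
        trace = ga_search(ds, ds.label_vector(), spec, _distance_ev())
        assert len(set(trace.best_subset) & set(truth)) / len(truth) >= 0.7


class TestTraceContract:
    def test_best_is_minimum_and_member(self, planted_dataset):
        y = planted_dataset.label_vector()
        trace = univariate_forward_search(planted_dataset, y, "f", _distance_ev(), 10)
        errors = [e for _, e in trace.steps]
        assert trace.best_error == min(errors)
        assert any(frozenset(trace.best_subset) == frozenset(s) for s, _ in trace.steps)

    def test_duplicate_subsets_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SelectionTrace(tuple([(("a",), 0.1), (("a",), 0.2)]))

    def test_perfect_separator_found_by_all_sequential_methods(self, tiny_two_class):
        y = tiny_two_class.label_vector()
        ev = _wrapper_ev(k=3)
        traces = [
            rfe_search(tiny_two_class, y, RfeSpec(m=1, x=5, y=0), ev),
            mrmr_search(tiny_two_class, y, DiscretizationSpec(3), ev, 3),
            univariate_forward_search(tiny_two_class, y, "f", ev, 3),
        ]
        for trace in traces:
            assert trace.best_error == 0.0
            assert "g0" in trace.best_subset
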