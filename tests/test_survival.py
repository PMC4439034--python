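"""DEG filtering, Kaplan-Meier estimation and log-rank validation."""

import numpy as np
import pytest

from sigselect import (
    ExpressionDataset,
    SimulationSpec,
    SurvivalTable,
    generate_progression,
    generate_survival,
    kaplan_meier,
    logrank_test,
    t_test_deg,
    univariate_scores,
    validate_signature,
)


class TestTTestDeg:
    def test_planted_shift_high_sensitivity(self):
        rng = np.random.default_rng(43)
        n_genes, shift_genes = 300, 30
        values = rng.normal(0, 0.5, size=(n_genes, 20))
        values[:shift_genes, 10:] += 1.5  # 3 sigma shift
        ds = ExpressionDataset(
            tuple(f"g{i}" for i in range(n_genes)), tuple(f"s{i}" for i in range(20)), values
        )
        hits = t_test_deg(ds, [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)],
                          alpha=0.001)
        found = {g for g, _, _ in hits}
        sens = len(found & {f"g{i}" for i in range(shift_genes)}) / shift_genes
        assert sens >= 0.95

    def test_null_flags_about_alpha(self):
        rng = np.random.default_rng(44)
        values = rng.normal(size=(5000, 16))
        ds = ExpressionDataset(
            tuple(f"g{i}" for i in range(5000)), tuple(f"s{i}" for i in range(16)), values
        )
        hits = t_test_deg(ds, [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)],
                          alpha=0.05)
        assert len(hits) / 5000 == pytest.approx(0.05, abs=0.015)

    def test_t_squared_equals_anova_f(self):
        rng = np.random.default_rng(45)
        values = rng.normal(size=(10, 12))
        ds = ExpressionDataset(
            tuple(f"g{i}" for i in range(10)), tuple(f"s{i}" for i in range(12)), values
        )
        a = [f"s{i}" for i in range(6)]
        b = [f"s{i}" for i in range(6, 12)]
        hits = {g: t for g, t, _ in t_test_deg(ds, a, b, alpha=1.0)}
        labels = np.array(["A"] * 6 + ["B"] * 6)
        f = univariate_scores(ds, labels, "f")
        for g, t in hits.items():
            assert t**2 == pytest.approx(f[g], rel=1e-6)

    def test_degenerate_gene_gets_p_one(self):
        import warnings

        values = np.vstack([np.zeros(8), np.r_[np.zeros(4), np.ones(4)]])
        ds = ExpressionDataset(("flat", "sep"), tuple(f"s{i}" for i in range(8)), values)
        with warnings.catch_warnings():
            # the all-zero gene intentionally triggers scipy's constant-input path
            warnings.simplefilter("ignore", RuntimeWarning)
            hits = t_test_deg(ds, [f"s{i}" for i in range(4)],
                              [f"s{i}" for i in range(4, 8)], alpha=1.01)
        as_dict = {g: p for g, _, p in hits}
        assert as_dict["flat"] == 1.0


class TestKaplanMeier:
    def test_hand_example_product_limit(self):
        # times 1 (event), 2 (censored), 3 (event): S = 1, 2/3, 2/3, 0
        t = SurvivalTable(("a", "b", "c"), np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        curve = kaplan_meier(t)
        s_at = dict(zip(curve.times, curve.survival))
        assert s_at[0.0] == pytest.approx(1.0)
        assert s_at[1.0] == pytest.approx(2 / 3)
        assert s_at[2.0] == pytest.approx(2 / 3)
        assert s_at[3.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(46)
        times = rng.exponential(100, size=40)
        t = SurvivalTable(tuple(f"s{i}" for i in range(40)), times, np.ones(40, dtype=int))
        curve = kaplan_meier(t)
        for ti, si in zip(curve.times, curve.survival):
            assert si == pytest.approx((times > ti).mean(), abs=1e-12)

    def test_all_censored_survival_stays_one(self):
        t = SurvivalTable(("a", "b", "c"), np.array([5.0, 7.0, 9.0]), np.zeros(3, dtype=int))
        curve = kaplan_meier(t)
        assert np.all(curve.survival == 1.0)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([3.0, 5.0, 8.0, 13.0])
        t = SurvivalTable(
            tuple(f"s{i}" for i in range(8)),
            np.concatenate([times, times]),
            np.ones(8, dtype=int),
            ("A",) * 4 + ("B",) * 4,
        )
        chi2, df, p = logrank_test(t)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1

    def test_manual_observed_expected_oracle(self):
        # 2 groups, hand-computed observed-minus-expected table
        t = SurvivalTable(
            ("a1", "a2", "a3", "b1", "b2", "b3"),
            np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0]),
            np.array([1, 1, 1, 1, 1, 0]),
            ("A", "A", "A", "B", "B", "B"),
        )
        grp = np.asarray(t.group)
        # manual log-rank over distinct event times
        o_minus_e = 0.0
        var = 0.0
        for ti in sorted(t.time[t.event == 1]):
            at_risk = t.time >= ti
            n = at_risk.sum()
            n_a = (at_risk & (grp == "A")).sum()
            d = ((t.time == ti) & (t.event == 1)).sum()
            d_a = ((t.time == ti) & (t.event == 1) & (grp == "A")).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, df, p = logrank_test(t)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_invariance_to_relabeling_and_time_shift(self):
        rng = np.random.default_rng(47)
        times = rng.exponential(50, 20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        groups = tuple(rng.choice(["X", "Y"], 20))
        t1 = SurvivalTable(tuple(f"s{i}" for i in range(20)), times, events, groups)
        relabeled = tuple({"X": "group2", "Y": "group1"}[g] for g in groups)
        t2 = SurvivalTable(tuple(f"s{i}" for i in range(20)), times + 7.0, events, relabeled)
        assert logrank_test(t1)[0] == pytest.approx(logrank_test(t2)[0], rel=1e-9)

    def test_zero_events_rejected(self):
        t = SurvivalTable(("a", "b"), np.array([1.0, 2.0]), np.zeros(2, dtype=int), ("A", "B"))
        with pytest.raises(ValueError, match="events"):
            logrank_test(t)


class TestValidateSignature:
    def _subtype_cohort(self, seed=48):
        from dataclasses import replace

        spec = SimulationSpec(
            n_genes=120, n_informative=15, n_samples_per_class=20,
            classes=("A", "B"), effect_size=2.0, noise_sd=0.5,
            n_redundant_blocks=0, hazard_ratio=4.0, censor_fraction=0.1, seed=seed,
        )
        # noise-only base so the subtype shift is the only expression signal
        base, _ = generate_progression(replace(spec, n_informative=0))
        shifted, table = generate_survival(base, spec)
        truth = [base.gene_ids[i] for i in range(spec.n_informative)]
        return shifted, table, truth

    def test_recovers_subtypes_with_significant_logrank(self):
        ds, table, truth = self._subtype_cohort()
        res = validate_signature(truth, ds, table, n_clusters=2)
        assert res["p_value"] < 0.05
        assert res["significant"]

    def test_assignment_independent_of_gene_order(self):
        ds, table, truth = self._subtype_cohort(seed=49)
        res1 = validate_signature(truth, ds, table, n_clusters=2)
        res2 = validate_signature(list(reversed(truth)), ds, table, n_clusters=2)
        assert res1["assignment"] == res2["assignment"]

    def test_no_present_gene_rejected(self):
        ds, table, _ = self._subtype_cohort(seed=50)
        with pytest.raises(ValueError, match="signature gene"):
            validate_signature(["not_a_gene"], ds, table)

    def test_degenerate_cluster_count_rejected(self):
        ds, table, truth = self._subtype_cohort(seed=51)
        with pytest.raises(ValueError, match="n_clusters"):
            validate_signature(truth, ds, table, n_clusters=ds.n_samples)
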