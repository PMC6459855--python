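import numpy as np
import pytest
from scipy import stats

import physcent as pc
from physcent.centrality import CentralityMap
from physcent.groupstats import MEASURES, CohortResult, anova_table


def _cohort_from_arrays(zmaps: dict[str, np.ndarray]) -> CohortResult:
    """Assemble a CohortResult directly from per-measure (N, n) arrays."""
    n = next(iter(zmaps.values())).shape[1]
    labels = tuple(f"n{i}" for i in range(n))
    group_mean = {
        k: CentralityMap(measure=k, values=z.mean(axis=0), labels=labels, z=True)
        for k, z in zmaps.items()
    }
    group_sd = {k: z.std(axis=0, ddof=1) for k, z in zmaps.items()}
    return CohortResult(
        labels=labels, zmaps=zmaps, group_mean=group_mean,
        group_sd=group_sd, group_hubs={},
    )


class TestJaccard:
    def test_hand_cases(self):
        assert pc.jaccard({1, 2, 3}, {2, 3, 4}) == pytest.approx(0.5)
        assert pc.jaccard({1, 2}, {1, 2}) == 1.0
        assert pc.jaccard({1}, {2}) == 0.0

    def test_both_empty_is_vacuous_overlap(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="physcent.groupstats"):
            assert pc.jaccard(set(), set()) == 1.0
        assert any("empty" in r.message for r in caplog.records)

    def test_symmetry_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = set(rng.integers(0, 10, size=rng.integers(0, 8)).tolist())
            b = set(rng.integers(0, 10, size=rng.integers(0, 8)).tolist())
            assert pc.jaccard(a, b) == pc.jaccard(b, a)
            assert len(a & b) <= min(len(a), len(b))

    def test_accepts_hub_sets(self):
        m1 = CentralityMap("C_D_node", np.array([0.0, 0, 0, 10]), tuple("abcd"))
        m2 = CentralityMap("C_P_node", np.array([0.0, 0, 10, 0]), tuple("abcd"))
        assert pc.jaccard(pc.detect_hubs(m1), pc.detect_hubs(m2)) == 0.0


class TestRegression:
    def test_identity(self):
        labels = tuple("abcde")
        x = CentralityMap("C_D_node", np.arange(5.0), labels)
        res = pc.pairwise_regression(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_null_relationship(self):
        rng = np.random.default_rng(6)
        labels = tuple(f"n{i}" for i in range(200))
        x = CentralityMap("C_D_node", rng.normal(size=200), labels)
        y = CentralityMap("C_B_node", rng.normal(size=200), labels)
        res = pc.pairwise_regression(x, y)
        assert res.r2 < 0.05

    def test_hand_computed_triple(self):
        # x = (-1, 0, 1), y = (-1, 0.1, 1): OLS slope 1, intercept 0.1/3... no:
        # slope = cov/var = ((-1)(-1-0.0333...) + ...) — compute from closed form
        x_vals = np.array([-1.0, 0.0, 1.0])
        y_vals = np.array([-1.0, 0.1, 1.0])
        slope = np.sum((x_vals - x_vals.mean()) * (y_vals - y_vals.mean())) / np.sum(
            (x_vals - x_vals.mean()) ** 2
        )
        intercept = y_vals.mean() - slope * x_vals.mean()
        ss_res = np.sum((y_vals - slope * x_vals - intercept) ** 2)
        ss_tot = np.sum((y_vals - y_vals.mean()) ** 2)
        r2_expected = 1 - ss_res / ss_tot
        labels = tuple("abc")
        res = pc.pairwise_regression(
            CentralityMap("C_D_node", x_vals, labels),
            CentralityMap("C_B_node", y_vals, labels),
        )
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.r2 == pytest.approx(r2_expected)

    def test_zero_variance_rejected(self):
        labels = tuple("abc")
        x = CentralityMap("C_D_node", np.zeros(3), labels)
        y = CentralityMap("C_B_node", np.arange(3.0), labels)
        with pytest.raises(ValueError, match="variance"):
            pc.pairwise_regression(x, y)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        z = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 2))  # 3 subjects, 2 nodes
        cohort = _cohort_from_arrays({m: z.copy() for m in MEASURES})
        rows = pc.compare_measures_anova(cohort)
        for r in rows:
            assert r.F == 0.0
            assert r.p == 1.0
            assert r.posthoc == ()

    def test_separated_group_flagged_by_posthoc(self):
        rng = np.random.default_rng(2)
        n_sub, n_nodes = 8, 3
        noise = lambda: rng.normal(0, 0.01, size=(n_sub, n_nodes))
        cohort = _cohort_from_arrays(
            {
                "C_D_node": noise(),
                "C_B_node": noise(),
                "C_P_node": 10.0 + noise(),
            }
        )
        rows = pc.compare_measures_anova(cohort)
        for r in rows:
            assert r.F > 100
            assert r.p_fdr < 0.05
            assert ("C_D_node", "C_P_node") in r.posthoc
            assert ("C_B_node", "C_P_node") in r.posthoc

    def test_textbook_f_value(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB=42 (df 2), SSW=6 (df 6) -> F=21
        cohort = _cohort_from_arrays(
            {
                "C_D_node": np.array([[1.0], [2.0], [3.0]]),
                "C_B_node": np.array([[2.0], [3.0], [4.0]]),
                "C_P_node": np.array([[6.0], [7.0], [8.0]]),
            }
        )
        row = pc.compare_measures_anova(cohort)[0]
        assert row.F == pytest.approx(21.0)
        assert row.p == pytest.approx(stats.f.sf(21.0, 2, 6))

    def test_fdr_monotone_and_geq_raw(self, small_cohort):
        rows = pc.compare_measures_anova(small_cohort)
        raw = np.array([r.p for r in rows])
        adj = np.array([r.p_fdr for r in rows])
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_single_subject_rejected(self):
        cohort = _cohort_from_arrays({m: np.ones((1, 2)) for m in MEASURES})
        with pytest.raises(ValueError, match="2 subjects"):
            pc.compare_measures_anova(cohort)

    def test_table_shape(self, small_cohort):
        df = anova_table(pc.compare_measures_anova(small_cohort))
        assert len(df) == small_cohort.n_nodes
        assert {"node", "F", "p", "p_fdr", "posthoc"} <= set(df.columns)


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        z = np.array([[2.0], [2.0], [2.0]])
        cohort = _cohort_from_arrays({m: z.copy() for m in MEASURES})
        assert pc.coefficient_of_variation(cohort, 0, "C_D_node") == 0.0

    def test_two_point_hand_value(self):
        z = np.array([[1.0], [3.0]])
        cohort = _cohort_from_arrays({m: z.copy() for m in MEASURES})
        cv = pc.coefficient_of_variation(cohort, 0, "C_B_node")
        assert cv == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 2, size=(7, 1))
        for a in (2.0, 0.3):
            c1 = _cohort_from_arrays({m: x.copy() for m in MEASURES})
            c2 = _cohort_from_arrays({m: a * x for m in MEASURES})
            assert pc.coefficient_of_variation(
                c1, 0, "C_P_node"
            ) == pytest.approx(pc.coefficient_of_variation(c2, 0, "C_P_node"))

    def test_near_zero_mean_reported_missing(self):
        z = np.array([[-1.0], [1.0]])
        cohort = _cohort_from_arrays({m: z.copy() for m in MEASURES})
        assert np.isnan(pc.coefficient_of_variation(cohort, 0, "C_D_node"))


class TestCvComparison:
    def _cohort(self, cv_a, cv_b):
        """Cohort whose C_D/C_B CV vectors across nodes equal cv_a/cv_b."""
        n = len(cv_a)
        subs = 2  # two subjects give CV = |x1-x2| / (sqrt(2)/2 / mean...)
        # construct X = mean 1, sd = cv (two-point sample mean 1, sd cv)
        d = {
            "C_D_node": np.vstack([1 + np.array(cv_a) / np.sqrt(2),
                                   1 - np.array(cv_a) / np.sqrt(2)]),
            "C_B_node": np.vstack([1 + np.array(cv_b) / np.sqrt(2),
                                   1 - np.array(cv_b) / np.sqrt(2)]),
            "C_P_node": np.ones((2, n)),
        }
        return _cohort_from_arrays(d)

    def test_identical_cvs(self):
        cohort = self._cohort([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        t, p = pc.cv_comparison_test(cohort, [0, 1, 2], ("C_D_node", "C_B_node"))
        assert t == 0.0
        assert p == 1.0

    def test_constant_offset_degenerate(self):
        # one CV vector uniformly larger: p collapses to the machine floor
        cohort = self._cohort([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        t, p = pc.cv_comparison_test(cohort, [0, 1, 2], ("C_B_node", "C_D_node"))
        assert t > 1e6 or np.isinf(t)
        assert p < 1e-12

    def test_hand_paired_t(self):
        a = np.array([0.1, 0.25, 0.3])
        b = np.array([0.4, 0.5, 0.62])
        cohort = self._cohort(a, b)
        t, p = pc.cv_comparison_test(cohort, [0, 1, 2], ("C_D_node", "C_B_node"))
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(t_expect, rel=1e-6)

    def test_too_few_nodes_rejected(self):
        cohort = self._cohort([0.1], [0.2])
        with pytest.raises(ValueError, match="fewer than 2"):
            pc.cv_comparison_test(cohort, [0], ("C_D_node", "C_B_node"))


class TestBuildCohort:
    def test_identical_subjects(self):
        base = pc.generate_connectome(
            pc.ConnectomeSpec(n=12, density=0.35, n_modules=2, seed=3)
        )
        cohort = pc.build_cohort([base] * 3)
        for m in MEASURES:
            np.testing.assert_allclose(cohort.group_sd[m], 0.0, atol=1e-12)

    def test_mismatched_nodes_rejected(self):
        a = pc.fixture("path3")
        b = pc.fixture("star4")
        with pytest.raises(ValueError, match="node set"):
            pc.build_cohort([a, b])

    def test_full_pipeline_deterministic(self, small_cohort):
        assert small_cohort.n_subjects == 6
        assert set(small_cohort.zmaps) == set(MEASURES)
        for m in MEASURES:
            z = small_cohort.zmaps[m]
            np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
            np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)
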