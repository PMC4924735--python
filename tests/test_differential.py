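from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mentx import (
    ComparisonSpec,
    SampleAnnotation,
    ValidationError,
    category_selector,
    permutation_fdr,
    t_test_de,
)
from mentx.differential import _pooled_t, default_comparisons

from conftest import make_matrix


def two_group_annotations(n_a, n_b):
    ann = []
    for i in range(n_a):
        ann.append(SampleAnnotation(f"s{i}", "I", "R", followup_months=24.0,
                                    pfs_months=20.0, progression_event=True))
    for i in range(n_a, n_a + n_b):
        ann.append(SampleAnnotation(f"s{i}", "I", "NR", followup_months=48.0))
    return ann


def simple_spec(p=0.01, fc=1.25):
    return ComparisonSpec("test", category_selector("1R"), category_selector("1NR"), p, fc)


class TestPooledT:
    def test_hand_computed_example(self):
        """A=(1,2,3), B=(4,5,6): pooled t = -3.674235, df = 4, p = 0.021312."""
        m = make_matrix([[1, 2, 3, 4, 5, 6]])
        res = t_test_de(m, simple_spec(), two_group_annotations(3, 3))
        assert res["t_statistic"].iloc[0] == pytest.approx(-3.6742346141747673, abs=1e-9)
        assert res["p_value"].iloc[0] == pytest.approx(0.021311641128756713, abs=1e-9)
        assert res["delta_log2"].iloc[0] == pytest.approx(-3.0)

    def test_identical_groups_give_t_zero_p_one(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = t_test_de(m, simple_spec(), two_group_annotations(3, 3))
        assert res["t_statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_fold_change_mapping(self):
        delta = np.log2(1.25)
        m = make_matrix([[delta, delta, delta, 0.0, 0.0, 0.0]])
        res = t_test_de(m, simple_spec(), two_group_annotations(3, 3))
        assert res["fold_change_linear"].iloc[0] == pytest.approx(1.25)

    def test_matches_scipy_ttest_ind(self, rng):
        """Dual route: vectorized pooled t vs scipy's equal-variance test."""
        X = rng.normal(0, 1, (200, 12))
        m = make_matrix(X)
        res = t_test_de(m, simple_spec(), two_group_annotations(5, 7))
        ref = stats.ttest_ind(X[:, :5], X[:, 5:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_statistic"], ref.statistic, rtol=1e-8)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, rtol=1e-8)

    def test_group_swap_negates_statistics(self, rng):
        X = rng.normal(0, 1, (50, 10))
        m = make_matrix(X)
        ann = two_group_annotations(5, 5)
        spec = simple_spec()
        swapped = ComparisonSpec("sw", spec.group_b, spec.group_a, 0.01, 1.25)
        a = t_test_de(m, spec, ann)
        b = t_test_de(m, swapped, ann)
        np.testing.assert_allclose(a["t_statistic"], -b["t_statistic"], rtol=1e-9)
        np.testing.assert_allclose(a["delta_log2"], -b["delta_log2"], rtol=1e-9)
        np.testing.assert_allclose(a["fold_change_linear"],
                                   1.0 / b["fold_change_linear"], rtol=1e-9)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-9)

    def test_sign_consistency_invariant(self, rng):
        X = rng.normal(0, 1, (300, 10))
        res = t_test_de(make_matrix(X), simple_spec(), two_group_annotations(5, 5))
        nz = res[res["t_statistic"] != 0]
        assert (np.sign(nz["t_statistic"]) == np.sign(nz["delta_log2"])).all()
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        assert (res["fold_change_linear"] > 0).all()

    def test_degenerate_constant_gene_flagged(self):
        m = make_matrix([[5.0] * 10, [5.0] * 5 + [6.0] * 5])
        res = t_test_de(m, simple_spec(), two_group_annotations(5, 5))
        assert bool(res["degenerate"].iloc[0]) and res["p_value"].iloc[0] == 1.0
        assert bool(res["degenerate"].iloc[1]) and res["p_value"].iloc[1] < 1e-6

    def test_group_size_minimum(self):
        m = make_matrix(np.zeros((3, 4)))
        with pytest.raises(ValidationError, match="2 samples"):
            t_test_de(m, simple_spec(), two_group_annotations(1, 3))

    def test_planted_recovery_at_power_scale(self, rng):
        """|delta|=1, sigma=0.5, 10v10: >=90% of planted genes pass p<0.01."""
        n_planted, n_null = 200, 800
        X = rng.normal(0, 0.5, (n_planted + n_null, 20))
        X[:n_planted, :10] += 1.0
        res = t_test_de(make_matrix(X), simple_spec(), two_group_annotations(10, 10))
        recovered = (res["p_value"].iloc[:n_planted] < 0.01).mean()
        assert recovered >= 0.90


class TestPermutationFdr:
    def test_determinism(self, rng):
        X = rng.normal(0, 1, (300, 12))
        m = make_matrix(X)
        lab = np.array([True] * 6 + [False] * 6)
        a = permutation_fdr(m, lab, n_perm=50, seed=123)
        b = permutation_fdr(m, lab, n_perm=50, seed=123)
        assert a.fdr == b.fdr
        np.testing.assert_array_equal(a.null_counts, b.null_counts)

    def test_null_data_high_fdr(self):
        """No group effect + liberal thresholds -> FDR estimate near 1."""
        fdrs = []
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            X = r.normal(0, 1, (400, 12))
            m = make_matrix(X)
            lab = np.array([True] * 6 + [False] * 6)
            est = permutation_fdr(m, lab, p_threshold=0.2, fc_threshold=1.05,
                                  n_perm=40, seed=rep)
            assert est.fdr is not None
            fdrs.append(est.fdr)
        assert np.mean(fdrs) >= 0.8

    def test_sampled_matches_exhaustive_enumeration(self, rng):
        """3v3: exhaustive C(6,3)=20 label assignments vs sampled permutations."""
        X = rng.normal(0, 1, (150, 6))
        X[:20, :3] += 1.5
        m = make_matrix(X)
        lab = np.array([True, True, True, False, False, False])

        def count_passing(mask):
            a, b = X[:, mask], X[:, ~mask]
            t, p, delta, _ = _pooled_t(a, b)
            fc = np.exp2(delta)
            return np.sum((p < 0.05) & ((fc > 1.25) | (fc < 0.8)))

        null = [count_passing(np.isin(np.arange(6), combo))
                for combo in combinations(range(6), 3)]
        exhaustive = np.median(null) / count_passing(lab)

        est = permutation_fdr(m, lab, p_threshold=0.05, fc_threshold=1.25,
                              n_perm=400, seed=5)
        assert est.fdr == pytest.approx(min(exhaustive, 1.0), abs=0.15)

    def test_zero_observed_returns_undefined_not_error(self, rng):
        X = rng.normal(0, 1, (50, 8))
        m = make_matrix(X)
        lab = np.array([True] * 4 + [False] * 4)
        est = permutation_fdr(m, lab, p_threshold=1e-12, fc_threshold=50.0,
                              n_perm=10, seed=0)
        assert est.observed_count == 0 and est.fdr is None


class TestComparisonSpecs:
    def test_default_comparisons_cover_aggressive_groups(self):
        specs = default_comparisons()
        assert [s.name for s in specs] == ["1M+R_vs_1NR", "2M+R_vs_1NR", "WHOIII_vs_1NR"]
        assert specs[2].p_threshold == 0.001

    def test_overlapping_groups_rejected(self):
        spec = ComparisonSpec("bad", category_selector("1NR"), category_selector("1NR"))
        with pytest.raises(ValidationError, match="overlap"):
            spec.select(two_group_annotations(2, 2))

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            ComparisonSpec("x", category_selector("1R"), category_selector("1NR"),
                           fc_threshold=0.9)
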