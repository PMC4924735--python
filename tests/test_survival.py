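import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mentx import (
    SampleAnnotation,
    ValidationError,
    combined_gene_groups,
    cox_fit,
    dichotomize,
    filter_survival_cohort,
    km_estimate,
    logrank,
    multivariate_covariate_set,
    select_genes_for_multivariate,
    simulate_ph_cohort,
    survival_frame,
    univariate_cox,
)


def ann(sid, grade="I", sub="NR", **kw):
    kw.setdefault("simpson", 2)
    kw.setdefault("followup_months", 48.0)
    return SampleAnnotation(sid, grade, sub, **kw)


class TestCohortFilter:
    def test_empty_input(self):
        eligible, log = filter_survival_cohort([])
        assert eligible == [] and log.empty

    def test_manual_rule_application(self):
        records = [
            SampleAnnotation("a", "III", "NA", simpson=4, followup_months=20.0,
                             pfs_months=20.0),                      # Simpson 4: out
            ann("b", followup_months=30.0),                         # NR, 30 mo: out
            ann("c", followup_months=40.0),                         # NR, 40 mo: in
            ann("d", sub="R", followup_months=12.0, pfs_months=12.0,
                progression_event=True),                            # event: in
        ]
        eligible, log = filter_survival_cohort(records)
        assert [a.sample_id for a in eligible] == ["c", "d"]
        assert "Simpson" in log.set_index("sample_id").loc["a", "reasons"]

    def test_prior_treatment_excluded(self):
        rec = ann("x", treatment_naive=False)
        eligible, log = filter_survival_cohort([rec])
        assert eligible == []
        assert "radio" in log["reasons"].iloc[0]

    def test_recurrent_tumor_excluded(self):
        rec = ann("x", sub="R", is_primary=False, followup_months=50.0,
                  pfs_months=20.0, progression_event=True)
        eligible, _ = filter_survival_cohort([rec])
        assert eligible == []

    def test_survival_frame_times(self):
        f = survival_frame([ann("a", followup_months=40.0)])
        assert f.loc["a", "time"] == 40.0 and not f.loc["a", "event"]


class TestDichotomize:
    def test_median_rule(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels, cut = dichotomize(values, "median")
        assert cut == 2.5
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_upper_quartile_linear_interpolation(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels, cut = dichotomize(values, "upper_quartile")
        assert cut == pytest.approx(3.25)
        assert set(labels[labels == "high"].index) == {"d"}

    def test_tie_at_cut_goes_low(self):
        values = pd.Series([1.0, 2.0, 2.0, 3.0])
        labels, cut = dichotomize(values, "median")
        assert cut == 2.0
        assert (labels == "high").sum() == 1    # only the 3.0

    def test_constant_values_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            dichotomize(pd.Series([1.0, 1.0, 1.0]))


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        est = km_estimate([1.0, 2.0, 3.0], [True, True, True]).set_index("time")
        assert est.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert est.loc[2.0, "survival"] == pytest.approx(1 / 3)
        assert est.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        """Events at 1 and 3, censored at 2: S = 2/3 after t=1, 0 after t=3."""
        est = km_estimate([1.0, 2.0, 3.0], [True, False, True]).set_index("time")
        assert est.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert est.loc[2.0, "survival"] == pytest.approx(2 / 3)
        assert est.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        est = km_estimate([5.0, 7.0], [False, False])
        assert (est["survival"] == 1.0).all()

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 40)
        est = km_estimate(t, np.ones(40, bool)).set_index("time")
        for tt in np.quantile(t, [0.2, 0.5, 0.8]):
            emp = (t > tt).mean()
            km_at = est["survival"][est.index <= tt].iloc[-1]
            assert km_at == pytest.approx(emp, abs=1e-9)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_o_minus_e(self):
        """6+6 worked dataset: chi-square matches a direct O−E/V tally to 1e-6."""
        tA, eA = [2, 4, 6, 8, 10, 12], [1, 1, 1, 0, 1, 1]
        tB, eB = [1, 3, 5, 7, 9, 11], [1, 1, 0, 1, 1, 1]

        data = sorted(
            [(t, e, 0) for t, e in zip(tA, eA)] + [(t, e, 1) for t, e in zip(tB, eB)]
        )
        O = E = V = 0.0
        for tt in sorted({t for t, e, _ in data if e}):
            nA = sum(1 for t, _, g in data if t >= tt and g == 0)
            nB = sum(1 for t, _, g in data if t >= tt and g == 1)
            dA = sum(1 for t, e, g in data if t == tt and e and g == 0)
            dB = sum(1 for t, e, g in data if t == tt and e and g == 1)
            n, d = nA + nB, dA + dB
            O += dA
            E += d * nA / n
            if n > 1:
                V += d * (nA / n) * (nB / n) * (n - d) / (n - 1)
        hand_chi2 = (O - E) ** 2 / V

        stat, p = logrank(tA + tB, eA + eB, ["A"] * 6 + ["B"] * 6)
        assert stat == pytest.approx(hand_chi2, abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(hand_chi2, 1), abs=1e-6)

    def test_planted_hazard_ratio_detected(self):
        """HR=3 between two arms of 200: log-rank p < 0.01 in >= 95% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            tA = r.exponential(1.0 / 0.02, 200)
            tB = r.exponential(1.0 / 0.06, 200)
            cens = r.exponential(200.0, 400)
            t = np.concatenate([tA, tB])
            e = t <= cens
            t = np.minimum(t, cens)
            _, p = logrank(t, e, ["A"] * 200 + ["B"] * 200)
            hits += p < 0.01
        assert hits / n_seeds >= 0.95

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank([1.0, 2.0], [True, True], ["a", "a"])


class TestCox:
    def test_planted_hr_recovery(self):
        """log-HR = log 2, n=500, ~20% censoring: HR estimates within [1.7, 2.3]."""
        hrs = []
        for seed in range(5):
            df = simulate_ph_cohort(500, np.log(2.0), censoring_fraction=0.2,
                                    seed=100 + seed)
            fit = cox_fit(df, ["x"])
            hrs.append(fit.hazard_ratio("x"))
        assert 1.7 <= np.mean(hrs) <= 2.3

    def test_null_covariate_ci_coverage(self):
        """Planted HR=1: the 95% CI covers 1.0 in roughly 95% of replicates."""
        cover = 0
        n_rep = 60
        for seed in range(n_rep):
            df = simulate_ph_cohort(150, 0.0, censoring_fraction=0.2, seed=seed)
            fit = cox_fit(df, ["x"])
            lo, hi = fit.ci("x")
            cover += lo <= 1.0 <= hi
        assert 0.85 <= cover / n_rep <= 1.0

    def test_ci_contains_hr(self):
        df = simulate_ph_cohort(300, 0.5, seed=3)
        fit = cox_fit(df, ["x"])
        lo, hi = fit.ci("x")
        assert lo < fit.hazard_ratio("x") < hi

    def test_constant_covariate_rejected(self):
        df = simulate_ph_cohort(50, 0.0, seed=0).assign(c=1.0)
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(df, ["c"])

    def test_categorical_expansion_against_reference(self):
        df = simulate_ph_cohort(300, 0.7, seed=9)
        df["grade"] = np.where(df["x"] > 0.5, "III", np.where(df["x"] > -0.5, "II", "I"))
        fit = cox_fit(df, ["grade"])
        assert {"grade_II_vs_I", "grade_III_vs_I"} == set(fit.summary.index)
        assert fit.hazard_ratio("grade_III_vs_I") > fit.hazard_ratio("grade_II_vs_I")

    def test_sparse_events_warns(self):
        df = simulate_ph_cohort(30, 0.0, censoring_fraction=0.9, seed=1)
        if df["event"].sum() < 5:
            with pytest.warns(UserWarning, match="events"):
                cox_fit(df, ["x"])


class TestModelSelection:
    def test_multivariate_set_is_pure_function_of_univariate_p(self):
        df = simulate_ph_cohort(400, np.log(2.0), seed=21)
        rng = np.random.default_rng(1)
        df["noise"] = rng.normal(size=len(df))
        uni = univariate_cox(df, ["x", "noise"])
        selected = multivariate_covariate_set(uni, alpha=0.05)
        expected = [
            cov for cov, grp in uni.groupby("covariate", sort=False)
            if (grp["p_lr"] < 0.05).any()
        ]
        assert selected == expected
        assert "x" in selected and "noise" not in selected

    def test_gene_entry_rule_lowest_p_below_cutoff(self):
        pvals = {"PTTG1": 2e-4, "LEPR": 5e-4, "ECT2": 5e-3, "MN1": 0.2}
        assert select_genes_for_multivariate(pvals) == ["PTTG1", "LEPR"]
        assert select_genes_for_multivariate(pvals, p_cutoff=1e-5) == []


class TestCombinedGroups:
    def test_hand_labels_eight_samples(self):
        p = pd.Series([1, 2, 3, 4, 5, 6, 7, 8.0], index=list("abcdefgh"))
        l = pd.Series([8, 7, 6, 5, 4, 3, 2, 1.0], index=list("abcdefgh"))
        labels, table, _ = combined_gene_groups(p, l)
        # PTTG1 upper quartile cut = 6.25 -> high = {g, h}; LEPR median = 4.5 -> high = {a..d}
        assert (labels[list("gh")] == "PTTG1-high/LEPR-low").all()
        assert (labels[list("abcd")] == "PTTG1-low/LEPR-high").all()
        assert (labels[list("ef")] == "PTTG1-low/LEPR-low").all()
        assert table["n"].sum() == 8

    def test_group_sizes_partition_cohort(self, rng):
        idx = [f"s{i}" for i in range(40)]
        p = pd.Series(rng.normal(0, 1, 40), index=idx)
        l = pd.Series(rng.normal(0, 1, 40), index=idx)
        labels, table, _ = combined_gene_groups(p, l)
        assert table["n"].sum() == 40
        assert labels.notna().all()

    def test_protective_combination_longest_pfs(self, default_cohort):
        """Low hazard-gene / high protective-gene group survives longest."""
        c = default_cohort
        eligible, _ = filter_survival_cohort(c.annotations)
        frame = survival_frame(eligible)
        p = c.matrix.values.loc["PTTG1L", frame.index]
        l = c.matrix.values.loc["LEPRL", frame.index]
        labels, table, test = combined_gene_groups(
            p, l, frame["time"], frame["event"]
        )
        med = table["median_pfs"].dropna()
        assert med.idxmax() == "PTTG1-low/LEPR-high"
        assert test is not None and test[1] < 0.05
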