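"""Trial statistics: printed-table worked examples and sampling properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from svdquant.trial_stats import (TreatmentEffect, adverse_event_summary,
                                  baseline_comparison, biomarker_analysis,
                                  pca_treatment, pooled_mean, power_n_per_arm,
                                  qalb, qalb_validation, treatment_effect)


def _cohort_from_tables(n_a=23, n_b=21):
    """Cohort with the published marginal counts for binary traits."""
    rows = []
    for arm, n, males, white in (("minocycline", n_a, 14, 20),
                                 ("placebo", n_b, 14, 19)):
        for i in range(n):
            rows.append({"arm": arm, "male": i < males,
                         "white_british": i < white,
                         "age_years": 70.0 + i, "fazekas": 2 + (i % 2),
                         "adverse_event": False})
    return pd.DataFrame(rows)


class TestBaselineComparison:
    def test_sex_table_chi2_p(self):
        # 9F/14M vs 7F/14M: chi-squared without continuity correction
        df = _cohort_from_tables()
        res = baseline_comparison(df, {"male": "binary"})
        row = res.iloc[0]
        assert row.test_used == "chi2"
        assert row.p == pytest.approx(0.69, abs=0.005)

    def test_ethnicity_fisher_exact(self):
        # 20/3 vs 19/2: a cell below five triggers Fisher; p = 1.00
        df = _cohort_from_tables()
        res = baseline_comparison(df, {"white_british": "binary"})
        row = res.iloc[0]
        assert row.test_used == "fisher"
        assert row.p == pytest.approx(1.00, abs=0.005)

    def test_identical_balanced_arms_fisher_p_one(self):
        rows = []
        for arm in ("minocycline", "placebo"):
            for i in range(10):
                rows.append({"arm": arm, "flag": i < 3})
        res = baseline_comparison(pd.DataFrame(rows), {"flag": "binary"})
        assert res.iloc[0].p == pytest.approx(1.0)

    def test_constant_variable_flagged_without_test(self):
        df = _cohort_from_tables()
        df["const"] = 1.0
        res = baseline_comparison(df, {"const": "continuous"})
        assert res.iloc[0].test_used == "none-constant"
        assert np.isnan(res.iloc[0].p)

    def test_ordinal_uses_median_regression(self):
        df = _cohort_from_tables()
        res = baseline_comparison(df, {"fazekas": "ordinal"})
        assert "median" in res.iloc[0].test_used

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20),
           st.integers(1, 20), st.integers(1, 20))
    def test_test_selection_is_pure_function_of_counts(self, e1, e2, n1, n2):
        e1, e2 = min(e1, n1), min(e2, n2)
        rows = ([{"arm": "a", "x": i < e1} for i in range(n1)]
                + [{"arm": "b", "x": i < e2} for i in range(n2)])
        df = pd.DataFrame(rows)
        if df.x.nunique() < 2:
            return
        res = baseline_comparison(df, {"x": "binary"})
        table = np.array([[e1, n1 - e1], [e2, n2 - e2]])
        expected = "fisher" if (table < 5).any() else "chi2"
        assert res.iloc[0].test_used == expected


def _outcome_frame(rng, n_per_arm=20, effect=1.0, sigma=0.3):
    base = rng.lognormal(0.0, 0.5, size=2 * n_per_arm)
    arm = np.array(["minocycline"] * n_per_arm + ["placebo"] * n_per_arm)
    follow = base * rng.lognormal(0.0, sigma, size=2 * n_per_arm)
    follow[arm == "minocycline"] *= effect
    return pd.DataFrame({
        "arm": arm, "age_years": rng.normal(70, 8, 2 * n_per_arm),
        "completed_treatment": True,
        "baseline_value": base, "followup_value": follow})


class TestTreatmentEffect:
    def test_no_change_no_noise_gives_rr_one(self):
        rng = np.random.default_rng(0)
        df = _outcome_frame(rng, sigma=1e-12, effect=1.0)
        df["followup_value"] = df["baseline_value"]
        est = treatment_effect(df)
        assert est.rr == pytest.approx(1.0, abs=1e-8)

    def test_recovers_simulated_effect_of_0p8(self):
        rng = np.random.default_rng(1)
        rrs = [TreatmentEffect(_outcome_frame(rng, effect=0.8)).fit().rr
               for _ in range(500)]
        se = np.std(np.log(rrs)) / np.sqrt(len(rrs))
        assert abs(np.mean(np.log(rrs)) - np.log(0.8)) < 3 * se

    def test_null_coverage_of_95_ci(self):
        rng = np.random.default_rng(2)
        cover = []
        for _ in range(1000):
            est = TreatmentEffect(_outcome_frame(rng)).fit()
            cover.append(est.ci_low <= 1.0 <= est.ci_high)
        assert abs(np.mean(cover) - 0.95) <= 0.02

    def test_rr_equivariance_under_followup_scaling(self):
        rng = np.random.default_rng(3)
        df = _outcome_frame(rng)
        a = treatment_effect(df)
        df2 = df.copy()
        act = df2.arm == "minocycline"
        df2.loc[act, "followup_value"] *= 3.0
        b = treatment_effect(df2)
        assert b.rr == pytest.approx(3.0 * a.rr, rel=1e-9)

    def test_per_protocol_drops_non_completers(self):
        rng = np.random.default_rng(4)
        df = _outcome_frame(rng, n_per_arm=10)
        df.loc[:2, "completed_treatment"] = False
        est = TreatmentEffect(df).fit(population="per-protocol")
        assert est.n_used == len(df) - 3

    def test_epsilon_recorded_when_zeros_present(self):
        rng = np.random.default_rng(5)
        df = _outcome_frame(rng, n_per_arm=10)
        df.loc[0, "followup_value"] = 0.0
        est = treatment_effect(df)
        assert est.epsilon > 0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(6)
        df = _outcome_frame(rng, n_per_arm=2)
        with pytest.raises(ValueError):
            treatment_effect(df)


class TestBiomarkersAndPca:
    def test_injected_effect_protein_flagged_most_often(self):
        from svdquant.phantom import generate_biomarker_panel, generate_cohort
        hits = np.zeros(92)
        for s in range(30):
            cohort = generate_cohort(44, seed=s)
            eff = np.ones(92)
            eff[10] = 2.0
            base, follow = generate_biomarker_panel(cohort, seed=s,
                                                    treatment_effects=eff)
            prot = [c for c in base.columns if c.startswith("P")]
            res = biomarker_analysis(base, follow, cohort, m=92,
                                     protein_cols=prot)
            hits += (res.p < res.attrs["bonferroni_threshold"]).to_numpy()
        assert np.argmax(hits) == 10

    def test_variance_shares_sum_to_one(self):
        from svdquant.phantom import generate_biomarker_panel, generate_cohort
        cohort = generate_cohort(30, seed=1)
        base, follow = generate_biomarker_panel(cohort, seed=1)
        prot = [c for c in base.columns if c.startswith("P")]
        X = base[prot].to_numpy()
        mu, sd = X.mean(0), X.std(0, ddof=1)
        Z = (X - mu) / sd
        _, S, _ = np.linalg.svd(Z, full_matrices=False)
        assert np.sum(S**2 / np.sum(S**2)) == pytest.approx(1.0)

    def test_pca_reconstruction_at_full_rank(self):
        from svdquant.phantom import generate_biomarker_panel, generate_cohort
        cohort = generate_cohort(25, seed=2)
        base, follow = generate_biomarker_panel(cohort, seed=2, m_proteins=20)
        prot = [c for c in base.columns if c.startswith("P")]
        pca, _ = pca_treatment(base, follow, cohort, k=len(prot),
                               protein_cols=prot)
        X = base[prot].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = pca.scores @ pca.loadings.T
        assert np.allclose(recon, Z, atol=1e-8)
        assert np.allclose(pca.loadings.T @ pca.loadings,
                           np.eye(pca.loadings.shape[1]), atol=1e-8)


class TestQalbAndPower:
    def test_ratio_definition(self):
        assert qalb(200.0, 40.0) == pytest.approx(5.0)

    def test_perfectly_linear_pairs_give_r_one(self):
        x = np.arange(1.0, 13.0)
        out = qalb_validation(2.0 * x + 1.0, x)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_sampling_distribution_centres_on_rho(self):
        rng = np.random.default_rng(8)
        rho, n = 0.6, 12
        rs = []
        for _ in range(1000):
            z = rng.normal(size=n)
            y = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
            rs.append(qalb_validation(5 + z, y)["pearson_r"])
        assert abs(np.median(rs) - rho) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            qalb_validation(np.full(5, 3.0), np.arange(5.0))

    def test_power_d_one_needs_17_per_arm(self):
        assert power_n_per_arm(0.2, mean=5.0, sd=1.0) == 17

    def test_power_d_0p9_needs_21_per_arm(self):
        assert power_n_per_arm(0.2, mean=4.5, sd=1.0) == 21

    def test_n_nonincreasing_in_effect_size(self):
        ns = [power_n_per_arm(0.2, mean=m, sd=1.0) for m in (3.0, 4.0, 5.0, 6.0)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_null_effect_rejected(self):
        with pytest.raises(ValueError):
            power_n_per_arm(0.0, mean=5.0, sd=1.0)


class TestTableHelpers:
    def test_pooled_age_reproduces_overall_mean(self):
        assert pooled_mean([73.0, 66.5], [23, 21]) == pytest.approx(69.9, abs=0.05)

    def test_pooled_wmh_reproduces_overall_mean(self):
        assert pooled_mean([31.2, 31.5], [23, 21]) == pytest.approx(31.3, abs=0.05)

    def test_equal_groups_reduce_to_arithmetic_mean(self):
        assert pooled_mean([10.0, 20.0], [7, 7]) == pytest.approx(15.0)

    def test_adverse_event_percentages(self):
        rows = ([{"arm": "minocycline", "adverse_event": i < 11} for i in range(23)]
                + [{"arm": "placebo", "adverse_event": i < 7} for i in range(21)])
        res = adverse_event_summary(pd.DataFrame(rows))
        by = {r.arm: r for r in res.itertuples()}
        assert by["minocycline"].pct == pytest.approx(47.8)
        assert by["placebo"].pct == pytest.approx(33.3)
        assert res.attrs["p"] > 0.05

    def test_no_events_skips_test(self):
        rows = [{"arm": a, "adverse_event": False}
                for a in ["minocycline"] * 5 + ["placebo"] * 5]
        res = adverse_event_summary(pd.DataFrame(rows))
        assert res.attrs["test_used"] == "skipped-no-events"
        assert np.all(res.pct == 0.0)
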