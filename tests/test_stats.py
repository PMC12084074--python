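"""Encodings, OLS against closed-form oracles, BH-FDR, power, summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from smnmeth.stats import (
    DesignSpec,
    PowerQuery,
    classify_treatment_response,
    dma_scan,
    encode_variable,
    exclude_modifier_genotypes,
    fdr_adjust,
    fit_site_model,
    linear_model_power,
    required_sample_size,
    severity_group_ont,
    summarize_cohort,
)

from conftest import make_matrix, make_sample


class TestEncodings:
    def test_sma_type_mapping(self):
        np.testing.assert_array_equal(
            encode_variable("sma_type", [1, 2, 3, 4]), [0, 1, 2, 3]
        )

    def test_presymptomatic_missing_for_type_contrast(self):
        out = encode_variable("sma_type", [None, 2])
        assert np.isnan(out[0]) and out[1] == 1.0

    def test_sex_convention(self):
        np.testing.assert_array_equal(
            encode_variable("sex", ["male", "female"]), [0.0, 1.0]
        )

    def test_copy_number_numeric(self):
        assert encode_variable("smn2_cn", [4])[0] == 4.0

    def test_missing_preserved(self):
        assert np.isnan(encode_variable("gqn", [None])[0])


class TestSeverityGroup:
    @pytest.mark.parametrize("cn,label,expected", [
        (3, "2b", "less severe"),
        (3, "3a", "less severe"),
        (3, "2a", "more severe"),
        (3, "1b", "more severe"),
        (4, "3b", "less severe"),
        (4, "4", "less severe"),
        (4, "3a", "more severe"),
        (2, "1a", None),
        (5, "3a", None),
    ])
    def test_split(self, cn, label, expected):
        assert severity_group_ont(cn, label) == expected

    def test_missing_subtype_where_needed(self):
        assert severity_group_ont(3, "2") is None
        assert severity_group_ont(3, None) is None
        assert severity_group_ont(3, "presymptomatic") is None


class TestModifierExclusion:
    def test_carriers_removed_and_reported(self):
        cohort = [make_sample(i) for i in range(10)]
        cohort[1].smn1_present = True
        cohort[5].c859_variant = True
        kept, report = exclude_modifier_genotypes(cohort)
        assert len(kept) == 8
        assert set(report["sample_id"]) == {"S001", "S005"}

    def test_no_carriers_identity(self):
        cohort = [make_sample(i) for i in range(4)]
        kept, report = exclude_modifier_genotypes(cohort)
        assert len(kept) == 4 and report.empty

    def test_all_carriers_warns(self):
        cohort = [make_sample(i, c859_variant=True) for i in range(3)]
        with pytest.warns(UserWarning):
            kept, _ = exclude_modifier_genotypes(cohort)
        assert kept == []


class TestFitSiteModel:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        fit = fit_site_model(2 * x, x)
        assert fit.estimate == pytest.approx(2.0)
        assert fit.p < 1e-12

    def test_orthogonal_predictor(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0, 5.0, 5.0])
        fit = fit_site_model(y, x)
        assert fit.estimate == pytest.approx(0.0, abs=1e-12)

    def test_listwise_deletion(self):
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0])
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0, 6.0, 7.0])
        fit = fit_site_model(y, x)
        assert fit.n_used == 5

    def test_zero_variance_response_flagged(self):
        fit = fit_site_model(np.full(8, 3.0), np.arange(8.0))
        assert fit.estimate == 0.0 and np.isnan(fit.p)
        assert fit.flag == "zero-variance y"

    def test_rank_deficient_flagged(self):
        x = np.arange(8.0)
        fit = fit_site_model(np.random.default_rng(0).normal(size=8), x, [x])
        assert fit.flag == "rank-deficient design"

    def test_insufficient_n_flagged(self):
        fit = fit_site_model([1.0, 2.0], [1.0, 2.0])
        assert fit.flag == "insufficient n"

    def test_matches_normal_equations_oracle(self, rng):
        """Coefficient, SE, t and p reproduce the closed-form
        (X'X)^-1 X'y solution with t-distribution p-values."""
        for _ in range(100):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(0, 4))
            x = rng.normal(size=n)
            covs = [rng.normal(size=n) for _ in range(k)]
            y = rng.normal(size=n) * 10 + 50
            fit = fit_site_model(y, x, covs)
            X = np.column_stack([np.ones(n), x] + covs)
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            df = n - X.shape[1]
            se = np.sqrt(resid @ resid / df * np.diag(XtX_inv))
            assert fit.estimate == pytest.approx(beta[1], abs=1e-8)
            assert fit.se == pytest.approx(se[1], abs=1e-8)
            p = 2 * sps.t.sf(abs(beta[1] / se[1]), df)
            assert fit.p == pytest.approx(p, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 40
        x = rng.normal(size=n)
        covs = [rng.normal(size=n), rng.normal(size=n)]
        y = 50 + 2 * x + rng.normal(size=n)
        fit = fit_site_model(y, x, covs)
        res = sm.OLS(y, np.column_stack([np.ones(n), x] + covs)).fit()
        assert fit.estimate == pytest.approx(res.params[1], abs=1e-10)
        assert fit.se == pytest.approx(res.bse[1], abs=1e-10)
        assert fit.p == pytest.approx(res.pvalues[1], abs=1e-10)


def brute_bh(p):
    """Definition-based BH step-up on a complete p-vector."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFdrAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(fdr_adjust([0.04]), [0.04])

    def test_hand_applied_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_output_at_least_input(self, rng):
        p = rng.uniform(size=200)
        assert (fdr_adjust(p) >= p).all()

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(fdr_adjust(p), brute_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        np.testing.assert_allclose(
            fdr_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_missing_p_propagates_and_excluded_from_m(self):
        out = fdr_adjust([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3]], brute_bh([0.01, 0.02, 0.03]))

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]),
                                   atol=1e-15)


class TestDmaScan:
    def _cohort(self, n=30):
        rng = np.random.default_rng(3)
        return [
            make_sample(i, age_at_sampling=float(rng.uniform(0, 60)),
                        gqn=float(rng.normal(7, 1)),
                        library_size_per_smn_copy=float(rng.lognormal(10, 0.3)))
            for i in range(n)
        ]

    def test_single_site_padj_equals_p(self):
        cohort = self._cohort()
        rng = np.random.default_rng(4)
        mat = make_matrix(rng.uniform(30, 70, (1, len(cohort))),
                          samples=[s.sample_id for s in cohort])
        res = dma_scan(mat, cohort, DesignSpec("age_at_sampling"))
        assert res.table["p_adj"].iloc[0] == pytest.approx(res.table["p"].iloc[0])

    def test_age_excluded_from_covariates_when_independent(self):
        spec = DesignSpec("age_at_sampling")
        assert "age_at_sampling" not in spec.covariates

    def test_independent_never_among_covariates(self):
        spec = DesignSpec("sex")
        assert "sex" not in spec.covariates
        assert "age_at_sampling" in spec.covariates

    def test_strong_effect_detected_and_ordered(self):
        cohort = self._cohort(60)
        ages = np.array([s.age_at_sampling for s in cohort])
        rng = np.random.default_rng(5)
        null_rows = rng.uniform(40, 60, (4, 60))
        effect_row = 20 + 0.8 * ages + rng.normal(0, 1, 60)
        mat = make_matrix(np.vstack([null_rows, effect_row]),
                          samples=[s.sample_id for s in cohort])
        res = dma_scan(mat, cohort, DesignSpec("age_at_sampling"))
        assert res.significant == [mat.percent.index[4]]
        assert res.table["c_pos"].is_monotonic_increasing


class TestPower:
    def test_reference_default_query(self):
        assert required_sample_size(PowerQuery()) == 115

    def test_strict_residual_df_convention(self):
        assert required_sample_size(PowerQuery(), df_convention="n-u-1") == 119

    def test_minimality(self):
        q = PowerQuery()
        n = required_sample_size(q)
        assert linear_model_power(q.u, n - 1, q.f2, q.alpha) >= q.power
        assert linear_model_power(q.u, n - 2, q.f2, q.alpha) < q.power

    def test_monotone_in_f2_alpha_power(self):
        base = required_sample_size(PowerQuery())
        assert required_sample_size(PowerQuery(f2=0.35)) <= base
        assert required_sample_size(PowerQuery(alpha=0.05)) <= base
        assert required_sample_size(PowerQuery(power=0.95)) >= base

    def test_huge_effect_small_n(self):
        n = required_sample_size(PowerQuery(f2=50.0, u=1, alpha=0.05, power=0.5))
        assert n <= 5

    def test_invalid_query(self):
        with pytest.raises(ValueError):
            PowerQuery(f2=-1.0)


class TestTreatmentResponse:
    @pytest.mark.parametrize("d,expected", [
        (-3, "decrease"), (-4, "decrease"), (0, "stabilization"),
        (2.9, "stabilization"), (-2.9, "stabilization"),
        (3, "increase"), (7, "increase"), (None, None), (float("nan"), None),
    ])
    def test_grouping(self, d, expected):
        assert classify_treatment_response(d) == expected


def printed_composition_cohort():
    """Cohort matching the reference baseline table's counts:
    per copy-number group totals, male counts and SMA-type counts."""
    totals = {2: 15, 3: 215, 4: 122, 5: 7}
    males = {2: 10, 3: 94, 4: 71, 5: 6}
    types = {2: (15, 0, 0, 0, 0), 3: (30, 138, 43, 0, 4),
             4: (1, 14, 96, 9, 2), 5: (0, 0, 5, 1, 1)}
    cohort = []
    i = 0
    for cn, total in totals.items():
        type_seq = []
        for t_idx, count in enumerate(types[cn]):
            type_seq += [t_idx] * count
        assert len(type_seq) == total
        for j in range(total):
            t = type_seq[j]
            cohort.append(
                make_sample(
                    i, sex="male" if j < males[cn] else "female",
                    smn2_cn=cn,
                    sma_type=None if t == 4 else t + 1,
                    sma_subtype=None,
                    presymptomatic=t == 4,
                )
            )
            i += 1
    return cohort


class TestCohortSummary:
    def test_printed_group_totals(self):
        summary = summarize_cohort(printed_composition_cohort())
        assert summary.counts.at["total", "overall"] == 359
        assert summary.counts.loc["total", ["2xSMN2", "3xSMN2", "4xSMN2", "5xSMN2"]].tolist() == [15, 215, 122, 7]

    def test_printed_sex_breakdown(self):
        summary = summarize_cohort(printed_composition_cohort())
        assert summary.counts.at["male", "overall"] == 181
        assert summary.percent.at["male", "overall"] == 50.4
        assert summary.percent.at["male", "2xSMN2"] == 66.7

    def test_printed_type_breakdown(self):
        summary = summarize_cohort(printed_composition_cohort())
        assert summary.counts.at["type_2", "overall"] == 152
        assert summary.percent.at["type_2", "overall"] == 42.3
        assert summary.percent.at["type_3", "4xSMN2"] == 78.7

    def test_empty_cohort(self):
        summary = summarize_cohort([])
        assert summary.counts.at["total", "overall"] == 0
        assert (summary.counts.drop("total") == 0).all().all()
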