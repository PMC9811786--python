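"""Clinical classifiers, logistic/Wald inference, t-test, CpG-CpG and
transcript associations, and Spearman correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snpmeth.phenotype import (
    SeparationError,
    classify_dawba_risk,
    classify_severity,
    cpg_cpg_association,
    fit_logistic,
    methylation_transcript_assoc,
    spearman,
    summarize_pair_consistency,
    ttest_equal_var,
    wald_summary,
)
from snpmeth.types import DawbaBand, FreemanAssessment


class TestSeverityClassifier:
    @pytest.mark.parametrize(
        "rev,intr,violent,completed,expected",
        [
            (4, 3, False, False, "severe"),  # 7 > 6
            (3, 3, False, False, "not_severe"),  # 6 is not > 6
            (1, 1, True, False, "severe"),  # violent method alone
            (2, 2, False, True, "severe"),  # completed suicide alone
            (5, 5, False, False, "severe"),
            (1, 1, False, False, "not_severe"),
        ],
    )
    def test_classification_rules(self, rev, intr, violent, completed, expected):
        a = FreemanAssessment(rev, intr, violent, completed)
        assert classify_severity(a) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        rev=st.integers(1, 5),
        intr=st.integers(1, 5),
        violent=st.booleans(),
        completed=st.booleans(),
    )
    def test_monotone_in_subscales(self, rev, intr, violent, completed):
        base = classify_severity(FreemanAssessment(rev, intr, violent, completed))
        if base == "severe":
            for dr, di in [(1, 0), (0, 1), (1, 1)]:
                r, i = min(rev + dr, 5), min(intr + di, 5)
                assert (
                    classify_severity(FreemanAssessment(r, i, violent, completed))
                    == "severe"
                )

    def test_out_of_range_subscale_rejected(self):
        with pytest.raises(ValueError):
            FreemanAssessment(0, 3)
        with pytest.raises(ValueError):
            FreemanAssessment(2, 6)

    def test_combined_score_range(self):
        assert FreemanAssessment(1, 1).combined_score == 2
        assert FreemanAssessment(5, 5).combined_score == 10


class TestDawbaClassifier:
    @pytest.mark.parametrize(
        "band,expected",
        [(0, "low"), (1, "low"), (2, "low"), (3, "low"), (4, "high"), (5, "high")],
    )
    def test_band_cut(self, band, expected):
        assert classify_dawba_risk(DawbaBand(band)) == expected

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            DawbaBand(6)


class TestFitLogistic:
    @staticmethod
    def _from_2x2(a, b, c, d):
        """Outcome x binary-predictor table: rows y=1/y=0, cols x=1/x=0."""
        y = np.array([1] * (a + b) + [0] * (c + d))
        x = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        return pd.Series(y), pd.DataFrame({"x": x.astype(float)})

    def test_closed_form_log_odds_ratio(self):
        y, X = self._from_2x2(10, 20, 30, 40)
        fit = fit_logistic(y, X)
        expected = np.log((10 * 40) / (20 * 30))
        assert fit.coef("x")["beta"] == pytest.approx(expected, abs=1e-6)

    def test_random_2x2_tables_match_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 31, 4)
            y, X = self._from_2x2(a, b, c, d)
            fit = fit_logistic(y, X)
            assert fit.coef("x")["beta"] == pytest.approx(
                np.log(a * d / (b * c)), abs=1e-6
            )
            se_expected = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert fit.coef("x")["se"] == pytest.approx(se_expected, rel=1e-4)

    def test_null_predictor_z_calibrated(self):
        rng = np.random.default_rng(1)
        big = 0
        for s in range(50):
            n = 5000
            y = pd.Series(rng.binomial(1, 0.3, n))
            X = pd.DataFrame({"m": rng.normal(0, 1, n)})
            fit = fit_logistic(y, X)
            big += int(abs(fit.coef("m")["z"]) >= 3)
        assert big <= 1

    def test_perfect_separation_raises(self):
        y = pd.Series([0, 0, 0, 1, 1, 1])
        X = pd.DataFrame({"x": [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]})
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_missing_rows_dropped_and_counted(self):
        y, X = self._from_2x2(10, 20, 30, 40)
        X.iloc[0, 0] = np.nan
        fit = fit_logistic(y, X)
        assert fit.n_dropped == 1
        assert fit.n == 99

    def test_wald_and_profile_ci_both_cover_mle(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(0, 1, n)
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-(0.5 + x)))))
        X = pd.DataFrame({"x": x})
        wald = fit_logistic(y, X)
        prof = fit_logistic(y, X, profile_ci=True)
        b = wald.coef("x")["beta"]
        assert wald.coef("x")["ci_low"] < b < wald.coef("x")["ci_high"]
        assert prof.coef("x")["ci_low"] < b < prof.coef("x")["ci_high"]
        # profile and Wald agree closely at this information level
        assert prof.coef("x")["ci_low"] == pytest.approx(
            wald.coef("x")["ci_low"], abs=0.1
        )

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.Series([0, 1, 2]), pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


class TestWaldSummary:
    @pytest.mark.parametrize(
        "beta,se,or_printed,z_printed",
        [
            (4.437, 1.505, 84.521, 2.947),
            (-1.728, 0.582, 0.178, -2.968),
            (0.955, 0.676, 2.599, 1.414),
        ],
    )
    def test_published_coefficient_arithmetic(self, beta, se, or_printed, z_printed):
        s = wald_summary(beta, se)
        assert s["odds_ratio"] == pytest.approx(or_printed, abs=0.005)
        assert s["z"] == pytest.approx(z_printed, abs=0.005)

    def test_zero_beta(self):
        s = wald_summary(0.0, 1.3)
        assert s["z"] == 0 and s["p"] == 1 and s["odds_ratio"] == 1

    def test_p_symmetric_in_sign(self):
        assert wald_summary(0.7, 0.2)["p"] == wald_summary(-0.7, 0.2)["p"]

    def test_or_scale_ci(self):
        s = wald_summary(1.0, 0.5, ci_on_or_scale=True)
        assert s["ci_low"] == pytest.approx(np.exp(1 - 1.96 * 0.5))
        assert s["ci_high"] == pytest.approx(np.exp(1 + 1.96 * 0.5))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_summary(1.0, 0.0)


class TestEqualVarianceTTest:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = ttest_equal_var(x, x)
        assert t == 0 and p == 1

    def test_hand_computed_example(self):
        t, p = ttest_equal_var([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=0.001)
        assert p == pytest.approx(0.0214, abs=0.0005)

    def test_equals_welch_at_equal_n_equal_sd(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        t_pooled, p_pooled = ttest_equal_var(x, y)
        welch = stats.ttest_ind(x, y, equal_var=False)
        assert t_pooled == pytest.approx(welch.statistic, abs=1e-12)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_equal_var([1.0, 1.0], [1.0, 1.0])


def _cohort_m(seed, n=100, n_stress=5, coupled=False):
    rng = np.random.default_rng(seed)
    samples = [f"s{j}" for j in range(n)]
    stress = pd.DataFrame(
        rng.normal(0, 1, (n_stress, n)),
        index=[f"st{i}" for i in range(n_stress)],
        columns=samples,
    )
    if coupled:
        cand = pd.DataFrame(
            {0: stress.iloc[0] + rng.normal(0, 0.1, n)}, index=samples
        ).T.set_axis(["cand1"])
        cand.columns = samples
    else:
        cand = pd.DataFrame(
            rng.normal(0, 1, (1, n)), index=["cand1"], columns=samples
        )
    covs = pd.DataFrame({"age": rng.normal(30, 5, n)}, index=samples)
    return cand, stress, covs


class TestCpgCpgAssociation:
    def test_coupled_pair_strongly_significant(self):
        cand, stress, covs = _cohort_m(0, coupled=True)
        out = cpg_cpg_association(cand, stress, covs)
        hit = out[(out["candidate"] == "cand1") & (out["stress_cpg"] == "st0")]
        assert hit["p_value"].iloc[0] < 1e-6

    def test_slope_matches_per_pair_ols_oracle(self):
        import statsmodels.api as sm

        cand, stress, covs = _cohort_m(1)
        out = cpg_cpg_association(cand, stress, covs)
        for _, row in out.iterrows():
            X = sm.add_constant(
                np.column_stack(
                    [stress.loc[row["stress_cpg"]], covs["age"]]
                )
            )
            ols = sm.OLS(cand.loc[row["candidate"]].to_numpy(), X).fit()
            assert row["beta"] == pytest.approx(ols.params[1], abs=1e-8)
            assert row["p_value"] == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_null_nominal_rate_calibrated(self):
        rng = np.random.default_rng(2)
        n = 60
        samples = [f"s{j}" for j in range(n)]
        cand = pd.DataFrame(
            rng.normal(0, 1, (10, n)), index=[f"c{i}" for i in range(10)], columns=samples
        )
        stress = pd.DataFrame(
            rng.normal(0, 1, (200, n)), index=[f"st{i}" for i in range(200)], columns=samples
        )
        out = cpg_cpg_association(cand, stress)
        assert out["nominal_significant"].mean() == pytest.approx(0.05, abs=0.01)


class TestPairConsistency:
    def _tab(self, betas_ps):
        return pd.DataFrame(
            {
                "candidate": ["c1"] * len(betas_ps),
                "stress_cpg": [f"st{i}" for i in range(len(betas_ps))],
                "beta": [b for b, _ in betas_ps],
                "p_value": [p for _, p in betas_ps],
            }
        )

    def test_three_cohort_positive_consistency(self):
        cohorts = {
            f"cohort{i}": self._tab([(b, 0.01)])
            for i, b in enumerate([0.237, 0.445, 0.666])
        }
        out = summarize_pair_consistency(cohorts)
        assert out.loc[0, "n_cohorts_significant"] == 3
        assert bool(out.loc[0, "direction_consistent"])

    def test_opposite_signs_inconsistent(self):
        cohorts = {
            "a": self._tab([(0.3, 0.01)]),
            "b": self._tab([(-0.2, 0.01)]),
        }
        out = summarize_pair_consistency(cohorts)
        assert not bool(out.loc[0, "direction_consistent"])

    def test_single_significant_cohort_trivially_consistent(self):
        cohorts = {
            "a": self._tab([(0.3, 0.01)]),
            "b": self._tab([(0.1, 0.5)]),
        }
        out = summarize_pair_consistency(cohorts)
        assert out.loc[0, "n_cohorts_significant"] == 1
        assert bool(out.loc[0, "direction_consistent"])

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_pair_consistency({"a": self._tab([(0.3, 0.01)])})


class TestTranscriptAssociation:
    def test_planted_coupling_recovered(self):
        from snpmeth.simulate import SimulatorConfig, simulate_cohort

        cfg = SimulatorConfig(
            n_samples=1000,
            n_probes=20,
            probe_positions=[
                (f"cg{j + 1:08d}", "chr7", 1_850_000 + 600 * j) for j in range(20)
            ],
            effect_table=[],
            transcript_gamma={"t1": ("cg00000001", 0.0, 0.25, 0.5)},
            seed=91,
        )
        cohort = simulate_cohort(cfg)
        out = methylation_transcript_assoc(
            cohort.transcripts,
            cohort.methylation.values.loc[["cg00000001"]],
        )
        assert out["beta"].iloc[0] == pytest.approx(0.25, abs=0.05)

    def test_published_adjusted_column_reproduced(self):
        from snpmeth.examples import (
            TRANSCRIPT_MODEL_ADJ_P_PRINTED,
            TRANSCRIPT_MODEL_RAW_P,
        )
        from snpmeth.discovery import bh_adjust

        adj = bh_adjust(np.array(TRANSCRIPT_MODEL_RAW_P))
        for got, printed in zip(adj, TRANSCRIPT_MODEL_ADJ_P_PRINTED):
            tol = 5e-4 if printed not in (0.834,) else 1e-12
            assert got == pytest.approx(printed, abs=tol)

    def test_zero_coupling_null_uniform(self):
        rng = np.random.default_rng(5)
        n = 80
        samples = [f"s{j}" for j in range(n)]
        tr = pd.DataFrame({"t1": rng.normal(0, 1, n)}, index=samples)
        meth = pd.DataFrame(
            rng.normal(0, 1, (300, n)), index=[f"cg{i}" for i in range(300)], columns=samples
        )
        out = methylation_transcript_assoc(tr, meth)
        ks = stats.kstest(out["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x, y = [1, 1, 2], [3, 5, 5]
        # mid-ranks: x -> (1.5, 1.5, 3); y -> (1, 2.5, 2.5); Pearson of ranks
        rx, ry = np.array([1.5, 1.5, 3.0]), np.array([1.0, 2.5, 2.5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
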