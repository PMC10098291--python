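import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from sealerdelta.errors import InsufficientReplicatesError, ValidationError
from sealerdelta.stats import RepeatedMeasuresCS, fit_cs_model, \
    inflate_for_dropout, ls_means_and_contrasts, measurement_uncertainty, \
    power_two_sample_t, sample_size_two_groups, simulate_longitudinal


class TestMeasurementUncertainty:
    def test_identical_repeats_zero_uncertainty(self):
        rec = measurement_uncertainty([1.2] * 10)
        assert rec.S == pytest.approx(0.0, abs=1e-12)
        assert rec.u == pytest.approx(0.0, abs=1e-12)
        assert rec.U == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_examples(self):
        rec = measurement_uncertainty([1.0, 2.0, 3.0])
        assert rec.S == pytest.approx(1.0)
        assert rec.u == pytest.approx(1.0 / np.sqrt(3.0))
        assert rec.U == pytest.approx(2.0 / np.sqrt(3.0))
        # S = 0.10, n = 10, k = 2 -> u ~ 0.0316, U ~ 0.0632
        vals = np.array([0.0, 0.1] * 5)
        vals = vals / vals.std(ddof=1) * 0.10  # scale to S = 0.10 exactly
        rec2 = measurement_uncertainty(vals)
        assert rec2.u == pytest.approx(0.10 / np.sqrt(10.0), rel=1e-9)
        assert rec2.U == pytest.approx(0.0632, abs=5e-4)

    @pytest.mark.parametrize("k", [1.0, 2.0, 3.0])
    def test_expanded_over_standard_is_exactly_k(self, k):
        rec = measurement_uncertainty([0.3, 0.5, 0.9, 0.4], k=k)
        assert rec.U / rec.u == k

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            measurement_uncertainty([1.0])


class TestSampleSize:
    def test_study_power_calculation(self):
        """33% difference, 20% SD, two-sided alpha 5%, 90% power -> 9 per
        group; 8 is insufficient."""
        n = sample_size_two_groups(33.0, 20.0, alpha=0.05, power=0.90)
        assert n == 9
        d = 33.0 / 20.0
        assert power_two_sample_t(9, d) >= 0.90
        assert power_two_sample_t(8, d) < 0.90

    def test_huge_effect_floors_at_two(self):
        assert sample_size_two_groups(1000.0, 1.0) == 2

    @pytest.mark.parametrize("delta,sd,alpha,power",
                             [(33.0, 20.0, 0.05, 0.90), (10.0, 15.0, 0.05, 0.80)])
    def test_monte_carlo_power_oracle(self, delta, sd, alpha, power):
        """Empirical two-sample t-test power at the returned n meets the
        target, and fails at n-1 (20k simulated experiments)."""
        n = sample_size_two_groups(delta, sd, alpha, power)
        rng = np.random.default_rng(12345)

        def mc_power(nn, reps=20000):
            a = rng.normal(0.0, sd, size=(reps, nn))
            b = rng.normal(delta, sd, size=(reps, nn))
            _, p = st.ttest_ind(a, b, axis=1)
            return (p < alpha).mean()

        tol = 3.0 * np.sqrt(power * (1 - power) / 20000)
        assert mc_power(n) >= power - tol
        if n > 2:
            assert mc_power(n - 1) < power

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            sample_size_two_groups(-1.0, 20.0)
        with pytest.raises(ValidationError):
            sample_size_two_groups(33.0, 20.0, alpha=0.5, power=0.4)


class TestDropoutInflation:
    @pytest.mark.parametrize("n,dropout,expected",
                             [(9, 0.10, 10), (9, 0.0, 9), (10, 0.5, 20),
                              (7, 0.25, 10)])
    def test_inflation(self, n, dropout, expected):
        assert inflate_for_dropout(n, dropout) == expected

    def test_invalid_dropout(self):
        with pytest.raises(ValidationError):
            inflate_for_dropout(9, 1.0)


GROUPS = ["AH", "AX", "BR", "TS", "GP"]
TIMES = ["1w", "1m", "3m", "18m"]


class TestCSModel:
    def test_balanced_ls_means_equal_cell_means(self):
        """On balanced complete data the model-based LS mean of every
        group x time cell equals the arithmetic cell mean to 1e-8."""
        df = simulate_longitudinal(6, GROUPS, TIMES, sigma_b=0.5, sigma_e=1.0,
                                   rng=np.random.default_rng(3))
        res = RepeatedMeasuresCS(df).fit()
        cell = res.ls_means(by="cell")
        arithmetic = df.groupby(["group", "time"], sort=False)["response"].mean()
        for _, row in cell.iterrows():
            g, t = row["effect"].rsplit(" ", 1)
            assert row["estimate"] == pytest.approx(arithmetic[(g, t)], abs=1e-8)

    def test_variance_components_recovered(self):
        """Median variance-component estimates over seeded replicates land
        within 25% of the simulation truth (sigma_b^2 = 0.25, sigma_e^2 = 1)."""
        rng = np.random.default_rng(77)
        sb2, se2 = [], []
        for _ in range(60):
            df = simulate_longitudinal(10, GROUPS, TIMES, sigma_b=0.5,
                                       sigma_e=1.0, rng=rng)
            res = RepeatedMeasuresCS(df).fit()
            sb2.append(res.sigma_b2)
            se2.append(res.sigma_e2)
        assert abs(np.median(sb2) - 0.25) / 0.25 < 0.25
        assert abs(np.median(se2) - 1.0) < 0.25

    def test_zero_between_variance_matches_ols(self):
        """With no specimen effect the mixed fit degenerates to the two-way
        fixed-effect model: estimates match OLS to 1e-6."""
        rng = np.random.default_rng(5)
        df = simulate_longitudinal(8, GROUPS[:3], TIMES[:2], sigma_b=0.0,
                                   sigma_e=1.0, rng=rng)
        res = RepeatedMeasuresCS(df).fit()
        import statsmodels.api as sm
        model = RepeatedMeasuresCS(df)
        ols = sm.OLS(model.endog, model.exog).fit()
        assert np.abs(res.fe_params.to_numpy() - ols.params.to_numpy()).max() < 1e-6
        assert res.sigma_b2 == pytest.approx(0.0, abs=0.05)

    def test_missing_rows_allowed_and_empty_cell_flagged(self):
        df = simulate_longitudinal(4, GROUPS[:2], TIMES[:3],
                                   rng=np.random.default_rng(1))
        # drop one scattered row (specimen loss) -> still fits
        res = RepeatedMeasuresCS(df.drop(index=[5])).fit()
        assert np.isfinite(res.sigma_e2)
        # wipe out an entire cell -> affected contrast flagged, not dropped
        df2 = df[~((df.group == "AX") & (df.time == "3m"))]
        res2 = RepeatedMeasuresCS(df2).fit()
        recs = res2.time_effects()
        flagged = [r for r in recs if not r.estimable]
        assert any(r.label == "AX 3m" for r in flagged)
        assert all(np.isfinite(r.estimate) for r in recs if r.estimable)

    def test_contrast_antisymmetry(self):
        df = simulate_longitudinal(6, GROUPS[:3], TIMES[:2],
                                   rng=np.random.default_rng(9))
        res = RepeatedMeasuresCS(df).fit()
        recs = {r.label: r for r in res.pairwise_groups()}
        ab = recs["AH versus AX"]
        # rebuild the reversed contrast directly
        rev = res._contrast(res.group_ls_vector("AX") - res.group_ls_vector("AH"),
                            "AX versus AH", res.df_between, len(recs))
        assert rev.estimate == pytest.approx(-ab.estimate, abs=1e-12)
        assert rev.se == pytest.approx(ab.se, abs=1e-12)
        assert rev.p_adj == pytest.approx(ab.p_adj, abs=1e-12)

    def test_bonferroni_arithmetic(self):
        """p_adj = min(1, m * p_raw): 0.001 -> 0.01 and 0.2 -> 1.00 at m=10."""
        df = simulate_longitudinal(6, GROUPS, TIMES[:2],
                                   rng=np.random.default_rng(2))
        res = RepeatedMeasuresCS(df).fit()
        recs = res.pairwise_groups()
        assert len(recs) == 10
        for r in recs:
            assert r.p_adj == pytest.approx(min(1.0, 10 * r.p_raw), abs=1e-12)
        assert min(1.0, 10 * 0.001) == pytest.approx(0.01)
        assert min(1.0, 10 * 0.2) == 1.0

    def test_designed_group_effect_detected(self):
        """A built-in group shift of Delta = 1.0 is estimated near 1 and
        detected; the contrast dispatch helper returns the same family."""
        effects = {("AX", t): -1.0 for t in TIMES}
        df = simulate_longitudinal(10, ["GP", "AX"], TIMES, effects=effects,
                                   sigma_b=0.3, sigma_e=0.4,
                                   rng=np.random.default_rng(21))
        res = fit_cs_model(df)
        recs = ls_means_and_contrasts(res, family="groups")
        rec = recs[0]
        assert rec.label == "GP versus AX"
        assert rec.estimate == pytest.approx(1.0, abs=0.4)
        assert rec.p_adj < 0.01
        assert rec.ci_low <= rec.estimate <= rec.ci_high

    def test_summary_mentions_variance_components(self):
        df = simulate_longitudinal(5, GROUPS[:2], TIMES[:2],
                                   rng=np.random.default_rng(4))
        text = RepeatedMeasuresCS(df).fit().summary()
        assert "sigma_b^2" in text and "compound symmetry" in text

    def test_response_type_filter(self):
        df = simulate_longitudinal(4, GROUPS[:2], TIMES[:2],
                                   rng=np.random.default_rng(6))
        df["response_type"] = "volume_mm3"
        res = fit_cs_model(df, response_type="volume_mm3")
        assert res.n_obs == len(df)
        with pytest.raises(ValidationError):
            fit_cs_model(df, response_type="rms_mm")
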