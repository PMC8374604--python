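"""Log-log marker models and the genome-wide correlation screen."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cuegene.markers import (
    correlation_screen,
    fit_loglog,
    marker_rank,
    predict_rate,
    zero_crossing,
)


class TestFitLoglog:
    def test_perfect_fit(self):
        x = np.exp(np.linspace(1, 3, 8))
        y = np.exp(2.0 * np.log(x) - 1.0)
        m = fit_loglog(x, y)
        assert m.alpha == pytest.approx(-1.0, abs=1e-12)
        assert m.beta == pytest.approx(2.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_hand_normal_equations_example(self):
        # ln-pairs x=(1,2,3,4), y=(1,2,2,3): Sxy=3, Sxx=5 -> beta=0.6,
        # alpha=2-0.6*2.5=0.5, SSE=0.2, SST=2 -> R^2=0.9
        m = fit_loglog(np.exp([1, 2, 3, 4]), np.exp([1, 2, 2, 3]))
        assert m.beta == pytest.approx(0.6, abs=1e-12)
        assert m.alpha == pytest.approx(0.5, abs=1e-12)
        assert m.r2 == pytest.approx(0.9, abs=1e-12)
        assert m.residual_se == pytest.approx(math.sqrt(0.2 / 2), abs=1e-12)
        assert m.f_stat == pytest.approx((0.9 / 0.1) * 2, abs=1e-9)
        assert (m.df_num, m.df_den, m.n_obs) == (1, 2, 4)

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(2.0, 0.7, 40))
        y = np.exp(-1.5 + 0.8 * np.log(x) + rng.normal(0, 0.3, 40))
        m = fit_loglog(x, y)
        ref = sm.OLS(np.log(y), sm.add_constant(np.log(x))).fit()
        assert m.alpha == pytest.approx(ref.params[0], rel=1e-10)
        assert m.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert m.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert m.f_stat == pytest.approx(ref.fvalue, rel=1e-8)
        assert m.p_value == pytest.approx(ref.f_pvalue, rel=1e-8)
        assert m.residual_se == pytest.approx(np.sqrt(ref.mse_resid), rel=1e-10)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(11)
        x = np.exp(rng.normal(0, 1, 30))
        y = np.exp(0.5 * np.log(x) + rng.normal(0, 0.5, 30))
        m = fit_loglog(x, y)
        r, _ = stats.pearsonr(np.log(x), np.log(y))
        assert m.r2 == pytest.approx(r**2, rel=1e-10)

    def test_nonpositive_pairs_dropped_with_warning(self):
        x = np.array([1.0, 2.0, 3.0, 0.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, -1.0])
        with pytest.warns(UserWarning, match="dropping 2"):
            m = fit_loglog(x, y)
        assert m.n_obs == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_loglog([1.0, 2.0], [1.0, 2.0])

    def test_unbiased_recovery_and_analytic_se(self):
        # simulation at the study's scale: n=62, sigma=0.45; the mean
        # fitted slope is unbiased and its spread matches the OLS SE
        rng = np.random.default_rng(99)
        n, alpha, beta, sigma = 62, -9.64, 1.4, 0.45
        betas, ses = [], []
        for _ in range(200):
            lnx = rng.normal(5.5, 0.42, n)
            lny = alpha + beta * lnx + rng.normal(0, sigma, n)
            m = fit_loglog(np.exp(lnx), np.exp(lny))
            betas.append(m.beta)
            ses.append(m.residual_se / math.sqrt(((lnx - lnx.mean()) ** 2).sum()))
        betas = np.asarray(betas)
        sem = betas.std(ddof=1) / math.sqrt(len(betas))
        assert abs(betas.mean() - beta) < 2 * sem
        assert betas.std(ddof=1) == pytest.approx(np.mean(ses), rel=0.25)


class TestPrediction:
    @pytest.mark.parametrize(
        "alpha, beta, expr, expected",
        [
            (0.0, 1.0, 5.0, 5.0),
            (-9.64, 1.4, math.exp(8.0), math.exp(1.56)),
            (-6.37, 0.98, math.exp(7.0), math.exp(0.49)),
        ],
    )
    def test_power_law(self, alpha, beta, expr, expected):
        # build a model with the wanted coefficients through an exact fit
        x = np.exp(np.array([1.0, 2.0, 3.0]))
        y = np.exp(alpha + beta * np.log(x))
        model = fit_loglog(x, y)
        assert predict_rate(model, expr) == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_expression_rejected(self):
        x = np.exp([1.0, 2.0, 3.0])
        model = fit_loglog(x, x)
        with pytest.raises(ValueError):
            predict_rate(model, 0.0)


class TestZeroCrossing:
    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [(-9.64, 1.40, 6.89), (0.0, 1.0, 0.0), (-6.0, 2.0, 3.0)],
    )
    def test_examples(self, alpha, beta, expected):
        x = np.exp(np.array([1.0, 2.0, 3.0]))
        model = fit_loglog(x, np.exp(alpha + beta * np.log(x)))
        assert zero_crossing(model) == pytest.approx(expected, abs=5e-3)

    def test_flat_model_rejected(self):
        from cuegene.markers import MarkerModel

        flat = MarkerModel("mu", "x", alpha=1.0, beta=0.0, r2=0.0, residual_se=1.0,
                           f_stat=0.0, df_num=1, df_den=10, n_obs=12, p_value=1.0)
        with pytest.raises(ValueError):
            zero_crossing(flat)


def toy_screen():
    rng = np.random.default_rng(3)
    rates = pd.Series([0.1, 0.2, 0.4, 0.8], index=list("abcd"))
    perfect = rates.to_numpy()  # ln equal up to affine map -> r = 1
    anti = 1.0 / rates.to_numpy()  # ln affine decreasing -> r = -1
    noise = np.exp(rng.normal(3, 0.5, 4))
    mat = pd.DataFrame(
        [perfect, anti, noise],
        index=["1.1.1.1", "2.2.2.2", "3.3.3.3"],
        columns=rates.index,
    )
    return mat, rates


class TestCorrelationScreen:
    def test_perfect_and_anticorrelated(self):
        mat, rates = toy_screen()
        ranking = correlation_screen(mat, rates, "mu")
        t = ranking.table.set_index("ec_id")
        assert t.loc["1.1.1.1", "pearson_r"] == pytest.approx(1.0, abs=1e-12)
        assert t.loc["1.1.1.1", "rank"] == 1
        assert t.loc["2.2.2.2", "pearson_r"] == pytest.approx(-1.0, abs=1e-12)
        assert t.loc["2.2.2.2", "rank"] == 3  # last among defined

    def test_matches_brute_force_pearson(self):
        mat, rates = toy_screen()
        ranking = correlation_screen(mat, rates, "mu")
        t = ranking.table.set_index("ec_id")
        for ec in mat.index:
            r_ref, _ = stats.pearsonr(np.log(mat.loc[ec]), np.log(rates))
            assert t.loc[ec, "pearson_r"] == pytest.approx(r_ref, rel=1e-10)

    def test_zero_variance_reported_missing_and_last(self):
        mat, rates = toy_screen()
        mat.loc["4.4.4.4"] = 7.0  # constant expression
        ranking = correlation_screen(mat, rates, "mu")
        t = ranking.table.set_index("ec_id")
        assert np.isnan(t.loc["4.4.4.4", "pearson_r"])
        assert t.loc["4.4.4.4", "rank"] == len(mat)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=20)
    def test_invariant_to_positive_rescaling(self, scale):
        mat, rates = toy_screen()
        base = correlation_screen(mat, rates, "mu").table.set_index("ec_id")
        scaled = mat.copy()
        scaled.loc["3.3.3.3"] *= scale
        new = correlation_screen(scaled, rates, "mu").table.set_index("ec_id")
        assert new.loc["3.3.3.3", "pearson_r"] == pytest.approx(
            base.loc["3.3.3.3", "pearson_r"], rel=1e-9
        )

    def test_deterministic_tie_break_by_ec_id(self):
        rates = pd.Series([0.1, 0.2, 0.4], index=list("abc"))
        mat = pd.DataFrame(
            [rates.to_numpy(), rates.to_numpy()], index=["2.2.2.2", "1.1.1.1"],
            columns=rates.index,
        )
        t = correlation_screen(mat, rates, "mu").table
        assert list(t["ec_id"]) == ["1.1.1.1", "2.2.2.2"]

    def test_marker_rank_lookup(self):
        mat, rates = toy_screen()
        ranking = correlation_screen(mat, rates, "mu")
        assert marker_rank(ranking, "1.1.1.1") == 1
        with pytest.raises(KeyError):
            marker_rank(ranking, "9.9.9.9")
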