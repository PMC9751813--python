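import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import erfinv, ndtr
from scipy.stats import norm

from seedage import viability
from seedage.viability import (
    NonIdentifiableError,
    SurvivalObservation,
    fit_combined,
    fit_viability,
    ned,
    p50_from_fit,
    p50_correlation_matrix,
    proportion_from_ned,
    summarize_panel,
)

from conftest import survival_frame


class TestNed:
    def test_median_is_zero(self):
        assert ned(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_against_erfinv_oracle(self):
        # independent route: probit(p) = sqrt(2) * erfinv(2p - 1)
        for p in (0.9535, 0.1, 0.25, 0.84):
            assert ned(p) == pytest.approx(np.sqrt(2) * erfinv(2 * p - 1), abs=1e-10)
        assert round(float(ned(0.9535)), 2) == 1.68

    def test_round_trip(self):
        for x in np.linspace(-3, 3, 13):
            assert ned(proportion_from_ned(x)) == pytest.approx(x, abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_boundary_rejected(self, p):
        with pytest.raises(ValueError):
            ned(p)


class TestFitViability:
    def test_recovers_noiseless_truth(self, noiseless_survival):
        df, truth = noiseless_survival
        fit = fit_viability(df)
        assert fit.Ki == pytest.approx(truth["Ki"], abs=0.05)
        assert fit.sigma_inv == pytest.approx(truth["sigma_inv"], abs=0.005)
        assert fit.p50 == pytest.approx(fit.Ki * fit.sigma, rel=1e-10)

    def test_matches_statsmodels_probit_glm(self, noiseless_survival):
        df, _ = noiseless_survival
        fit = fit_viability(df)
        endog = np.column_stack(
            [df["germinated"], df["total"] - df["germinated"]]
        )
        exog = sm.add_constant(df["storage_days"].to_numpy())
        glm = sm.GLM(
            endog, exog, family=sm.families.Binomial(sm.families.links.Probit())
        ).fit()
        assert fit.Ki == pytest.approx(glm.params[0], abs=1e-5)
        assert fit.sigma_inv == pytest.approx(-glm.params[1], abs=1e-6)
        # SEs: observed information here vs expected information in the GLM
        # IRLS; the two differ slightly for the non-canonical probit link
        assert fit.se_Ki == pytest.approx(glm.bse[0], rel=0.05)
        assert fit.se_sigma_inv == pytest.approx(glm.bse[1], rel=0.05)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_two_point_exact_interpolation(self):
        # a two-point fit is saturated: the line passes through both probits
        df = survival_frame([0.0, 20.0], [45, 14], 90)
        fit = fit_viability(df)
        pred0 = ndtr(fit.Ki)
        pred1 = ndtr(fit.Ki - fit.sigma_inv * 20.0)
        assert pred0 == pytest.approx(0.5, abs=1e-6)
        assert pred1 == pytest.approx(14 / 90, abs=1e-6)

    def test_replication_pooling_invariance(self, noiseless_survival):
        df, _ = noiseless_survival
        split = pd.concat(
            [
                df.assign(germinated=df["germinated"] // 2, total=45),
                df.assign(
                    germinated=df["germinated"] - df["germinated"] // 2, total=45
                ),
            ]
        )
        a, b = fit_viability(df), fit_viability(split)
        assert a.Ki == pytest.approx(b.Ki, abs=1e-6)
        assert a.sigma_inv == pytest.approx(b.sigma_inv, abs=1e-7)

    def test_degenerate_proportions_handled_exactly(self):
        # boundary counts (0 and 100%) enter the binomial likelihood directly
        df = survival_frame([0, 14, 28, 42, 56], [90, 80, 40, 5, 0], 90)
        fit = fit_viability(df)
        assert fit.converged and fit.sigma_inv > 0

    def test_non_identifiable_inputs(self):
        with pytest.raises(NonIdentifiableError):
            fit_viability(survival_frame([0, 14, 28], [0, 0, 0], 90))
        with pytest.raises(NonIdentifiableError):
            fit_viability(survival_frame([0, 14, 28], [90, 90, 90], 90))
        with pytest.raises(NonIdentifiableError):
            fit_viability(survival_frame([14, 14], [50, 52], 90))

    def test_increasing_germination_flagged(self):
        df = survival_frame([0, 14, 28, 42], [10, 30, 60, 80], 90)
        with pytest.warns(UserWarning, match="increases"):
            fit = fit_viability(df)
        assert fit.increasing_with_time

    def test_accepts_observation_records(self, noiseless_survival):
        df, _ = noiseless_survival
        obs = [
            SurvivalObservation(
                storage_days=r.storage_days,
                germinated=int(r.germinated),
                total=int(r.total),
            )
            for r in df.itertuples()
        ]
        assert fit_viability(obs).Ki == pytest.approx(fit_viability(df).Ki, abs=1e-9)


class TestFitCombined:
    @pytest.fixture
    def dormant_data(self):
        # truth: Knd=-0.5, sigma_nd=10 d, Ki=2.5, sigma_inv=0.07
        days = np.array([0.0, 7.0, 14.0, 28.0, 42.0, 56.0])
        prob = norm.cdf(-0.5 + days / 10.0) * norm.cdf(2.5 - 0.07 * days)
        g = np.round(90 * prob).astype(int)
        return survival_frame(days, g, 90)

    def test_recovers_dormancy_truth(self, dormant_data):
        fit = fit_combined(dormant_data)
        assert fit.Knd == pytest.approx(-0.5, rel=0.10)
        assert fit.sigma_nd == pytest.approx(10.0, rel=0.10)
        assert fit.Ki == pytest.approx(2.5, rel=0.10)
        assert fit.sigma_inv == pytest.approx(0.07, rel=0.10)
        assert fit.dormancy_supported

    def test_reduces_to_viability_fit_without_dormancy(self, noiseless_survival):
        df, _ = noiseless_survival
        red = fit_viability(df)
        com = fit_combined(df)
        assert not com.dormancy_supported
        assert com.Ki == pytest.approx(red.Ki, abs=1e-3)
        assert com.sigma_inv == pytest.approx(red.sigma_inv, abs=1e-3)

    def test_never_worse_deviance_than_reduced(self, dormant_data, noiseless_survival):
        for df in (dormant_data, noiseless_survival[0]):
            assert fit_combined(df).loglik >= fit_viability(df).loglik - 1e-6

    def test_monotone_decline_flags_dormancy_unsupported(self):
        days = np.array([0, 14, 28, 42, 56.0])
        g = np.round(90 * norm.cdf(1.5 - 0.07 * days)).astype(int)
        fit = fit_combined(survival_frame(days, g, 90))
        assert not fit.dormancy_supported

    def test_p50_uses_viability_component_only(self, dormant_data):
        fit = fit_combined(dormant_data)
        assert fit.p50 == pytest.approx(fit.Ki / fit.sigma_inv, rel=1e-10)


class TestP50:
    @pytest.mark.parametrize(
        "ki,s,expected",
        [(1.72, 0.104, 16.5), (1.59, 0.070, 22.7), (0.70, 0.080, 8.8)],
    )
    def test_published_row_identity(self, ki, s, expected):
        assert round(p50_from_fit(ki, s), 1) == expected

    def test_boundary_cases(self):
        assert p50_from_fit(0.0, 0.08) == 0.0
        assert np.isnan(p50_from_fit(-0.5, 0.08))
        with pytest.raises(ValueError):
            p50_from_fit(1.0, 0.0)


class TestPanelSummaries:
    def test_single_fit_max_min_mean_equal(self):
        df = pd.DataFrame({"Ki": [1.5], "sigma_inv": [0.08], "p50": [18.75]})
        out = summarize_panel(df)
        assert (out.loc["Maximum"] == out.loc["Minimum"]).all()
        assert (out.loc["Mean"] == out.loc["Maximum"]).all()

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            summarize_panel(pd.DataFrame(columns=["Ki", "sigma_inv", "p50"]))


class TestP50CorrelationMatrix:
    def test_identical_and_anti_ordered_columns(self):
        base = pd.Series([10.0, 15.0, 20.0, 25.0, 30.0, 12.0, 22.0])
        df = pd.DataFrame(
            {"A": base, "B": base.copy(), "C": 40.0 - 0.5 * base}
        )
        r, sig = p50_correlation_matrix(df)
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert r.loc["A", "C"] == pytest.approx(-1.0)
        assert sig.loc["A", "B"]

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(42)
        n = 7
        x = rng.uniform(10, 30, n)
        y = 0.9 * (x - x.mean()) / x.std() + rng.normal(0, np.sqrt(1 - 0.81), n)
        df = pd.DataFrame({"A": x, "B": y})
        r, _ = p50_correlation_matrix(df)
        # direct-formula oracle
        oracle = np.corrcoef(x, y)[0, 1]
        assert r.loc["A", "B"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_undefined(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        r, sig = p50_correlation_matrix(df)
        assert np.isnan(r.loc["A", "B"]) and not sig.loc["A", "B"]

    def test_too_few_lots_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]})
        with pytest.raises(ValueError):
            p50_correlation_matrix(df)


def test_monotone_fitted_survival(noiseless_survival):
    df, _ = noiseless_survival
    fit = fit_viability(df)
    days = np.linspace(0, 80, 50)
    pred = ndtr(fit.Ki - fit.sigma_inv * days)
    assert np.all(np.diff(pred) < 0)


def test_table_rows_rounding():
    fits = {
        "lot1": viability.ViabilityFit(
            Ki=1.7211, sigma_inv=0.10422, se_Ki=0.131, se_sigma_inv=0.0071,
            p50=16.514, loglik=-10.0, n_obs=5,
        )
    }
    row = viability.table_rows(fits).iloc[0]
    assert row["Ki"] == 1.72 and row["sigma_inv"] == 0.104 and row["P50"] == 16.5
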