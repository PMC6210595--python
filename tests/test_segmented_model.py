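"""Design coding, mixed-model estimation, LR tests and predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tsa.arima_process import arma_acf

from prescvar import panel_io as pio
from prescvar import segmented_model as seg
from prescvar import synthetic_data as synth


def _share_panel(n_practices=30, seed=2, **kw):
    cfg = synth.SimConfig(n_practices=n_practices, seed=seed, **kw)
    panel, prof, truth = synth.simulate_panel(cfg)
    return pio.compute_share(panel), prof, truth, cfg


class TestBuildDesign:
    def test_coding_table(self):
        months = pd.period_range("2015-07", "2015-11", freq="M")
        panel = pio.compute_share(pd.DataFrame({
            "practice_id": ["A"] * 5,
            "period": months,
            "focal_items": [5] * 5,
            "class_items": [50] * 5,
            "total_items": [60] * 5,
        }))
        d = seg.build_design(panel, "2015-09")
        assert d["t"].tolist() == [-1, 0, 2, 3]
        assert d["post"].tolist() == [0, 0, 1, 1]
        assert d["s"].tolist() == [0, 0, 0, 1]
        assert d["month"].tolist() == [7, 8, 10, 11]

    def test_transition_month_included_as_pre(self):
        months = pd.period_range("2015-07", "2015-11", freq="M")
        panel = pio.compute_share(pd.DataFrame({
            "practice_id": ["A"] * 5, "period": months,
            "focal_items": [5] * 5, "class_items": [50] * 5,
            "total_items": [60] * 5}))
        d = seg.build_design(panel, "2015-09", include_transition=True)
        row = d[d["is_transition"]]
        assert len(row) == 1
        assert row["post"].iloc[0] == 0 and row["s"].iloc[0] == 0

    def test_row_count_is_defined_minus_transition(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        defined = int(small_share["share_defined"].sum())
        transition = int((small_share["period"] == pd.Period("2015-09", "M"))
                         & small_share["share_defined"]).sum() if False else \
            int(((small_share["period"] == pd.Period("2015-09", "M"))
                 & small_share["share_defined"]).sum())
        assert len(d) == defined - transition

    def test_boundary_dhpc_rejected(self, small_share):
        with pytest.raises(ValueError):
            seg.build_design(small_share, "2017-02")


class TestOlsDegeneration:
    def test_matches_lstsq_oracle(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        fit = seg.fit_segmented(d, random_spec=(), ar_order=0,
                                seasonality=False)
        X = np.column_stack([np.ones(len(d)), d["t"], d["post"], d["s"]])
        beta, *_ = np.linalg.lstsq(X, d["share_pct"].to_numpy(), rcond=None)
        assert np.abs(fit.beta.to_numpy() - beta).max() < 1e-8

    def test_ml_loglik_matches_statsmodels_ols(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        fit = seg.fit_segmented(d, random_spec=(), ar_order=0, method="ml",
                                seasonality=False)
        X = sm.add_constant(d[["t", "post", "s"]])
        ols = sm.OLS(d["share_pct"], X).fit()
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)


def test_ar2_correlation_matches_arma_acf():
    rho1, rho2 = 0.35, 0.18
    times = np.arange(10.0)
    R = seg.ar2_corr(rho1, rho2, times)
    ref = arma_acf([1.0, -rho1, -rho2], [1.0], lags=10)
    assert np.allclose(R[0], ref, atol=1e-10)


def test_reml_objective_matches_mixedlm():
    """Evaluate this module's REML objective at MixedLM's solution."""
    share, _, _, _ = _share_panel(n_practices=40, seed=5, rho1=0, rho2=0)
    d = seg.build_design(share, "2015-09")
    X, _ = seg._design_matrix(d, False)
    pats = seg._group_patterns(d, X, [0])
    md = smf.mixedlm("share_pct ~ t + post + s", d, groups=d["practice_id"])
    with pytest.warns(Warning):
        mf = md.fit(reml=True)
    theta = np.array([0.5 * np.log(mf.cov_re.iloc[0, 0]),
                      0.5 * np.log(mf.scale)])
    mine = -0.5 * seg._neg2ll(theta, pats, 4, 1, 0, True)
    assert mine == pytest.approx(mf.llf, abs=1e-8)
    # and this module's optimum is at least as good
    fit = seg.fit_segmented(d, random_spec=("intercept",), ar_order=0,
                            seasonality=False)
    assert fit.loglik >= mf.llf - 1e-6
    assert np.abs(fit.beta.to_numpy() - mf.params[:4].to_numpy()).max() < 1e-3


class TestFit:
    def test_degenerate_truth_recovers_fixed_effects(self):
        # near-homoscedastic denominators so no practice heterogeneity can
        # masquerade as random-effect variance
        share, _, truth, cfg = _share_panel(
            n_practices=150, seed=6, sd_b=(0, 0, 0, 0), rho1=0, rho2=0,
            sigma_w=0.0, gamma=tuple([0.0] * 12), lambda_mean=5000,
            lambda_sigma=0.0)
        d = seg.build_design(share, "2015-09")
        fit = seg.fit_segmented(d, ar_order=0, seasonality=False)
        for name, col in zip(synth.RANDOM_EFFECTS,
                             ("intercept", "t", "post", "s")):
            est = fit.params.loc[col]
            assert abs(est["estimate"] - truth["beta"][name]) < 3 * est["se"] + 1e-6
        # G should be near zero
        assert np.sqrt(np.diag(fit.G)).max() < 0.5

    def test_fitted_plus_residuals_reproduce_outcome(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        fit = seg.fit_segmented(d, ar_order=2)
        recon = fit.results["fitted"] + fit.results["resid"]
        assert np.allclose(recon, fit.results["share_pct"], atol=1e-10)

    def test_ar_estimated_when_present(self):
        share, _, _, cfg = _share_panel(n_practices=80, seed=14,
                                        rho1=0.5, rho2=0.2)
        d = seg.build_design(share, "2015-09")
        fit = seg.fit_segmented(d, random_spec=("intercept", "slope"),
                                ar_order=2, seasonality=False)
        # binomial sampling noise is white, so the fitted AR coefficients
        # are attenuated relative to the latent process; check sign and
        # rough magnitude
        assert fit.rho[0] > 0.05
        assert fit.converged

    def test_blups_shrink_toward_zero_and_track_truth(self):
        share, _, truth, cfg = _share_panel(n_practices=100, seed=8,
                                            rho1=0, rho2=0)
        d = seg.build_design(share, "2015-09")
        fit = seg.fit_segmented(d, ar_order=0, seasonality=False)
        blup = fit.blups.set_index("practice_id")["b_intercept"]
        tru = truth["practice_effects"].set_index("practice_id")["intercept"]
        r = np.corrcoef(blup[tru.index], tru)[0, 1]
        assert r > 0.9
        assert blup.abs().mean() < tru.abs().mean() * 1.2

    def test_strict_unknown_effect_raises(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        with pytest.raises(ValueError):
            seg.fit_segmented(d, random_spec=("banana",))

    def test_rank_deficient_seasonality_rejected(self):
        months = pd.period_range("2015-06", periods=6, freq="M")
        panel = pio.compute_share(pd.DataFrame({
            "practice_id": ["A"] * 6 + ["B"] * 6,
            "period": list(months) * 2,
            "focal_items": [5] * 12, "class_items": [50] * 12,
            "total_items": [50] * 12}))
        d = seg.build_design(panel, "2015-09")
        with pytest.raises(ValueError, match="seasonality"):
            seg.fit_segmented(d, seasonality=True)


class TestLrTest:
    def test_identical_models_statistic_zero(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        fit = seg.fit_segmented(d, random_spec=("intercept",), ar_order=0,
                                method="ml", seasonality=False)
        res = seg.lr_test_random_effect(fit, fit)
        assert res["statistic"] == 0.0
        assert res["p"] == 1.0

    def test_detects_needed_random_slope(self):
        share, _, _, _ = _share_panel(n_practices=100, seed=10, rho1=0,
                                      rho2=0, sd_b=(2.0, 0.15, 0.0, 0.0))
        d = seg.build_design(share, "2015-09")
        full = seg.fit_segmented(d, random_spec=("intercept", "slope"),
                                 ar_order=0, method="ml", seasonality=False)
        red = seg.fit_segmented(d, random_spec=("intercept",), ar_order=0,
                                method="ml", seasonality=False)
        res = seg.lr_test_random_effect(full, red)
        assert res["df"] == 2
        assert res["statistic"] > 0
        assert res["p"] < 1e-4

    def test_non_nested_rejected(self, small_share):
        d = seg.build_design(small_share, "2015-09")
        a = seg.fit_segmented(d, random_spec=("intercept",), ar_order=0,
                              method="ml", seasonality=False)
        b = seg.fit_segmented(d, random_spec=("slope",), ar_order=0,
                              method="ml", seasonality=False)
        with pytest.raises(ValueError, match="nested"):
            seg.lr_test_random_effect(b, a)


@pytest.fixture(scope="module")
def fit_and_design(small_share):
    d = seg.build_design(small_share, "2015-09")
    fit = seg.fit_segmented(d, ar_order=0)
    return fit, d


class TestCounterfactual:
    def test_pre_period_curves_coincide(self, fit_and_design):
        fit, d = fit_and_design
        pred = seg.predict_counterfactual(fit, d)
        pre = pred[pred["period"] < pd.Period("2015-09", "M")]
        assert np.allclose(pre["factual"], pre["counterfactual"], atol=1e-12)

    def test_first_post_month_gap_is_level_change(self, fit_and_design):
        fit, d = fit_and_design
        pred = seg.predict_counterfactual(fit, d)
        oct15 = pred[pred["period"] == pd.Period("2015-10", "M")].iloc[0]
        gap = oct15["factual"] - oct15["counterfactual"]
        assert gap == pytest.approx(fit.beta["post"], abs=1e-10)

    def test_late_gap_is_level_plus_slope_change(self, fit_and_design):
        fit, d = fit_and_design
        pred = seg.predict_counterfactual(fit, d)
        # 18 months after the anchor: t = 18, s = 16
        m = pd.Period("2015-08", "M") + 18
        row = pred[pred["period"] == m].iloc[0]
        gap = row["factual"] - row["counterfactual"]
        expect = fit.beta["post"] + 16 * fit.beta["s"]
        assert gap == pytest.approx(expect, abs=1e-10)


def test_ci_coverage_for_trend_on_scaled_replicates():
    """Nominal 95% Wald CIs for the pre-period trend cover the planted
    truth in at least 90% of scaled-down replicates."""
    hits = 0
    n_reps = 60
    for i in range(n_reps):
        cfg = synth.recovery_config(n_practices=40, seed=20_000 + i)
        panel, _, _ = synth.simulate_panel(cfg)
        share = pio.compute_share(panel)
        d = seg.build_design(share, "2015-09")
        fit = seg.fit_segmented(d, ar_order=0, seasonality=False)
        row = fit.params.loc["t"]
        hits += row["ci_low"] <= cfg.beta1 <= row["ci_high"]
    assert hits / n_reps >= 0.90
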