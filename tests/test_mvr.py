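import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ufgpanel.core_io import ExpressionMatrix, PanelStudy, PotencyTable
from ufgpanel.mvr import (
    EnsembleModel,
    PublishedModel,
    UnivariateModel,
    calibrate,
    ensemble_predict,
    evaluate_published_model,
    fit_ensemble,
    fit_univariate_models,
    load_published_model,
    prioritize_subset,
    quartile_mean_prediction,
)
from ufgpanel.potency import assign_quartiles
from ufgpanel.synthetic_data import SynthConfig, cognate_config, simulate_panel


def panel_from_arrays(expr_values, log10_ic50_by_drug, genes=None):
    genes = genes or [f"g{i}" for i in range(expr_values.shape[0])]
    lines = [f"L{i:03d}" for i in range(expr_values.shape[1])]
    expr = ExpressionMatrix(pd.DataFrame(expr_values, index=genes, columns=lines))
    ic50 = pd.DataFrame(
        {l: {d: 10.0 ** y[i] for d, y in log10_ic50_by_drug.items()}
         for i, l in enumerate(lines)}
    )
    censored = pd.DataFrame(False, index=ic50.index, columns=ic50.columns)
    top = pd.Series({d: 1.0 for d in ic50.index})
    return PanelStudy(expr, PotencyTable(ic50, censored, top))


class TestFitUnivariate:
    def test_noiseless_recovery(self):
        x = np.linspace(2, 8, 10)
        panel = panel_from_arrays(x[None, :], {"d": -0.5 * x - 6.0})
        (m,) = fit_univariate_models(["g0"], panel, "d")
        assert m.slope == pytest.approx(-0.5, abs=1e-12)
        assert m.intercept == pytest.approx(-6.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0)

    def test_duplicate_gene_is_error(self):
        x = np.linspace(2, 8, 10)
        panel = panel_from_arrays(x[None, :], {"d": -x})
        with pytest.raises(ValueError, match="duplicate"):
            fit_univariate_models(["g0", "g0"], panel, "d")

    def test_slope_estimate_unbiased_with_noise(self):
        rng = np.random.default_rng(30)
        slopes = []
        for _ in range(200):
            x = rng.normal(5, 1, size=100)
            y = -0.4 * x - 6 + rng.normal(0, 0.5, size=100)
            res = stats.linregress(x, y)
            slopes.append(res.slope)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) + 0.4) < 3 * se


class TestEnsembleAlgebra:
    members = (
        UnivariateModel("g0", -0.5, -6.0, 0.9, 1e-6),
        UnivariateModel("g1", 0.25, -8.0, 0.5, 1e-3),
        UnivariateModel("g2", 0.0, -7.0, 0.0, 1.0),
    )

    def expr(self):
        return ExpressionMatrix(
            pd.DataFrame([[2.0, 4.0], [4.0, 8.0], [1.0, 1.0]],
                         index=["g0", "g1", "g2"], columns=["A", "B"])
        )

    def test_single_member_identity(self):
        single = ensemble_predict(self.members[:1], self.expr())
        np.testing.assert_allclose(single, [-7.0, -8.0])

    def test_mean_of_two(self):
        m = (UnivariateModel("g0", 0.0, -8.0, 0, 1), UnivariateModel("g1", 0.0, -9.0, 0, 1))
        pred = ensemble_predict(m, self.expr())
        np.testing.assert_allclose(pred, [-8.5, -8.5])

    def test_three_member_hand_arithmetic(self):
        # line A: (-7.0, -7.0, -7.0) -> -7; line B: (-8.0, -6.0, -7.0) -> -7
        pred = ensemble_predict(self.members, self.expr())
        np.testing.assert_allclose(pred, [-7.0, -7.0])

    def test_member_order_invariance(self):
        a = ensemble_predict(self.members, self.expr())
        b = ensemble_predict(self.members[::-1], self.expr())
        np.testing.assert_allclose(a, b)

    def test_adding_agreeing_member_is_neutral(self):
        pred = ensemble_predict(self.members, self.expr())
        clone = UnivariateModel("g2", 0.0, float(pred.iloc[0]), 0.0, 1.0)
        assert (pred == pred.iloc[0]).all()  # agreeing member exists only then
        grown = ensemble_predict(self.members + (clone,), self.expr())
        np.testing.assert_allclose(grown, pred)

    def test_missing_member_gene_is_error(self):
        with pytest.raises(KeyError, match="nope"):
            ensemble_predict((UnivariateModel("nope", 1, 0, 0, 1),), self.expr())


class TestCalibrate:
    def test_identity(self):
        y = np.array([-9.0, -8.0, -7.5, -6.0])
        cal = calibrate(y, y)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(31)
        pred = rng.normal(-8, 1, size=12)
        meas = 0.8 * pred + rng.normal(0, 0.4, size=12)
        cal = calibrate(pred, meas)
        ref = stats.linregress(pred, meas)
        assert cal.slope == pytest.approx(ref.slope, abs=1e-12)
        assert cal.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(32)
        p = [calibrate(rng.normal(size=20), rng.normal(size=20)).p for _ in range(500)]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_constant_prediction_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            calibrate(np.full(5, -8.0), np.arange(5.0))


class TestPrioritizeSubset:
    def make_leaky_panel(self):
        rng = np.random.default_rng(33)
        n = 60
        xa, xb = rng.normal(5, 1, n), rng.normal(5, 1, n)
        y_cog = -0.8 * xa - 4.5 + rng.normal(0, 0.3, n)
        y_non = 0.5 * xb - 10.5 + rng.normal(0, 0.3, n)
        return panel_from_arrays(
            np.vstack([xa, xb]), {"cog": y_cog, "non": y_non}, genes=["A", "B"]
        )

    def test_single_specific_gene_returns_k1(self):
        panel = self.make_leaky_panel()
        models = fit_univariate_models(["A", "B"], panel, "cog")
        ensemble, specific = prioritize_subset(models, panel, "cog", ["non"])
        assert specific
        assert ensemble.genes == ("A",)

    def test_full_set_leaks_but_prefix_is_specific(self):
        # the 2-gene ensemble carries B's noncognate signal; the search stops before it
        panel = self.make_leaky_panel()
        expr, pot = panel.joint()
        models = fit_univariate_models(["A", "B"], panel, "cog")
        full_pred = ensemble_predict(models, expr).to_numpy()
        y_non = np.log10(pot.drug_ic50("non").to_numpy(float))
        assert calibrate(full_pred, y_non).p < 0.05  # leakage exists
        ensemble, specific = prioritize_subset(models, panel, "cog", ["non"])
        assert specific and len(ensemble.members) < 2

    def test_no_specific_prefix_flags_full_set(self):
        rng = np.random.default_rng(34)
        n = 50
        x = rng.normal(5, 1, n)
        shared = -0.9 * x + rng.normal(0, 0.2, n)
        panel = panel_from_arrays(
            x[None, :], {"cog": shared - 4, "non": shared - 9}, genes=["A"]
        )
        models = fit_univariate_models(["A"], panel, "cog")
        ensemble, specific = prioritize_subset(models, panel, "cog", ["non"])
        assert not specific
        assert ensemble.genes == ("A",)


class TestPublishedModels:
    def test_shipped_intercepts_at_zero_expression(self):
        eri = load_published_model("eribulin_4gene")
        vin = load_published_model("vinorelbine_5gene")
        assert eri.evaluate({g: 0.0 for g in eri.genes}) == pytest.approx(-8.54)
        assert vin.evaluate({g: 0.0 for g in vin.genes}) == pytest.approx(-9.81)

    def test_unit_term_identity(self):
        eri = load_published_model("eribulin_4gene")
        expr = {g: 0.0 for g in eri.genes}
        expr["CD70"] = 5.40
        assert evaluate_published_model(eri, expr) == pytest.approx(-7.54)

    def test_missing_gene_is_error(self):
        eri = load_published_model("eribulin_4gene")
        with pytest.raises(KeyError, match="IRX2"):
            eri.evaluate({"CD70": 1.0, "C5ORF38": 1.0, "DAAM1": 1.0})

    def test_negative_rpkm_is_error(self):
        eri = load_published_model("eribulin_4gene")
        with pytest.raises(ValueError, match="negative"):
            eri.evaluate({g: -1.0 for g in eri.genes})

    def test_serialization_round_trip_predictions(self, tmp_path):
        eri = load_published_model("eribulin_4gene")
        path = tmp_path / "m.json"
        path.write_text(eri.to_json())
        again = load_published_model(str(path))
        assert again == eri
        rng = np.random.default_rng(35)
        rpkm = pd.DataFrame(
            rng.uniform(0, 30, size=(4, 6)), index=eri.genes,
            columns=[f"L{i}" for i in range(6)]
        )
        pd.testing.assert_series_equal(eri.predict_lines(rpkm), again.predict_lines(rpkm))


class TestQuartilePrediction:
    def test_perfect_model_identity(self, default_panel):
        panel, _ = default_panel
        _, pot = panel.joint()
        measured = np.log10(pot.drug_ic50("eribulin"))
        a = assign_quartiles(pot, "eribulin")
        out = quartile_mean_prediction(measured, measured, a)
        assert (out["p"] == 1.0).all()
        np.testing.assert_allclose(out["predicted_mean"], out["measured_mean"])

    def test_cognate_fit_orders_quartiles_and_agrees(self):
        expr, pot, truth = simulate_panel(cognate_config(SynthConfig(seed=40)))
        panel = PanelStudy(expr, pot)
        ens = fit_ensemble(sorted(truth.unique["eribulin"]), panel, "eribulin")
        pred = ens.predict(expr)
        meas = np.log10(pot.drug_ic50("eribulin"))
        a = assign_quartiles(pot, "eribulin")
        out = quartile_mean_prediction(pred, meas, a).set_index("quartile")
        assert out.loc["top", "predicted_mean"] < out.loc["bottom", "predicted_mean"]
        assert (out["p"] >= 0.05).all()
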