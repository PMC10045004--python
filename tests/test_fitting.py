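"""Goodness-of-fit statistics, least-squares fitting, and model ranking."""

import numpy as np
import pytest

from drykin import (
    ParameterSet,
    ThinLayerModel,
    eval_model,
    fit_all,
    fit_model,
    goodness_of_fit,
    select_best,
)
from drykin.fitting import SelectionTable, _failed_fit
from drykin.models import get_model


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([1.0, 0.7, 0.4, 0.2, 0.1])
        r2, chi2, rmse = goodness_of_fit(y, y, z=2)
        assert (r2, chi2, rmse) == (1.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        # SSE = 0.0009, SS_tot = 0.1475 about the observed mean
        obs = [1.0, 0.8, 0.6, 0.5]
        pre = [1.0, 0.78, 0.62, 0.49]
        r2, chi2, rmse = goodness_of_fit(obs, pre, z=2)
        assert rmse == pytest.approx(0.015, abs=1e-12)
        assert chi2 == pytest.approx(0.00045, abs=1e-12)
        assert round(r2, 5) == 0.99390

    def test_chi2_rmse_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            z = int(rng.integers(1, 4))
            obs = rng.uniform(0, 1, n)
            pre = obs + rng.normal(0, 0.01, n)
            r2, chi2, rmse = goodness_of_fit(obs, pre, z)
            assert chi2 == pytest.approx(n * rmse**2 / (n - z), rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2], [1, 2, 3], 1)
        with pytest.raises(ValueError):
            goodness_of_fit([1, 0.5, 0.2], [1, 0.5, 0.2], 3)
        with pytest.raises(ValueError):
            goodness_of_fit([0.5, 0.5, 0.5], [0.5, 0.4, 0.3], 1)


class TestFitModel:
    def test_newton_self_recovery_noiseless(self):
        t = np.arange(0.0, 451.0, 10.0)
        fit = fit_model(t, np.exp(-0.05 * t), "Newton")
        assert fit.converged
        assert fit.params["k"] == pytest.approx(0.05, abs=1e-7)

    def test_exponential_recovery_of_reference_rate(self, md600_exponential_curve):
        t, mr = md600_exponential_curve
        fit = fit_model(t, mr, "Henderson and Pabis")
        assert round(fit.params["k"], 4) == 0.1535
        assert round(fit.params["a"], 4) == 1.0101

    def test_sledz_nests_logistic_curve(self, cd40_logistic_curve):
        t, mr, _ = cd40_logistic_curve
        fit = fit_model(t, mr, "Sledz et al.")
        assert fit.r_squared >= 0.9995
        assert fit.rmse < 1e-6

    def test_anchored_models_self_recover(self):
        # noiseless self-generated data refits to the truth constants
        cases = {
            "Page": {"k": 0.02, "n": 1.3},
            "Weibull": {"a": 35.0, "b": 1.1},
            "Wang and Singh": {"a": -0.012, "b": 3.6e-5},
        }
        t = np.arange(0.0, 151.0, 5.0)
        for name, truth in cases.items():
            mr = eval_model(ParameterSet(name, truth), t)
            fit = fit_model(t, mr, name)
            for p, v in truth.items():
                assert fit.params[p] == pytest.approx(v, rel=1e-6), name

    def test_fit_precondition_errors(self):
        with pytest.raises(ValueError):
            fit_model([0, 1, 2], [1.0, 0.9, 0.8],
                      "Sledz et al.")  # N <= z
        with pytest.raises(ValueError):
            fit_model([0, 1, 2, 3], [1.0, np.nan, 0.8, 0.7], "Newton")
        with pytest.raises(ValueError):
            fit_model([0, 1, 1, 3], [1.0, 0.9, 0.8, 0.7], "Newton")

    def test_model_object_api(self, md600_exponential_curve):
        import pandas as pd

        t, mr = md600_exponential_curve
        df = pd.DataFrame({"time_min": t, "mr": mr})
        model = ThinLayerModel.from_dataframe(df, "Newton")
        res = model.fit()
        assert "Newton" in res.summary()
        assert res.n_obs == t.size
        assert np.allclose(res.predict(t), np.exp(-res.params["k"] * t))

    def test_plot_smoke(self, md600_exponential_curve):
        import matplotlib

        matplotlib.use("Agg")
        t, mr = md600_exponential_curve
        res = fit_model(t, mr, "Newton")
        ax = res.plot(t, observed=mr)
        assert ax.get_xlabel() == "time (min)"

    def test_rmse_approaches_noise_floor(self):
        # with additive noise sd sigma the fitted RMSE estimates
        # sigma * sqrt((N - z)/N) in expectation
        sigma, n_rep = 0.003, 200
        t = np.arange(0.0, 451.0, 10.0)  # N = 46
        truth = np.exp(-0.01 * t)
        rng = np.random.default_rng(7)
        rmses = []
        for _ in range(n_rep):
            fit = fit_model(t, truth + rng.normal(0, sigma, t.size), "Newton")
            rmses.append(fit.rmse)
        n, z = t.size, 1
        expected = sigma * np.sqrt((n - z) / n)
        se = sigma / np.sqrt(2 * n * n_rep)  # MC error of the mean RMSE
        assert np.mean(rmses) == pytest.approx(expected, abs=4 * se)


class TestOptimizerAgainstGridSearch:
    """The optimizer SSE never exceeds an exhaustive grid search."""

    @staticmethod
    def _sse(name, values, t, y):
        from drykin.models import _eval_raw

        return float(np.sum((_eval_raw(name, values, t) - y) ** 2))

    def test_small_models_beat_grid(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 121.0, 4.0)
        ks = np.linspace(1e-3, 0.2, 120)
        amps = np.linspace(0.5, 1.5, 80)
        ns = np.linspace(0.5, 2.0, 80)
        for rep in range(20):
            k_true = rng.uniform(0.01, 0.1)
            y = np.exp(-k_true * t**rng.uniform(0.9, 1.2)) \
                + rng.normal(0, 0.01, t.size)
            for name in ("Newton", "Henderson and Pabis", "Page"):
                fit = fit_model(t, y, name)
                if name == "Newton":
                    grid = min(self._sse(name, {"k": k}, t, y) for k in ks)
                elif name == "Henderson and Pabis":
                    pred = amps[:, None, None] * np.exp(
                        -ks[None, :, None] * t[None, None, :])
                    grid = float(np.min(np.sum((pred - y) ** 2, axis=-1)))
                else:
                    pred = np.exp(
                        -ks[:, None, None] * t[None, None, :]
                        ** ns[None, :, None])
                    grid = float(np.min(np.sum((pred - y) ** 2, axis=-1)))
                assert fit.sse <= grid * (1 + 1e-9) + 1e-12, (name, rep)


class TestSelection:
    def test_full_catalog_gives_22_rows(self, cd40_logistic_curve):
        t, mr, _ = cd40_logistic_curve
        table = fit_all(t, mr, label="CD-40")
        assert len(table) == 22
        df = table.to_frame()
        assert set(df["model"]) == set(m.name for m in
                                       __import__("drykin").model_catalog())

    def test_ranking_prefers_higher_r2(self):
        a = _failed_fit(get_model("Newton"), 10, {})
        a.r_squared, a.rmse, a.chi_squared, a.converged = 0.999, 0.01, 1e-4, True
        b = _failed_fit(get_model("Page"), 10, {})
        b.r_squared, b.rmse, b.chi_squared, b.converged = 0.99, 0.03, 1e-3, True
        table = SelectionTable(label="x", results=[b, a])
        assert table.best().model_name == "Newton"

    def test_tie_breaks_rmse_then_parsimony_then_name(self):
        def make(name, r2, rmse):
            f = _failed_fit(get_model(name), 10, {})
            f.r_squared, f.rmse, f.converged = r2, rmse, True
            f.chi_squared = 0.0
            return f

        # exact R^2 tie -> lower RMSE wins
        t1 = SelectionTable("x", [make("Newton", 0.999, 0.02),
                                  make("Page", 0.999, 0.01)])
        assert t1.best().model_name == "Page"
        # full statistic tie -> fewer parameters win (Newton z=1 < Page z=2)
        t2 = SelectionTable("x", [make("Page", 0.999, 0.01),
                                  make("Newton", 0.999, 0.01)])
        assert t2.best().model_name == "Newton"
        # same z -> name order
        t3 = SelectionTable("x", [make("Weibull", 0.999, 0.01),
                                  make("Page", 0.999, 0.01)])
        assert t3.best().model_name == "Page"

    def test_failed_fits_sink_and_all_failed_errors(self):
        bad = _failed_fit(get_model("Newton"), 10, {})
        good = _failed_fit(get_model("Page"), 10, {})
        good.r_squared, good.rmse, good.chi_squared, good.converged = \
            0.9, 0.05, 1e-3, True
        table = SelectionTable("x", [bad, good])
        assert select_best(table).model_name == "Page"
        with pytest.raises(ValueError):
            SelectionTable("x", [bad]).best()
        with pytest.raises(ValueError):
            SelectionTable("x", []).best()

    def test_empty_model_list_rejected(self, md600_exponential_curve):
        t, mr = md600_exponential_curve
        with pytest.raises(ValueError):
            fit_all(t, mr, models=[])

    def test_serialisation(self, md600_exponential_curve, tmp_path):
        import json

        t, mr = md600_exponential_curve
        table = fit_all(t, mr, models=["Newton", "Henderson and Pabis"],
                        label="MD-600")
        p = tmp_path / "sel.csv"
        table.to_csv(p)
        assert p.read_text().count("\n") == 3  # header + 2 models
        doc = json.loads(table.to_json())
        assert doc["label"] == "MD-600"
        assert len(doc["results"]) == 2
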