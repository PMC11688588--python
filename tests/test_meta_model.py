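import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from samplecurve.meta_model import (
    PREDICTORS,
    adjusted_pseudo_r2,
    encode_predictors,
    events_per_variable,
    fit_nb,
    fit_nb_best_subset,
    predict_sample_size,
    published_models,
)


def meta_frame(n_stable, **columns):
    base = {
        "minority_pct": 25.0, "separability": 80.0, "n_features": 10.0,
        "pct_continuous": 30.0, "pct_core_linear": 60.0, "nonlinearity_high": 0.0,
    }
    n = len(n_stable)
    data = {"n_stable": n_stable}
    for k, v in base.items():
        data[k] = columns.get(k, np.full(n, v))
    return pd.DataFrame(data)


class TestEncoding:
    def test_separability_centered_at_fifty(self):
        df = meta_frame([10, 20], separability=np.array([50.0, 80.0]))
        enc = encode_predictors(df, ("separability",))
        assert enc["separability"].tolist() == [0.0, 30.0]

    def test_nonlinearity_binary(self):
        df = meta_frame([10, 20], nonlinearity_high=np.array([0.0, 7.0]))
        enc = encode_predictors(df, ("nonlinearity_high",))
        assert enc["nonlinearity_high"].tolist() == [0.0, 1.0]

    def test_missing_predictor_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            encode_predictors(pd.DataFrame({"a": [1]}), ("minority_pct",))


class TestFitNB:
    def test_intercept_only_on_constant_counts(self):
        fit = fit_nb(meta_frame([50] * 12), predictors=())
        assert fit.multipliers["intercept"] == pytest.approx(50.0, rel=1e-4)
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-8)
        assert adjusted_pseudo_r2(fit) == pytest.approx(0.0, abs=1e-8)

    def test_poisson_limit_without_overdispersion(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 50, 300)
        y = rng.poisson(200 * 0.97**x)
        df = meta_frame(np.maximum(y, 1), minority_pct=x)
        nb = fit_nb(df, ("minority_pct",))
        X = sm.add_constant(x)
        pois = sm.GLM(np.maximum(y, 1), X, family=sm.families.Poisson()).fit()
        assert nb.dispersion < 0.05
        assert nb.coefficients["minority_pct"] == pytest.approx(pois.params[1], abs=1e-3)
        assert nb.coefficients["intercept"] == pytest.approx(pois.params[0], abs=1e-2)

    def test_multiplier_recovery_with_ci_coverage(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 50, 200)
            mu = 1000 * 0.95**x
            size = 2.0  # NB size; alpha = 1/size = 0.5
            counts = rng.poisson(rng.gamma(size, mu / size))
            df = meta_frame(np.maximum(counts, 1), minority_pct=x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_nb(df, ("minority_pct",))
            lo, hi = fit.conf_intervals["minority_pct"]
            covered += lo <= 0.95 <= hi
        assert covered >= 90

    def test_collinear_predictors_rejected(self):
        df = meta_frame([10, 12, 30, 45, 80, 120, 33, 56],
                        pct_continuous=np.full(8, 30.0),
                        pct_core_linear=np.full(8, 30.0))
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_nb(df, ("pct_continuous", "pct_core_linear"))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            fit_nb(meta_frame([5, 6, 7]), ("minority_pct", "separability"))


class TestBestSubset:
    def test_enumerates_41_candidate_subsets(self):
        rng = np.random.default_rng(3)
        n = 40
        df = meta_frame(
            rng.poisson(100, n) + 1,
            minority_pct=rng.uniform(2, 50, n),
            separability=rng.uniform(60, 98, n),
            n_features=rng.integers(5, 40, n).astype(float),
            pct_continuous=rng.uniform(0, 100, n),
            pct_core_linear=rng.uniform(0, 100, n),
            nonlinearity_high=rng.integers(0, 2, n).astype(float),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best = fit_nb_best_subset(df, max_predictors=3)
        non_null = [s for s, _ in best.ranking if s]
        assert len(non_null) == math.comb(6, 1) + math.comb(6, 2) + math.comb(6, 3) == 41
        assert best.aic == min(a for _, a in best.ranking)

    def test_recovers_the_generating_predictor(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.uniform(0, 50, n)
        df = meta_frame(
            np.maximum(rng.poisson(2000 * 0.93**x), 1),
            minority_pct=x,
            separability=rng.uniform(60, 98, n),
            pct_continuous=rng.uniform(0, 100, n),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best = fit_nb_best_subset(df)
        assert "minority_pct" in best.predictor_names


class TestPublishedModels:
    def test_all_four_algorithms_present(self):
        models = published_models()
        assert set(models) == {"xgb", "rf", "lr", "nn"}
        assert models["xgb"].intercept_count == 121967
        assert models["xgb"].multipliers["minority_pct"] == 0.956
        assert models["rf"].multipliers["nonlinearity_high"] == 12.298
        assert models["lr"].multipliers["n_features"] == 1.054
        assert models["nn"].multipliers["pct_continuous"] == 0.973

    def test_predict_balanced_low_nonlinearity_xgb(self):
        # 121,967 x 0.956^50 x 0.952^30.2 = 2910.5
        model = published_models()["xgb"]
        n, interval = predict_sample_size(
            {"minority_pct": 50, "separability": 80.2, "nonlinearity_high": False},
            model,
        )
        assert n == 2911
        assert interval[0] < n < interval[1]

    def test_predict_lr_example(self):
        # 1801 x 0.968^50 x 1.054^11 x 0.988^100 = 188.9
        model = published_models()["lr"]
        n, _ = predict_sample_size(
            {"minority_pct": 50, "n_features": 11, "pct_core_linear": 100},
            model,
        )
        assert n == 189

    def test_baseline_returns_intercept(self):
        for model in published_models().values():
            values = {
                "minority_pct": 0, "separability": 50, "nonlinearity_high": False,
                "n_features": 0, "pct_continuous": 0, "pct_core_linear": 0,
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n, _ = predict_sample_size(values, model)
            assert n == math.ceil(model.intercept_count)

    def test_prediction_decreasing_in_minority_pct(self):
        for model in published_models().values():
            values = {
                "minority_pct": 2.1, "separability": 80, "nonlinearity_high": False,
                "n_features": 15, "pct_continuous": 30, "pct_core_linear": 60,
            }
            prev = math.inf
            for m in (5, 15, 25, 35, 50):
                values["minority_pct"] = m
                n, _ = predict_sample_size(values, model)
                assert n < prev
                prev = n

    @pytest.mark.parametrize("algo", ["xgb", "rf", "nn"])
    def test_nonlinearity_multiplier_is_exact_ratio(self, algo):
        model = published_models()[algo]
        values = {
            "minority_pct": 30, "separability": 80, "nonlinearity_high": False,
            "n_features": 15, "pct_continuous": 30, "pct_core_linear": 60,
        }
        raw_low = predict_sample_size(values, model)
        values["nonlinearity_high"] = True
        raw_high = predict_sample_size(values, model)
        # compare before rounding via the interval-free recomputation
        mult = model.multipliers["nonlinearity_high"]
        assert raw_high[0] == pytest.approx(raw_low[0] * mult, rel=2e-3)

    def test_extrapolation_warning_outside_observed_ranges(self):
        model = published_models()["xgb"]
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_sample_size(
                {"minority_pct": 1.0, "separability": 80, "nonlinearity_high": False},
                model,
            )

    def test_missing_predictor_rejected(self):
        with pytest.raises(ValueError, match="missing predictor"):
            predict_sample_size({"minority_pct": 30}, published_models()["xgb"])


class TestEventsPerVariable:
    def test_simple_arithmetic(self):
        assert events_per_variable(10_000, 0.20, 10) == pytest.approx(200.0)

    def test_cardio_xgb_row(self):
        assert events_per_variable(4341, 0.50, 11) == pytest.approx(197.3, abs=0.05)

    def test_single_feature(self):
        assert events_per_variable(1234, 0.3, 1) == pytest.approx(1234 * 0.3)

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            events_per_variable(100, 0.3, 0)


def test_refit_on_simulated_published_model_recovers_multipliers():
    """Counts simulated from the XGB published equation (mild NB noise) give
    back the generating multipliers within tight relative error."""
    model = published_models()["xgb"]
    rng = np.random.default_rng(123)
    n = 150
    minority = rng.uniform(2, 50, n)
    sep = rng.uniform(60, 98, n)
    nl = rng.integers(0, 2, n).astype(float)
    mu = (
        model.intercept_count
        * model.multipliers["minority_pct"] ** minority
        * model.multipliers["separability"] ** (sep - 50)
        * model.multipliers["nonlinearity_high"] ** nl
    )
    size = 10.0
    counts = np.maximum(rng.poisson(rng.gamma(size, mu / size)), 1)
    df = meta_frame(counts, minority_pct=minority, separability=sep, nonlinearity_high=nl)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_nb(df, ("minority_pct", "separability", "nonlinearity_high"))
    assert fit.multipliers["minority_pct"] == pytest.approx(0.956, abs=0.01)
    assert fit.multipliers["separability"] == pytest.approx(0.952, abs=0.01)
    assert fit.multipliers["nonlinearity_high"] == pytest.approx(3.091, rel=0.15)
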