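"""Collinearity screening, weighted boosted-tree fitting, buffered LOO and
SHAP interpretation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import forestedge as fe
from forestedge.attribution import (
    DEFAULT_XGB_PARAMS,
    DriverModel,
    biome_models,
    collinearity_screen,
    fit_attribution_model,
    shap_summary,
    spatial_buffered_loo,
    tune_hyperparameters,
)
from forestedge.simulate import generate_attribution_truth

PLANTED = {
    "mat": lambda v: 0.8 * (v - 9.0),
    "agriculture": lambda v: 0.15 * (v - 50.0),
    "map": lambda v: 0.003 * (v - 1850.0),
}
ALL_COVS = ["mat", "map", "wind", "soil_moisture", "elevation", "slope", "agriculture"]


def planted_data(seed: int, n: int = 150, noise_sd: float = 3.0):
    covs, b1 = generate_attribution_truth(n, PLANTED, noise_sd=noise_sd, seed=seed, baseline=40)
    return covs, b1


class TestScreen:
    def test_duplicated_covariate_drops_exactly_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=50)
        res = collinearity_screen(df)
        assert sorted(res.retained + [d[0] for d in res.dropped]) == ["a", "b", "c"]
        assert len(res.retained) == 2 and "c" in res.retained

    def test_independent_covariates_all_retained(self):
        covs, _ = planted_data(0)
        res = collinearity_screen(covs[ALL_COVS])
        assert res.retained == ALL_COVS
        assert not res.flagged_pairs

    def test_orthogonal_design_unit_vifs(self):
        rows = list(itertools.product([-1.0, 1.0], repeat=3)) * 4
        df = pd.DataFrame(rows, columns=["a", "b", "c"])
        res = collinearity_screen(df)
        np.testing.assert_allclose(res.vif.to_numpy(), 1.0, atol=1e-10)

    def test_constant_covariate_dropped_with_reason(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "k": 5.0, "b": rng.normal(size=30)})
        res = collinearity_screen(df)
        assert ("k", "constant") in res.dropped

    def test_idempotent(self):
        covs, _ = planted_data(1)
        df = covs[ALL_COVS].copy()
        df["mat_copy"] = df["mat"] * 1.0
        first = collinearity_screen(df)
        second = collinearity_screen(df[first.retained])
        assert second.retained == first.retained
        assert not second.dropped


class TestFit:
    def test_planted_monotone_signal_high_r2(self):
        covs, _ = planted_data(2, noise_sd=0.0)
        b1 = 2.0 * covs["mat"].to_numpy()
        res = fit_attribution_model(covs[ALL_COVS], b1, seed=0)
        assert res.metrics["r2"] > 0.95

    def test_permuted_target_near_zero_r2(self, rng):
        covs, b1 = planted_data(3)
        res = fit_attribution_model(covs[ALL_COVS], rng.permutation(b1), seed=0)
        assert res.metrics["r2"] <= 0.1

    def test_fixed_seed_reproducible_metrics(self):
        covs, b1 = planted_data(4)
        w = np.full(len(b1), 2.0)
        a = fit_attribution_model(covs[ALL_COVS], b1, weights=w, seed=5)
        b = fit_attribution_model(covs[ALL_COVS], b1, weights=w, seed=5)
        assert a.metrics == b.metrics

    def test_small_n_rejected(self):
        covs, b1 = planted_data(5, n=30)
        with pytest.raises(ValueError, match=">= 25"):
            fit_attribution_model(covs[ALL_COVS].head(20), b1[:20])

    def test_duplicating_a_cell_equals_doubling_its_weight(self):
        covs, b1 = planted_data(6, n=40)
        x = covs[ALL_COVS]
        params = {**DEFAULT_XGB_PARAMS, "subsample": 1.0, "colsample_bytree": 1.0,
                  "n_estimators": 50, "random_state": 0}
        import xgboost as xgb

        w = np.ones(len(b1))
        w[3] = 2.0
        m_w = xgb.XGBRegressor(**params)
        m_w.fit(x, b1, sample_weight=w)
        x_dup = pd.concat([x, x.iloc[[3]]], ignore_index=True)
        y_dup = np.append(b1, b1[3])
        m_d = xgb.XGBRegressor(**params)
        m_d.fit(x_dup, y_dup)
        np.testing.assert_allclose(m_w.predict(x), m_d.predict(x), atol=1e-5)

    def test_bayesian_tuner_improves_or_matches_default(self):
        covs, b1 = planted_data(7, n=80)
        x = covs[ALL_COVS].to_numpy()
        best, trace = tune_hyperparameters(x, b1, None, budget=6, seed=0, method="bayes")
        assert len(trace) == 6
        assert set(best) == set(trace.columns) - {"cv_rmse"}
        best2, _ = tune_hyperparameters(x, b1, None, budget=6, seed=0, method="bayes")
        assert best == best2  # seeded determinism

    def test_random_search_fallback(self):
        covs, b1 = planted_data(8, n=60)
        _, trace = tune_hyperparameters(
            covs[ALL_COVS].to_numpy(), b1, None, budget=3, seed=1, method="random"
        )
        assert len(trace) == 3


class TestSpatialLOO:
    def test_buffer_zero_equals_plain_loo(self):
        covs, b1 = planted_data(9, n=30)
        x = covs[ALL_COVS]
        coords = covs[["x_km", "y_km"]].to_numpy()
        params = {"n_estimators": 50}
        res = spatial_buffered_loo(x, b1, coords, buffer=0.0, params=params, seed=0)
        # oracle: train on all-but-i explicitly
        import xgboost as xgb

        preds = np.empty(len(b1))
        for i in range(len(b1)):
            keep = np.arange(len(b1)) != i
            m = xgb.XGBRegressor(**{**DEFAULT_XGB_PARAMS, **params, "random_state": 0})
            m.fit(x.to_numpy()[keep], b1[keep])
            preds[i] = m.predict(x.to_numpy()[i : i + 1])[0]
        np.testing.assert_allclose(res["predictions"], preds, atol=1e-6)

    def test_buffer_larger_than_domain_errors(self):
        covs, b1 = planted_data(10, n=30)
        with pytest.raises(ValueError, match="no training data"):
            spatial_buffered_loo(
                covs[ALL_COVS], b1, covs[["x_km", "y_km"]].to_numpy(), buffer=1e9
            )

    def test_smooth_confounder_r2_nonincreasing_with_buffer(self, rng):
        # target driven by a spatially smooth field: nearby cells leak
        n = 48
        coords = rng.uniform(0, 100, (n, 2))
        smooth = np.sin(coords[:, 0] / 18.0) + np.cos(coords[:, 1] / 23.0)
        x = pd.DataFrame(
            {
                "f1": smooth + rng.normal(0, 0.05, n),
                "f2": rng.normal(size=n),
                "f3": rng.normal(size=n),
            }
        )
        y = 10.0 * smooth + rng.normal(0, 0.5, n)
        r2 = [
            spatial_buffered_loo(
                x, y, coords, buffer=b, params={"n_estimators": 80}, seed=0
            )["r2"]
            for b in (0.0, 15.0, 40.0)
        ]
        assert r2[0] >= r2[1] >= r2[2]


class TestShap:
    def test_additivity_per_sample(self):
        covs, b1 = planted_data(11)
        res = fit_attribution_model(covs[ALL_COVS], b1, seed=0)
        sh = res.shap()
        recon = sh.shap_values.sum(axis=1).to_numpy() + sh.base_value
        # float32 tree arithmetic: tolerance at single-precision scale
        np.testing.assert_allclose(recon, sh.predictions, atol=1e-3)

    def test_planted_driver_ranked_first(self):
        covs, _ = planted_data(12, noise_sd=0.0)
        b1 = 3.0 * covs["wind"].to_numpy() + 0.01 * covs["mat"].to_numpy()
        res = fit_attribution_model(covs[ALL_COVS], b1, seed=0)
        assert res.shap().ranking[0] == "wind"

    def test_constant_covariate_zero_shap(self):
        covs, b1 = planted_data(13, n=60)
        x = covs[ALL_COVS].copy()
        x["slope"] = 11.0
        res = fit_attribution_model(x, b1, seed=0)
        assert res.shap().shap_values["slope"].abs().max() < 1e-8

    def test_feature_mismatch_rejected(self):
        covs, b1 = planted_data(14, n=40)
        res = fit_attribution_model(covs[ALL_COVS], b1, seed=0)
        bad = covs[ALL_COVS].rename(columns={"mat": "temperature"})
        with pytest.raises(ValueError, match="mismatch"):
            shap_summary(res.model_, bad)

    def test_dependence_table_columns(self):
        covs, b1 = planted_data(15, n=60)
        res = fit_attribution_model(covs[ALL_COVS], b1, seed=0)
        dep = res.shap().dependence_table("mat", color_by="map")
        assert list(dep.columns) == ["value", "shap", "color"]
        assert len(dep) == 60


class TestBiomeModels:
    @staticmethod
    def _biome_setup(seed=16, n=160):
        covs, _ = planted_data(seed, n=n)
        biome = np.where(covs["x_km"] < 500, "tropical", "boreal")
        strad = np.zeros(n, dtype=bool)
        strad[:5] = True
        b1 = np.where(
            biome == "tropical",
            2.0 * covs["mat"].to_numpy(),
            1.5 * covs["agriculture"].to_numpy(),
        )
        return covs, b1, biome, strad

    def test_straddling_cells_excluded_everywhere(self):
        covs, b1, biome, strad = self._biome_setup()
        out = biome_models(covs[ALL_COVS], b1, biome, strad, seed=0)
        total = sum(len(r.features) for r in out.values())
        assert total == len(b1) - strad.sum()

    def test_biome_specific_planted_drivers_recovered(self):
        covs, b1, biome, strad = self._biome_setup()
        out = biome_models(covs[ALL_COVS], b1, biome, strad, seed=0)
        assert out["tropical"].shap().ranking[0] == "mat"
        assert out["boreal"].shap().ranking[0] == "agriculture"

    def test_small_biome_skipped(self):
        covs, b1, biome, strad = self._biome_setup()
        biome = biome.copy()
        biome[:10] = "temperate"  # only 5 non-straddling temperate cells
        out = biome_models(covs[ALL_COVS], b1, biome, strad, seed=0)
        assert "temperate" not in out

    def test_single_biome_equals_global_model(self):
        covs, b1, *_ = self._biome_setup()
        one = np.full(len(b1), "tropical")
        out = biome_models(covs[ALL_COVS], b1, one, None, seed=3)
        ref = fit_attribution_model(covs[ALL_COVS], b1, seed=3)
        assert out["tropical"].metrics == ref.metrics


class TestDriverModelFrontEnd:
    def test_from_dataframe_and_summary(self):
        covs, b1 = planted_data(17, n=60)
        df = covs.copy()
        df["beta1"] = b1
        df["inv_cv"] = 1.0
        model = DriverModel.from_dataframe(
            df.drop(columns=["biome"], errors="ignore"),
            target_col="beta1",
            feature_cols=ALL_COVS,
            weight_col="inv_cv",
            coord_cols=("x_km", "y_km"),
        )
        res = model.fit(seed=0)
        text = res.summary()
        assert "mean |SHAP|" in text and "RMSE" in text
        cv = res.spatial_cv([0.0])
        assert np.isfinite(cv["r2"].iloc[0])
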