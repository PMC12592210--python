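"""Self-contained benchmark computations of the package's headline checks.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns measured quantities: the printed carbon-conversion
chain, the biome slope contrast, distance-transform agreement with a brute
force oracle, slope recovery and confidence-interval coverage, Moran
filtering efficacy, end-to-end missing-biomass recovery, and attribution
sanity checks.  The test suite asserts on these numbers and the acceptance
script reports them.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import forestedge as fe
from forestedge import geometry, pipeline
from forestedge.accounting import biomass_to_carbon
from forestedge.simulate import LandscapeTruth, RandomFieldClearings, generate_attribution_truth


def carbon_chain(agb_pg: float = 58.0) -> dict:
    """Aboveground and root-inclusive carbon equivalents of an AGB stock."""
    return {
        "aboveground_c_pg": biomass_to_carbon(agb_pg),
        "total_c_with_roots_pg": biomass_to_carbon(agb_pg, include_roots=True),
    }


def biome_contrast_percent(stronger: float = 53.0, weaker: float = 43.0) -> float:
    """Percent reduction of the weaker biome mean slope relative to the stronger."""
    return (stronger - weaker) / stronger * 100.0


def _brute_force_distance(mask: np.ndarray, resolution: float) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    nonforest = np.argwhere(~mask)
    if nonforest.size == 0:
        out[mask] = np.inf
        return out
    for r, c in np.argwhere(mask):
        d2 = ((nonforest - [r, c]) ** 2).sum(axis=1)
        out[r, c] = np.sqrt(d2.min()) * resolution
    return out


def distance_agreement(seed: int, n_masks: int = 30, shape=(40, 40)) -> dict:
    """Exact per-pixel agreement of the distance transform with brute force."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    exact = 0
    for _ in range(n_masks):
        mask = rng.random(shape) > 0.3
        fast = fe.distance_to_edge(mask, 30.0)
        slow = _brute_force_distance(mask, 30.0)
        if np.allclose(np.nan_to_num(fast, posinf=-1), np.nan_to_num(slow, posinf=-1)):
            exact += 1
    return {"n_masks": n_masks, "agreement_fraction": exact / n_masks}


def _simulated_cell_points(
    seed: int,
    beta1: float,
    noise_sd_white: float,
    noise_sd_spatial: float = 0.0,
    noise_range_spatial: float = 200.0,
    n_points: int = 500,
) -> pd.DataFrame:
    land = fe.generate_forest_mask(
        (128, 128), 30.0, RandomFieldClearings(0.3, 150.0), seed=seed
    )
    truth = LandscapeTruth(
        beta0=80.0,
        beta1=beta1,
        noise_sd_white=noise_sd_white,
        noise_sd_spatial=noise_sd_spatial,
        noise_range_spatial=noise_range_spatial,
        seed=seed + 500_000,
    )
    land, _ = fe.generate_biomass(land, truth)
    dist = fe.distance_to_edge(land.forest_mask(), 30.0)
    return fe.sample_points(land, dist, 128, n_points, seed=seed + 900_000)


def slope_recovery(seed: int, n_cells: int = 200, true_beta1: float = 50.0) -> dict:
    """Bias and 95% CI coverage of the slope over iid-noise cells."""
    base = int(np.random.SeedSequence([seed, 41]).generate_state(1)[0] % 2**20)
    hits, biases = 0, []
    for i in range(n_cells):
        pts = _simulated_cell_points(base + i, beta1=true_beta1, noise_sd_white=20.0)
        est = fe.fit_cell_regression(pts, seed=base + i)
        hits += abs(est.beta1 - true_beta1) <= 1.96 * est.se_beta1
        biases.append(est.beta1 - true_beta1)
    biases = np.asarray(biases)
    return {
        "n_cells": n_cells,
        "mean_bias": float(biases.mean()),
        "bias_se": float(biases.std(ddof=1) / np.sqrt(n_cells)),
        "coverage_percent": 100.0 * hits / n_cells,
    }


def filtering_efficacy(seed: int, n_cells: int = 30) -> dict:
    """Moran's I reduction under planted autocorrelated residuals, and exact
    OLS equivalence of the unfiltered path."""
    import statsmodels.api as sm

    base = int(np.random.SeedSequence([seed, 43]).generate_state(1)[0] % 2**20)
    decreased = 0
    for i in range(n_cells):
        pts = _simulated_cell_points(
            base + i,
            beta1=50.0,
            noise_sd_white=5.0,
            noise_sd_spatial=20.0,
            n_points=300,
        )
        est = fe.fit_cell_regression(pts, seed=base + i)
        decreased += est.moran_i_after < est.moran_i_before
    pts = _simulated_cell_points(base, beta1=50.0, noise_sd_white=20.0)
    res = fe.EdgeEffectModel.from_points(pts).fit(spatial_filter=False)
    x = sm.add_constant(np.log10(pts["distance_m"].to_numpy()))
    ref = sm.OLS(pts["agb_mg_ha"].to_numpy(), x).fit()
    ols_dev = max(
        float(np.abs(res.params - ref.params).max()),
        float(np.abs(res.bse - ref.bse).max()),
    )
    return {
        "n_cells": n_cells,
        "decrease_fraction": decreased / n_cells,
        "ols_equivalence_max_dev": ols_dev,
    }


def _pipeline_missing(config: pipeline.RunConfig) -> float:
    pipeline.stage_sample(config)
    pipeline.stage_fit(config)
    accounts = pipeline.stage_account(config)
    return float(accounts["missing_agb"].sum())


def missing_biomass_recovery(seed: int, n_seeds: int = 10, n_cells: int = 20) -> dict:
    """End-to-end recovery of the planted deficit, and the null check."""
    errors = []
    for rep in range(n_seeds):
        with tempfile.TemporaryDirectory() as tmp:
            cfg = pipeline.RunConfig(
                n_cells=n_cells,
                seed=seed * 1000 + rep,
                out_dir=tmp,
                tuning_budget=0,
            )
            study = pipeline.stage_simulate(cfg)
            true_missing = study.true_missing_biomass()
            est_missing = _pipeline_missing(cfg)
            errors.append(100.0 * (est_missing / true_missing - 1.0))
    with tempfile.TemporaryDirectory() as tmp:
        cfg = pipeline.RunConfig(
            n_cells=8,
            seed=seed,
            out_dir=tmp,
            tuning_budget=0,
            beta1_baseline=0.0,
            mat_effect=0.0,
            agriculture_effect=0.0,
            map_effect=0.0,
            beta1_noise_sd=0.0,
            noise_sd_white=0.5,
            noise_sd_spatial=0.0,
        )
        study = pipeline.stage_simulate(cfg)
        null_missing = _pipeline_missing(cfg)
        actual = float(np.nansum(study.landscape.biomass)) * (
            study.landscape.resolution**2 / 1e4
        )
    return {
        "errors_percent": errors,
        "median_error_percent": float(np.median(errors)),
        "median_abs_error_percent": float(np.median(np.abs(errors))),
        "null_missing_over_actual_percent": 100.0 * null_missing / actual,
    }


def attribution_sanity(seed: int, n_replicates: int = 10) -> dict:
    """SHAP additivity, planted-driver ranking and buffered-LOO consistency."""
    planted = {
        "mat": lambda v: 0.8 * (v - 9.0),
        "agriculture": lambda v: 0.15 * (v - 50.0),
        "map": lambda v: 0.003 * (v - 1850.0),
    }
    cols = ["mat", "map", "wind", "soil_moisture", "elevation", "slope", "agriculture"]
    top_hits = 0
    additivity_dev = 0.0
    base = int(np.random.SeedSequence([seed, 47]).generate_state(1)[0] % 2**20)
    for rep in range(n_replicates):
        covs, b1 = generate_attribution_truth(
            150, planted, noise_sd=3.0, seed=base + rep, baseline=40.0
        )
        res = fe.fit_attribution_model(covs[cols], b1, seed=base + rep)
        sh = res.shap()
        recon = sh.shap_values.sum(axis=1).to_numpy() + sh.base_value
        additivity_dev = max(additivity_dev, float(np.abs(recon - sh.predictions).max()))
        top_hits += sh.ranking[0] == "mat"
    covs, b1 = generate_attribution_truth(
        30, planted, noise_sd=3.0, seed=base, baseline=40.0
    )
    coords = covs[["x_km", "y_km"]].to_numpy()
    params = {"n_estimators": 50}
    buffered = fe.spatial_buffered_loo(
        covs[cols], b1, coords, buffer=0.0, params=params, seed=seed
    )
    import xgboost as xgb

    from forestedge.attribution import DEFAULT_XGB_PARAMS

    plain = np.empty(len(b1))
    xmat = covs[cols].to_numpy()
    for i in range(len(b1)):
        keep = np.arange(len(b1)) != i
        m = xgb.XGBRegressor(**{**DEFAULT_XGB_PARAMS, **params, "random_state": seed})
        m.fit(xmat[keep], b1[keep])
        plain[i] = m.predict(xmat[i : i + 1])[0]
    loo_dev = float(np.abs(buffered["predictions"] - plain).max())
    return {
        "n_replicates": n_replicates,
        "top_driver_rate": top_hits / n_replicates,
        "shap_additivity_max_dev": additivity_dev,
        "loo_buffer0_max_dev": loo_dev,
    }


def filter_rule_fidelity() -> dict:
    """Boundary behaviour of the cell retention rules on constructed cells."""

    def toy(cell_id, n, n_near):
        d = np.full(n, 500.0)
        d[:n_near] = 50.0
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "row": np.arange(n),
                "col": 0,
                "x": 0.0,
                "y": 0.0,
                "distance_m": d,
                "agb_mg_ha": 100.0,
                "cover_pct": 80.0,
            }
        )

    pts = pd.concat(
        [toy(0, 20, 5), toy(1, 500, 14), toy(2, 500, 15)], ignore_index=True
    )
    _, ledger = geometry.filter_cells(pts)
    status = dict(zip(ledger["cell_id"], ledger["retained"]))
    return {
        "exact_20_points_dropped": bool(not status[0]),
        "near_2p8_percent_dropped": bool(not status[1]),
        "near_3_percent_retained": bool(status[2]),
        "all_rules_exact": bool(not status[0] and not status[1] and status[2]),
    }
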