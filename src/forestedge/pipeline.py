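"""End-to-end orchestration of the edge-effect analysis.

Stages: simulate (or ingest) -> sample -> filter -> fit -> trim ->
summarise -> attribute -> account -> report.  Every stochastic step derives
its seed deterministically from the global seed, each stage writes its
outputs under the run directory (so any stage can be re-run from the
checkpoints of the previous one), and the run metadata records the config
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from forestedge import accounting, attribution, geometry, io, regression, simulate
from forestedge.geometry import CellGrid
from forestedge.simulate import ForestLandscape, LandscapeTruth, RandomFieldClearings

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and offending cell ids."""

    def __init__(self, stage: str, message: str, cell_ids=()):
        super().__init__(f"stage {stage!r}: {message}" + (f" (cells {list(cell_ids)})" if len(list(cell_ids)) else ""))
        self.stage = stage
        self.cell_ids = list(cell_ids)


@dataclass
class RunConfig:
    """Reproducible configuration of a full pipeline run."""

    mode: str = "synthetic"  # synthetic | raster
    seed: int = 0
    out_dir: str = "runs/demo"
    # landscape
    n_cells: int = 48
    cell_px: int = 128
    resolution: float = 30.0
    clearing_quantile: float = 0.3
    clearing_range_m: float = 150.0
    forest_threshold: float = 30.0
    # generative biomass law
    beta0: float = 100.0
    beta1_baseline: float = 40.0
    depth_star: float = math.inf
    noise_sd_white: float = 20.0
    noise_sd_spatial: float = 10.0
    noise_range_spatial: float = 150.0
    # planted covariate effects on beta1 (per unit of covariate, centred)
    mat_effect: float = 0.8
    agriculture_effect: float = 0.15
    map_effect: float = 0.003
    beta1_noise_sd: float = 3.0
    # sampling and filters
    n_per_cell: int = 500
    min_points: int = 20
    near_frac: float = 0.03
    near_dist: float = 100.0
    exclude_within: float = 0.0
    # regression
    response: str = "biomass"
    knn: int = 8
    n_permutations: int = 199
    trim_fraction: float = 0.025
    # attribution
    tuning_budget: int = 10
    tuning_method: str = "bayes"
    buffer_radii_cells: tuple = (0.0, 1.0, 2.0)
    # accounting
    depth_percentile: float = 90.0
    depth_band: float | None = None
    # raster mode inputs
    raster_dir: str | None = None
    biome_stripes: tuple = (0.3, 0.65)  # x-fraction boundaries of the 3 biomes

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["buffer_radii_cells"] = list(self.buffer_radii_cells)
        d["biome_stripes"] = list(self.biome_stripes)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("buffer_radii_cells", "biome_stripes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str, extra: int = 0) -> int:
        """Deterministic per-stage integer seed below 2^31."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


BIOME_NAMES = ("tropical", "temperate", "boreal")


@dataclass
class SyntheticStudy:
    """A fully generated multi-cell study with its ground truth."""

    landscape: ForestLandscape
    distance: np.ndarray
    covariates: pd.DataFrame  # cell_id, covariates, x_km, y_km, biome, straddling
    beta1_true: np.ndarray
    cell_truths: list[LandscapeTruth] = field(default_factory=list)
    grid: CellGrid | None = None

    def true_missing_biomass(self, percentile: float = 90.0) -> float:
        """Planted missing biomass (Mg): the population-level deficit.

        Missing biomass is defined operationally: the depth of edge
        influence is the mean distance of the pixels whose biomass reaches
        the ``percentile``-th percentile, edge pixels are those nearer the
        edge than it, and the counterfactual assigns them the interior
        density at that depth.  Here the operational definition is applied
        with full knowledge of the generative truth: over *all* forest
        pixels of each cell (no sampling), with the replacement density
        taken from the true biomass law rather than a fitted one.  The
        sample-based pipeline estimates exactly this quantity.
        """
        total = 0.0
        res = self.landscape.resolution
        area_ha = res**2 / 1e4
        for cid, truth in enumerate(self.cell_truths):
            rs, cs = self.grid.cell_slices(cid)
            d = self.distance[rs, cs]
            obs = self.landscape.biomass[rs, cs]
            forest = np.isfinite(d)
            if not forest.any():
                continue
            df, yf = d[forest], obs[forest]
            qual = yf >= np.percentile(yf, percentile)
            d_star = float(df[qual].mean())
            edge = df < d_star
            if edge.any():
                deficit = truth.noiseless_agb(d_star) - yf[edge]
                total += float(deficit.sum()) * area_ha
        return total


def effect_spec(config: RunConfig) -> dict:
    """Planted covariate response functions (linear, centred at mid-range)."""
    return {
        "mat": lambda v, a=config.mat_effect: a * (v - 9.0),
        "agriculture": lambda v, a=config.agriculture_effect: a * (v - 50.0),
        "map": lambda v, a=config.map_effect: a * (v - 1850.0),
    }


def _biome_of_cell(config: RunConfig, grid: CellGrid) -> tuple[np.ndarray, np.ndarray]:
    """Biome label per cell (by cell-centre stripe) and straddling flag."""
    total_w = grid.n_cell_cols * config.cell_px * config.resolution
    bounds = [b * total_w for b in config.biome_stripes]

    def stripe(x: float) -> int:
        return int(np.searchsorted(bounds, x, side="right"))

    labels, straddle = [], []
    for cid in range(config.n_cells):
        _, c = divmod(cid, grid.n_cell_cols)
        x0 = c * config.cell_px * config.resolution
        x1 = x0 + config.cell_px * config.resolution
        s0, s1 = stripe(x0), stripe(x1 - 1e-9)
        labels.append(BIOME_NAMES[min(s0, 2)])
        straddle.append(s0 != s1)
    return np.array(labels), np.array(straddle)


def simulate_study(config: RunConfig) -> SyntheticStudy:
    """Generate the multi-cell synthetic study defined by ``config``.

    Cells are laid out row-major on a near-square grid; each cell is an
    independent fragmented landscape whose true slope is driven by the
    cell's environmental covariates through :func:`effect_spec`.  Distances
    are computed within cells (cells are separate landscapes, not
    neighbours).
    """
    n = config.n_cells
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    shape = (nrows * config.cell_px, ncols * config.cell_px)
    grid = CellGrid(shape, config.cell_px)
    covs, beta1_true = simulate.generate_attribution_truth(
        n_cells=max(n, 30),
        effect_spec=effect_spec(config),
        noise_sd=config.beta1_noise_sd,
        seed=config.stage_seed("attribution_truth"),
        baseline=config.beta1_baseline,
    )
    covs, beta1_true = covs.iloc[:n].copy(), beta1_true[:n]
    cover = np.zeros(shape)
    biomass = np.full(shape, np.nan)
    distance = np.full(shape, np.nan)
    cell_truths = []
    child_seeds = np.random.SeedSequence(config.stage_seed("landscape")).spawn(n)
    for cid in range(n):
        rs, cs = grid.cell_slices(cid)
        sub_seed = int(child_seeds[cid].generate_state(1)[0] % (2**31))
        land = simulate.generate_forest_mask(
            (config.cell_px, config.cell_px),
            resolution=config.resolution,
            clearing_spec=RandomFieldClearings(
                quantile=config.clearing_quantile,
                correlation_range=config.clearing_range_m,
            ),
            seed=sub_seed,
            threshold=config.forest_threshold,
        )
        truth = LandscapeTruth(
            beta0=config.beta0,
            beta1=float(beta1_true[cid]),
            depth_star=config.depth_star,
            noise_sd_white=config.noise_sd_white,
            noise_sd_spatial=config.noise_sd_spatial,
            noise_range_spatial=config.noise_range_spatial,
            seed=sub_seed,
        )
        land, _ = simulate.generate_biomass(land, truth, config.forest_threshold)
        mask = land.forest_mask(config.forest_threshold)
        dist = geometry.distance_to_edge(mask, config.resolution)
        cover[rs, cs] = land.cover
        biomass[rs, cs] = land.biomass
        distance[rs, cs] = dist
        cell_truths.append(truth)
    # cell-centre coordinates (km) and biome stripes for attribution
    rr, cc = np.divmod(np.arange(n), grid.n_cell_cols)
    cell_w_km = config.cell_px * config.resolution / 1e3
    covs["x_km"] = (cc + 0.5) * cell_w_km
    covs["y_km"] = (nrows - rr - 0.5) * cell_w_km
    biome, straddle = _biome_of_cell(config, grid)
    covs["biome"] = biome
    covs["straddling"] = straddle
    landscape = ForestLandscape(
        cover=cover, biomass=biomass, resolution=config.resolution
    )
    return SyntheticStudy(
        landscape=landscape,
        distance=distance,
        covariates=covs,
        beta1_true=beta1_true,
        cell_truths=cell_truths,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# stages (each reads the previous stage's artifacts from the run directory)
# ---------------------------------------------------------------------------


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: RunConfig) -> SyntheticStudy:
    out = _out(config)
    study = simulate_study(config)
    io.write_landscape(out / "landscape", study.landscape, distance=study.distance)
    study.covariates.to_csv(out / "covariates.csv", index=False)
    pd.DataFrame(
        {"cell_id": study.covariates["cell_id"], "beta1_true": study.beta1_true}
    ).to_csv(out / "truth_beta1.csv", index=False)
    truths = pd.DataFrame([dataclasses.asdict(t) for t in study.cell_truths])
    truths.insert(0, "cell_id", np.arange(len(study.cell_truths)))
    truths.to_csv(out / "truth_cells.csv", index=False)
    return study


def _load_landscape(config: RunConfig):
    land_dir = Path(config.raster_dir or Path(config.out_dir) / "landscape")
    landscape, distance, _ = io.read_landscape(land_dir)
    if distance is None:
        mask = landscape.forest_mask(config.forest_threshold)
        distance = geometry.distance_to_edge(mask, landscape.resolution)
    return landscape, distance


def stage_sample(config: RunConfig) -> pd.DataFrame:
    out = _out(config)
    landscape, distance = _load_landscape(config)
    points = geometry.sample_points(
        landscape,
        distance,
        cell_px=config.cell_px,
        n_per_cell=config.n_per_cell,
        seed=config.stage_seed("sample"),
        threshold=config.forest_threshold,
    )
    points.to_csv(out / "points.csv", index=False)
    retained, ledger = geometry.filter_cells(
        points,
        min_points=config.min_points,
        near_frac=config.near_frac,
        near_dist=config.near_dist,
        exclude_within=config.exclude_within,
    )
    retained.to_csv(out / "points_retained.csv", index=False)
    ledger.to_csv(out / "cells.csv", index=False)
    return retained


def stage_fit(config: RunConfig) -> pd.DataFrame:
    out = _out(config)
    points = pd.read_csv(out / "points_retained.csv")
    rows, failed = [], []
    for cid, pts in points.groupby("cell_id"):
        try:
            est = regression.fit_cell_regression(
                pts,
                response=config.response,
                cell_id=cid,
                knn=config.knn,
                n_permutations=config.n_permutations,
                seed=config.stage_seed("fit", int(cid)),
            )
            rho, rho_p = regression.spearman_edge_effect(pts, config.response)
            row = est.as_dict()
            row["spearman_rho"], row["spearman_p"] = rho, rho_p
            row["classification"] = regression.classify_effect(est.beta1)
            rows.append(row)
        except ValueError as exc:
            logger.warning("cell %s fit failed: %s", cid, exc)
            failed.append(cid)
    if not rows:
        raise PipelineError("fit", "no cell produced an estimate", failed)
    estimates = pd.DataFrame(rows)
    estimates.to_csv(out / "estimates.csv", index=False)
    trimmed, removed = regression.trim_outliers(estimates, config.trim_fraction)
    trimmed.to_csv(out / "estimates_trimmed.csv", index=False)
    removed.to_csv(out / "estimates_removed.csv", index=False)
    covs = pd.read_csv(out / "covariates.csv")
    merged = trimmed.merge(covs[["cell_id", "biome"]], on="cell_id", how="left")
    summary = pd.concat(
        [
            regression.weighted_summary(merged),
            regression.weighted_summary(merged, by="biome"),
        ],
        ignore_index=True,
    )
    summary.to_csv(out / "summary.csv", index=False)
    return estimates


def stage_attribute(config: RunConfig) -> dict:
    out = _out(config)
    estimates = pd.read_csv(out / "estimates_trimmed.csv")
    covs = pd.read_csv(out / "covariates.csv")
    df = estimates.merge(covs, on="cell_id", how="inner")
    df = df[np.isfinite(df["cv"]) & (df["cv"] > 0)].reset_index(drop=True)
    feature_cols = [c for c in simulate.DEFAULT_COVARIATE_RANGES if c in df.columns]
    result: dict = {"n_cells": int(len(df))}
    if len(df) < 25:
        logger.warning(
            "attribution skipped: %d cells (< 25 needed for the 80/20 split)",
            len(df),
        )
        result["skipped"] = "fewer than 25 usable cells"
        (out / "attribution_metrics.json").write_text(
            json.dumps(result, indent=2, sort_keys=True)
        )
        pd.DataFrame().to_csv(out / "shap_values.csv", index=False)
        pd.DataFrame().to_csv(out / "shap_importance.csv", index=False)
        return result
    screen = attribution.collinearity_screen(df[feature_cols])
    model = attribution.DriverModel(
        df[screen.retained],
        df["beta1"].to_numpy(),
        weights=1.0 / df["cv"].to_numpy(),
        coords=df[["x_km", "y_km"]].to_numpy(),
    )
    res = model.fit(
        tuning_budget=config.tuning_budget,
        seed=config.stage_seed("attribute"),
        method=config.tuning_method,
    )
    shap_res = res.shap()
    shap_df = shap_res.shap_values.copy()
    shap_df.insert(0, "cell_id", df["cell_id"].to_numpy())
    shap_df.to_csv(out / "shap_values.csv", index=False)
    shap_res.mean_abs_shap.rename("mean_abs_shap").to_csv(out / "shap_importance.csv")
    cell_w_km = config.cell_px * config.resolution / 1e3
    radii_km = [r * cell_w_km for r in config.buffer_radii_cells]
    spatial_cv = res.spatial_cv(radii_km)
    spatial_cv.to_csv(out / "spatial_cv.csv", index=False)
    result.update(
        {
            "metrics": res.metrics,
            "retained_features": screen.retained,
            "dropped_features": screen.dropped,
            "tuned_params": {
                k: v for k, v in res.params.items() if k in attribution.TUNING_SPACE
            },
            "base_value": shap_res.base_value,
            "mean_abs_shap": shap_res.mean_abs_shap.to_dict(),
            "spatial_cv": spatial_cv.to_dict(orient="records"),
        }
    )
    (out / "attribution_metrics.json").write_text(
        json.dumps(result, indent=2, sort_keys=True, default=float)
    )
    return result


def stage_account(config: RunConfig) -> pd.DataFrame:
    out = _out(config)
    landscape, distance = _load_landscape(config)
    grid = CellGrid(landscape.shape, config.cell_px)
    points = pd.read_csv(out / "points_retained.csv")
    estimates = pd.read_csv(out / "estimates_trimmed.csv")
    accounts, flagged = [], []
    for _, row in estimates.iterrows():
        cid = row["cell_id"]
        pts = points[points["cell_id"] == cid]
        est = regression.EdgeEffectEstimate(
            cell_id=cid,
            beta0=row["beta0"],
            beta1=row["beta1"],
            se_beta1=row["se_beta1"],
            cv=row["cv"],
            n_points=int(row["n_points"]),
            n_eigenvectors_used=int(row["n_eigenvectors_used"]),
            moran_i_before=row["moran_i_before"],
            moran_i_after=row["moran_i_after"],
            moran_p_before=row["moran_p_before"],
            moran_p_after=row["moran_p_after"],
        )
        try:
            d_star, mode = accounting.depth_of_edge_influence(
                pts["distance_m"].to_numpy(),
                pts["agb_mg_ha"].to_numpy(),
                percentile=config.depth_percentile,
                band=config.depth_band,
            )
            rs, cs = grid.cell_slices(int(cid))
            acc = accounting.counterfactual_cell(
                landscape.biomass[rs, cs],
                distance[rs, cs],
                landscape.resolution,
                est,
                d_star,
                depth_mode=mode,
            )
            accounts.append(acc)
        except ValueError as exc:
            logger.warning("cell %s accounting failed: %s", cid, exc)
            flagged.append(cid)
    if not accounts:
        raise PipelineError("account", "no cell produced an account", flagged)
    acc_df = pd.DataFrame([a.as_dict() for a in accounts])
    acc_df.to_csv(out / "accounts.csv", index=False)
    covs = pd.read_csv(out / "covariates.csv")
    biome = dict(zip(covs["cell_id"], covs["biome"]))
    summary = accounting.aggregate_missing(accounts, biome)
    summary.to_csv(out / "account_summary.csv", index=False)
    missing_pg = float(summary.loc[summary["group"] == "global", "missing_pg"].iloc[0])
    carbon = {
        "missing_agb_pg": missing_pg,
        "aboveground_carbon_pg": accounting.biomass_to_carbon(max(missing_pg, 0.0)),
        "total_carbon_with_roots_pg": accounting.biomass_to_carbon(
            max(missing_pg, 0.0), include_roots=True
        ),
    }
    (out / "carbon.json").write_text(json.dumps(carbon, indent=2, sort_keys=True))
    return acc_df


def stage_report(config: RunConfig) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = _out(config)
    report = out / "report"
    report.mkdir(exist_ok=True)
    summary = pd.read_csv(out / "summary.csv")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(summary["group"], summary["mean_beta1"], yerr=summary["sd_beta1"], color="seagreen")
    ax.set_ylabel(r"$\Delta$AGB/$\Delta$D (Mg ha$^{-1}$ per log$_{10}$ m)")
    ax.set_title("Inverse-CV weighted edge effect")
    fig.tight_layout()
    fig.savefig(report / "edge_effects.png", dpi=120)
    plt.close(fig)
    imp_path = out / "shap_importance.csv"
    if imp_path.exists() and imp_path.stat().st_size > 1:
        try:
            imp = pd.read_csv(imp_path, index_col=0)
            if len(imp):
                fig, ax = plt.subplots(figsize=(5, 3.2))
                ax.barh(imp.index[::-1], imp.iloc[::-1, 0], color="steelblue")
                ax.set_xlabel("mean |SHAP| (Mg ha$^{-1}$ per log$_{10}$ m)")
                ax.set_title("Driver importance")
                fig.tight_layout()
                fig.savefig(report / "shap_importance.png", dpi=120)
                plt.close(fig)
        except pd.errors.EmptyDataError:
            pass
    acc = pd.read_csv(out / "account_summary.csv")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    err = np.vstack(
        [
            (acc["missing_pg"] - acc["missing_lower_pg"]).clip(lower=0),
            (acc["missing_upper_pg"] - acc["missing_pg"]).clip(lower=0),
        ]
    )
    ax.bar(acc["group"], acc["missing_pg"], yerr=err, color="sienna")
    ax.set_ylabel("missing AGB (Pg)")
    ax.set_title("Missing biomass by group")
    fig.tight_layout()
    fig.savefig(report / "missing_biomass.png", dpi=120)
    plt.close(fig)
    return report


STAGES = {
    "simulate": stage_simulate,
    "sample": stage_sample,
    "fit": stage_fit,
    "attribute": stage_attribute,
    "account": stage_account,
    "report": stage_report,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the artifact directory."""
    out = _out(config)
    timing = {}
    for name, fn in STAGES.items():
        t0 = time.perf_counter()
        try:
            fn(config)
        except PipelineError:
            raise
        except Exception as exc:  # surface the failing stage
            raise PipelineError(name, str(exc)) from exc
        timing[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timing[name])
    meta = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "timing_s": timing,
        "package_version": __import__("forestedge").__version__,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return out
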