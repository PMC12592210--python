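"""Synthetic fragmented-landscape generator with known ground truth.

Produces percent-tree-cover grids with clearings, biomass-density grids that
follow a log-linear distance-to-edge law with an optional interior plateau,
and per-cell environmental covariate tables with planted effects on the
edge-effect slope.  Every generator is deterministic under its seed, so each
downstream stage (distance transform, per-cell regression, driver
attribution, carbon accounting) has a parameter-recovery test surface.

The generative biomass law for a forest pixel at distance ``D`` (m) from the
nearest non-forest pixel is::

    AGB(D) = beta0 + beta1 * log10(min(D, depth_star)) + eta(x, y) + eps

where ``eta`` is a spatially correlated Gaussian field (white noise smoothed
with a Gaussian kernel whose sigma equals the correlation range) and ``eps``
is white noise.  ``beta1`` is the edge-effect slope dAGB/dD in Mg ha^-1 per
log10 metre; ``depth_star`` is the depth beyond which biomass plateaus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Default percent-cover threshold separating forest from non-forest pixels.
FOREST_COVER_THRESHOLD = 30.0

#: Covariates the attribution stage knows about, with realistic sampling
#: ranges (uniform draws).  Units: mat degC, map mm yr^-1, wind m s^-1,
#: soil_moisture volumetric fraction, elevation m, slope degrees,
#: agriculture percent of surrounding land under cultivation.
DEFAULT_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "mat": (-10.0, 28.0),
    "map": (200.0, 3500.0),
    "wind": (0.5, 10.0),
    "soil_moisture": (0.05, 0.45),
    "elevation": (0.0, 3000.0),
    "slope": (0.0, 30.0),
    "agriculture": (0.0, 100.0),
}


@dataclass(frozen=True)
class LandscapeTruth:
    """Generative parameters of a synthetic landscape.

    Parameters
    ----------
    beta0 : float
        Biomass intercept at D = 1 m (Mg ha^-1).  Must be >= 0.
    beta1 : float
        True edge-effect slope (Mg ha^-1 per log10 m).  Positive values mean
        lower biomass near edges.
    depth_star : float
        Plateau distance (m): beyond it biomass no longer responds to edge
        distance.  ``inf`` disables the plateau.  Must be > 0.
    noise_sd_white : float
        Standard deviation of per-pixel white noise (Mg ha^-1).
    noise_sd_spatial : float
        Standard deviation of the spatially correlated noise field
        (Mg ha^-1).
    noise_range_spatial : float
        Correlation range of the spatial noise field (m); the Gaussian
        smoothing kernel sigma.
    seed : int
        Seed for all noise draws; identical seed + parameters regenerate the
        landscape bit-identically.
    """

    beta0: float = 100.0
    beta1: float = 50.0
    depth_star: float = math.inf
    noise_sd_white: float = 20.0
    noise_sd_spatial: float = 10.0
    noise_range_spatial: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta0 < 0:
            raise ValueError(f"beta0 must be >= 0, got {self.beta0}")
        if not self.depth_star > 0:
            raise ValueError(f"depth_star must be > 0, got {self.depth_star}")
        if self.noise_sd_white < 0 or self.noise_sd_spatial < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.noise_range_spatial < 0:
            raise ValueError("noise_range_spatial must be >= 0")

    def noiseless_agb(self, distance_m: np.ndarray | float) -> np.ndarray | float:
        """Expected biomass density at distance(s) ``distance_m`` (m)."""
        d_eff = np.minimum(distance_m, self.depth_star)
        return self.beta0 + self.beta1 * np.log10(d_eff)


@dataclass
class ForestLandscape:
    """Co-registered percent-cover and biomass grids on a planar grid.

    ``cover`` holds percent tree cover in [0, 100]; ``biomass`` holds AGB
    density (Mg ha^-1) and is NaN on non-forest pixels (and ``None`` before
    :func:`generate_biomass` has run).  ``resolution`` is metres per pixel
    side and ``origin`` the planar (x, y) of the grid's lower-left corner.
    """

    cover: np.ndarray
    biomass: np.ndarray | None = None
    resolution: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=float)
        if self.cover.ndim != 2:
            raise ValueError("cover grid must be 2-D")
        if self.cover.min() < 0 or self.cover.max() > 100:
            raise ValueError("cover values must lie in [0, 100]")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.biomass is not None:
            self.biomass = np.asarray(self.biomass, dtype=float)
            if self.biomass.shape != self.cover.shape:
                raise ValueError("cover and biomass grids must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cover.shape

    def forest_mask(self, threshold: float = FOREST_COVER_THRESHOLD) -> np.ndarray:
        from forestedge.geometry import classify_forest

        return classify_forest(self.cover, threshold)

    def forest_fraction(self, threshold: float = FOREST_COVER_THRESHOLD) -> float:
        return float(self.forest_mask(threshold).mean())


@dataclass(frozen=True)
class GeometricClearings:
    """Rectangular clearings given as (row, col, height, width) pixel boxes."""

    boxes: Sequence[tuple[int, int, int, int]] = field(default_factory=tuple)


@dataclass(frozen=True)
class RandomFieldClearings:
    """Clearings as a correlated Gaussian random field thresholded at a quantile.

    ``quantile`` is the target non-forest fraction; pixels where the field
    falls below its ``quantile``-quantile are cleared.  ``correlation_range``
    (m) sets the spatial grain of the clearings.
    """

    quantile: float = 0.3
    correlation_range: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantile < 1.0:
            raise ValueError("quantile must lie in [0, 1)")


ClearingSpec = GeometricClearings | RandomFieldClearings


def correlated_field(
    shape: tuple[int, int],
    correlation_range: float,
    resolution: float,
    rng: np.random.Generator,
    sd: float = 1.0,
) -> np.ndarray:
    """Sample a zero-mean Gaussian field with Gaussian-kernel correlation.

    White noise is smoothed with a Gaussian kernel of sigma =
    ``correlation_range / resolution`` pixels and rescaled to sample
    standard deviation ``sd``.  A range of zero returns plain white noise.
    """
    white = rng.standard_normal(shape)
    if correlation_range <= 0 or sd == 0:
        return white * sd
    sigma_px = correlation_range / resolution
    smooth = ndimage.gaussian_filter(white, sigma=sigma_px, mode="reflect")
    s = smooth.std()
    if s == 0:  # degenerate tiny grid
        return np.zeros(shape)
    return smooth * (sd / s)


def generate_forest_mask(
    shape: tuple[int, int],
    resolution: float = 30.0,
    clearing_spec: ClearingSpec | None = None,
    seed: int = 0,
    threshold: float = FOREST_COVER_THRESHOLD,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ForestLandscape:
    """Generate the percent-cover layer of a fragmented landscape.

    Forest pixels draw cover uniformly in [threshold, 100], cleared pixels in
    [0, threshold).  Only the binary mask matters downstream; the continuous
    cover values exist for the tree-cover response variant.

    Raises
    ------
    ValueError
        If the grid is smaller than 3x3 or the clearings leave no forest.
    """
    nrow, ncol = int(shape[0]), int(shape[1])
    if nrow < 3 or ncol < 3:
        raise ValueError(f"degenerate grid shape {shape}; need at least 3x3")
    # keyed stream: a mask and a biomass layer built from the same integer
    # seed must not share white-noise draws
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    cleared = np.zeros((nrow, ncol), dtype=bool)
    if clearing_spec is None:
        clearing_spec = GeometricClearings(())
    if isinstance(clearing_spec, GeometricClearings):
        for (r0, c0, h, w) in clearing_spec.boxes:
            cleared[max(r0, 0) : r0 + h, max(c0, 0) : c0 + w] = True
    elif isinstance(clearing_spec, RandomFieldClearings):
        fld = correlated_field(
            (nrow, ncol), clearing_spec.correlation_range, resolution, rng
        )
        if clearing_spec.quantile > 0:
            cut = np.quantile(fld, clearing_spec.quantile)
            cleared = fld < cut
    else:
        raise TypeError(f"unsupported clearing_spec {type(clearing_spec)!r}")
    if cleared.all():
        raise ValueError("clearing specification removes every pixel: no forest")
    cover = np.empty((nrow, ncol))
    u = rng.random((nrow, ncol))
    cover[~cleared] = threshold + u[~cleared] * (100.0 - threshold)
    cover[cleared] = u[cleared] * threshold * 0.999  # strictly below threshold
    return ForestLandscape(cover=cover, resolution=resolution, origin=origin)


def generate_biomass(
    landscape: ForestLandscape,
    truth: LandscapeTruth,
    threshold: float = FOREST_COVER_THRESHOLD,
) -> tuple[ForestLandscape, int]:
    """Fill the biomass layer of ``landscape`` according to ``truth``.

    Noiseless pixel value is ``beta0 + beta1 * log10(min(D, depth_star))``;
    spatially correlated and white noise are added on top, and negative
    values are clipped at zero.  Returns the landscape (new object, cover
    shared) and the count of clipped pixels; clipping is logged, never
    silent.

    Raises
    ------
    ValueError
        If the mask is all forest while ``beta1 != 0`` and ``depth_star`` is
        infinite (distance to edge undefined, no plateau to fall back on).
    """
    from forestedge.geometry import distance_to_edge

    mask = landscape.forest_mask(threshold)
    if mask.all() and truth.beta1 != 0 and math.isinf(truth.depth_star):
        raise ValueError(
            "all-forest mask with beta1 != 0 and infinite depth_star: "
            "distance to edge is undefined"
        )
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 202]))
    biomass = np.full(landscape.shape, np.nan)
    if truth.beta1 == 0:
        noiseless = np.full(landscape.shape, truth.beta0)
    else:
        dist = distance_to_edge(mask, landscape.resolution)
        noiseless = truth.noiseless_agb(np.where(mask, dist, 1.0))
    noise = np.zeros(landscape.shape)
    if truth.noise_sd_spatial > 0:
        noise += correlated_field(
            landscape.shape,
            truth.noise_range_spatial,
            landscape.resolution,
            rng,
            sd=truth.noise_sd_spatial,
        )
    if truth.noise_sd_white > 0:
        noise += rng.normal(0.0, truth.noise_sd_white, landscape.shape)
    values = noiseless + noise
    clipped = int(((values < 0) & mask).sum())
    if clipped:
        logger.warning("clipped %d negative biomass pixels at 0", clipped)
    biomass[mask] = np.clip(values[mask], 0.0, None)
    out = ForestLandscape(
        cover=landscape.cover,
        biomass=biomass,
        resolution=landscape.resolution,
        origin=landscape.origin,
    )
    return out, clipped


def generate_attribution_truth(
    n_cells: int,
    effect_spec: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 0.0,
    covariate_ranges: Mapping[str, tuple[float, float]] | None = None,
    extent_km: float = 1000.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-cell covariates and a planted true edge-effect slope.

    The true slope per cell is ``baseline + sum_j f_j(covariate_j) + eps``
    with ``eps ~ N(0, noise_sd^2)``.  The returned table carries the
    covariates plus planar cell coordinates ``x_km``/``y_km`` (uniform over a
    square of side ``extent_km``) for spatially buffered evaluation.

    Raises
    ------
    KeyError
        If ``effect_spec`` names a covariate that is not generated.
    """
    if n_cells < 30:
        raise ValueError(f"n_cells must be >= 30, got {n_cells}")
    ranges = dict(covariate_ranges or DEFAULT_COVARIATE_RANGES)
    for name in effect_spec:
        if name not in ranges:
            raise KeyError(f"unknown covariate {name!r} in effect_spec")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    table = {}
    for name, (lo, hi) in ranges.items():
        table[name] = rng.uniform(lo, hi, n_cells)
    df = pd.DataFrame(table)
    df.insert(0, "cell_id", np.arange(n_cells))
    df["x_km"] = rng.uniform(0.0, extent_km, n_cells)
    df["y_km"] = rng.uniform(0.0, extent_km, n_cells)
    beta1_true = np.full(n_cells, float(baseline))
    for name, f in effect_spec.items():
        beta1_true = beta1_true + np.asarray(f(df[name].to_numpy()), dtype=float)
    if noise_sd > 0:
        beta1_true = beta1_true + rng.normal(0.0, noise_sd, n_cells)
    return df, beta1_true
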