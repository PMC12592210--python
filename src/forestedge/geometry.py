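"""From rasters to the analysis point set.

Forest classification at a percent-cover threshold, Euclidean
distance-to-edge on the binary mask, gridded random point sampling, and the
cell-level retention filters (minimum point count, minimum near-edge
fraction) that guarantee edge effects are detectable in every retained cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from forestedge.simulate import FOREST_COVER_THRESHOLD, ForestLandscape

logger = logging.getLogger(__name__)

POINT_COLUMNS = [
    "cell_id",
    "row",
    "col",
    "x",
    "y",
    "distance_m",
    "agb_mg_ha",
    "cover_pct",
]


def classify_forest(
    cover: np.ndarray, threshold: float = FOREST_COVER_THRESHOLD
) -> np.ndarray:
    """Binary forest mask: a pixel is forest iff cover >= threshold.

    The boundary is inclusive: a pixel at exactly the threshold counts as
    forest.  An empty mask is legal; downstream filters handle it.
    """
    cover = np.asarray(cover, dtype=float)
    if cover.min() < 0 or cover.max() > 100:
        raise ValueError("cover values must lie in [0, 100]")
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must lie in (0, 100], got {threshold}")
    return cover >= threshold


def distance_to_edge(
    mask: np.ndarray,
    resolution: float,
    nodata: np.ndarray | None = None,
    nodata_is_nonforest: bool = True,
) -> np.ndarray:
    """Per-pixel Euclidean distance (m) to the nearest non-forest pixel.

    Distances are measured centre-to-centre, so the minimum possible
    distance for a forest pixel is one resolution unit.  Non-forest pixels
    carry NaN.  If the mask is all forest every distance is infinite and the
    caller decides what to do.  ``nodata`` pixels count as non-forest for
    edge purposes by default (``nodata_is_nonforest``); set it to False to
    ignore them instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    eff = mask.copy()
    if nodata is not None and nodata_is_nonforest:
        eff &= ~np.asarray(nodata, dtype=bool)
    out = np.full(mask.shape, np.nan)
    if eff.all():
        out[mask] = np.inf
        return out
    dist_px = ndimage.distance_transform_edt(eff)
    out[mask] = dist_px[mask] * resolution
    return out


@dataclass(frozen=True)
class CellGrid:
    """Tiling of the landscape into square pixel blocks (analysis cells).

    Synthetic-mode cells are configurable pixel blocks; the 100 km real-mode
    analysis cell is just ``cell_px = 100_000 / resolution``.
    """

    shape: tuple[int, int]
    cell_px: int

    def __post_init__(self) -> None:
        if self.cell_px < 1:
            raise ValueError("cell_px must be >= 1")

    @property
    def n_cell_rows(self) -> int:
        return -(-self.shape[0] // self.cell_px)

    @property
    def n_cell_cols(self) -> int:
        return -(-self.shape[1] // self.cell_px)

    def cell_id(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row // self.cell_px) * self.n_cell_cols + (col // self.cell_px)

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cell_rows * self.n_cell_cols)

    def cell_slices(self, cell_id: int) -> tuple[slice, slice]:
        r, c = divmod(int(cell_id), self.n_cell_cols)
        return (
            slice(r * self.cell_px, min((r + 1) * self.cell_px, self.shape[0])),
            slice(c * self.cell_px, min((c + 1) * self.cell_px, self.shape[1])),
        )


def sample_points(
    landscape: ForestLandscape,
    distance: np.ndarray,
    cell_px: int = 128,
    n_per_cell: int = 500,
    seed: int = 0,
    threshold: float = FOREST_COVER_THRESHOLD,
    prefilter_forest: bool = True,
) -> pd.DataFrame:
    """Sample up to ``n_per_cell`` random points per grid cell.

    With ``prefilter_forest`` (default) points are drawn uniformly without
    replacement from the cell's forest pixels, capped at the available
    count.  With ``prefilter_forest=False`` points are drawn from all pixels
    of the cell and non-forest draws are then discarded (the
    sample-then-filter variant), which yields fewer forest points per cell.

    Each point carries planar coordinates of its pixel centre, distance to
    edge, biomass density and percent cover.  Cells without forest pixels
    yield zero points.  Reproducible under ``seed`` regardless of cell
    iteration order.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if landscape.biomass is None:
        raise ValueError("landscape has no biomass layer; run generate_biomass")
    grid = CellGrid(landscape.shape, cell_px)
    mask = landscape.forest_mask(threshold)
    nrow = landscape.shape[0]
    res = landscape.resolution
    x0, y0 = landscape.origin
    children = np.random.SeedSequence(seed).spawn(len(grid.cell_ids()))
    frames = []
    for cid, ss in zip(grid.cell_ids(), children):
        rs, cs = grid.cell_slices(cid)
        sub_mask = mask[rs, cs]
        rng = np.random.default_rng(ss)
        if prefilter_forest:
            rr, cc = np.nonzero(sub_mask)
            n_avail = rr.size
            if n_avail == 0:
                continue
            take = min(n_per_cell, n_avail)
            idx = rng.choice(n_avail, size=take, replace=False)
        else:
            n_pix = sub_mask.size
            take = min(n_per_cell, n_pix)
            flat = rng.choice(n_pix, size=take, replace=False)
            rr, cc = np.unravel_index(flat, sub_mask.shape)
            keep = sub_mask[rr, cc]
            rr, cc = rr[keep], cc[keep]
            idx = np.arange(rr.size)
        if idx.size == 0:
            continue
        rows = rr[idx] + rs.start
        cols = cc[idx] + cs.start
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "row": rows,
                    "col": cols,
                    # y axis points north: row 0 is the top of the grid
                    "x": x0 + (cols + 0.5) * res,
                    "y": y0 + (nrow - rows - 0.5) * res,
                    "distance_m": distance[rows, cols],
                    "agb_mg_ha": landscape.biomass[rows, cols],
                    "cover_pct": landscape.cover[rows, cols],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=POINT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[POINT_COLUMNS]


def filter_cells(
    points: pd.DataFrame,
    min_points: int = 20,
    near_frac: float = 0.03,
    near_dist: float = 100.0,
    exclude_within: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cell retention rules; return (retained points, cell ledger).

    A cell is retained iff it has strictly more than ``min_points`` points
    and the fraction of its points within ``near_dist`` of an edge is at
    least ``near_frac`` (exactly 3% is retained: only cells with *less*
    than the threshold fraction are dropped).  When ``exclude_within > 0``,
    points with D <= exclude_within are removed first (the mixed-pixel
    robustness variant).

    The ledger has one row per cell with columns ``cell_id, n_points,
    frac_near, retained, reason``; a dropped cell carries exactly the first
    failing rule (``min_points`` before ``near_fraction``).
    """
    pts = points
    if exclude_within > 0:
        pts = pts[pts["distance_m"] > exclude_within]
    grouped = pts.groupby("cell_id")
    n = grouped.size()
    frac = grouped["distance_m"].apply(lambda d: float((d <= near_dist).mean()))
    ledger = pd.DataFrame(
        {"cell_id": n.index, "n_points": n.to_numpy(), "frac_near": frac.to_numpy()}
    )
    fail_n = ledger["n_points"] <= min_points
    fail_f = ledger["frac_near"] < near_frac
    ledger["retained"] = ~(fail_n | fail_f)
    reason = np.where(fail_n, "min_points", np.where(fail_f, "near_fraction", ""))
    ledger["reason"] = reason
    kept = set(ledger.loc[ledger["retained"], "cell_id"])
    retained = pts[pts["cell_id"].isin(kept)].reset_index(drop=True)
    n_drop = int((~ledger["retained"]).sum())
    if n_drop:
        logger.info("filter_cells dropped %d of %d cells", n_drop, len(ledger))
    return retained, ledger
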