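"""Raster and table IO.

Rasters are written as plain single-band TIFFs (tifffile) with a JSON
sidecar carrying the georeferencing (resolution, origin) and, for synthetic
landscapes, the generative truth parameters.  Tables travel as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import tifffile

from forestedge.simulate import ForestLandscape, LandscapeTruth


def _jsonable(v):
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    return v


def write_landscape(
    directory: str | Path,
    landscape: ForestLandscape,
    truth: LandscapeTruth | None = None,
    distance: np.ndarray | None = None,
) -> Path:
    """Write cover/biomass/distance TIFFs plus the JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "cover.tif", landscape.cover.astype(np.float32))
    if landscape.biomass is not None:
        tifffile.imwrite(
            directory / "biomass.tif", landscape.biomass.astype(np.float32)
        )
    if distance is not None:
        tifffile.imwrite(directory / "distance.tif", distance.astype(np.float32))
    meta = {
        "resolution": landscape.resolution,
        "origin": list(landscape.origin),
        "shape": list(landscape.shape),
    }
    if truth is not None:
        meta["truth"] = {
            k: _jsonable(v) for k, v in dataclasses.asdict(truth).items()
        }
    (directory / "landscape.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return directory


def read_landscape(
    directory: str | Path,
) -> tuple[ForestLandscape, np.ndarray | None, LandscapeTruth | None]:
    """Read back a landscape directory; returns (landscape, distance, truth)."""
    directory = Path(directory)
    meta = json.loads((directory / "landscape.json").read_text())
    cover = tifffile.imread(directory / "cover.tif").astype(float)
    biomass_path = directory / "biomass.tif"
    biomass = tifffile.imread(biomass_path).astype(float) if biomass_path.exists() else None
    dist_path = directory / "distance.tif"
    distance = tifffile.imread(dist_path).astype(float) if dist_path.exists() else None
    landscape = ForestLandscape(
        cover=cover,
        biomass=biomass,
        resolution=meta["resolution"],
        origin=tuple(meta["origin"]),
    )
    truth = None
    if "truth" in meta:
        t = dict(meta["truth"])
        if t.get("depth_star") == "inf":
            t["depth_star"] = math.inf
        truth = LandscapeTruth(**t)
    return landscape, distance, truth
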