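"""Shared fixtures: small synthetic landscapes generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import forestedge as fe
from forestedge.simulate import LandscapeTruth, RandomFieldClearings


def make_cell(
    seed: int,
    beta0: float = 80.0,
    beta1: float = 50.0,
    depth_star: float = np.inf,
    noise_sd_white: float = 20.0,
    noise_sd_spatial: float = 0.0,
    noise_range_spatial: float = 150.0,
    shape: tuple[int, int] = (128, 128),
    resolution: float = 30.0,
    quantile: float = 0.3,
    correlation_range: float = 150.0,
    n_points: int = 500,
) -> pd.DataFrame:
    """One fragmented cell's sampled point table with known truth."""
    land = fe.generate_forest_mask(
        shape,
        resolution,
        RandomFieldClearings(quantile, correlation_range),
        seed=seed,
    )
    truth = LandscapeTruth(
        beta0=beta0,
        beta1=beta1,
        depth_star=depth_star,
        noise_sd_white=noise_sd_white,
        noise_sd_spatial=noise_sd_spatial,
        noise_range_spatial=noise_range_spatial,
        seed=seed + 10_000,
    )
    land, _ = fe.generate_biomass(land, truth)
    dist = fe.distance_to_edge(land.forest_mask(), resolution)
    return fe.sample_points(land, dist, shape[0], n_points, seed=seed + 20_000)


@pytest.fixture(scope="session")
def noisy_cell_points() -> pd.DataFrame:
    return make_cell(seed=42)


@pytest.fixture(scope="session")
def noiseless_cell_points() -> pd.DataFrame:
    return make_cell(seed=7, noise_sd_white=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
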