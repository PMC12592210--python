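"""Spatially filtered per-cell regression: eigenvector construction, exact
OLS equivalence, recovery, trimming, weighting, classification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import forestedge as fe
from forestedge.regression import (
    NEGATIVE_EDGE_EFFECT,
    NEGLIGIBLE,
    POSITIVE_EDGE_EFFECT,
    EdgeEffectModel,
    classify_effect,
    spearman_edge_effect,
    trim_outliers,
    weighted_summary,
)
from forestedge.spatial import knn_graph, moran_eigenvectors, morans_i

from conftest import make_cell


@pytest.fixture(scope="module")
def basis():
    coords = np.random.default_rng(0).random((60, 2)) * 1000
    w = knn_graph(coords, 8)
    evecs, ivals = moran_eigenvectors(coords, w=w)
    return coords, w, evecs, ivals


class TestMoranEigenvectors:
    def test_centred_and_orthogonal(self, basis):
        _, _, evecs, _ = basis
        np.testing.assert_allclose(evecs.sum(axis=0), 0, atol=1e-8)
        gram = evecs.T @ evecs
        np.testing.assert_allclose(gram, np.eye(evecs.shape[1]), atol=1e-8)

    def test_moran_i_nonincreasing_and_recomputable(self, basis):
        _, w, evecs, ivals = basis
        assert (np.diff(ivals) <= 1e-10).all()
        recomputed = [morans_i(evecs[:, j], w) for j in range(evecs.shape[1])]
        np.testing.assert_allclose(recomputed, ivals, atol=1e-8)

    def test_at_most_n_minus_one_vectors(self, basis):
        coords, _, evecs, _ = basis
        assert evecs.shape[1] <= coords.shape[0] - 1

    def test_duplicate_coordinates_rejected(self):
        coords = np.tile([[1.0, 2.0], [3.0, 4.0]], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            knn_graph(coords, 4)


class TestEdgeEffectFit:
    def test_noiseless_exact_recovery_zero_vectors(self):
        pts = make_cell(seed=7, beta0=80.0, beta1=40.0, noise_sd_white=0.0)
        res = EdgeEffectModel.from_points(pts).fit(seed=0)
        assert res.beta0 == pytest.approx(80.0, abs=1e-6)
        assert res.beta1 == pytest.approx(40.0, abs=1e-6)
        assert res.n_eigenvectors_used == 0

    def test_zero_eigenvector_fit_equals_statsmodels_ols(self, noisy_cell_points):
        pts = noisy_cell_points
        res = EdgeEffectModel.from_points(pts).fit(spatial_filter=False)
        x = sm.add_constant(np.log10(pts["distance_m"].to_numpy()))
        ref = sm.OLS(pts["agb_mg_ha"].to_numpy(), x).fit()
        np.testing.assert_allclose(res.params, ref.params, rtol=1e-9)
        np.testing.assert_allclose(res.bse, ref.bse, rtol=1e-9)

    def test_perfect_collinearity_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            EdgeEffectModel([1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 10.0, 10.0]).fit(
                spatial_filter=False
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            EdgeEffectModel([1.0, 2.0], [10.0, 20.0]).fit(spatial_filter=False)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError, match="finite and > 0"):
            EdgeEffectModel([1.0, 2.0, 3.0], [0.0, 30.0, 60.0])

    def test_filtering_reduces_planted_autocorrelation(self):
        pts = make_cell(
            seed=11,
            noise_sd_white=5.0,
            noise_sd_spatial=20.0,
            noise_range_spatial=200.0,
            n_points=300,
        )
        res = EdgeEffectModel.from_points(pts).fit(seed=1)
        assert res.n_eigenvectors_used > 0
        assert res.moran_i_after < res.moran_i_before

    def test_cover_response_variant(self, noisy_cell_points):
        est = fe.fit_cell_regression(noisy_cell_points, response="cover", seed=0)
        assert est.response == "cover"
        assert np.isfinite(est.beta1)

    def test_summary_renders(self, noisy_cell_points):
        res = EdgeEffectModel.from_points(noisy_cell_points).fit(seed=0)
        text = res.summary()
        assert "beta1" in text and "Moran" in text


class TestSpearman:
    def test_noiseless_monotone_is_one(self):
        pts = make_cell(seed=3, noise_sd_white=0.0)
        rho, _ = spearman_edge_effect(pts)
        assert rho == pytest.approx(1.0)

    def test_null_slope_mean_rho_near_zero(self):
        rhos = [
            spearman_edge_effect(
                make_cell(seed=s, beta1=0.0, noise_sd_white=10.0, n_points=200)
            )[0]
            for s in range(20)
        ]
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * max(se, 1e-3)

    def test_sign_agrees_with_slope_under_strong_effect(self):
        for s in range(10):
            pts = make_cell(seed=100 + s, beta1=50.0, noise_sd_white=10.0, n_points=200)
            est = fe.fit_cell_regression(pts, seed=s)
            rho, _ = spearman_edge_effect(pts)
            assert np.sign(rho) == np.sign(est.beta1)

    def test_constant_biomass_flagged(self):
        pts = pd.DataFrame(
            {"agb_mg_ha": [5.0] * 10, "distance_m": np.arange(1, 11) * 30.0}
        )
        rho, p = spearman_edge_effect(pts)
        assert np.isnan(rho) and np.isnan(p)


def _estimates(beta1_values, cv=0.1) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(beta1_values)),
            "beta1": np.asarray(beta1_values, dtype=float),
            "cv": cv if np.ndim(cv) else np.full(len(beta1_values), cv),
        }
    )


class TestTrim:
    def test_1000_estimates_keep_950(self, rng):
        est = _estimates(rng.normal(50, 10, 1000))
        kept, removed = trim_outliers(est)
        assert len(kept) == 950 and len(removed) == 50

    def test_extremes_always_removed(self, rng):
        est = _estimates(rng.normal(0, 1, 200))
        kept, removed = trim_outliers(est)
        assert est["beta1"].min() in removed["beta1"].values
        assert est["beta1"].max() in removed["beta1"].values

    def test_ties_removed_by_index_order(self):
        est = _estimates(np.full(100, 7.0))
        kept, removed = trim_outliers(est)
        assert len(removed) == 4  # floor(2.5) per side
        assert list(removed["cell_id"][:2]) == [0, 1]

    def test_trim_then_summary_order_invariant(self, rng):
        est = _estimates(rng.normal(40, 15, 300), cv=rng.uniform(0.05, 0.5, 300))
        shuffled = est.sample(frac=1, random_state=1).reset_index(drop=True)
        a = weighted_summary(trim_outliers(est)[0])
        b = weighted_summary(trim_outliers(shuffled)[0])
        assert a["mean_beta1"].iloc[0] == pytest.approx(b["mean_beta1"].iloc[0])
        assert a["sd_beta1"].iloc[0] == pytest.approx(b["sd_beta1"].iloc[0])


class TestWeightedSummary:
    def test_closed_form_two_cells(self):
        est = _estimates([40.0, 60.0], cv=np.array([0.1, 0.2]))
        out = weighted_summary(est)
        assert out["mean_beta1"].iloc[0] == pytest.approx(700 / 15)

    def test_equal_weights_reduce_to_arithmetic_mean(self, rng):
        b = rng.normal(50, 5, 40)
        out = weighted_summary(_estimates(b, cv=0.2))
        assert out["mean_beta1"].iloc[0] == pytest.approx(b.mean())

    def test_single_estimate(self):
        out = weighted_summary(_estimates([42.0]))
        assert out["mean_beta1"].iloc[0] == 42.0
        assert out["sd_beta1"].iloc[0] == 0.0

    def test_undefined_cv_excluded(self):
        est = _estimates([40.0, 60.0, 80.0], cv=np.array([0.1, np.nan, 0.1]))
        out = weighted_summary(est)
        assert out["n_cells"].iloc[0] == 2
        assert out["n_excluded"].iloc[0] == 1
        assert out["mean_beta1"].iloc[0] == pytest.approx(60.0)

    def test_grouped_output(self):
        est = _estimates([40.0, 60.0])
        est["biome"] = ["tropical", "boreal"]
        out = weighted_summary(est, by="biome")
        assert set(out["group"]) == {"tropical", "boreal"}


class TestClassify:
    @pytest.mark.parametrize(
        "beta1,label",
        [
            (0.05, NEGLIGIBLE),
            (53.0, NEGATIVE_EDGE_EFFECT),
            (-0.5, POSITIVE_EDGE_EFFECT),
            (0.1, NEGLIGIBLE),
            (-0.1, NEGLIGIBLE),
        ],
    )
    def test_examples(self, beta1, label):
        assert classify_effect(beta1) == label

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_labels_partition_the_line(self, beta1):
        label = classify_effect(beta1)
        expected = (
            NEGATIVE_EDGE_EFFECT
            if beta1 > 0.1
            else POSITIVE_EDGE_EFFECT
            if beta1 < -0.1
            else NEGLIGIBLE
        )
        assert label == expected
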