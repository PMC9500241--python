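import numpy as np
import pytest

from terrattrib import GridSpec, SyntheticTruth, generate_landscape
from terrattrib.synthetic import (TERRAIN_LAYERS, gaussian_field,
                                  generate_fvc_series)


def lag1(field: np.ndarray) -> float:
    return float(np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1])


class TestGaussianField:
    def test_deterministic_for_fixed_seed(self):
        g = GridSpec(32, 32)
        a = gaussian_field(g, 4.0, seed=5).values
        b = gaussian_field(g, 4.0, seed=5).values
        np.testing.assert_array_equal(a, b)

    def test_standardised(self):
        f = gaussian_field(GridSpec(64, 64), 8.0, seed=1).values
        assert abs(f.mean()) < 1e-12 and abs(f.std() - 1.0) < 1e-12

    def test_white_noise_limit(self):
        f = gaussian_field(GridSpec(64, 64), 1e-3, seed=3).values
        assert abs(lag1(f)) < 0.1

    def test_correlated_at_stated_scale(self):
        # mean lag-1 autocorrelation over 20 seeds at L=8 cells is 0.984
        # (min 0.978); the spec-level bound 0.5 is far below it
        f = gaussian_field(GridSpec(64, 64), 8.0, seed=9).values
        assert lag1(f) > 0.5

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            gaussian_field(GridSpec(8, 8), 0.0, seed=0)


class TestGenerateLandscape:
    def test_deterministic_and_physical_ranges(self, bundle64):
        b2 = generate_landscape(GridSpec(64, 64), SyntheticTruth(
            seed=7, terrain_share=0.5, interaction_share=0.5, noise_sd=5.0))
        np.testing.assert_array_equal(bundle64.lambda_true.values,
                                      b2.lambda_true.values)
        L = bundle64.layers
        assert np.all(L["wtd"].values >= 0) and np.all(L["hand"].values >= 0)
        assert np.all((L["vrm"].values >= 0) & (L["vrm"].values <= 1))
        for name in ("wetland_fraction", "tree_cover", "nontree_cover",
                     "burned_fraction", "sand_top", "clay_top"):
            v = L[name].values
            assert np.all((v >= 0) & (v <= 1)), name
        assert np.all(L["sand_top"].values + L["clay_top"].values <= 1.0 + 1e-9)
        pft = L["pft_class"].values
        assert np.array_equal(pft, np.round(pft))
        assert np.all(bundle64.lambda_true.values >= 1.0)

    def test_all_expected_layers_present(self, bundle64):
        for name in TERRAIN_LAYERS:
            assert name in bundle64.layers
        assert "precip_01" in bundle64.layers and "rad_12" in bundle64.layers

    def test_zero_terrain_share_is_terrain_independent(self):
        # with no terrain term, the lambda field must be byte-identical even
        # though all terrain layers still exist and vary
        t = SyntheticTruth(seed=3, terrain_share=0.0)
        b = generate_landscape(GridSpec(48, 48), t)
        for k in ("terrain_direct", "terrain_clim", "terrain_veg"):
            assert np.all(b.terms[k] == 0.0)
        assert t.realized_terrain_share == 0.0

    def test_variance_decomposition_matches_requested_share(self):
        t = SyntheticTruth(seed=11, terrain_share=0.5, noise_sd=5.0)
        generate_landscape(GridSpec(128, 128), t)
        assert abs(t.realized_terrain_share - 0.5) <= 0.05

    @pytest.mark.parametrize("share", [0.25, 0.75])
    def test_realized_share_tracks_request(self, share):
        t = SyntheticTruth(seed=2, terrain_share=share)
        generate_landscape(GridSpec(96, 96), t)
        assert abs(t.realized_terrain_share - share) <= 0.05

    def test_terms_reconstruct_lambda(self, bundle64):
        total = sum(bundle64.terms.values()) + bundle64.truth.baseline_days
        np.testing.assert_allclose(np.maximum(total, 1.0),
                                   bundle64.lambda_true.values, atol=1e-10)

    def test_terrain_terms_follow_physical_signs(self, bundle64):
        # deeper water tables must associate with faster decay (smaller
        # terrain contribution), topographic convergence with slower decay
        from scipy.stats import spearmanr
        t = (bundle64.terms["terrain_direct"] + bundle64.terms["terrain_clim"]
             + bundle64.terms["terrain_veg"]).ravel()
        assert spearmanr(t, bundle64.layers["wtd"].values.ravel())[0] < 0
        assert spearmanr(t, bundle64.layers["vrm"].values.ravel())[0] > 0

    def test_nodata_fraction_masks_all_layers(self):
        g = GridSpec(32, 32, nodata_fraction=0.2)
        b = generate_landscape(g, SyntheticTruth(seed=1))
        mask = ~np.isfinite(b.lambda_true.values)
        assert 0.1 < mask.mean() < 0.3
        for layer in b.layers.values():
            assert np.array_equal(~layer.mask, mask)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruth(terrain_share=1.2)
        with pytest.raises(ValueError):
            SyntheticTruth(noise_sd=-1.0)


class TestFvcSeries:
    def test_noiseless_endpoints_and_midpoint(self):
        v = generate_fvc_series(60.0, v0=0.8, v_min=0.2, n_days=400,
                                noise_sd=0.0)
        assert v[0] == pytest.approx(0.8)
        assert v[-1] == pytest.approx(0.2, abs=1e-3)      # asymptote
        assert v[60] == pytest.approx(0.2 + 0.6 * np.exp(-1), abs=1e-12)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            generate_fvc_series(60.0, v0=0.2, v_min=0.5)
        with pytest.raises(ValueError):
            generate_fvc_series(-3.0)

    def test_noise_reproducible(self):
        a = generate_fvc_series(60.0, noise_sd=0.02, seed=4)
        b = generate_fvc_series(60.0, noise_sd=0.02, seed=4)
        np.testing.assert_array_equal(a, b)
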