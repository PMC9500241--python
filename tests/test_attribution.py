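import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from terrattrib import (GridSpec, SyntheticTruth, generate_landscape,
                        group_attribution, interaction_values,
                        normalize_importance)
from terrattrib.attribution import (GroupedAttribution, binned_importance,
                                    interaction_values_native)
from terrattrib.model import TrainedModel

from _shapley_oracle import interaction_matrix


def tiny_model(n_features=4, depth=2, n_trees=3, seed=0, n=400):
    """A minimal booster plus training data on named features."""
    rng = np.random.default_rng(seed)
    cols = [f"x{i}" for i in range(n_features)]
    X = rng.random((n, n_features))
    y = X[:, 0] + 2.0 * X[:, 1] * X[:, min(2, n_features - 1)] \
        + 0.1 * rng.random(n)
    dtrain = xgb.DMatrix(X, label=y, feature_names=cols)
    booster = xgb.train({"objective": "reg:squarederror", "max_depth": depth,
                         "eta": 0.5, "nthread": 1, "seed": 0},
                        dtrain, n_trees)
    model = TrainedModel(booster=booster, columns=cols,
                         spec={c: 0 for c in cols}, base_value=float(y.mean()),
                         hyperparams={}, seed=0, train_index=np.arange(n))
    return model, X


class TestInteractionValues:
    def test_additivity_identity_per_cell(self, model64, table64):
        im = interaction_values(model64, table64.data.head(200))
        total = im.phi.sum(axis=(1, 2))
        np.testing.assert_allclose(total, im.predictions - im.base_values,
                                   rtol=1e-10, atol=1e-8)

    def test_agrees_with_booster_native_treeshap(self, model64, table64):
        sub = table64.data.head(50)
        ours = interaction_values(model64, sub)
        native = interaction_values_native(model64, sub)
        # the booster computes in float32; agreement is at that resolution
        scale = np.abs(native.phi).max()
        assert np.abs(ours.phi - native.phi).max() < 1e-4 * max(scale, 1.0)

    @pytest.mark.parametrize("depth,n_trees", [(1, 3), (2, 3), (2, 1)])
    def test_matches_exhaustive_shapley_enumeration(self, depth, n_trees):
        model, X = tiny_model(depth=depth, n_trees=n_trees)
        im = interaction_values(model, X[:12])
        for k in range(12):
            oracle = interaction_matrix(model.booster, X[k], model.columns)
            np.testing.assert_allclose(im.phi[k], oracle, atol=1e-8)

    def test_binary_features_single_tree_full_coalition_enumeration(self):
        model, X = tiny_model(n_features=3, depth=2, n_trees=1, seed=3)
        Xb = (X[:8] > 0.5).astype(float)  # binary feature values
        im = interaction_values(model, Xb)
        for k in range(8):
            oracle = interaction_matrix(model.booster, Xb[k], model.columns)
            np.testing.assert_allclose(im.phi[k], oracle, atol=1e-8)

    def test_unused_feature_has_zero_row_and_column(self):
        rng = np.random.default_rng(1)
        cols = ["a", "b", "dead"]
        X = rng.random((300, 3))
        y = 3.0 * X[:, 0] - X[:, 1]
        booster = xgb.train({"objective": "reg:squarederror", "max_depth": 2,
                             "eta": 0.5, "nthread": 1},
                            xgb.DMatrix(X, label=y, feature_names=cols), 10)
        model = TrainedModel(booster, cols, {c: 0 for c in cols},
                             float(y.mean()), {}, 0, np.arange(300))
        im = interaction_values(model, X[:20])
        dead = cols.index("dead")
        assert np.abs(im.phi[:, dead, :]).max() < 1e-12
        assert np.abs(im.phi[:, :, dead]).max() < 1e-12

    def test_column_mismatch_rejected(self, model64):
        with pytest.raises((KeyError, ValueError)):
            interaction_values(model64, pd.DataFrame({"wtd": [1.0]}))


class TestGroupAttribution:
    def test_eq1_additivity_on_landscape(self, model64, table64):
        im = interaction_values(model64, table64.data.head(300))
        ga = group_attribution(im, table64.groups)
        assert ga.additivity_error().max() < 1e-6

    def test_single_group_collapse(self):
        model, X = tiny_model()
        im = interaction_values(model, X[:10])
        ga = group_attribution(im, {c: "terrain" for c in model.columns})
        comp = ga.components
        np.testing.assert_allclose(comp["terrain_direct"],
                                   im.predictions - im.base_values,
                                   rtol=1e-10, atol=1e-10)
        for other in ("terrain_clim", "terrain_veg", "clim_direct",
                      "clim_veg", "veg_direct"):
            assert np.all(comp[other] == 0.0)

    def test_two_predictor_decomposition(self):
        # two features in different groups: prediction - base splits into
        # the two direct terms plus one cross term
        model, X = tiny_model(n_features=2)
        im = interaction_values(model, X[:20])
        ga = group_attribution(im, {"x0": "terrain", "x1": "climate"})
        total = (ga.components["terrain_direct"] + ga.components["clim_direct"]
                 + ga.components["terrain_clim"])
        np.testing.assert_allclose(total, im.predictions - im.base_values,
                                   rtol=1e-10, atol=1e-10)

    def test_model_without_terrain_columns_attributes_none(self):
        model, X = tiny_model()
        im = interaction_values(model, X[:10])
        ga = group_attribution(im, {c: "climate" for c in model.columns})
        assert np.abs(ga.components[["terrain_direct", "terrain_clim",
                                     "terrain_veg"]].to_numpy()).max() == 0.0

    def test_non_partition_rejected(self, model64, table64):
        im = interaction_values(model64, table64.data.head(5))
        with pytest.raises(ValueError):
            group_attribution(im, {"wtd": "terrain"})


class TestNormalizeImportance:
    def _grouped(self, rows):
        comp = pd.DataFrame(rows, columns=list(
            ("terrain_direct", "terrain_clim", "terrain_veg",
             "clim_direct", "clim_veg", "veg_direct")))
        n = len(comp)
        return GroupedAttribution(comp, np.zeros(n), np.zeros(n))

    def test_worked_example(self):
        ni = normalize_importance(self._grouped(
            [[0.2, -0.1, 0.1, 0.4, -0.1, 0.1]]))
        assert ni.terrain_total[0] == pytest.approx(0.4)

    def test_all_zero_is_nodata(self):
        ni = normalize_importance(self._grouped([[0.0] * 6]))
        assert np.isnan(ni.terrain_total[0])

    def test_group_totals_sum_to_one(self, model64, table64):
        im = interaction_values(model64, table64.data.head(100))
        ni = normalize_importance(group_attribution(im, table64.groups))
        # cross terms are shared between two groups, so the three totals
        # overcount by exactly the cross-term mass; the six shares sum to 1
        shares = ni.table[[c for c in ni.table.columns
                           if c.endswith("_share")]].to_numpy()
        np.testing.assert_allclose(shares.sum(axis=1), 1.0, rtol=1e-9)
        assert np.all((ni.terrain_total >= 0) & (ni.terrain_total <= 1))


@pytest.fixture(scope="module")
def imp64(model64, table64):
    im = interaction_values(model64, table64.data.head(500))
    return (normalize_importance(group_attribution(im, table64.groups)),
            table64.data.head(500))


class TestBinnedImportance:

    def test_single_bin_equals_domain_mean(self, imp64):
        imp, cells = imp64
        b = binned_importance(imp, cells["vrm"].to_numpy(),
                              np.array([-np.inf, np.inf]))
        assert b.table["mean_terrain_total"][0] == pytest.approx(
            float(np.nanmean(imp.terrain_total)))
        assert b.table["cumulative_share"].iloc[-1] == pytest.approx(1.0)

    def test_constant_conditioner_single_occupied_bin(self, imp64):
        imp, cells = imp64
        b = binned_importance(imp, np.full(len(cells), 0.5),
                              np.array([0.0, 0.4, 0.6, 1.0]))
        counts = b.table["count"].to_numpy()
        assert counts[1] == len(cells) and counts[0] == counts[2] == 0
        assert np.isnan(b.table["mean_terrain_total"][0])

    def test_decreasing_edges_rejected(self, imp64):
        imp, cells = imp64
        with pytest.raises(ValueError):
            binned_importance(imp, cells["vrm"].to_numpy(),
                              np.array([1.0, 0.5]))

    def test_vrm_gated_terrain_effect_concentrates_above_gate(self):
        # landscape whose generative terrain effect exists only where
        # VRM > 0.5: binned importance must be higher above the gate
        truth = SyntheticTruth(seed=13, terrain_share=0.6, vrm_gate=0.5,
                               noise_sd=3.0)
        bundle = generate_landscape(GridSpec(64, 64), truth)
        from terrattrib import (apply_domain_filters, build_feature_table,
                                fit, split_train)
        table = apply_domain_filters(build_feature_table(bundle))
        train, _ = split_train(table, 0.10, seed=13)
        model = fit(train, table.groups, seed=13)
        sub = table.data.head(1200)
        imp = normalize_importance(group_attribution(
            interaction_values(model, sub), table.groups))
        vrm = sub["vrm"].to_numpy()
        b = binned_importance(imp, vrm, np.array([0.0, 0.5, 1.0]))
        below, above = b.table["mean_terrain_total"]
        assert above > below
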