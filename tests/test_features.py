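import numpy as np
import pandas as pd
import pytest

from terrattrib import (apply_domain_filters, block_aggregate,
                        seasonality_features, shannon_diversity)
from terrattrib.features import FeatureTable
from terrattrib.grids import GridSpec, RasterLayer


def layer(values, categorical=False):
    a = np.asarray(values, dtype=float)
    return RasterLayer(a, GridSpec(*a.shape), categorical=categorical)


class TestBlockAggregate:
    def test_mode_smallest_class_wins_tie(self):
        lay = layer([[1, 1], [2, 3]], categorical=True)
        out = block_aggregate(lay, 2, "mode")
        assert out.values[0, 0] == 1.0
        tie = layer([[2, 2], [1, 1]], categorical=True)
        assert block_aggregate(tie, 2, "mode").values[0, 0] == 1.0

    def test_fraction_true(self):
        lay = layer([[1, 0], [0, 0]])
        assert block_aggregate(lay, 2, "fraction_true").values[0, 0] == 0.25

    def test_mean_ignores_nodata(self):
        lay = layer([[0.1, 0.3], [np.nan, np.nan]])
        assert block_aggregate(lay, 2, "mean").values[0, 0] == pytest.approx(0.2)

    def test_block_below_valid_fraction_is_nodata(self):
        lay = layer([[0.1, np.nan], [np.nan, np.nan]])
        assert np.isnan(block_aggregate(lay, 2, "mean").values[0, 0])

    def test_mean_of_block_means_conserves_fine_mean(self, rng):
        lay = layer(rng.random((16, 16)))
        coarse = block_aggregate(lay, 4, "mean")
        assert coarse.values.mean() == pytest.approx(lay.values.mean(),
                                                     rel=1e-12)

    def test_categorical_method_on_continuous_rejected(self):
        with pytest.raises(ValueError):
            block_aggregate(layer([[1.0, 2.0], [3.0, 4.0]]), 2, "mode")

    def test_coarse_grid_metadata(self):
        lay = layer(np.zeros((8, 8)))
        out = block_aggregate(lay, 2, "mean")
        assert out.grid.shape == (4, 4) and out.grid.cell_size == 2.0


class TestShannonDiversity:
    def test_single_class_is_zero(self):
        assert shannon_diversity(np.array([3, 3, 3])) == 0.0

    def test_uniform_four_classes(self):
        assert shannon_diversity(np.array([1, 2, 3, 4])) == pytest.approx(
            np.log(4.0))

    def test_counts_2_1_1(self):
        h = shannon_diversity(np.array([1, 1, 2, 3]))
        expect = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert h == pytest.approx(expect, abs=1e-10)

    def test_empty_block_is_nodata(self):
        assert np.isnan(shannon_diversity(np.array([np.nan])))


class TestSeasonality:
    def test_constant_months_zero_seasonality(self):
        out = seasonality_features({"precip": np.full(12, 80.0)})
        assert out["precip_seasonality"] == pytest.approx(0.0)
        assert out["precip_mean"] == pytest.approx(80.0)

    def test_precip_cv_convention(self):
        # six months at 100 mm and six dry months: population CV is 1
        months = np.array([100.0] * 6 + [0.0] * 6)
        out = seasonality_features({"precip": months})
        assert out["precip_mean"] == pytest.approx(50.0)
        assert out["precip_seasonality"] == pytest.approx(100.0)
        assert out["precip_wettest"] == 100.0 and out["precip_driest"] == 0.0

    def test_temperature_std_convention(self):
        months = np.array([10.0, 20.0] * 6)
        out = seasonality_features({"temp": months})
        assert out["temp_seasonality"] == pytest.approx(500.0)
        assert out["temp_warmest"] == 20.0 and out["temp_coldest"] == 10.0

    def test_nonfinite_month_rejected(self):
        months = np.full(12, 10.0)
        months[3] = np.nan
        with pytest.raises(ValueError):
            seasonality_features({"rad": months})


def make_table(precip, rse=None):
    n = len(precip)
    df = pd.DataFrame({
        "row": np.arange(n), "col": np.zeros(n, dtype=int),
        "wtd": np.ones(n), "precip_annual": np.asarray(precip, dtype=float),
        "lambda": np.full(n, 60.0),
    })
    return FeatureTable(df, {"wtd": "terrain", "precip_annual": "climate"})


class TestDomainFilters:
    def test_precipitation_boundary_is_strict(self):
        t = make_table([1400.0, 1500.0, 1600.0])
        kept = apply_domain_filters(t).data["precip_annual"].tolist()
        assert kept == [1400.0, 1500.0]   # exactly 1500 retained

    def test_qc_failures_dropped(self):
        t = make_table([1000.0, 1000.0, 1000.0])
        qc = pd.DataFrame({"row": [0, 1, 2], "col": [0, 0, 0],
                           "pass_qc": [True, False, True]})
        kept = apply_domain_filters(t, qc=qc).data["row"].tolist()
        assert kept == [0, 2]

    def test_idempotent(self):
        t = make_table([800.0, 1700.0, 1200.0])
        once = apply_domain_filters(t)
        twice = apply_domain_filters(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestFeatureTableContract:
    def test_untagged_column_rejected(self):
        df = pd.DataFrame({"row": [0], "col": [0], "wtd": [1.0],
                           "mystery": [2.0], "lambda": [60.0]})
        with pytest.raises(ValueError, match="mystery"):
            FeatureTable(df, {"wtd": "terrain"})

    def test_unknown_group_rejected(self):
        df = pd.DataFrame({"row": [0], "col": [0], "wtd": [1.0],
                           "lambda": [60.0]})
        with pytest.raises(ValueError):
            FeatureTable(df, {"wtd": "geology"})

    def test_roundtrip_tsv(self, tmp_path, table64):
        table64.write(tmp_path / "feat.tsv")
        back = FeatureTable.read(tmp_path / "feat.tsv")
        assert back.groups == table64.groups
        assert len(back.data) == len(table64.data)

    def test_groups_partition_and_all_present(self, table64):
        tags = set(table64.groups.values())
        assert tags == {"terrain", "climate", "vegetation"}
        for col in table64.predictor_columns:
            assert col in table64.groups
        for col in ("paw_top", "kfc_deep", "icap_top", "precip_seasonality",
                    "pft_shannon"):
            assert col in table64.predictor_columns
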