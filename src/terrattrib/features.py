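"""Feature-table assembly: aggregation, derived features, domain filters.

Turns a stack of co-registered rasters into a flat per-cell predictor table
in which every column carries exactly one group tag (terrain / climate /
vegetation) alongside the target decay rate.  Continuous layers aggregate by
block mean, categorical layers by block mode (smallest class id wins ties),
wetland masks by the within-block fraction, and plant-functional-type
diversity by Shannon's index.  Monthly climatologies are reduced to
bioclim-style annual means, seasonality and monthly extremes.  The study
domain keeps dryland cells (annual precipitation <= 1500 mm/yr, strict
"larger than" excluded) whose decay-rate fit passed quality control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .capillary import icap_brooks_corey
from .grids import GridSpec, RasterLayer
from .soil import SoilComposition, bubbling_head, pedotransfer
from .synthetic import (CLIMATE_LAYERS, LandscapeBundle, TERRAIN_LAYERS,
                        VEGETATION_LAYERS)

GROUPS = ("terrain", "climate", "vegetation")
PRECIP_CEILING_MM_YR = 1500.0
#: a coarse cell is valid when at least this fraction of fine cells are valid
MIN_VALID_FRACTION = 0.5


@dataclass
class FeatureTable:
    """Per-cell predictors with group tags and the target decay rate."""

    data: pd.DataFrame                 # predictors + "lambda" + "row","col"
    groups: dict[str, str]             # predictor column -> group

    def __post_init__(self) -> None:
        predictors = self.predictor_columns
        untagged = [c for c in predictors if c not in self.groups]
        if untagged:
            raise ValueError(f"untagged predictor columns: {untagged}")
        bad = {c: g for c, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group tags: {bad}")

    @property
    def predictor_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in ("lambda", "row", "col")]

    def matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        return self.data[self.predictor_columns], self.data["lambda"]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False, float_format="%.8g")
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        sidecar.write_text(json.dumps(self.groups, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path, sep="\t")
        groups = json.loads(
            path.with_suffix(path.suffix + ".groups.json").read_text())
        return cls(data, groups)


# ---------------------------------------------------------------------------
# block aggregation
# ---------------------------------------------------------------------------

def _blocks(values: np.ndarray, factor: int) -> np.ndarray:
    """(ny, nx) -> (ny//f, nx//f, f*f); trailing partial blocks are dropped."""
    ny, nx = values.shape
    ny_c, nx_c = ny // factor, nx // factor
    v = values[:ny_c * factor, :nx_c * factor]
    return (v.reshape(ny_c, factor, nx_c, factor)
            .transpose(0, 2, 1, 3).reshape(ny_c, nx_c, factor * factor))


def shannon_diversity(block: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i of the class frequencies."""
    b = np.asarray(block, dtype=float)
    b = b[np.isfinite(b)]
    if b.size == 0:
        return np.nan
    _, counts = np.unique(b, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def block_aggregate(layer: RasterLayer, factor: int, method: str) -> RasterLayer:
    """Aggregate non-overlapping factor x factor blocks to a coarse layer.

    ``mean`` ignores nodata; ``mode`` returns the most frequent class
    (smallest id on ties); ``fraction_true`` the share of nonzero cells;
    ``shannon`` the class diversity.  Blocks whose valid fraction falls below
    :data:`MIN_VALID_FRACTION` become nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if method in ("mode", "shannon") and not layer.categorical:
        raise ValueError(f"{method} aggregation requires a categorical layer")
    if method not in ("mean", "mode", "fraction_true", "shannon"):
        raise ValueError(f"unknown aggregation method {method!r}")

    blocks = _blocks(layer.values, factor)
    valid = np.isfinite(blocks)
    n_valid = valid.sum(axis=-1)
    enough = n_valid >= max(1, int(np.ceil(MIN_VALID_FRACTION * factor * factor)))

    if method == "mean":
        with np.errstate(invalid="ignore"):
            out = np.nansum(np.where(valid, blocks, 0.0), axis=-1) / n_valid
    elif method == "fraction_true":
        out = np.nansum(np.where(valid, blocks != 0, 0.0), axis=-1) / n_valid
    else:
        ny, nx, _ = blocks.shape
        out = np.full((ny, nx), np.nan)
        for iy in range(ny):
            for ix in range(nx):
                b = blocks[iy, ix][valid[iy, ix]]
                if b.size == 0:
                    continue
                if method == "mode":
                    vals, counts = np.unique(b, return_counts=True)
                    out[iy, ix] = vals[np.argmax(counts)]  # first max: smallest id
                else:
                    out[iy, ix] = shannon_diversity(b)
    out = np.where(enough, out, np.nan)
    ny_c, nx_c = out.shape
    coarse = GridSpec(ny_c, nx_c, layer.grid.cell_size * factor,
                      layer.grid.origin)
    return RasterLayer(out, coarse, name=layer.name, units=layer.units,
                       categorical=layer.categorical and method == "mode")


# ---------------------------------------------------------------------------
# derived climate features
# ---------------------------------------------------------------------------

def seasonality_features(monthly: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Bioclim-style reductions of monthly climatologies.

    For each variable in ``monthly`` (arrays stacked month-first, shape
    ``(12, ...)``): the annual mean, a seasonality index — coefficient of
    variation x100 for precipitation and radiation, population standard
    deviation x100 for temperature — and the extreme-month values.
    """
    out: dict[str, np.ndarray] = {}
    for var, stack in monthly.items():
        a = np.asarray(stack, dtype=float)
        if a.shape[0] != 12:
            raise ValueError(f"{var}: expected 12 months first, got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{var}: non-finite monthly values")
        mean = a.mean(axis=0)
        std = a.std(axis=0)  # population std (n), bioclim convention
        if var.startswith("temp"):
            season = 100.0 * std
            out[f"{var}_warmest"] = a.max(axis=0)
            out[f"{var}_coldest"] = a.min(axis=0)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                season = 100.0 * np.where(mean != 0, std / mean, 0.0)
            out[f"{var}_wettest"] = a.max(axis=0)
            out[f"{var}_driest"] = a.min(axis=0)
        out[f"{var}_mean"] = mean
        out[f"{var}_seasonality"] = season
    return out


# ---------------------------------------------------------------------------
# table assembly and domain filters
# ---------------------------------------------------------------------------

def build_feature_table(bundle: LandscapeBundle,
                        lambda_layer: RasterLayer | None = None,
                        aggregation_factor: int = 1,
                        capillary_height_m: float = 1.0) -> FeatureTable:
    """Assemble the grouped predictor table from a landscape bundle.

    Soil texture enters not as raw composition but through the pedotransfer
    pipeline: plant available water, conductivity at field capacity and the
    maximum capillary flux (``icap``) at ``capillary_height_m`` above the
    water table, for top and deep soil.  ``lambda_layer`` defaults to the
    bundle's true field (in production it is the fitted decay rate).
    """
    f = aggregation_factor

    def agg(name: str, method: str = "mean") -> np.ndarray:
        return block_aggregate(bundle.layers[name], f, method).values if f > 1 \
            else bundle.layers[name].values

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}

    for name in ("wtd", "hand", "twi", "vrm", "roughness_magnitude",
                 "roughness_scale"):
        cols[name] = agg(name)
        groups[name] = "terrain"
    cols["wetland_fraction"] = agg("wetland_fraction")
    groups["wetland_fraction"] = "terrain"

    for horizon in ("top", "deep"):
        comp = SoilComposition(
            sand=np.nan_to_num(agg(f"sand_{horizon}"), nan=0.4),
            clay=np.nan_to_num(agg(f"clay_{horizon}"), nan=0.2),
            om=np.nan_to_num(np.clip(agg(f"om_{horizon}"), 0, 1), nan=0.02),
            gravel_vol=np.nan_to_num(agg(f"gravel_{horizon}"), nan=0.1))
        hyd = pedotransfer(comp)
        nodata = ~np.isfinite(agg(f"sand_{horizon}"))
        icap_v = icap_brooks_corey(hyd.ks, bubbling_head(hyd), hyd.b_ret,
                                   height=capillary_height_m)
        for key, arr in (("paw", hyd.paw), ("kfc", hyd.k_fc), ("icap", icap_v)):
            v = np.asarray(arr, dtype=float).copy()
            v[nodata] = np.nan
            cols[f"{key}_{horizon}"] = v
            groups[f"{key}_{horizon}"] = "terrain"

    monthly = {var: np.stack([agg(f"{var}_{m:02d}") for m in range(1, 13)])
               for var in ("precip", "temp", "rad")}
    clim = seasonality_features(
        {k: np.where(np.isfinite(v), v, 0.0) for k, v in monthly.items()})
    clim_nodata = ~np.isfinite(monthly["precip"][0])
    for key, arr in clim.items():
        v = arr.copy()
        v[clim_nodata] = np.nan
        cols[key] = v
        groups[key] = "climate"
    # annual precipitation total (mm/yr) for the domain filter
    precip_annual = np.where(clim_nodata, np.nan, monthly["precip"].sum(axis=0))
    cols["precip_annual"] = precip_annual
    groups["precip_annual"] = "climate"

    for name in ("canopy_height", "tree_cover", "nontree_cover",
                 "burned_fraction"):
        cols[name] = agg(name)
        groups[name] = "vegetation"
    cols["pft_mode"] = agg("pft_class", "mode") if f > 1 \
        else bundle.layers["pft_class"].values
    groups["pft_mode"] = "vegetation"
    if f > 1:
        cols["pft_shannon"] = agg("pft_class", "shannon")
    else:
        cols["pft_shannon"] = np.zeros_like(cols["pft_mode"])
    groups["pft_shannon"] = "vegetation"

    lam_layer = bundle.lambda_true if lambda_layer is None else lambda_layer
    lam = block_aggregate(lam_layer, f, "mean").values if f > 1 \
        else lam_layer.values

    ny, nx = lam.shape
    rows, colsix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    data = {"row": rows.ravel(), "col": colsix.ravel()}
    for k, v in cols.items():
        data[k] = v.ravel()
    data["lambda"] = lam.ravel()
    df = pd.DataFrame(data)
    keep = np.isfinite(df[list(cols)].to_numpy()).all(axis=1) \
        & np.isfinite(df["lambda"])
    return FeatureTable(df.loc[keep].reset_index(drop=True), groups)


def apply_domain_filters(table: FeatureTable,
                         qc: pd.DataFrame | None = None,
                         precip_ceiling: float = PRECIP_CEILING_MM_YR) -> FeatureTable:
    """Restrict to the dryland study domain with trustworthy decay rates.

    Keeps cells with annual precipitation <= ``precip_ceiling`` (strictly
    "larger than" is excluded, so exactly 1500 mm/yr is retained) and, when a
    ``qc`` frame with columns (row, col, pass_qc) is given, cells whose decay
    fit passed quality control.  Idempotent.
    """
    df = table.data
    keep = df["precip_annual"] <= precip_ceiling
    if qc is not None:
        flags = qc.set_index(["row", "col"])["pass_qc"]
        idx = pd.MultiIndex.from_arrays([df["row"], df["col"]])
        keep &= flags.reindex(idx).fillna(False).to_numpy(dtype=bool)
    return FeatureTable(df.loc[keep].reset_index(drop=True), dict(table.groups))
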