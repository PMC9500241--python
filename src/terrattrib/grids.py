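"""Gridded-layer container and raster I/O.

A :class:`RasterLayer` is the interchange unit between pipeline stages: a 2-D
float (or integer-coded categorical) array with an explicit nodata mask and
grid metadata.  Layers are written as single-band float32 TIFF files with a
JSON sidecar carrying the grid geometry and the nodata sentinel (-9999), and
bundles of co-registered layers as NetCDF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid (arbitrary planar units)."""

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not 0.0 <= self.nodata_fraction <= 1.0:
            raise ValueError("nodata_fraction must be in [0, 1]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class RasterLayer:
    """One gridded variable on a :class:`GridSpec`.

    ``values`` is float64; missing cells are ``nan`` internally and -9999 on
    disk.  ``categorical`` marks integer-coded class layers (e.g. plant
    functional type), which restricts the aggregation methods that apply.
    """

    values: np.ndarray
    grid: GridSpec
    name: str = ""
    units: str = ""
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds a valid value."""
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, **kw) -> "RasterLayer":
        out = RasterLayer(values, self.grid, name=self.name, units=self.units,
                          categorical=self.categorical)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def write_tiff(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as single-band float32 TIFF plus a JSON grid sidecar."""
    path = Path(path)
    data = np.where(layer.mask, layer.values, NODATA).astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {
        "name": layer.name,
        "units": layer.units,
        "categorical": layer.categorical,
        "nodata": NODATA,
        "grid": {
            "n_rows": layer.grid.n_rows,
            "n_cols": layer.grid.n_cols,
            "cell_size": layer.grid.cell_size,
            "origin": list(layer.grid.origin),
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tiff(path: str | Path) -> RasterLayer:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    g = meta["grid"]
    grid = GridSpec(g["n_rows"], g["n_cols"], g["cell_size"], tuple(g["origin"]))
    data[data == meta["nodata"]] = np.nan
    return RasterLayer(data, grid, name=meta["name"], units=meta["units"],
                       categorical=meta["categorical"])


def layers_to_dataset(layers: dict[str, RasterLayer]) -> xr.Dataset:
    """Pack co-registered layers into an xarray Dataset (y, x dims)."""
    first = next(iter(layers.values()))
    g = first.grid
    y = g.origin[1] + (np.arange(g.n_rows) + 0.5) * g.cell_size
    x = g.origin[0] + (np.arange(g.n_cols) + 0.5) * g.cell_size
    data = {}
    for name, layer in layers.items():
        if layer.grid != g:
            raise ValueError(f"layer {name!r} is not on the common grid")
        data[name] = xr.DataArray(layer.values, dims=("y", "x"),
                                  coords={"y": y, "x": x},
                                  attrs={"units": layer.units,
                                         "categorical": int(layer.categorical)})
    ds = xr.Dataset(data)
    ds.attrs["cell_size"] = g.cell_size
    return ds


def write_netcdf(layers: dict[str, RasterLayer], path: str | Path) -> None:
    layers_to_dataset(layers).to_netcdf(Path(path), engine="scipy")


def read_netcdf(path: str | Path) -> dict[str, RasterLayer]:
    ds = xr.open_dataset(Path(path), engine="scipy")
    cell = float(ds.attrs.get("cell_size", 1.0))
    out: dict[str, RasterLayer] = {}
    for name, da in ds.data_vars.items():
        grid = GridSpec(da.sizes["y"], da.sizes["x"], cell)
        out[str(name)] = RasterLayer(
            np.asarray(da.values, dtype=float), grid, name=str(name),
            units=str(da.attrs.get("units", "")),
            categorical=bool(da.attrs.get("categorical", 0)))
    return out
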