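"""Synthetic landscape generator with known attribution ground truth.

Emulates the kind of co-registered raster stack the attribution pipeline
consumes in production — spatially autocorrelated terrain, climate and
vegetation predictor fields plus a dry-season vegetation decay-rate field
``lambda_true`` (days) — from a fully known generative model:

    lambda = b0 + f_clim + f_veg + f_terr + f_terr_x_clim + f_terr_x_veg + eps

Every terrain term is monotone in its terrain driver with the physically
expected sign (deeper water table / higher drainage position -> faster
decay; more topographic convergence, wetland presence or water-holding
texture -> slower decay).  The fraction of explainable variance carried by
the terrain terms (``terrain_share``) and the split of that effect between
direct and interaction terms (``interaction_share``) are controllable, and
the realized shares are recorded so recovery of attribution can be scored
against them.

Cross-group confounding ("mountains are wetter") is injected through latent
fields shared between groups with a configurable mixing weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import GridSpec, RasterLayer, write_netcdf, write_tiff
from .soil import SoilComposition, pedotransfer

TERRAIN_LAYERS = (
    "wtd", "hand", "twi", "vrm", "roughness_magnitude", "roughness_scale",
    "wetland_fraction",
    "sand_top", "clay_top", "om_top", "gravel_top",
    "sand_deep", "clay_deep", "om_deep", "gravel_deep",
)
CLIMATE_LAYERS = tuple(f"precip_{m:02d}" for m in range(1, 13)) \
    + tuple(f"temp_{m:02d}" for m in range(1, 13)) \
    + tuple(f"rad_{m:02d}" for m in range(1, 13))
VEGETATION_LAYERS = ("canopy_height", "tree_cover", "nontree_cover",
                     "burned_fraction", "pft_class")

LAMBDA_FLOOR_DAYS = 1.0
N_PFT_CLASSES = 5


@dataclass
class SyntheticTruth:
    """Generative parameters against which attribution recovery is scored."""

    seed: int = 0
    terrain_share: float = 0.5
    interaction_share: float = 0.5
    noise_sd: float = 5.0            # days
    cross_group_mixing: float = 0.3  # weight of shared latents between groups
    baseline_days: float = 60.0      # b0
    explained_sd_days: float = 20.0  # sd of the explainable lambda signal
    correlation_length: float = 8.0  # of latent fields, in cells
    vrm_gate: float | None = None    # terrain effect only where vrm > gate
    effect_functions: dict = field(default_factory=dict)
    realized_terrain_share: float | None = None
    realized_interaction_share: float | None = None
    n_clipped: int | None = None

    def __post_init__(self) -> None:
        for name in ("terrain_share", "interaction_share", "cross_group_mixing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LandscapeBundle:
    """All predictor layers, the true decay-rate field and its generative terms."""

    grid: GridSpec
    layers: dict[str, RasterLayer]
    lambda_true: RasterLayer
    truth: SyntheticTruth
    terms: dict[str, np.ndarray]  # generative terms in days, incl. "noise"

    def group_of(self, name: str) -> str:
        if name in TERRAIN_LAYERS:
            return "terrain"
        if name in CLIMATE_LAYERS:
            return "climate"
        if name in VEGETATION_LAYERS:
            return "vegetation"
        raise KeyError(name)


def gaussian_field(grid: GridSpec, correlation_length: float,
                   seed: int) -> RasterLayer:
    """Zero-mean unit-variance Gaussian random field with Gaussian covariance.

    ``correlation_length`` is the e-folding distance of the squared-exponential
    autocorrelation, in grid units.  Implemented as white noise smoothed by a
    periodic Gaussian kernel (sigma = L/2 cells gives rho(d) = exp(-d^2/L^2)),
    then empirically standardised.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    sigma_cells = correlation_length / grid.cell_size / 2.0
    if sigma_cells > 0.05:
        fieldv = gaussian_filter(noise, sigma_cells, mode="wrap")
    else:
        fieldv = noise
    fieldv = (fieldv - fieldv.mean()) / fieldv.std()
    return RasterLayer(fieldv, grid, name="gaussian_field")


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def generate_fvc_series(lambda_days: float, v0: float = 0.8,
                        v_min: float = 0.2, n_days: int = 120,
                        noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Daily fractional-vegetation-cover decay series.

    v(t) = v_min + (v0 - v_min) * exp(-t / lambda) + eps_t for t = 0..n_days-1.
    """
    if not (0.0 <= v_min < v0 <= 1.0):
        raise ValueError("require 0 <= v_min < v0 <= 1")
    if lambda_days <= 0:
        raise ValueError("lambda_days must be positive")
    t = np.arange(n_days, dtype=float)
    v = v_min + (v0 - v_min) * np.exp(-t / lambda_days)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, n_days)
    return v


def generate_landscape(grid: GridSpec, truth: SyntheticTruth) -> LandscapeBundle:
    """Generate the full predictor stack and the true decay-rate field."""
    ss = np.random.SeedSequence(truth.seed)
    children = iter(ss.generate_state(64))

    def latent() -> np.ndarray:
        return gaussian_field(grid, truth.correlation_length * grid.cell_size,
                              int(next(children))).values

    mix = truth.cross_group_mixing
    w = np.sqrt(max(1.0 - mix ** 2, 0.0))

    def blend(own: np.ndarray, shared: np.ndarray) -> np.ndarray:
        return w * own + mix * shared

    # shared latents inject cross-group covariation
    z_relief = latent()   # mountains: rugged, cool, wetter
    z_wet = latent()      # wetness: shallow water table, greener, rainier

    layers: dict[str, np.ndarray] = {}

    # --- terrain ---------------------------------------------------------
    l_wtd = _standardize(blend(latent(), z_relief) - 0.7 * z_wet)
    layers["wtd"] = np.exp(0.9 * l_wtd + 0.8)                       # m, ~e^0.8 median
    l_hand = _standardize(blend(latent(), z_relief) - 0.4 * z_wet)
    layers["hand"] = np.exp(0.8 * l_hand + 1.2)
    layers["twi"] = np.clip(6.0 + 2.0 * blend(latent(), z_wet), 0.0, None)
    layers["vrm"] = expit(1.3 * blend(latent(), z_relief) - 1.0)
    layers["roughness_magnitude"] = np.exp(0.7 * blend(latent(), z_relief))
    layers["roughness_scale"] = np.exp(0.5 * latent() + 1.0)
    layers["wetland_fraction"] = expit(1.6 * blend(latent(), z_wet) - 2.5)

    sand = np.clip(0.45 + 0.15 * latent(), 0.05, 0.90)
    clay = np.clip(0.25 + 0.10 * latent(), 0.02, 0.60)
    over = sand + clay > 0.95
    scale = np.where(over, 0.95 / (sand + clay), 1.0)
    layers["sand_top"], layers["clay_top"] = sand * scale, clay * scale
    layers["om_top"] = np.clip(0.02 + 0.012 * latent(), 0.001, 0.10)
    layers["gravel_top"] = np.clip(0.10 + 0.08 * latent(), 0.0, 0.6)
    for v in ("sand", "clay", "om", "gravel"):
        top = layers[f"{v}_top"]
        lo, hi = {"sand": (0.05, 0.90), "clay": (0.02, 0.60),
                  "om": (0.0005, 0.10), "gravel": (0.0, 0.7)}[v]
        layers[f"{v}_deep"] = np.clip(top * (1 + 0.15 * latent()), lo, hi)
    over = layers["sand_deep"] + layers["clay_deep"] > 0.95
    scale = np.where(over, 0.95 / (layers["sand_deep"] + layers["clay_deep"]), 1.0)
    layers["sand_deep"] *= scale
    layers["clay_deep"] *= scale

    # --- climate ---------------------------------------------------------
    z_precip = _standardize(blend(latent(), z_wet) + 0.4 * z_relief)
    precip_annual = np.exp(6.6 + 0.55 * z_precip)                   # mm/yr
    phase = latent()  # smooth spatial variation of season timing strength
    months = np.arange(12)
    amp_p = 0.3 + 0.65 * expit(phase)
    weights = 1.0 + amp_p[..., None] * np.cos(2 * np.pi * (months - 1) / 12)
    weights /= weights.sum(axis=-1, keepdims=True)
    for m in range(12):
        layers[f"precip_{m + 1:02d}"] = precip_annual * weights[..., m]  # mm/month

    t_mean = 25.0 - 3.5 * blend(latent(), z_relief) + 1.0 * latent()
    amp_t = 3.0 + 2.0 * expit(latent())
    for m in range(12):
        layers[f"temp_{m + 1:02d}"] = t_mean + amp_t * np.cos(2 * np.pi * (m - 6) / 12)

    r_mean = 220.0 + 12.0 * latent() - 6.0 * blend(latent(), z_wet)
    amp_r = 15.0 + 10.0 * expit(latent())
    for m in range(12):
        layers[f"rad_{m + 1:02d}"] = r_mean + amp_r * np.cos(2 * np.pi * (m - 3) / 12)

    # --- vegetation ------------------------------------------------------
    z_canopy = _standardize(blend(latent(), z_wet) + 0.3 * z_precip)
    layers["canopy_height"] = np.clip(np.exp(1.2 + 0.6 * z_canopy), 0.3, 45.0)
    tree = 0.8 * expit(0.9 * blend(latent(), z_wet) + 0.5 * z_canopy - 0.8)
    layers["tree_cover"] = tree
    layers["nontree_cover"] = (1.0 - tree) * 0.7 * expit(latent() + 0.3)
    layers["burned_fraction"] = expit(1.2 * latent() - 2.0)
    pft_latent = blend(latent(), z_wet)
    edges = np.quantile(pft_latent, np.linspace(0, 1, N_PFT_CLASSES + 1)[1:-1])
    layers["pft_class"] = np.digitize(pft_latent, edges).astype(float)

    # --- generative decay-rate model -------------------------------------
    # plant available water from the generated texture, so the texture route
    # into lambda is the physically meaningful one (more PAW, slower decay)
    paw_top = np.asarray(pedotransfer(SoilComposition(
        sand=layers["sand_top"], clay=layers["clay_top"],
        om=np.clip(layers["om_top"], 0, 1),
        gravel_vol=layers["gravel_top"])).paw)

    # direct terrain signal: monotone transforms oriented so that each is
    # non-decreasing in the lambda-favourable direction, positive weights
    monotone_drivers = {
        "wtd": (1.0, -np.log1p(layers["wtd"])),       # deeper water table -> faster decay
        "hand": (0.6, -np.log1p(layers["hand"])),
        "twi": (0.5, layers["twi"]),
        "vrm": (0.7, layers["vrm"]),
        "wetland_fraction": (0.5, layers["wetland_fraction"]),
        "paw_top": (0.5, paw_top),                    # PAW-relevant texture
    }
    g_dir = _standardize(sum(wgt * _standardize(tr)
                             for wgt, tr in monotone_drivers.values()))
    # second terrain signal feeding the interactions
    g2 = _standardize(_standardize(-np.log1p(layers["wtd"]))
                      + _standardize(layers["vrm"])
                      + 0.5 * _standardize(paw_top))
    m_clim = expit(-1.2 * z_precip)          # drier -> stronger terrain leverage
    m_veg = expit(z_canopy)                  # taller canopy -> stronger coupling

    i = truth.interaction_share
    t_dir = np.sqrt(1.0 - i) * g_dir
    t_tc = np.sqrt(i / 2.0) * _standardize(g2 * m_clim)
    t_tv = np.sqrt(i / 2.0) * _standardize(g2 * m_veg)

    if truth.vrm_gate is not None:
        gate = (layers["vrm"] > truth.vrm_gate).astype(float)
        shift = t_dir + t_tc + t_tv
        shift = shift - shift.min()       # nonnegative, keeps monotone signs
        t_dir, t_tc, t_tv = shift * gate, np.zeros(grid.shape), np.zeros(grid.shape)

    t_sum = t_dir + t_tc + t_tv
    f_clim = _standardize(1.0 * z_precip - 0.5 * _standardize(t_mean))
    f_veg = _standardize(0.8 * z_canopy + 0.5 * _standardize(tree))
    c_part = np.sqrt(0.65) * f_clim
    v_part = np.sqrt(0.35) * f_veg

    s = truth.terrain_share
    if s > 0 and t_sum.std() > 0:
        sd_t = t_sum.std()
        t_dir, t_tc, t_tv = t_dir / sd_t, t_tc / sd_t, t_tv / sd_t
        t_sum = t_sum / sd_t
        # orthogonalise the non-terrain signal against the terrain signal so
        # the requested variance split is realized exactly; predictor-level
        # cross-group correlation (the confounding of interest) is untouched
        tc = t_sum - t_sum.mean()
        n_raw = c_part + v_part
        beta = np.vdot(n_raw.ravel() - n_raw.mean(), tc.ravel()) / np.vdot(
            tc.ravel(), tc.ravel())
        c_part = c_part - 0.5 * beta * t_sum
        v_part = v_part - 0.5 * beta * t_sum
    else:
        t_dir = t_tc = t_tv = np.zeros(grid.shape)

    sd = truth.explained_sd_days
    sd_n = (c_part + v_part).std()
    scale_t = sd * np.sqrt(s)
    scale_n = sd * np.sqrt(1.0 - s) / sd_n
    terms = {
        "terrain_direct": scale_t * (t_dir - t_dir.mean()),
        "terrain_clim": scale_t * (t_tc - t_tc.mean()),
        "terrain_veg": scale_t * (t_tv - t_tv.mean()),
        "clim_direct": scale_n * (c_part - c_part.mean()),
        "veg_direct": scale_n * (v_part - v_part.mean()),
    }

    rng_eps = np.random.default_rng(int(next(children)))
    eps = rng_eps.normal(0.0, truth.noise_sd, grid.shape) if truth.noise_sd > 0 \
        else np.zeros(grid.shape)
    terms["noise"] = eps

    lam = (truth.baseline_days + terms["terrain_direct"] + terms["terrain_clim"]
           + terms["terrain_veg"] + terms["clim_direct"] + terms["veg_direct"]
           + eps)
    n_clipped = int(np.sum(lam < LAMBDA_FLOOR_DAYS))
    lam = np.maximum(lam, LAMBDA_FLOOR_DAYS)

    # realized variance shares from the stored generative terms
    t_field = (terms["terrain_direct"] + terms["terrain_clim"]
               + terms["terrain_veg"])
    n_field = terms["clim_direct"] + terms["veg_direct"]
    var_t, var_n = t_field.var(), n_field.var()
    truth.realized_terrain_share = float(var_t / (var_t + var_n))
    inter = terms["terrain_clim"] + terms["terrain_veg"]
    truth.realized_interaction_share = float(inter.var() / var_t) if var_t > 0 else 0.0
    truth.n_clipped = n_clipped
    truth.effect_functions = {
        "terrain_direct_drivers": {k: v[0] for k, v in monotone_drivers.items()},
        "interaction_drivers": ["wtd", "vrm", "clay_top"],
        "interaction_modulators": {"climate": "expit(-1.2*z_precip)",
                                   "vegetation": "expit(z_canopy)"},
        "vrm_gate": truth.vrm_gate,
    }

    # --- nodata mask and packaging ---------------------------------------
    mask = None
    if grid.nodata_fraction > 0:
        rng_mask = np.random.default_rng(int(next(children)))
        mask = rng_mask.random(grid.shape) < grid.nodata_fraction

    raster_layers: dict[str, RasterLayer] = {}
    for name, vals in layers.items():
        v = vals.astype(float).copy()
        if mask is not None:
            v[mask] = np.nan
        raster_layers[name] = RasterLayer(
            v, grid, name=name, categorical=(name == "pft_class"))
    lam_v = lam.copy()
    if mask is not None:
        lam_v[mask] = np.nan
    lambda_layer = RasterLayer(lam_v, grid, name="lambda_true", units="days")

    return LandscapeBundle(grid=grid, layers=raster_layers,
                           lambda_true=lambda_layer, truth=truth, terms=terms)


def write_bundle(bundle: LandscapeBundle, out_dir: str | Path) -> None:
    """Write all layers (TIFF + one NetCDF) and the truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    everything = dict(bundle.layers)
    everything["lambda_true"] = bundle.lambda_true
    for name, layer in everything.items():
        write_tiff(layer, out / f"{name}.tif")
    write_netcdf(everything, out / "landscape.nc")
    truth = asdict(bundle.truth)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=float))
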