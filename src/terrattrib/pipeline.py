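"""End-to-end orchestration: simulate -> fit -> attribute -> bin.

A single :class:`RunConfig` drives every stage with explicit seeds; the run
manifest records the config hash, per-stage output checksums and the
headline numbers (validation NSE, domain-mean terrain importance and its
direct/interaction split), so two runs with the same config are verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from .features import (FeatureTable, apply_domain_filters, build_feature_table,
                       PRECIP_CEILING_MM_YR)
from .grids import GridSpec
from .model import DEFAULT_HYPERPARAMS, TrainedModel, fit, nse, split_train
from .synthetic import LandscapeBundle, SyntheticTruth, generate_landscape, write_bundle

log = logging.getLogger("terrattrib")


@dataclass
class RunConfig:
    n_rows: int = 128
    n_cols: int = 128
    terrain_share: float = 0.5
    interaction_share: float = 0.5
    noise_sd: float = 5.0
    cross_group_mixing: float = 0.3
    seed: int = 0
    aggregation_factor: int = 1
    precip_ceiling: float = PRECIP_CEILING_MM_YR
    capillary_height_m: float = 1.0
    training_fraction: float = 0.10
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    n_attribution_cells: int | None = 4000  # None = all cells
    out_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if min(self.precip_ceiling, self.capillary_height_m,
               self.training_fraction) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunResult:
    bundle: LandscapeBundle
    table: FeatureTable
    model: TrainedModel
    importance: attr.NormalizedImportance
    grouped: attr.GroupedAttribution
    cells: pd.DataFrame          # the rows attribution was computed on
    manifest: dict


def run_all(config: RunConfig, write_outputs: bool = False) -> RunResult:
    """Execute every stage; returns all intermediates plus the manifest."""
    stage = "simulate"
    try:
        grid = GridSpec(config.n_rows, config.n_cols)
        truth = SyntheticTruth(seed=config.seed,
                               terrain_share=config.terrain_share,
                               interaction_share=config.interaction_share,
                               noise_sd=config.noise_sd,
                               cross_group_mixing=config.cross_group_mixing)
        bundle = generate_landscape(grid, truth)
        log.info("simulated %dx%d landscape (realized terrain share %.3f)",
                 grid.n_rows, grid.n_cols, truth.realized_terrain_share)

        stage = "features"
        table = build_feature_table(
            bundle, aggregation_factor=config.aggregation_factor,
            capillary_height_m=config.capillary_height_m)
        n_before = len(table.data)
        table = apply_domain_filters(table,
                                     precip_ceiling=config.precip_ceiling)
        log.info("feature table: %d cells (%d before domain filters)",
                 len(table.data), n_before)

        stage = "train"
        train, valid = split_train(table, config.training_fraction,
                                   seed=config.seed)
        model = fit(train, table.groups, hyperparams=config.hyperparams,
                    seed=config.seed)
        val_nse = nse(valid["lambda"].to_numpy(), model.predict(valid))
        log.info("validation NSE %.3f", val_nse)

        stage = "attribute"
        cells = table.data
        if (config.n_attribution_cells is not None
                and len(cells) > config.n_attribution_cells):
            rng = np.random.default_rng(config.seed)
            keep = np.sort(rng.choice(len(cells), config.n_attribution_cells,
                                      replace=False))
            cells = cells.iloc[keep]
        im = attr.interaction_values(model, cells)
        grouped = attr.group_attribution(im, table.groups)
        imp = attr.normalize_importance(grouped)

        stage = "bins"
        tt = imp.terrain_total
        mean_tt = float(np.nanmean(tt))
        mean_direct = float(imp.table["terrain_direct_share"].mean())
        mean_inter = float((imp.table["terrain_clim_share"]
                            + imp.table["terrain_veg_share"]).mean())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stage_checksums": {
            "lambda_true": _checksum(bundle.lambda_true.values),
            "feature_table": _checksum(table.data.to_numpy(dtype=float)),
            "predictions": _checksum(model.predict(table.data)),
            "terrain_total": _checksum(tt),
        },
        "realized_terrain_share": truth.realized_terrain_share,
        "n_cells": len(table.data),
        "n_attribution_cells": len(cells),
        "validation_nse": val_nse,
        "mean_terrain_total": mean_tt,
        "mean_terrain_direct": mean_direct,
        "mean_terrain_interaction": mean_inter,
    }

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bundle(bundle, out / "landscape")
        table.write(out / "features.tsv")
        model.save(out / "model.json")
        comp = grouped.components.copy()
        comp[["row", "col"]] = cells[["row", "col"]].to_numpy()
        comp.to_csv(out / "attribution_components.tsv", sep="\t", index=False)
        imp.table.to_csv(out / "normalized_importance.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(bundle=bundle, table=table, model=model, importance=imp,
                     grouped=grouped, cells=cells, manifest=manifest)
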