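"""Monotonicity-constrained gradient-boosted model of the decay rate.

The decay rate lambda is modelled on its natural scale (days) with XGBoost
regression trees.  Every terrain predictor carries a monotonic constraint
encoding the prior that secondary water can only slow vegetation decay:
water table depth and height above nearest drainage are constrained
negative (deeper groundwater, weaker support), every other terrain
predictor positive; climate and vegetation predictors are unconstrained.
The constraints prescribe only the sign of the response — the shape stays
flexible.

Training uses a small random sample of cells (10% by default) to limit
overfitting to spatial autocorrelation; the remaining cells serve as
validation, scored with Nash–Sutcliffe efficiency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import FeatureTable

NEGATIVE_TERRAIN = ("wtd", "hand")

# depth 3 keeps every tree on <= 7 distinct features, which the exact
# double-precision SHAP interaction enumeration requires to stay cheap
DEFAULT_HYPERPARAMS = {
    "max_depth": 3,
    "eta": 0.05,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "min_child_weight": 2,
    "num_boost_round": 200,
}


def monotone_spec(groups: dict[str, str],
                  columns: list[str]) -> dict[str, int]:
    """Constraint per predictor: -1 for WTD/HAND, +1 for other terrain, 0 else."""
    spec: dict[str, int] = {}
    for col in columns:
        if col not in groups:
            raise KeyError(f"column {col!r} has no group tag")
        if groups[col] == "terrain":
            spec[col] = -1 if col in NEGATIVE_TERRAIN else 1
        else:
            spec[col] = 0
    return spec


@dataclass
class TrainedModel:
    booster: xgb.Booster
    columns: list[str]
    spec: dict[str, int]
    base_value: float          # mean prediction over the training sample
    hyperparams: dict
    seed: int
    train_index: np.ndarray

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy(dtype=float)
        return self.booster.predict(xgb.DMatrix(X, feature_names=self.columns))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.booster.save_model(path)
        sidecar = {"columns": self.columns, "spec": self.spec,
                   "base_value": self.base_value, "seed": self.seed,
                   "hyperparams": self.hyperparams,
                   "train_index": self.train_index.tolist()}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(booster, meta["columns"], meta["spec"], meta["base_value"],
                   meta["hyperparams"], meta["seed"],
                   np.asarray(meta["train_index"]))


def split_train(table: FeatureTable, fraction: float = 0.10,
                seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive train/validation split of the cells."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(table.data)
    if n == 0:
        raise ValueError("empty feature table")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    return (table.data.iloc[np.sort(perm[:n_train])],
            table.data.iloc[np.sort(perm[n_train:])])


def fit(train: pd.DataFrame, groups: dict[str, str],
        hyperparams: dict | None = None, seed: int = 0,
        columns: list[str] | None = None) -> TrainedModel:
    """Train the constrained booster; deterministic for a fixed seed.

    Runs single-threaded with the exact tree method so repeated fits are
    bit-identical.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    num_round = int(hp.pop("num_boost_round"))

    if columns is None:
        columns = [c for c in train.columns if c not in ("lambda", "row", "col")]
    unknown = [c for c in columns if c not in groups]
    if unknown:
        raise KeyError(f"no group tag (hence no constraint) for: {unknown}")
    spec = monotone_spec(groups, columns)

    X = train[columns].to_numpy(dtype=float)
    y = train["lambda"].to_numpy(dtype=float)
    dtrain = xgb.DMatrix(X, label=y, feature_names=columns)
    params = {
        "objective": "reg:squarederror",
        "tree_method": "exact",
        "nthread": 1,
        "seed": int(seed),
        "monotone_constraints": "(" + ",".join(str(spec[c]) for c in columns) + ")",
        **hp,
    }
    booster = xgb.train(params, dtrain, num_boost_round=num_round)
    base = float(np.mean(booster.predict(dtrain)))
    return TrainedModel(booster=booster, columns=columns, spec=spec,
                        base_value=base, hyperparams={**hp, "num_boost_round": num_round},
                        seed=int(seed),
                        train_index=train.index.to_numpy())


def nse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Nash–Sutcliffe efficiency: 1 - SSE / SS_tot.

    1 is a perfect match, 0 the skill of predicting the observed mean.
    Undefined (raises) when the observations have no variance.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed variance is zero; NSE undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def monotonicity_sweep(model: TrainedModel, X: pd.DataFrame,
                       feature: str, n_anchors: int = 50,
                       n_points: int = 50, seed: int = 0) -> int:
    """Count monotonicity violations of ``feature`` over full-range sweeps.

    Draws random anchor rows, sweeps the feature from its observed minimum to
    maximum and counts sign violations of the constrained direction.
    """
    direction = model.spec[feature]
    if direction == 0:
        raise ValueError(f"{feature} carries no monotone constraint")
    rng = np.random.default_rng(seed)
    anchors = X.iloc[rng.choice(len(X), size=min(n_anchors, len(X)),
                                replace=False)]
    grid = np.linspace(X[feature].min(), X[feature].max(), n_points)
    violations = 0
    j = model.columns.index(feature)
    for _, row in anchors.iterrows():
        block = np.tile(row[model.columns].to_numpy(dtype=float), (n_points, 1))
        block[:, j] = grid
        pred = model.booster.predict(
            xgb.DMatrix(block, feature_names=model.columns))
        diffs = np.diff(pred) * direction
        violations += int(np.sum(diffs < -1e-9))
    return violations
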