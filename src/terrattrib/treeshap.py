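"""Exact tree-path-dependent SHAP interaction values in float64.

Shapley and Shapley-interaction values are additive over the trees of a
boosted ensemble, and each regression tree only involves the handful of
features it actually splits on.  For shallow trees the game can therefore
be solved exactly: for every tree, the conditional expectation

    v(S) = E[f_tree(x) | x_S]        (cover-weighted tree traversal)

is enumerated over all subsets S of the tree's own feature set, and the
Shapley values / pairwise interaction indices follow from their defining
sums.  This yields the same tree-path-dependent attribution as the TreeSHAP
algorithm, but in double precision — the per-cell additivity identity
(sum of the interaction matrix equals prediction minus base value) holds to
float64 roundoff, which the grouped Eq.-style decomposition downstream
relies on.

The subset enumeration is exact and fast for trees using at most
:data:`MAX_TREE_FEATURES` distinct features (depth <= 3 guarantees 7);
deeper ensembles are rejected at parse time.  Kernels are numba-compiled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import factorial

import numpy as np
import xgboost as xgb
from numba import njit

MAX_TREE_FEATURES = 14


@dataclass
class TreeEnsemble:
    """Flat-array view of a boosted regression ensemble."""

    node_offset: np.ndarray   # (T+1,) int64, node ranges per tree
    feature: np.ndarray       # (N,) int64, split feature index, -1 at leaves
    threshold: np.ndarray     # (N,) float64
    left: np.ndarray          # (N,) int64 (x < threshold branch)
    right: np.ndarray         # (N,) int64
    cover: np.ndarray         # (N,) float64 (training weight per node)
    value: np.ndarray         # (N,) float64 leaf values
    bitpos: np.ndarray        # (N,) int64, split feature's bit within its tree
    u_flat: np.ndarray        # concatenated per-tree feature sets
    u_offset: np.ndarray      # (T+1,) int64
    base_score: float
    n_features: int


def parse_booster(booster: xgb.Booster, columns: list[str]) -> TreeEnsemble:
    """Flatten an XGBoost booster into traversal arrays."""
    df = booster.trees_to_dataframe()
    col_index = {c: i for i, c in enumerate(columns)}
    id_map = {t: {} for t in df["Tree"].unique()}
    for pos, (tree, node) in enumerate(zip(df["Tree"], df["Node"])):
        id_map[tree][f"{tree}-{node}"] = pos

    n = len(df)
    feature = np.full(n, -1, dtype=np.int64)
    threshold = np.zeros(n)
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)
    cover = df["Cover"].to_numpy(dtype=float)
    value = np.zeros(n)
    for pos, row in enumerate(df.itertuples(index=False)):
        if row.Feature == "Leaf":
            value[pos] = row.Gain
        else:
            feature[pos] = col_index[row.Feature]
            threshold[pos] = row.Split
            left[pos] = id_map[row.Tree][row.Yes]
            right[pos] = id_map[row.Tree][row.No]

    trees = df["Tree"].to_numpy()
    t_ids = np.unique(trees)
    node_offset = np.zeros(len(t_ids) + 1, dtype=np.int64)
    for i, t in enumerate(t_ids):
        node_offset[i + 1] = node_offset[i] + int(np.sum(trees == t))

    bitpos = np.full(n, -1, dtype=np.int64)
    u_parts = []
    u_offset = np.zeros(len(t_ids) + 1, dtype=np.int64)
    for i in range(len(t_ids)):
        lo, hi = node_offset[i], node_offset[i + 1]
        used = np.unique(feature[lo:hi][feature[lo:hi] >= 0])
        if used.size > MAX_TREE_FEATURES:
            raise ValueError(
                f"tree {i} splits on {used.size} distinct features; exact "
                f"subset enumeration supports <= {MAX_TREE_FEATURES} "
                "(lower max_depth)")
        pos_of = {f: b for b, f in enumerate(used)}
        for j in range(lo, hi):
            if feature[j] >= 0:
                bitpos[j] = pos_of[feature[j]]
        u_parts.append(used)
        u_offset[i + 1] = u_offset[i] + used.size
    u_flat = (np.concatenate(u_parts) if u_parts
              else np.zeros(0, dtype=np.int64)).astype(np.int64)

    cfg = json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    return TreeEnsemble(node_offset=node_offset, feature=feature,
                        threshold=threshold, left=left, right=right,
                        cover=cover, value=value, bitpos=bitpos,
                        u_flat=u_flat, u_offset=u_offset,
                        base_score=base, n_features=len(columns))


@njit(cache=True)
def _v_of_subset(root, mask, feature, threshold, left, right, cover, value,
                 bitpos, x):
    """Cover-weighted conditional expectation of one tree given x_S."""
    total = 0.0
    stack_node = np.empty(128, dtype=np.int64)
    stack_w = np.empty(128, dtype=np.float64)
    stack_node[0] = root
    stack_w[0] = 1.0
    top = 1
    while top > 0:
        top -= 1
        node = stack_node[top]
        w = stack_w[top]
        f = feature[node]
        if f < 0:
            total += w * value[node]
        elif (mask >> bitpos[node]) & 1:
            child = left[node] if x[f] < threshold[node] else right[node]
            stack_node[top] = child
            stack_w[top] = w
            top += 1
        else:
            l, r = left[node], right[node]
            stack_node[top] = l
            stack_w[top] = w * cover[l] / cover[node]
            top += 1
            stack_node[top] = r
            stack_w[top] = w * cover[r] / cover[node]
            top += 1
    return total


@njit(cache=True)
def _interactions_one_cell(x, node_offset, feature, threshold, left, right,
                           cover, value, bitpos, u_flat, u_offset,
                           fact, phi_out):
    """Accumulate the full SHAP interaction matrix for one row."""
    n_trees = node_offset.size - 1
    pred = 0.0
    base = 0.0
    for t in range(n_trees):
        root = node_offset[t]
        n = u_offset[t + 1] - u_offset[t]
        u0 = u_offset[t]
        n_sub = 1 << n
        v = np.empty(n_sub)
        for mask in range(n_sub):
            v[mask] = _v_of_subset(root, mask, feature, threshold, left,
                                   right, cover, value, bitpos, x)
        pred += v[n_sub - 1]
        base += v[0]
        if n == 0:
            continue
        # per-feature Shapley values of this tree
        phi_t = np.zeros(n)
        for i in range(n):
            bit_i = 1 << i
            for mask in range(n_sub):
                if mask & bit_i:
                    continue
                size = 0
                mm = mask
                while mm:
                    size += mm & 1
                    mm >>= 1
                w = fact[size] * fact[n - size - 1] / fact[n]
                phi_t[i] += w * (v[mask | bit_i] - v[mask])
        # pairwise interaction totals
        half_sum = np.zeros(n)
        for i in range(n):
            gi = u_flat[u0 + i]
            bit_i = 1 << i
            for j in range(i + 1, n):
                gj = u_flat[u0 + j]
                bit_j = 1 << j
                inter = 0.0
                for mask in range(n_sub):
                    if mask & (bit_i | bit_j):
                        continue
                    size = 0
                    mm = mask
                    while mm:
                        size += mm & 1
                        mm >>= 1
                    w = fact[size] * fact[n - size - 2] / fact[n - 1]
                    inter += w * (v[mask | bit_i | bit_j] - v[mask | bit_i]
                                  - v[mask | bit_j] + v[mask])
                phi_out[gi, gj] += inter / 2.0
                phi_out[gj, gi] += inter / 2.0
                half_sum[i] += inter / 2.0
                half_sum[j] += inter / 2.0
        for i in range(n):
            gi = u_flat[u0 + i]
            phi_out[gi, gi] += phi_t[i] - half_sum[i]
    return pred, base


def shap_interactions(ens: TreeEnsemble, X: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SHAP interaction matrices for every row of X, in float64.

    Returns ``(phi, predictions, base_values)`` where ``phi`` has shape
    (n, m, m); base_values is constant across rows (cover-weighted mean
    tree output plus the ensemble base score).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n_cells, m = X.shape
    if m != ens.n_features:
        raise ValueError("feature count mismatch with the parsed ensemble")
    fact = np.array([float(factorial(k)) for k in range(MAX_TREE_FEATURES + 2)])
    phi = np.zeros((n_cells, m, m))
    pred = np.empty(n_cells)
    base = np.empty(n_cells)
    for k in range(n_cells):
        p, b = _interactions_one_cell(
            X[k], ens.node_offset, ens.feature, ens.threshold, ens.left,
            ens.right, ens.cover, ens.value, ens.bitpos, ens.u_flat,
            ens.u_offset, fact, phi[k])
        pred[k] = p + ens.base_score
        base[k] = b + ens.base_score
    return phi, pred, base
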