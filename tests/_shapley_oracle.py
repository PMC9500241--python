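"""Brute-force Shapley-interaction oracle for small tree ensembles.

Deliberately independent of terrattrib.treeshap: trees are read from the
booster's JSON dump (not trees_to_dataframe), conditional expectations are
evaluated recursively on the nested structure, per-feature Shapley values
are averaged over explicit permutations, and pairwise interaction indices
use the textbook subset-weight formula.  Feasible only for a handful of
features; used to pin down the production path on tiny models.
"""

import itertools
import json
from math import factorial

import numpy as np


def parse_dump(booster):
    return [json.loads(t) for t in booster.get_dump(dump_format="json",
                                                    with_stats=True)]


def _value(node, x, present, name_to_idx):
    if "leaf" in node:
        return node["leaf"]
    f = name_to_idx[node["split"]]
    kids = {c["nodeid"]: c for c in node["children"]}
    yes, no = kids[node["yes"]], kids[node["no"]]
    if f in present:
        child = yes if x[f] < node["split_condition"] else no
        return _value(child, x, present, name_to_idx)
    wy, wn = yes["cover"], no["cover"]
    return (wy * _value(yes, x, present, name_to_idx)
            + wn * _value(no, x, present, name_to_idx)) / (wy + wn)


def coalition_value(trees, x, present, name_to_idx):
    """v(S): cover-weighted conditional expectation of the ensemble."""
    return sum(_value(t, x, frozenset(present), name_to_idx) for t in trees)


def shapley_values(trees, x, features, name_to_idx):
    """Per-feature Shapley values by averaging over all orderings."""
    n = len(features)
    phi = {f: 0.0 for f in features}
    for order in itertools.permutations(features):
        before = set()
        for f in order:
            gain = (coalition_value(trees, x, before | {f}, name_to_idx)
                    - coalition_value(trees, x, before, name_to_idx))
            phi[f] += gain
            before.add(f)
    n_perm = factorial(n)
    return {f: v / n_perm for f, v in phi.items()}


def interaction_matrix(booster, x, columns):
    """Full SHAP interaction matrix (m x m) for one row, float64.

    Shapley values go on the diagonal net of interactions; each pairwise
    interaction index is split evenly between its two off-diagonal cells,
    so the matrix sums to v(all) - v(empty).
    """
    trees = parse_dump(booster)
    name_to_idx = {c: i for i, c in enumerate(columns)}
    used = sorted({name_to_idx[s] for t in trees for s in _splits(t)})
    out = np.zeros((len(columns), len(columns)))
    phi = shapley_values(trees, x, used, name_to_idx)
    n = len(used)
    pair_half = {f: 0.0 for f in used}
    for i, j in itertools.combinations(used, 2):
        rest = [f for f in used if f not in (i, j)]
        total = 0.0
        for size in range(len(rest) + 1):
            w = factorial(size) * factorial(n - size - 2) / factorial(n - 1)
            for S in itertools.combinations(rest, size):
                S = set(S)
                delta = (coalition_value(trees, x, S | {i, j}, name_to_idx)
                         - coalition_value(trees, x, S | {i}, name_to_idx)
                         - coalition_value(trees, x, S | {j}, name_to_idx)
                         + coalition_value(trees, x, S, name_to_idx))
                total += w * delta
        out[i, j] = out[j, i] = total / 2.0
        pair_half[i] += total / 2.0
        pair_half[j] += total / 2.0
    for f in used:
        out[f, f] = phi[f] - pair_half[f]
    return out


def _splits(node):
    if "leaf" in node:
        return []
    return [node["split"]] + [s for c in node["children"] for s in _splits(c)]
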