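"""Exact additive feature attributions for gradient-boosted tree ensembles.

Path-dependent TreeSHAP (Lundberg's polynomial-time algorithm) evaluated in
float64 over the parsed booster, so the additivity identity

    base value + sum_i phi_i  ==  raw margin

holds to full double precision for every instance. Margins are recomputed
here by direct tree descent (an independent code path from the attribution
recursion), making the additivity check a real test of the algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["parse_booster", "shap_values", "margins"]


@dataclass
class _Tree:
    left: np.ndarray
    right: np.ndarray
    default_left: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray      # leaf value at leaves, 0 elsewhere
    cover: np.ndarray      # sum of hessians per node

    def is_leaf(self, j: int) -> bool:
        return self.left[j] < 0


def parse_booster(booster):
    """Parse an xgboost Booster into per-tree arrays + the base margin."""
    model = json.loads(bytearray(booster.save_raw(raw_format="json")))
    learner = model["learner"]
    base_score = float(learner["learner_model_param"]["base_score"])
    objective = learner["objective"]["name"]
    if objective in ("binary:logistic", "reg:logistic"):
        base_margin = float(np.log(base_score / (1.0 - base_score)))
    else:
        base_margin = base_score
    trees = []
    for t in learner["gradient_booster"]["model"]["trees"]:
        left = np.asarray(t["left_children"], dtype=np.int64)
        right = np.asarray(t["right_children"], dtype=np.int64)
        # the booster stores and compares split conditions in float32
        cond = np.asarray(t["split_conditions"], dtype=np.float32)
        value = np.where(left < 0, cond.astype(np.float64), 0.0)
        trees.append(_Tree(
            left=left, right=right,
            default_left=np.asarray(t["default_left"], dtype=np.int64),
            feature=np.asarray(t["split_indices"], dtype=np.int64),
            threshold=cond,
            value=value,
            cover=np.asarray(t["sum_hessian"], dtype=np.float64)))
    return trees, base_margin


def margins(booster, X: np.ndarray) -> np.ndarray:
    """Raw margins recomputed in float64 by direct tree descent.

    Split decisions compare float32-cast feature values, matching the
    booster's own evaluation; leaf values are accumulated in float64.
    """
    trees, base = parse_booster(booster)
    X = np.asarray(X, dtype=np.float32)
    out = np.full(len(X), base, dtype=np.float64)
    for tree in trees:
        for i, x in enumerate(X):
            j = 0
            while not tree.is_leaf(j):
                xv = x[tree.feature[j]]
                if np.isnan(xv):
                    j = tree.left[j] if tree.default_left[j] else tree.right[j]
                elif xv < tree.threshold[j]:
                    j = tree.left[j]
                else:
                    j = tree.right[j]
            out[i] += tree.value[j]
    return out


def _expected_value(tree: _Tree) -> float:
    """Cover-weighted mean leaf value (the tree's contribution to the base)."""
    total = 0.0
    stack = [(0, 1.0)]
    while stack:
        j, w = stack.pop()
        if tree.is_leaf(j):
            total += w * tree.value[j]
        else:
            c = tree.cover[j]
            stack.append((tree.left[j], w * tree.cover[tree.left[j]] / c))
            stack.append((tree.right[j], w * tree.cover[tree.right[j]] / c))
    return total


# --- the path-dependent TreeSHAP recursion -------------------------------
# The "unique path" is a record of the features split on so far, each with
# the fraction of subsets flowing down when the feature is excluded (zero
# fraction) or included (one fraction), plus a permutation weight.

def _extend(pd_, pz, po, pw, depth, zero_fraction, one_fraction, feature):
    pd_[depth] = feature
    pz[depth] = zero_fraction
    po[depth] = one_fraction
    pw[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[i + 1] += one_fraction * pw[i] * (i + 1) / (depth + 1)
        pw[i] = zero_fraction * pw[i] * (depth - i) / (depth + 1)


def _unwind(pd_, pz, po, pw, depth, index):
    one = po[index]
    zero = pz[index]
    nxt = pw[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[i]
            pw[i] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - pw[i] * zero * (depth - i) / (depth + 1)
        else:
            pw[i] = pw[i] * (depth + 1) / (zero * (depth - i))
    for i in range(index, depth):
        pd_[i] = pd_[i + 1]
        pz[i] = pz[i + 1]
        po[i] = po[i + 1]


def _unwound_sum(pz, po, pw, depth, index):
    one = po[index]
    zero = pz[index]
    nxt = pw[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (depth + 1) / ((i + 1) * one)
            total += tmp
            nxt = pw[i] - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += pw[i] / (zero * (depth - i) / (depth + 1))
    return total


def _recurse(tree: _Tree, x, phi, j, depth, pd_, pz, po, pw,
             parent_zero, parent_one, parent_feature):
    # work on a private copy of the path for this branch
    pd_ = pd_.copy()
    pz = pz.copy()
    po = po.copy()
    pw = pw.copy()
    _extend(pd_, pz, po, pw, depth, parent_zero, parent_one, parent_feature)
    if tree.is_leaf(j):
        v = tree.value[j]
        for i in range(1, depth + 1):
            w = _unwound_sum(pz, po, pw, depth, i)
            phi[pd_[i]] += w * (po[i] - pz[i]) * v
        return
    feat = tree.feature[j]
    xv = x[feat]
    if np.isnan(xv):
        hot = tree.left[j] if tree.default_left[j] else tree.right[j]
    elif xv < tree.threshold[j]:
        hot = tree.left[j]
    else:
        hot = tree.right[j]
    cold = tree.right[j] if hot == tree.left[j] else tree.left[j]
    inc_zero = 1.0
    inc_one = 1.0
    # undo a previous split on the same feature along this path
    k = -1
    for i in range(1, depth + 1):
        if pd_[i] == feat:
            k = i
            break
    if k >= 0:
        inc_zero = pz[k]
        inc_one = po[k]
        _unwind(pd_, pz, po, pw, depth, k)
        depth -= 1
    cov = tree.cover[j]
    _recurse(tree, x, phi, hot, depth + 1, pd_, pz, po, pw,
             inc_zero * tree.cover[hot] / cov, inc_one, feat)
    _recurse(tree, x, phi, cold, depth + 1, pd_, pz, po, pw,
             inc_zero * tree.cover[cold] / cov, 0.0, feat)


def shap_values(booster, X: np.ndarray, n_features: int):
    """Per-instance attributions phi (n, n_features) and the base value.

    base + phi.sum(axis=1) equals the float64 margin of each instance.
    """
    trees, base_margin = parse_booster(booster)
    X = np.asarray(X, dtype=np.float32)  # split decisions match the booster
    phi = np.zeros((len(X), n_features), dtype=np.float64)
    base = base_margin + sum(_expected_value(t) for t in trees)
    maxdepth = max(_depth(t) for t in trees) + 2
    for tree in trees:
        for i, x in enumerate(X):
            pd_ = np.full(maxdepth, -1, dtype=np.int64)
            pz = np.zeros(maxdepth)
            po = np.zeros(maxdepth)
            pw = np.zeros(maxdepth)
            _recurse(tree, x, phi[i], 0, 0, pd_, pz, po, pw, 1.0, 1.0, -1)
    return phi, float(base)


def _depth(tree: _Tree, j: int = 0) -> int:
    if tree.is_leaf(j):
        return 0
    return 1 + max(_depth(tree, tree.left[j]), _depth(tree, tree.right[j]))
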