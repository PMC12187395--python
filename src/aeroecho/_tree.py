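"""Depth-limited least-squares regression trees for the boosting engine.

Trees are grown best-first: at every step the leaf whose best split gives
the largest squared-error reduction is expanded, until ``max_splits``
splits have been made or no split improves the fit.  ``max_splits`` is
the interaction-order knob of the boosting engine (a tree with s splits
has s+1 leaves and can represent interactions of order up to s).

Numeric predictors split on a threshold (x <= t goes left); categorical
predictors split on a subset of levels, found by ordering levels by their
mean response — optimal for squared error — and scanning prefix splits.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegressionTree", "fit_tree"]


@dataclass
class _Node:
    is_leaf: bool = True
    value: float = 0.0
    feature: int = -1
    threshold: float = 0.0
    left_levels: frozenset | None = None  # categorical: codes going left
    left: int = -1
    right: int = -1


@dataclass
class RegressionTree:
    nodes: list[_Node] = field(default_factory=list)
    gains: dict[int, float] = field(default_factory=dict)  # feature -> summed SSE gain

    def predict(self, x: np.ndarray, is_cat: np.ndarray) -> np.ndarray:
        """Vectorised prediction by recursive index partition."""
        out = np.empty(x.shape[0])
        stack = [(0, np.arange(x.shape[0]))]
        while stack:
            node_id, idx = stack.pop()
            if idx.size == 0:
                continue
            node = self.nodes[node_id]
            if node.is_leaf:
                out[idx] = node.value
                continue
            col = x[idx, node.feature]
            if node.left_levels is not None:
                go_left = np.isin(col, list(node.left_levels))
            else:
                go_left = col <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out


def _best_numeric_split(xs: np.ndarray, ys: np.ndarray, min_obs: int):
    order = np.argsort(xs, kind="mergesort")
    x_s, y_s = xs[order], ys[order]
    n = xs.size
    csum = np.cumsum(y_s)
    total = csum[-1]
    k = np.arange(1, n)  # size of left child
    valid = (x_s[:-1] < x_s[1:]) & (k >= min_obs) & (n - k >= min_obs)
    if not valid.any():
        return None
    left_sum = csum[:-1]
    gain = left_sum**2 / k + (total - left_sum) ** 2 / (n - k) - total**2 / n
    gain = np.where(valid, gain, -np.inf)
    i = int(np.argmax(gain))
    thr = 0.5 * (x_s[i] + x_s[i + 1])
    return float(gain[i]), thr


def _best_categorical_split(xs: np.ndarray, ys: np.ndarray, min_obs: int):
    codes = xs.astype(np.int64)
    n_lvl = codes.max() + 1
    counts = np.bincount(codes, minlength=n_lvl)
    sums = np.bincount(codes, weights=ys, minlength=n_lvl)
    present = counts > 0
    lvls = np.nonzero(present)[0]
    if lvls.size < 2:
        return None
    means = sums[lvls] / counts[lvls]
    order = lvls[np.argsort(means, kind="mergesort")]
    c_counts = np.cumsum(counts[order])[:-1]
    c_sums = np.cumsum(sums[order])[:-1]
    n, total = codes.size, sums[order].sum()
    valid = (c_counts >= min_obs) & (n - c_counts >= min_obs)
    if not valid.any():
        return None
    gain = c_sums**2 / c_counts + (total - c_sums) ** 2 / (n - c_counts) - total**2 / n
    gain = np.where(valid, gain, -np.inf)
    i = int(np.argmax(gain))
    return float(gain[i]), frozenset(int(c) for c in order[: i + 1])


def _node_best_split(x: np.ndarray, y: np.ndarray, idx: np.ndarray, is_cat: np.ndarray, min_obs: int):
    best = None
    for f in range(x.shape[1]):
        xs = x[idx, f]
        res = (
            _best_categorical_split(xs, y[idx], min_obs)
            if is_cat[f]
            else _best_numeric_split(xs, y[idx], min_obs)
        )
        if res is None:
            continue
        gain, rule = res
        if gain <= 1e-12:
            continue
        if best is None or gain > best[0]:
            best = (gain, f, rule)
    return best


def fit_tree(
    x: np.ndarray,
    y: np.ndarray,
    is_cat: np.ndarray,
    max_splits: int,
    min_obs: int = 10,
) -> RegressionTree:
    """Grow a best-first regression tree on (x, y).

    Terminal values are mean responses of the training rows in each leaf.
    When the node is too small to honour ``min_obs`` on both sides, it
    stays a leaf (the effective depth shrinks with the data).
    """
    tree = RegressionTree()
    root = _Node(is_leaf=True, value=float(y.mean()) if y.size else 0.0)
    tree.nodes.append(root)
    all_idx = np.arange(x.shape[0])
    heap: list = []
    counter = 0

    def _push(node_id: int, idx: np.ndarray) -> None:
        nonlocal counter
        best = _node_best_split(x, y, idx, is_cat, min_obs)
        if best is not None:
            gain, f, rule = best
            heapq.heappush(heap, (-gain, counter, node_id, idx, f, rule))
            counter += 1

    _push(0, all_idx)
    n_splits = 0
    while heap and n_splits < max_splits:
        neg_gain, _, node_id, idx, f, rule = heapq.heappop(heap)
        col = x[idx, f]
        if isinstance(rule, frozenset):
            go_left = np.isin(col, list(rule))
            node_rule = dict(left_levels=rule, threshold=0.0)
        else:
            go_left = col <= rule
            node_rule = dict(left_levels=None, threshold=rule)
        left_idx, right_idx = idx[go_left], idx[~go_left]
        left = _Node(is_leaf=True, value=float(y[left_idx].mean()))
        right = _Node(is_leaf=True, value=float(y[right_idx].mean()))
        tree.nodes.extend([left, right])
        node = tree.nodes[node_id]
        node.is_leaf = False
        node.feature = f
        node.threshold = node_rule["threshold"]
        node.left_levels = node_rule["left_levels"]
        node.left = len(tree.nodes) - 2
        node.right = len(tree.nodes) - 1
        tree.gains[f] = tree.gains.get(f, 0.0) + (-neg_gain)
        n_splits += 1
        _push(node.left, left_idx)
        _push(node.right, right_idx)
    return tree
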