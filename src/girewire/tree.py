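"""CART-style regression trees with mean-squared-error split search.

The tree is the building block of the bagged degree model.  Splits minimize
the size-weighted sum of child squared-error impurities; candidate
thresholds are midpoints between consecutive distinct observed values of a
feature.  Missing feature values are excluded from a candidate split's
impurity computation; once a split is chosen, samples (and later query
genes) missing that feature are routed to the child that received more
training samples (tie -> left).  Ties among equally good splits break
deterministically: lowest feature index in canonical order, then smallest
threshold.  Leaves predict the mean training target of their node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["TreeNode", "RegressionTree", "grow_tree", "best_split"]

_EPS = 1e-12


@dataclass
class TreeNode:
    """One node of a regression tree; ``feature < 0`` marks a leaf."""

    feature: int
    threshold: float
    left: int
    right: int
    value: float  # mean training target at this node
    n_samples: int
    missing_to_left: bool = True


class RegressionTree:
    """A fitted binary regression tree over a fixed feature list."""

    def __init__(self, nodes: list[TreeNode], feature_names: Sequence[str]):
        self.nodes = nodes
        self.feature_names = list(feature_names)

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes if nd.feature < 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict targets for an (n, p) feature matrix (NaN = missing)."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node_id, idx = stack.pop()
            nd = self.nodes[node_id]
            if nd.feature < 0:
                out[idx] = nd.value
                continue
            x = X[idx, nd.feature]
            miss = np.isnan(x)
            go_left = x <= nd.threshold
            go_left[miss] = nd.missing_to_left
            left_idx = idx[go_left]
            right_idx = idx[~go_left]
            if len(left_idx):
                stack.append((nd.left, left_idx))
            if len(right_idx):
                stack.append((nd.right, right_idx))
        return out

    def decision_path(self, x: np.ndarray) -> list[int]:
        """Node ids visited for a single feature vector (for inspection)."""
        path = [0]
        nd = self.nodes[0]
        while nd.feature >= 0:
            v = x[nd.feature]
            if np.isnan(v):
                nxt = nd.left if nd.missing_to_left else nd.right
            else:
                nxt = nd.left if v <= nd.threshold else nd.right
            path.append(nxt)
            nd = self.nodes[nxt]
        return path


def best_split(
    X: np.ndarray, y: np.ndarray
) -> Optional[tuple[int, float, float]]:
    """Best (feature, threshold, gain) over all features and midpoints.

    Gain is the reduction in summed squared error over the samples with the
    candidate feature observed.  Returns None when no split strictly reduces
    impurity.  Ties break toward the lowest feature index, then the smallest
    threshold.
    """
    n, p = X.shape
    if n < 2:
        return None
    # sort every feature column at once; NaNs sort to the bottom
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    obs = ~np.isnan(xs)
    m = obs.sum(axis=0)  # observed count per feature
    ys0 = np.where(obs, ys, 0.0)
    cs = np.cumsum(ys0, axis=0)
    css = np.cumsum(ys0 * ys0, axis=0)
    ok = m >= 2
    if not ok.any():
        return None
    last = np.maximum(m - 1, 0)
    tot_s = np.take_along_axis(cs, last[None, :], axis=0)[0]
    tot_ss = np.take_along_axis(css, last[None, :], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        parent_sse = tot_ss - tot_s * tot_s / np.where(m > 0, m, 1)
        nl = np.arange(1, n, dtype=float)[:, None]  # left size at split position
        nr = m[None, :] - nl
        sse_l = css[:-1] - cs[:-1] ** 2 / nl
        sse_r = (tot_ss - css[:-1]) - (tot_s - cs[:-1]) ** 2 / np.where(nr > 0, nr, 1)
        gain = parent_sse[None, :] - (sse_l + sse_r)
    valid = obs[:-1] & obs[1:] & (xs[:-1] < xs[1:]) & ok[None, :] & (nr > 0)
    gain = np.where(valid, gain, -np.inf)
    # deterministic tie-breaks under floating-point noise: gains within a
    # relative tolerance of the maximum count as tied; pick the lowest
    # canonical feature index, then the smallest threshold
    gmax = float(np.max(gain))
    if not np.isfinite(gmax) or gmax <= _EPS:
        return None
    tol = 1e-9 * max(1.0, abs(gmax))
    col_gain = np.max(gain, axis=0)
    f = int(np.argmax(col_gain >= gmax - tol))
    i = int(np.argmax(gain[:, f] >= gmax - tol))  # first -> smallest threshold
    thr = (xs[i, f] + xs[i + 1, f]) / 2.0
    return (f, float(thr), float(gain[i, f]))


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    min_split: int = 10,
    feature_names: Optional[Sequence[str]] = None,
) -> RegressionTree:
    """Grow a regression tree on an (n, p) matrix (NaN = missing) and targets.

    Nodes with fewer than ``min_split`` samples, constant targets, or no
    impurity-reducing split become leaves predicting the node target mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, p) with matching y")
    if len(y) == 0:
        raise ValueError("cannot grow a tree on zero samples")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    if np.isnan(X).all():
        warnings.warn("all feature values missing; returning a single-leaf tree")
        return RegressionTree(
            [TreeNode(-1, np.nan, -1, -1, float(y.mean()), len(y))], names
        )

    # iterative depth-first construction (avoids recursion limits on deep trees)
    nodes: list[TreeNode] = []
    stack: list[tuple[np.ndarray, int, str]] = [(np.arange(len(y)), -1, "")]
    while stack:
        idx, parent, side = stack.pop()
        node_id = len(nodes)
        yv = y[idx]
        nodes.append(TreeNode(-1, np.nan, -1, -1, float(yv.mean()), len(idx)))
        if parent >= 0:
            if side == "left":
                nodes[parent].left = node_id
            else:
                nodes[parent].right = node_id
        if len(idx) < min_split or np.ptp(yv) <= 0:
            continue
        found = best_split(X[idx], yv)
        if found is None:
            continue
        f, thr, _ = found
        x = X[idx, f]
        miss = np.isnan(x)
        go_left = x <= thr
        n_left = int(go_left[~miss].sum())
        n_right = int((~go_left[~miss]).sum())
        missing_left = n_left >= n_right  # larger child; tie -> left
        go_left[miss] = missing_left
        nd = nodes[node_id]
        nd.feature, nd.threshold = f, thr
        nd.missing_to_left = missing_left
        # push right first so the left child is built (and numbered) first
        stack.append((idx[~go_left], node_id, "right"))
        stack.append((idx[go_left], node_id, "left"))
    return RegressionTree(nodes, names)
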