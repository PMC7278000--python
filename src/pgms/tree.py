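"""Weighted CART regression tree on a single feature.

This is the weak learner inside the boosting ensemble: greedy binary
splits minimizing weighted squared error, leaf value = weighted mean of
the targets.  Growth stops at ``max_depth``, at fewer than two examples,
or when no split reduces the weighted SSE (e.g. constant targets or all
features equal, which yield a single-leaf tree rather than an error).

Split thresholds are placed at the midpoint between adjacent distinct
feature values; a query goes left when ``x <= threshold``.  Among splits
with equal criterion the lowest threshold wins, so fitting is fully
deterministic.  The hot loops are numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _grow(xs, ys, ws, max_depth):  # pragma: no cover - compiled
    n = xs.shape[0]
    max_nodes = 2 * n + 1
    thresh = np.zeros(max_nodes)
    value = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    stack = np.empty((max_nodes, 4), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = 0
    sp = 1
    node_count = 1
    while sp > 0:
        sp -= 1
        s = stack[sp, 0]
        e = stack[sp, 1]
        depth = stack[sp, 2]
        nid = stack[sp, 3]
        m = e - s
        W = 0.0
        S = 0.0
        for i in range(s, e):
            W += ws[i]
            S += ws[i] * ys[i]
        value[nid] = S / W
        if depth >= max_depth or m < 2:
            continue
        ymin = ys[s]
        ymax = ys[s]
        for i in range(s + 1, e):
            if ys[i] < ymin:
                ymin = ys[i]
            if ys[i] > ymax:
                ymax = ys[i]
        if ymin == ymax:
            continue
        base = S * S / W
        best_proxy = base
        best_p = -1
        cw = 0.0
        cs = 0.0
        for i in range(s, e - 1):
            cw += ws[i]
            cs += ws[i] * ys[i]
            if xs[i] == xs[i + 1] or cw <= 0.0 or W - cw <= 0.0:
                continue
            rw = W - cw
            rsum = S - cs
            proxy = cs * cs / cw + rsum * rsum / rw
            if proxy > best_proxy:
                best_proxy = proxy
                best_p = i + 1
        if best_p < 0:
            continue
        t = 0.5 * (xs[best_p - 1] + xs[best_p])
        if t == xs[best_p]:
            t = xs[best_p - 1]
        thresh[nid] = t
        lid = node_count
        rid = node_count + 1
        node_count += 2
        left[nid] = lid
        right[nid] = rid
        stack[sp, 0] = s
        stack[sp, 1] = best_p
        stack[sp, 2] = depth + 1
        stack[sp, 3] = lid
        sp += 1
        stack[sp, 0] = best_p
        stack[sp, 1] = e
        stack[sp, 2] = depth + 1
        stack[sp, 3] = rid
        sp += 1
    return (
        left[:node_count].copy(),
        right[:node_count].copy(),
        thresh[:node_count].copy(),
        value[:node_count].copy(),
    )


@njit(cache=True)
def _predict(left, right, thresh, value, xq):  # pragma: no cover - compiled
    out = np.empty(xq.shape[0])
    for i in range(xq.shape[0]):
        nid = 0
        while left[nid] >= 0:
            if xq[i] <= thresh[nid]:
                nid = left[nid]
            else:
                nid = right[nid]
        out[i] = value[nid]
    return out


class RegressionTree:
    """Single-feature weighted regression tree.

    Parameters
    ----------
    max_depth : int
        Maximum tree depth; depth 0 is a bare weighted mean.
    """

    def __init__(self, max_depth: int = 10):
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        self.max_depth = int(max_depth)
        self._arrays = None

    def fit(self, x, y, sample_weight=None) -> "RegressionTree":
        x = np.ascontiguousarray(x, dtype=np.float64).ravel()
        y = np.ascontiguousarray(y, dtype=np.float64).ravel()
        if x.size != y.size or x.size == 0:
            raise ValueError("x and y must be non-empty and aligned")
        if sample_weight is None:
            w = np.ones_like(x)
        else:
            w = np.ascontiguousarray(sample_weight, dtype=np.float64).ravel()
            if w.size != x.size or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("invalid sample weights")
        order = np.argsort(x, kind="mergesort")
        self._arrays = _grow(x[order], y[order], w[order], self.max_depth)
        return self

    def predict(self, x) -> np.ndarray:
        if self._arrays is None:
            raise RuntimeError("tree is not fitted")
        xq = np.ascontiguousarray(np.atleast_1d(x), dtype=np.float64)
        return _predict(*self._arrays, xq)

    @property
    def n_nodes(self) -> int:
        return 0 if self._arrays is None else self._arrays[0].size

    def to_dict(self) -> dict:
        left, right, thresh, value = self._arrays
        return {
            "max_depth": self.max_depth,
            "left": left.tolist(),
            "right": right.tolist(),
            "threshold": thresh.tolist(),
            "value": value.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RegressionTree":
        tree = cls(max_depth=payload["max_depth"])
        tree._arrays = (
            np.asarray(payload["left"], dtype=np.int64),
            np.asarray(payload["right"], dtype=np.int64),
            np.asarray(payload["threshold"], dtype=np.float64),
            np.asarray(payload["value"], dtype=np.float64),
        )
        return tree
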