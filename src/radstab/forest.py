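"""A compact random decision forest for small tabular cohorts.

Binary-classification CART forest (Gini splitting, bootstrap resampling,
``sqrt(d)`` candidate features per node, trees grown to purity) implemented
with numba so that leave-one-out schemes requiring tens of thousands of
forest fits on cohorts of under ~100 lesions stay interactive.  The forest
natively exposes the two canonical importances:

* mean decrease Gini (MDG): bootstrap-weighted impurity decrease credited to
  the split feature, averaged over trees (unnormalized);
* mean decrease accuracy (MDA): per-tree out-of-bag accuracy drop after
  permuting one feature's OOB values, averaged over trees.

The prediction score of the forest is the fraction of trees voting for the
positive class (a tied leaf contributes half a vote).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RandomDecisionForest"]


@njit(cache=True)
def _fit_forest(X, y, n_trees, mtry, seed):  # pragma: no cover - jitted
    n, d = X.shape
    max_nodes = 2 * n - 1 if n > 1 else 1
    feat_arr = np.full((n_trees, max_nodes), -1, np.int64)
    thr_arr = np.zeros((n_trees, max_nodes))
    left_arr = np.full((n_trees, max_nodes), -1, np.int64)
    right_arr = np.full((n_trees, max_nodes), -1, np.int64)
    vote_arr = np.zeros((n_trees, max_nodes))
    n_nodes = np.zeros(n_trees, np.int64)
    inbag = np.zeros((n_trees, n), np.int64)
    mdg = np.zeros(d)

    idx = np.empty(n, np.int64)
    buf = np.empty(n, np.int64)
    pool = np.arange(d)
    node_stack = np.empty(max_nodes, np.int64)
    s_stack = np.empty(max_nodes, np.int64)
    e_stack = np.empty(max_nodes, np.int64)

    np.random.seed(seed)
    for t in range(n_trees):
        boot = np.random.randint(0, n, n)
        for b in boot:
            inbag[t, b] += 1
        Xb = X[boot]
        yb = y[boot]
        for i in range(n):
            idx[i] = i
        n_used = 1
        top = 0
        node_stack[0] = 0
        s_stack[0] = 0
        e_stack[0] = n
        while top >= 0:
            node = node_stack[top]
            s = s_stack[top]
            e = e_stack[top]
            top -= 1
            m = e - s
            pos = 0
            for i in range(s, e):
                pos += yb[idx[i]]
            if m < 2 or pos == 0 or pos == m:
                if 2 * pos > m:
                    vote_arr[t, node] = 1.0
                elif 2 * pos < m:
                    vote_arr[t, node] = 0.0
                else:
                    vote_arr[t, node] = 0.5
                continue
            p1 = pos / m
            imp = 2.0 * p1 * (1.0 - p1)
            best_gain = -1.0
            best_f = -1
            best_thr = 0.0
            # draw mtry distinct candidate features (partial Fisher-Yates)
            for k in range(mtry):
                j = k + np.random.randint(0, d - k)
                tmp = pool[k]
                pool[k] = pool[j]
                pool[j] = tmp
            for k in range(mtry):
                f = pool[k]
                vals = np.empty(m)
                labs = np.empty(m, np.int64)
                for i in range(m):
                    vals[i] = Xb[idx[s + i], f]
                order = np.argsort(vals, kind="mergesort")
                for i in range(m):
                    labs[i] = yb[idx[s + order[i]]]
                cum_pos = 0
                for i in range(1, m):
                    cum_pos += labs[i - 1]
                    v_prev = vals[order[i - 1]]
                    v_cur = vals[order[i]]
                    if v_cur <= v_prev:
                        continue
                    nl = i
                    nr = m - i
                    pl = cum_pos / nl
                    pr = (pos - cum_pos) / nr
                    child = (
                        nl * 2.0 * pl * (1.0 - pl) + nr * 2.0 * pr * (1.0 - pr)
                    ) / m
                    gain = imp - child
                    if gain > best_gain + 1e-15:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (v_prev + v_cur)
            if best_f < 0:
                # all candidate features constant on this node
                if 2 * pos > m:
                    vote_arr[t, node] = 1.0
                elif 2 * pos < m:
                    vote_arr[t, node] = 0.0
                else:
                    vote_arr[t, node] = 0.5
                continue
            # stable partition of idx[s:e] by the chosen split
            nl = 0
            for i in range(s, e):
                if Xb[idx[i], best_f] <= best_thr:
                    buf[nl] = idx[i]
                    nl += 1
            nr = nl
            for i in range(s, e):
                if Xb[idx[i], best_f] > best_thr:
                    buf[nr] = idx[i]
                    nr += 1
            for i in range(m):
                idx[s + i] = buf[i]
            lid = n_used
            rid = n_used + 1
            n_used += 2
            feat_arr[t, node] = best_f
            thr_arr[t, node] = best_thr
            left_arr[t, node] = lid
            right_arr[t, node] = rid
            mdg[best_f] += (m / n) * best_gain
            top += 1
            node_stack[top] = lid
            s_stack[top] = s
            e_stack[top] = s + nl
            top += 1
            node_stack[top] = rid
            s_stack[top] = s + nl
            e_stack[top] = e
        n_nodes[t] = n_used
    mdg /= n_trees
    return feat_arr, thr_arr, left_arr, right_arr, vote_arr, n_nodes, inbag, mdg


@njit(cache=True)
def _predict_votes(feat_arr, thr_arr, left_arr, right_arr, vote_arr, X):  # pragma: no cover
    n_trees = feat_arr.shape[0]
    n = X.shape[0]
    out = np.zeros(n)
    for t in range(n_trees):
        for i in range(n):
            node = 0
            while feat_arr[t, node] >= 0:
                if X[i, feat_arr[t, node]] <= thr_arr[t, node]:
                    node = left_arr[t, node]
                else:
                    node = right_arr[t, node]
            out[i] += vote_arr[t, node]
    return out / n_trees


@njit(cache=True)
def _oob_mda(feat_arr, thr_arr, left_arr, right_arr, vote_arr, inbag, X, y, seed):  # pragma: no cover
    n_trees, n = inbag.shape
    d = X.shape[1]
    imp = np.zeros(d)
    used = np.zeros(d, np.int64)
    np.random.seed(seed)
    for t in range(n_trees):
        n_oob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                n_oob += 1
        if n_oob == 0:
            continue
        oob = np.empty(n_oob, np.int64)
        j = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob[j] = i
                j += 1
        # features this tree actually splits on
        for f in range(d):
            used[f] = 0
        for nd in range(feat_arr.shape[1]):
            f = feat_arr[t, nd]
            if f >= 0:
                used[f] = 1
        base_correct = 0.0
        for i in range(n_oob):
            node = 0
            row = oob[i]
            while feat_arr[t, node] >= 0:
                if X[row, feat_arr[t, node]] <= thr_arr[t, node]:
                    node = left_arr[t, node]
                else:
                    node = right_arr[t, node]
            pred = 1 if vote_arr[t, node] > 0.5 else 0
            if pred == y[row]:
                base_correct += 1.0
        base_acc = base_correct / n_oob
        for f in range(d):
            if used[f] == 0:
                continue
            perm = np.empty(n_oob)
            for i in range(n_oob):
                perm[i] = X[oob[i], f]
            np.random.shuffle(perm)
            correct = 0.0
            for i in range(n_oob):
                row = oob[i]
                node = 0
                while feat_arr[t, node] >= 0:
                    fn = feat_arr[t, node]
                    v = perm[i] if fn == f else X[row, fn]
                    if v <= thr_arr[t, node]:
                        node = left_arr[t, node]
                    else:
                        node = right_arr[t, node]
                pred = 1 if vote_arr[t, node] > 0.5 else 0
                if pred == y[row]:
                    correct += 1.0
            imp[f] += base_acc - correct / n_oob
    return imp / n_trees


class RandomDecisionForest:
    """Bootstrap ensemble of Gini CART trees for binary classification.

    Parameters
    ----------
    n_trees:
        Ensemble size.
    seed:
        Seed for bootstrap resampling and per-node feature subsampling.
    mtry:
        Candidate features per node; defaults to ``round(sqrt(d))``.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0, mtry: int | None = None):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = int(n_trees)
        self.seed = int(seed) & 0x7FFFFFFF
        self.mtry = mtry
        self._fitted = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomDecisionForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.int64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        d = X.shape[1]
        mtry = self.mtry if self.mtry is not None else max(1, int(round(np.sqrt(d))))
        mtry = min(mtry, d)
        self._fitted = _fit_forest(X, y, self.n_trees, mtry, self.seed)
        self._X = X
        self._y = y
        return self

    def _require_fitted(self):
        if self._fitted is None:
            raise RuntimeError("forest is not fitted")
        return self._fitted

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for the positive class, per row of X."""
        feat, thr, left, right, vote, *_ = self._require_fitted()
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _predict_votes(feat, thr, left, right, vote, X)

    @property
    def mean_decrease_gini(self) -> np.ndarray:
        """Per-feature impurity decrease averaged over trees (unnormalized)."""
        return self._require_fitted()[7].copy()

    def oob_mean_decrease_accuracy(self, seed: int | None = None) -> np.ndarray:
        """Out-of-bag permutation importance, averaged over trees."""
        feat, thr, left, right, vote, _, inbag, _ = self._require_fitted()
        s = self.seed + 1 if seed is None else int(seed) & 0x7FFFFFFF
        return _oob_mda(feat, thr, left, right, vote, inbag, self._X, self._y, s)
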