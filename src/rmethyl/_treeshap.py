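"""Exact interventional Shapley values for decision-tree ensembles.

For a single tree, a foreground sample ``x`` and one background sample ``z``,
the coalition function is ``f(S) = tree(w)`` where ``w`` takes its entries
from ``x`` on features in ``S`` and from ``z`` elsewhere.  A leaf with value
``v`` is reached exactly when the coalition contains every feature whose
splits on the leaf's path are satisfied only by ``x`` (the set ``A``) and
excludes every feature satisfied only by ``z`` (the set ``B``); features
satisfied by both are irrelevant and features satisfied by neither make the
leaf unreachable.  For such an AND-game the Shapley value has the closed
form

    phi_i = +v * (|A|-1)! |B|! / (|A|+|B|)!   for i in A
    phi_i = -v * |A|! (|B|-1)! / (|A|+|B|)!   for i in B

Summing leaf contributions gives exact per-feature attributions whose total
telescopes to ``tree(x) - tree(z)``; averaging over a background set and
over the trees of a forest therefore satisfies local accuracy exactly:
``sum(phi) = model(x) - mean(model(Z))``.

The traversal below visits only branches reachable by ``x`` or ``z`` (at a
split where both go the same way the other branch is unreachable for every
coalition) and keeps per-feature consistency states with an undo log, so a
pair costs O(visited leaves * path length).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# per-feature consistency states
_UNSEEN, _CONSISTENT, _VIOLATED = 0, 1, 2


@njit(cache=True)
def _accumulate_tree(children_left, children_right, split_feature, threshold,
                     leaf_value, X, Z, phi, fact):  # pragma: no cover - jitted
    n_samples, n_features = X.shape
    n_background = Z.shape[0]
    n_nodes = children_left.shape[0]
    cap = 3 * n_nodes + 8

    xstat = np.zeros(n_features, dtype=np.int8)
    zstat = np.zeros(n_features, dtype=np.int8)
    path = np.empty(n_nodes + 1, dtype=np.int64)
    log_feat = np.empty(cap, dtype=np.int64)
    log_oldx = np.empty(cap, dtype=np.int8)
    log_oldz = np.empty(cap, dtype=np.int8)
    log_new = np.empty(cap, dtype=np.int8)
    st_kind = np.empty(cap, dtype=np.int8)  # 0 = enter node, 1 = undo
    st_node = np.empty(cap, dtype=np.int64)
    st_feat = np.empty(cap, dtype=np.int64)
    st_xc = np.empty(cap, dtype=np.int8)
    st_zc = np.empty(cap, dtype=np.int8)

    scale = 1.0 / n_background
    for i in range(n_samples):
        x = X[i]
        for j in range(n_background):
            z = Z[j]
            sp = 0
            lp = 0
            pl = 0
            st_kind[sp] = 0
            st_node[sp] = 0
            st_feat[sp] = -1
            sp += 1
            while sp > 0:
                sp -= 1
                kind = st_kind[sp]
                node = st_node[sp]
                f = st_feat[sp]
                xc = st_xc[sp]
                zc = st_zc[sp]
                if kind == 1:
                    lp -= 1
                    ff = log_feat[lp]
                    if log_new[lp] == 1:
                        pl -= 1
                    xstat[ff] = log_oldx[lp]
                    zstat[ff] = log_oldz[lp]
                    continue
                blocked = False
                if f >= 0:
                    log_feat[lp] = f
                    log_oldx[lp] = xstat[f]
                    log_oldz[lp] = zstat[f]
                    was_new = xstat[f] == _UNSEEN and zstat[f] == _UNSEEN
                    log_new[lp] = 1 if was_new else 0
                    lp += 1
                    if was_new:
                        path[pl] = f
                        pl += 1
                    if xstat[f] == _UNSEEN:
                        xstat[f] = xc
                    elif xstat[f] == _CONSISTENT and xc == _VIOLATED:
                        xstat[f] = _VIOLATED
                    if zstat[f] == _UNSEEN:
                        zstat[f] = zc
                    elif zstat[f] == _CONSISTENT and zc == _VIOLATED:
                        zstat[f] = _VIOLATED
                    if xstat[f] == _VIOLATED and zstat[f] == _VIOLATED:
                        blocked = True
                    st_kind[sp] = 1  # schedule the undo below this subtree
                    st_node[sp] = node
                    st_feat[sp] = f
                    sp += 1
                if blocked:
                    continue
                if children_left[node] < 0:  # leaf
                    v = leaf_value[node]
                    a = 0
                    b = 0
                    for t in range(pl):
                        ff = path[t]
                        if xstat[ff] == _CONSISTENT and zstat[ff] == _VIOLATED:
                            a += 1
                        elif xstat[ff] == _VIOLATED and zstat[ff] == _CONSISTENT:
                            b += 1
                    if a + b > 0:
                        denom = fact[a + b]
                        w_a = v * fact[a - 1] * fact[b] / denom if a > 0 else 0.0
                        w_b = v * fact[a] * fact[b - 1] / denom if b > 0 else 0.0
                        for t in range(pl):
                            ff = path[t]
                            if xstat[ff] == _CONSISTENT and zstat[ff] == _VIOLATED:
                                phi[i, ff] += scale * w_a
                            elif xstat[ff] == _VIOLATED and zstat[ff] == _CONSISTENT:
                                phi[i, ff] -= scale * w_b
                    continue
                fs = split_feature[node]
                thr = threshold[node]
                x_left = x[fs] <= thr
                z_left = z[fs] <= thr
                if x_left == z_left:
                    child = children_left[node] if x_left else children_right[node]
                    st_kind[sp] = 0
                    st_node[sp] = child
                    st_feat[sp] = fs
                    st_xc[sp] = _CONSISTENT
                    st_zc[sp] = _CONSISTENT
                    sp += 1
                else:
                    st_kind[sp] = 0
                    st_node[sp] = children_right[node]
                    st_feat[sp] = fs
                    st_xc[sp] = _CONSISTENT if not x_left else _VIOLATED
                    st_zc[sp] = _CONSISTENT if not z_left else _VIOLATED
                    sp += 1
                    st_kind[sp] = 0
                    st_node[sp] = children_left[node]
                    st_feat[sp] = fs
                    st_xc[sp] = _CONSISTENT if x_left else _VIOLATED
                    st_zc[sp] = _CONSISTENT if z_left else _VIOLATED
                    sp += 1


def _leaf_probabilities(tree) -> np.ndarray:
    """Positive-class probability stored at every node of a fitted tree."""
    value = tree.tree_.value  # (n_nodes, 1, n_classes), counts or fractions
    totals = value[:, 0, :].sum(axis=1)
    return value[:, 0, 1] / np.where(totals > 0, totals, 1.0)


def tree_ensemble_shap(estimator, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact interventional Shapley values of a fitted tree or forest.

    Attributions target the positive-class probability.  Returns an
    ``(n_samples, n_features)`` array such that for every row
    ``base + phi.sum() == predict_proba(x)[1]`` with
    ``base = predict_proba(background)[:, 1].mean()``, up to float error.
    """
    trees = getattr(estimator, "estimators_", [estimator])
    # sklearn trees compare float32-cast inputs against float64 thresholds;
    # mirror that cast so threshold-equality cases route identically
    X = np.ascontiguousarray(X, dtype=np.float32).astype(np.float64)
    Z = np.ascontiguousarray(background, dtype=np.float32).astype(np.float64)
    if X.shape[1] != Z.shape[1]:
        raise ValueError("foreground and background widths differ")
    if Z.shape[0] == 0:
        raise ValueError("background must not be empty")
    phi = np.zeros(X.shape, dtype=np.float64)
    # |A| + |B| is bounded by the longest root-to-leaf path, so factorials
    # stay far below the float64 overflow point for any reasonable tree
    max_depth = max(fitted.tree_.max_depth for fitted in trees)
    fact = np.ones(max_depth + 2, dtype=np.float64)
    for n in range(1, fact.shape[0]):
        fact[n] = fact[n - 1] * n
    for fitted in trees:
        t = fitted.tree_
        _accumulate_tree(
            t.children_left.astype(np.int64),
            t.children_right.astype(np.int64),
            t.feature.astype(np.int64),
            t.threshold.astype(np.float64),
            _leaf_probabilities(fitted),
            X, Z, phi, fact,
        )
    return phi / len(trees)
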