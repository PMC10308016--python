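"""Heterogeneous-mixture learning surrogate.

Learns a :class:`~weightmix.model.PiecewiseLinearModel` from one-year weight
transitions: a binary gating tree over {BMI, age, sex} grown by greedy
top-down search, with a sparse forward-selection OLS model in every leaf.
Both the split decision and the leaf sparsity use one penalized Gaussian
log-likelihood criterion with a component-local BIC penalty — each selected
parameter of a child leaf is charged ``log(n_child) / 2`` — standing in for
the factorized-Bayesian machinery of the proprietary original.  What is
reproduced is the behavioural contract: the number of splits and the
per-leaf variable selection are chosen automatically by the criterion.

Implementation notes
--------------------
Leaf fits operate on Gram matrices (``X'X``, ``X'y``, ``y'y``) so that the
threshold scan at a node can reuse prefix sums of per-bin Grams: scoring all
~64 quantile thresholds of a gate feature costs one pass over the node's
rows plus cheap order-recursive updates per threshold.  The brute-force
oracle re-derives the same criterion through plain ``lstsq`` fits and is
used in tests as an independent check of the greedy step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular

from .features import TrainingTable
from .model import GateRule, LeafFormula, PiecewiseLinearModel

_RSS_FLOOR = 1e-10  # per-row floor on sigma^2, guards exact interpolation


@dataclass
class FitConfig:
    max_depth: int = 3
    min_leaf_n: int = 200
    gate_candidates: tuple = ("bmi", "age", "sex")
    threshold_grid: int = 64
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.min_leaf_n < 2 + n_features:
            raise ValueError(
                f"min_leaf_n={self.min_leaf_n} too small for {n_features} "
                f"candidate features (need >= {2 + n_features})")
        if self.threshold_grid < 2:
            raise ValueError("threshold_grid must be >= 2")


@dataclass
class SplitCandidate:
    feature: str
    threshold: Optional[float] = None  # None for the sex gate
    gain: Optional[float] = None
    feasible: bool = True


@dataclass
class FitResult:
    model: PiecewiseLinearModel
    trace: list = field(default_factory=list)   # per-node criterion records
    n_per_leaf: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


# --------------------------------------------------------------------------
# penalized criterion

def penalized_loglik(rss: float, n: int, k_params: int) -> float:
    """Gaussian profile log-likelihood minus (k_params + 1) * log(n) / 2.

    ``k_params`` counts the regression parameters (intercept included); the
    extra +1 charges the residual variance.  ``n`` is the component-local
    sample size.
    """
    sigma2 = max(rss, _RSS_FLOOR * n) / n
    return (-0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
            - 0.5 * (k_params + 1) * math.log(n))


# --------------------------------------------------------------------------
# forward selection on Gram matrices

def _forward_select_gram(G, g, yy, n):
    """Forward-selection sparse OLS from Gram matrices.

    Column 0 of the design is the (always-included) intercept.  Features are
    added greedily by RSS reduction while the penalized criterion improves.
    Returns ``(selected, beta, rss, pll)`` with ``selected`` the design
    columns in inclusion order and ``beta`` their coefficients.
    """
    p = G.shape[0]
    S = [0]
    L = np.array([[math.sqrt(G[0, 0])]])
    w = np.array([g[0] / L[0, 0]])
    rss = max(yy - w @ w, 0.0)
    pll = penalized_loglik(rss, n, 1)
    cand = np.arange(1, p)
    while cand.size and len(S) < n - 1:
        Z = solve_triangular(L, G[np.ix_(S, cand)], lower=True,
                             check_finite=False)
        d = G[cand, cand] - np.einsum("ij,ij->j", Z, Z)
        ok = d > 1e-9 * (G[cand, cand] + 1.0)
        resid = g[cand] - Z.T @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(ok, resid * resid / d, -np.inf)
        j_rel = int(np.argmax(delta))
        if not np.isfinite(delta[j_rel]):
            break
        rss_new = max(rss - delta[j_rel], 0.0)
        pll_new = penalized_loglik(rss_new, n, len(S) + 1)
        if pll_new <= pll:
            break
        j = int(cand[j_rel])
        zj = Z[:, j_rel]
        dj = math.sqrt(d[j_rel])
        k = L.shape[0]
        L_new = np.zeros((k + 1, k + 1))
        L_new[:k, :k] = L
        L_new[k, :k] = zj
        L_new[k, k] = dj
        L = L_new
        w = np.append(w, resid[j_rel] / dj)
        S.append(j)
        rss, pll = rss_new, pll_new
        cand = np.delete(cand, j_rel)
    beta = solve_triangular(L.T, w, lower=False, check_finite=False)
    return S, beta, rss, pll


def _gram(X1, y):
    return X1.T @ X1, X1.T @ y, float(y @ y)


def fit_leaf_regression(X, y, config: FitConfig, feature_names,
                        formula_id: int = 0) -> LeafFormula:
    """Sparse OLS leaf: forward selection under the penalized criterion.

    Unselected features are exact zeros (absent from ``terms``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < config.min_leaf_n:
        raise ValueError(
            f"leaf fit needs >= min_leaf_n={config.min_leaf_n} rows, "
            f"got {X.shape[0]}")
    X1 = np.hstack([np.ones((X.shape[0], 1)), X])
    G, g, yy = _gram(X1, y)
    S, beta, _, _ = _forward_select_gram(G, g, yy, X.shape[0])
    bias = float(beta[0])
    terms = {feature_names[j - 1]: float(b)
             for j, b in zip(S[1:], beta[1:])}
    return LeafFormula(formula_id=formula_id, bias=bias, terms=terms)


# --------------------------------------------------------------------------
# split scoring

def _node_pll(X1, y):
    G, g, yy = _gram(X1, y)
    S, beta, rss, pll = _forward_select_gram(G, g, yy, X1.shape[0])
    return S, beta, rss, pll


def score_split(X, y, gate_values, candidate: SplitCandidate,
                config: FitConfig):
    """Criterion gain of one candidate split at a node.

    ``gate_values`` are the candidate feature's values for the node's rows
    (for the sex gate: the male indicator).  Returns the gain
    ``pll(left) + pll(right) − pll(parent)``; an undersized child marks the
    candidate infeasible (gain −inf), it does not raise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gate_values = np.asarray(gate_values, dtype=float)
    thr = 1.0 if candidate.threshold is None else candidate.threshold
    right = gate_values >= thr
    n_r = int(right.sum())
    n_l = int(right.size - n_r)
    if min(n_l, n_r) < config.min_leaf_n:
        candidate.feasible = False
        candidate.gain = -np.inf
        return -np.inf
    X1 = np.hstack([np.ones((X.shape[0], 1)), X])
    _, _, _, pll_parent = _node_pll(X1, y)
    _, _, _, pll_l = _node_pll(X1[~right], y[~right])
    _, _, _, pll_r = _node_pll(X1[right], y[right])
    candidate.gain = float(pll_l + pll_r - pll_parent)
    candidate.feasible = True
    return candidate.gain


# --------------------------------------------------------------------------
# greedy partition fitting

def _candidate_thresholds(vals, feature, config):
    if feature == "sex":
        return np.array([1.0])
    qs = np.arange(1, config.threshold_grid) / config.threshold_grid
    thr = np.unique(np.quantile(vals, qs))
    return thr[thr > vals.min()]


def _scan_gate_feature(X1, y, vals, thresholds, min_leaf_n):
    """Best (threshold, gain, children pll) for one gate feature at a node,
    via prefix-summed per-segment Gram matrices."""
    n = y.shape[0]
    order = np.argsort(vals, kind="stable")
    Xs, ys = X1[order], y[order]
    vs = vals[order]
    n_left = np.searchsorted(vs, thresholds, side="left")
    feasible = (n_left >= min_leaf_n) & (n - n_left >= min_leaf_n)
    if not feasible.any():
        return None
    cuts = np.unique(np.concatenate([[0], n_left[feasible], [n]]))
    seg_G = np.empty((len(cuts) - 1, X1.shape[1], X1.shape[1]))
    seg_g = np.empty((len(cuts) - 1, X1.shape[1]))
    seg_yy = np.empty(len(cuts) - 1)
    for i, (a, b) in enumerate(zip(cuts[:-1], cuts[1:])):
        seg_G[i] = Xs[a:b].T @ Xs[a:b]
        seg_g[i] = Xs[a:b].T @ ys[a:b]
        seg_yy[i] = ys[a:b] @ ys[a:b]
    cum_G = np.cumsum(seg_G, axis=0)
    cum_g = np.cumsum(seg_g, axis=0)
    cum_yy = np.cumsum(seg_yy)
    G_tot, g_tot, yy_tot = cum_G[-1], cum_g[-1], cum_yy[-1]
    cut_of = {c: i for i, c in enumerate(cuts[1:])}

    best = None
    for thr, nl, feas in zip(thresholds, n_left, feasible):
        if not feas:
            continue
        i = cut_of[nl]
        GL, gL, yyL = cum_G[i], cum_g[i], cum_yy[i]
        _, _, _, pll_l = _forward_select_gram(GL, gL, yyL, nl)
        _, _, _, pll_r = _forward_select_gram(G_tot - GL, g_tot - gL,
                                              yy_tot - yyL, n - nl)
        total = pll_l + pll_r
        if best is None or total > best[1]:
            best = (float(thr), total)
    return best


def fit_partition(table: TrainingTable, config: FitConfig) -> FitResult:
    """Greedy top-down gating-tree fit with sparse OLS leaves.

    At every node all candidate (gate feature, threshold) pairs are scored;
    the max-gain candidate is accepted iff its gain is positive and the node
    is above ``max_depth``.  Ties break on the configured gate-candidate
    order, then on the lower threshold.  Deterministic given data and config.
    """
    if table.n == 0:
        raise ValueError("empty training table")
    p = table.X.shape[1]
    config.validate(p)
    X1 = np.hstack([np.ones((table.n, 1)), table.X])
    y = table.y
    gates = {f: table.gates[("sex_male" if f == "sex" else f)].to_numpy()
             for f in config.gate_candidates}
    result = FitResult(model=None)

    def grow(idx, depth):
        Xn, yn = X1[idx], y[idx]
        _, _, _, pll_parent = _node_pll(Xn, yn)
        node_rec = {"depth": depth, "n": int(idx.size),
                    "pll_parent": pll_parent, "accepted": None}
        best = None  # (feature, threshold, gain)
        if depth < config.max_depth and idx.size >= 2 * config.min_leaf_n:
            for feat in config.gate_candidates:
                vals = gates[feat][idx]
                thrs = _candidate_thresholds(vals, feat, config)
                if thrs.size == 0:
                    continue
                hit = _scan_gate_feature(Xn, yn, vals, thrs,
                                         config.min_leaf_n)
                if hit is None:
                    continue
                thr, total = hit
                gain = total - pll_parent
                if best is None or gain > best[2]:
                    best = (feat, thr, gain)
        if best is not None and best[2] > 0:
            feat, thr, gain = best
            node_rec["accepted"] = {"feature": feat, "threshold": thr,
                                    "gain": gain}
            result.trace.append(node_rec)
            right = gates[feat][idx] >= thr
            child_true = grow(idx[right], depth + 1)
            child_false = grow(idx[~right], depth + 1)
            if feat == "sex":
                return GateRule(feature="sex", op="eq", category="male",
                                if_true=child_true, if_false=child_false)
            return GateRule(feature=feat, op="ge", threshold=thr,
                            if_true=child_true, if_false=child_false)
        result.trace.append(node_rec)
        return ("leaf", idx)

    raw_tree = grow(np.arange(table.n), 0)

    # number leaves depth-first (condition-true branch first) and fit them
    leaves = {}
    counter = {"next": 1}

    def finalize(node):
        if isinstance(node, GateRule):
            node.if_true = finalize(node.if_true)
            node.if_false = finalize(node.if_false)
            return node
        _, idx = node
        lid = counter["next"]
        counter["next"] += 1
        leaves[lid] = fit_leaf_regression(table.X[idx], y[idx], config,
                                          table.feature_names, formula_id=lid)
        result.n_per_leaf[lid] = int(idx.size)
        return lid

    tree = finalize(raw_tree)
    result.model = PiecewiseLinearModel(
        tree=tree, leaves=leaves,
        meta={"version": "fit", "n_train": int(table.n),
              "gate_candidates": list(config.gate_candidates)})
    result.log.append(
        f"fit {len(leaves)} leaves from {table.n} transitions "
        f"(depth<={config.max_depth}, min_leaf_n={config.min_leaf_n})")
    return result


# --------------------------------------------------------------------------
# brute-force oracle (tests only)

def _naive_pll(X1, y):
    """Forward selection via repeated lstsq — independent of the Gram path."""
    n = X1.shape[0]
    S = [0]
    beta, rss = _naive_ols(X1[:, S], y)
    pll = penalized_loglik(rss, n, 1)
    cand = [j for j in range(1, X1.shape[1])]
    while cand and len(S) < n - 1:
        scores = []
        for j in cand:
            _, rss_j = _naive_ols(X1[:, S + [j]], y)
            scores.append(rss_j)
        j_rel = int(np.argmin(scores))
        pll_new = penalized_loglik(scores[j_rel], n, len(S) + 1)
        if pll_new <= pll:
            break
        S.append(cand.pop(j_rel))
        pll = pll_new
        rss = scores[j_rel]
    return pll


def _naive_ols(A, y):
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ beta
    return beta, float(r @ r)


def brute_force_best_split(X, y, gates, config: FitConfig):
    """Exhaustive enumeration of every candidate split at one node.

    Small instances only (<= 500 rows); serves as the greedy step's oracle.
    Returns the best SplitCandidate, or ``None`` when no candidate is
    feasible ("no split").
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] > 500:
        raise ValueError("brute-force oracle is limited to small instances")
    X1 = np.hstack([np.ones((X.shape[0], 1)), X])
    pll_parent = _naive_pll(X1, y)
    best = None
    for feat in config.gate_candidates:
        vals = np.asarray(gates[("sex_male" if feat == "sex" else feat)],
                          dtype=float)
        thrs = _candidate_thresholds(vals, feat, config)
        for thr in thrs:
            right = vals >= thr
            n_r, n_l = int(right.sum()), int((~right).sum())
            if min(n_l, n_r) < config.min_leaf_n:
                continue
            gain = (_naive_pll(X1[~right], y[~right])
                    + _naive_pll(X1[right], y[right]) - pll_parent)
            if best is None or gain > best.gain:
                best = SplitCandidate(
                    feature=feat,
                    threshold=None if feat == "sex" else float(thr),
                    gain=float(gain))
    return best
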