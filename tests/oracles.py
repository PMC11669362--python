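"""Independent brute-force oracles used to verify the package's statistics.

Everything here is deliberately naive (explicit loops, enumeration, scalar
optimization of a from-scratch likelihood) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def pairwise_auc(values, labels) -> float:
    """AUC by direct enumeration of responder/non-responder pairs."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def efron_loglik(beta: float, times, events, x) -> float:
    """Efron partial log-likelihood for a single covariate.

    Written directly from the definition: one boolean-mask risk set per
    distinct event time, no cumulative-sum machinery.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    w = np.exp(beta * x)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        deaths = (times == t) & (events == 1)
        at_risk = times >= t
        sum_r = float(w[at_risk].sum())
        sum_d = float(w[deaths].sum())
        d = int(deaths.sum())
        ll += float(beta * x[deaths].sum())
        for l in range(d):
            ll -= math.log(sum_r - (l / d) * sum_d)
    return ll


def gridsearch_cox_beta(times, events, x, lo=-6.0, hi=6.0) -> float:
    """Maximize the naive Efron likelihood: coarse grid, then local refinement.

    The partial log-likelihood is concave in beta, so a coarse unimodal grid
    plus bounded scalar refinement cannot miss the optimum."""
    grid = np.arange(lo, hi + 1e-9, 0.25)
    lls = [efron_loglik(b, times, events, x) for b in grid]
    best = grid[int(np.argmax(lls))]
    res = minimize_scalar(
        lambda b: -efron_loglik(b, times, events, x),
        bounds=(best - 0.5, best + 0.5),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def exhaustive_threshold_scan(values, times, events, min_frac=0.3, bound=15.0):
    """Scan every midpoint split meeting the per-group constraint; return
    (threshold, |ln HR|) of the best split by the naive Cox oracle.

    Splits whose likelihood optimum sticks to the search boundary have no
    finite maximizer (monotone likelihood) and are excluded, mirroring the
    definition of a valid split."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    min_group = math.ceil(min_frac * n)
    distinct = np.unique(values)
    best_thr, best_metric = None, -np.inf
    for thr in (distinct[:-1] + distinct[1:]) / 2.0:
        high = (values > thr).astype(float)
        if min(int(high.sum()), int(n - high.sum())) < min_group:
            continue
        beta = gridsearch_cox_beta(times, events, high, lo=-bound, hi=bound)
        if abs(beta) > bound - 1.0:
            continue
        metric = abs(beta)
        if metric > best_metric + 1e-12:
            best_metric = metric
            best_thr = float(thr)
    return best_thr, best_metric


def bfs_neighborhood(edges, center, radius):
    """Plain breadth-first enumeration of nodes within ``radius`` hops of
    ``center`` on the undirected version of a typed edge list."""
    adjacency: dict[str, set[str]] = {}
    for src, _typ, dst in edges:
        adjacency.setdefault(src, set()).add(dst)
        adjacency.setdefault(dst, set()).add(src)
    seen = {center: 0}
    frontier = [center]
    for depth in range(1, radius + 1):
        nxt = []
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb not in seen:
                    seen[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return seen


def gridsearch_logistic(x, y, bounds=(-10.0, 10.0), steps=2001):
    """Maximize the 1-feature logistic likelihood (with intercept) by
    alternating 1-d grid refinement; good to ~1e-3 in the slope."""

    def nll(b0, b1):
        eta = b0 + b1 * np.asarray(x)
        return float(np.sum(np.log1p(np.exp(-np.where(y == 1, eta, -eta)))))

    b0, b1 = 0.0, 0.0
    for _ in range(12):
        grid = np.linspace(*bounds, steps)
        b0 = grid[int(np.argmin([nll(g, b1) for g in grid]))]
        b1 = grid[int(np.argmin([nll(b0, g) for g in grid]))]
    return b0, b1


def product_limit(times, events):
    """Naive Kaplan-Meier: returns dict time -> survival after that time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    surv = 1.0
    out = {}
    for t in sorted(set(times)):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        if d:
            surv *= 1.0 - d / at_risk
        out[t] = surv
    return out
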