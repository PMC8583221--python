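"""Independent reference implementations used only to check the package.

These are deliberately naive (enumeration, brute force, hand formulas) and
share no code with the implementation under test.
"""
from __future__ import annotations

import itertools

import numpy as np


def assign_first_match(calls: dict[str, bool], rule_specs) -> str:
    """Brute-force rule scan: rule_specs = [(name, all_of, any_of, none_of)]."""
    for name, all_of, any_of, none_of in rule_specs:
        ok = all(calls[m] for m in all_of)
        if any_of:
            ok = ok and any(calls[m] for m in any_of)
        ok = ok and not any(calls[m] for m in none_of)
        if ok:
            return name
    return "other"


def mann_whitney_exact_p(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    m = n1 * n2

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    total = extreme = 0
    idx = range(n1 + n2)
    for comb in itertools.combinations(idx, n1):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in idx if i not in comb]]
        u = u_of(xs, ys)
        total += 1
        if u <= lo or u >= hi:
            extreme += 1
    return float(u_obs), extreme / total


def bh_stepup(p) -> np.ndarray:
    """Hand application of the BH step-up formula q_i = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        val = m * p[order[rank - 1]] / rank
        running = min(running, val)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pearson_chi2(table) -> float:
    """Direct Pearson statistic from the definition."""
    t = np.asarray(table, float)
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    return float(((t - expected) ** 2 / expected).sum())


def ward_merge_sequence(X) -> list[frozenset]:
    """Greedy Ward agglomeration evaluating every candidate merge each step.

    Returns the member set of each newly formed cluster, in merge order.
    """
    X = np.asarray(X, float)
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            A, B = clusters[a], clusters[b]
            ca, cb = X[A].mean(axis=0), X[B].mean(axis=0)
            cost = len(A) * len(B) / (len(A) + len(B)) * ((ca - cb) ** 2).sum()
            if best is None or cost < best[0]:
                best = (cost, a, b)
        _, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        merges.append(frozenset(merged))
        next_id += 1
    return merges


def linkage_merge_sequence(Z, n: int) -> list[frozenset]:
    """Member sets of each merge in a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Hand-coded partial log-likelihood for one covariate, no tied times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_mle(times, events, x, grid=None) -> float:
    grid = grid if grid is not None else np.arange(-5.0, 5.0, 1e-4)
    ll = [cox_partial_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(ll))])
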