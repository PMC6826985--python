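"""Independent brute-force oracles used across the suite.

Everything here is deliberately naive — exact integer combinatorics,
explicit BFS, per-cell tallies — and shares no code with the package
paths it checks.
"""
from __future__ import annotations

import math

import numpy as np


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by exhaustive enumeration with all margins fixed."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    hi = min(r1, c1)
    num = sum(math.comb(r1, i) * math.comb(n - r1, c1 - i) for i in range(a, hi + 1))
    return num / denom


def fisher_less(a: int, b: int, c: int, d: int) -> float:
    """P(X <= a) by exhaustive enumeration with all margins fixed."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    lo = max(0, c1 - (n - r1))
    num = sum(math.comb(r1, i) * math.comb(n - r1, c1 - i) for i in range(lo, a + 1))
    return num / denom


def hypergeom_upper(nall: int, na: int, nb: int, nab: int) -> float:
    """P(X >= nab) for X ~ Hypergeom(nall, na, nb), exact combinatorics."""
    denom = math.comb(nall, nb)
    hi = min(na, nb)
    num = sum(math.comb(na, i) * math.comb(nall - na, nb - i)
              for i in range(nab, hi + 1))
    return num / denom


def hypergeom_pmf0(nall: int, na: int, nb: int) -> float:
    return math.comb(nall - na, nb) / math.comb(nall, nb) if nb <= nall - na else 0.0


def bh_stepup(pvalues) -> np.ndarray:
    """Reference Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = running
    q = np.empty(n)
    q[order] = q_sorted
    return q


def k_ball(adjacency: dict, seed_genes, k: int) -> frozenset:
    """All genes within graph distance k of the seed set (BFS)."""
    frontier = set(seed_genes)
    seen = set(seed_genes)
    for _ in range(k):
        frontier = {w for v in frontier for w in adjacency.get(v, ())} - seen
        seen |= frontier
    return frozenset(seen)


def all_three_node_dags(nodes):
    """Every DAG on three labelled nodes, as parents dicts (25 of them)."""
    a, b, c = nodes
    pairs = [(a, b), (a, c), (b, c)]
    dags = []
    for states in np.ndindex(3, 3, 3):
        parents = {v: set() for v in nodes}
        for (u, v), st in zip(pairs, states):
            if st == 1:
                parents[v].add(u)
            elif st == 2:
                parents[u].add(v)
        if _is_acyclic(parents):
            dags.append({k: tuple(sorted(vs)) for k, vs in parents.items()})
    return dags


def _is_acyclic(parents: dict) -> bool:
    seen, done = set(), set()

    def visit(v):
        if v in done:
            return True
        if v in seen:
            return False
        seen.add(v)
        ok = all(visit(p) for p in parents[v])
        done.add(v)
        return ok

    return all(visit(v) for v in parents)


def dag_loglik_score(data: np.ndarray, names, parents: dict,
                     penalty_discount: float) -> float:
    """Penalised log-likelihood of a DAG, computed from scratch.

    data is samples x variables in the order of ``names``.
    """
    idx = {v: i for i, v in enumerate(names)}
    n = data.shape[0]
    total = 0.0
    for v in names:
        y = data[:, idx[v]]
        ps = parents[v]
        if ps:
            keys = [tuple(row) for row in data[:, [idx[p] for p in ps]]]
        else:
            keys = [()] * n
        cells: dict = {}
        for key, val in zip(keys, y):
            cells.setdefault(key, [0, 0])[val] += 1
        ll = 0.0
        for n0, n1 in cells.values():
            nc = n0 + n1
            for cnt in (n0, n1):
                if cnt:
                    ll += cnt * math.log(cnt / nc)
        total += ll - penalty_discount * (2 ** len(ps) / 2.0) * math.log(n)
    return total


def dag_v_structures(parents: dict) -> frozenset:
    """Colliders (a, b, c) with a->c<-b, a < b, a and b non-adjacent."""
    adjacent = set()
    for v, ps in parents.items():
        for u in ps:
            adjacent.add(frozenset({u, v}))
    out = set()
    for c, ps in parents.items():
        for a in ps:
            for b in ps:
                if a < b and frozenset({a, b}) not in adjacent:
                    out.add((a, b, c))
    return frozenset(out)


def dag_skeleton(parents: dict) -> frozenset:
    return frozenset(frozenset({u, v}) for v, ps in parents.items() for u in ps)
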