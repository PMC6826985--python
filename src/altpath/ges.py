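"""Greedy equivalence search over binary activity data.

Learns a condition-specific directed gene network from one group's
activity matrix. The search is the two-phase greedy equivalence search:
a forward phase that repeatedly applies the best score-improving Insert
operator and a backward phase that applies the best Delete operator,
both moving between Markov equivalence classes (CPDAGs). Operator
validity conditions and the local rescoring rules are the classical
ones; the equivalence class is re-completed after each move by
extending the modified PDAG to a DAG and recovering its pattern.

The local model is a saturated Bernoulli conditional table per node:
with parent set Pa the node contributes its maximised log-likelihood
minus a penalised dimension term

    score(v | Pa) = loglik - PD * (2^|Pa| / 2) * ln(n),

where PD is the penalty discount multiplying the BIC penalty
(TETRAD/pcalg convention; larger PD, sparser networks; default 6) and
n the number of samples. The score is decomposable and score-equivalent:
Markov-equivalent DAGs receive identical totals, so the search is well
defined on equivalence classes. ``depth`` caps the parent-set size
during Insert; -1 means unlimited.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivityProfile
from .graph import PDAG, Cpdag, dag_to_cpdag, empty_cpdag, pdag_to_dag

logger = logging.getLogger("altpath")

#: score-improvement threshold guarding against floating-point ties
_EPS = 1e-10
#: cap on the neighbour subsets enumerated per Insert/Delete candidate
_MAX_SUBSET = 8


@dataclass(frozen=True)
class GesConfig:
    """Search parameters: BIC penalty discount and in-degree cap."""

    penalty_discount: float = 6.0
    depth: int = -1

    def __post_init__(self) -> None:
        if self.penalty_discount <= 0:
            raise ValueError("penalty_discount must be positive")
        if self.depth < -1:
            raise ValueError("depth must be -1 (unlimited) or non-negative")


class _Scorer:
    """Decomposable penalised log-likelihood on a binary data matrix."""

    def __init__(self, data: np.ndarray, penalty_discount: float):
        if data.size == 0:
            raise ValueError("empty data")
        self.data = np.ascontiguousarray(data, dtype=np.int64)  # samples x vars
        self.n = data.shape[0]
        self.pd_ = penalty_discount
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, child: int, parents: tuple[int, ...]) -> float:
        parents = tuple(sorted(parents))
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if len(parents) > 12:
            raise ValueError("parent set too large to tabulate")
        y = self.data[:, child]
        if parents:
            idx = np.zeros(self.n, dtype=np.int64)
            for j, p in enumerate(parents):
                idx |= self.data[:, p] << j
            cells = np.bincount(idx * 2 + y, minlength=2 << len(parents))
            n0 = cells[0::2].astype(float)
            n1 = cells[1::2].astype(float)
        else:
            n1 = np.array([float(y.sum())])
            n0 = np.array([float(self.n - y.sum())])
        nc = n0 + n1
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(n1 > 0, n1 * np.log(np.where(n1 > 0, n1, 1) / np.where(nc > 0, nc, 1)), 0.0) \
               + np.where(n0 > 0, n0 * np.log(np.where(n0 > 0, n0, 1) / np.where(nc > 0, nc, 1)), 0.0)
        loglik = float(ll.sum())
        k = 2 ** len(parents)
        score = loglik - self.pd_ * (k / 2.0) * np.log(self.n)
        self._cache[key] = score
        return score


def bic_local_score(child: str, parents, profile: ActivityProfile,
                    penalty_discount: float = 6.0) -> float:
    """Penalised local score of ``child`` given ``parents`` on a profile.

    Convenience wrapper around the scorer the search uses; variables are
    genes (rows of the profile), observations are samples.
    """
    genes = list(profile.activity.index)
    data = profile.activity.to_numpy().T
    scorer = _Scorer(data, penalty_discount)
    index = {g: i for i, g in enumerate(genes)}
    if child not in index:
        raise ValueError(f"gene {child!r} not in profile")
    return scorer.local(index[child], tuple(index[g] for g in parents))


def _subsets(items, max_size):
    items = sorted(items)
    for r in range(min(len(items), max_size) + 1):
        yield from itertools.combinations(items, r)


class _Search:
    def __init__(self, nodes: list[str], scorer: _Scorer, config: GesConfig):
        self.nodes = nodes
        self.index = {v: i for i, v in enumerate(nodes)}
        self.scorer = scorer
        self.config = config
        self.pdag = PDAG(nodes)
        self.trace: list[float] = []

    # -- scoring helpers ----------------------------------------------
    def _delta(self, y: str, base: set[str], with_x: str) -> float:
        iy = self.index[y]
        base_idx = tuple(self.index[v] for v in base)
        new_idx = tuple(sorted(base_idx + (self.index[with_x],)))
        return self.scorer.local(iy, new_idx) - self.scorer.local(iy, base_idx)

    def total_score(self) -> float:
        """Score of a consistent extension of the current CPDAG."""
        parents = pdag_to_dag(self.pdag)
        return sum(self.scorer.local(self.index[v],
                                     tuple(self.index[u] for u in ps))
                   for v, ps in parents.items())

    # -- forward phase ------------------------------------------------
    def _best_insert(self):
        best = None
        p = self.pdag
        for y in self.nodes:
            na_all = p.und[y]
            for x in self.nodes:
                if x == y or p.adjacent(x, y):
                    continue
                na = {v for v in na_all if p.adjacent(v, x)}
                t_pool = {v for v in na_all if not p.adjacent(v, x)}
                for t in _subsets(t_pool, _MAX_SUBSET):
                    cond = na | set(t)
                    if not p.is_clique(cond):
                        continue
                    if p.has_semidirected_path(y, x, blocked=cond):
                        continue
                    new_parents = p.par[y] | cond | {x}
                    if self.config.depth >= 0 and len(new_parents) > self.config.depth:
                        continue
                    if len(new_parents) > 12:
                        continue
                    delta = self._delta(y, p.par[y] | cond, x)
                    if delta <= _EPS:
                        continue
                    key = (-delta, x, y, t)
                    if best is None or key < best[0]:
                        best = (key, x, y, t)
        return None if best is None else (-best[0][0], best[1], best[2], best[3])

    def _apply_insert(self, x: str, y: str, t) -> None:
        p = self.pdag
        p.add_directed(x, y)
        for v in t:
            p.orient(v, y)
        self._recomplete()

    # -- backward phase -----------------------------------------------
    def _best_delete(self):
        best = None
        p = self.pdag
        pairs = []
        for y in self.nodes:
            for x in p.par[y]:
                pairs.append((x, y))
            for x in p.und[y]:
                pairs.append((x, y))  # both orientations visited
        for x, y in pairs:
            na = {v for v in p.und[y] if p.adjacent(v, x)}
            for h in _subsets(na, _MAX_SUBSET):
                keep = na - set(h)
                if not p.is_clique(keep):
                    continue
                base = (p.par[y] | keep) - {x}
                delta = -self._delta(y, base, x)
                if delta <= _EPS:
                    continue
                key = (-delta, x, y, h)
                if best is None or key < best[0]:
                    best = (key, x, y, h)
        return None if best is None else (-best[0][0], best[1], best[2], best[3])

    def _apply_delete(self, x: str, y: str, h) -> None:
        p = self.pdag
        p.remove_edge(x, y)
        for v in h:
            if v in p.und[y]:
                p.orient(y, v)
            if v in p.und[x]:
                p.orient(x, v)
        self._recomplete()

    def _recomplete(self) -> None:
        parents = pdag_to_dag(self.pdag)
        cpdag = dag_to_cpdag(self.nodes, parents)
        self.pdag = PDAG.from_cpdag(cpdag)

    def run(self) -> Cpdag:
        self.trace.append(self.total_score())
        while True:
            best = self._best_insert()
            if best is None:
                break
            _, x, y, t = best
            self._apply_insert(x, y, t)
            self.trace.append(self.total_score())
        while True:
            best = self._best_delete()
            if best is None:
                break
            _, x, y, h = best
            self._apply_delete(x, y, h)
            self.trace.append(self.total_score())
        return self.pdag.to_cpdag()


def ges_fit(profile: ActivityProfile, config: GesConfig | None = None,
            return_trace: bool = False):
    """Learn the CPDAG of one condition's gene network.

    ``profile`` holds binary activity (genes x samples) for the samples
    of a single group. Constant genes carry no structural information
    and are dropped with a warning; they appear as isolated nodes in the
    result. Deterministic given the data (ties broken by lexicographic
    node order).
    """
    config = config or GesConfig()
    genes = list(profile.activity.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if len(profile.sample_ids) < 10:
        raise ValueError("need at least 10 samples")
    data = profile.activity.to_numpy().T  # samples x genes
    variable = data.std(axis=0) > 0
    if not variable.all():
        dropped = [g for g, keep in zip(genes, variable) if not keep]
        logger.warning("dropped %d constant gene(s) from structure search: %s",
                       len(dropped), ", ".join(dropped[:5]))
    active_genes = [g for g, keep in zip(genes, variable) if keep]
    if len(active_genes) < 2:
        result = empty_cpdag(genes)
        return (result, [0.0]) if return_trace else result
    scorer = _Scorer(data[:, variable], config.penalty_discount)
    search = _Search(active_genes, scorer, config)
    fitted = search.run()
    result = Cpdag(tuple(genes), fitted.directed, fitted.undirected)
    if return_trace:
        return result, search.trace
    return result


def load_network(path) -> Cpdag:
    """Read a CPDAG from an edge-list TSV (source, target, type).

    type is "directed" or "undirected"; contradictory duplicates (a
    2-cycle, or an edge listed both directed and undirected) are errors.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target", "type"):
        if col not in frame.columns:
            raise ValueError(f"network file lacks column {col!r}")
    directed, undirected, nodes = set(), set(), []
    seen_nodes = set()
    for _, row in frame.iterrows():
        u, v, kind = row["source"], row["target"], row["type"]
        for w in (u, v):
            if w not in seen_nodes:
                seen_nodes.add(w)
                nodes.append(w)
        if kind == "directed":
            if (v, u) in directed:
                raise ValueError(f"contradictory rows: 2-cycle {u!r}<->{v!r}")
            directed.add((u, v))
        elif kind == "undirected":
            undirected.add(frozenset({u, v}))
        else:
            raise ValueError(f"unknown edge type {kind!r}")
    clash = {frozenset(e) for e in directed} & undirected
    if clash:
        u, v = tuple(next(iter(clash)))
        raise ValueError(f"edge {u!r},{v!r} listed both directed and undirected")
    return Cpdag(tuple(nodes), frozenset(directed), frozenset(undirected))


def save_network(net: Cpdag, path) -> None:
    """Write a CPDAG as an edge-list TSV (source, target, type)."""
    rows = [{"source": u, "target": v, "type": "directed"}
            for u, v in sorted(net.directed)]
    rows += [{"source": u, "target": v, "type": "undirected"}
             for u, v in sorted(tuple(sorted(e)) for e in net.undirected)]
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
        path, sep="\t", index=False)
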