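"""Partially directed graphs for score-based structure learning.

A CPDAG (completed partially directed acyclic graph) represents a
Markov equivalence class of DAGs: directed edges are compelled —
oriented the same way in every member — and undirected edges are
reversible. The conversions here are the classical ones: a PDAG is
extended to a consistent DAG by repeatedly removing a node whose
undirected neighbours are adjacent to all its other neighbours
(Dor-Tarsi), and a DAG's equivalence class is recovered by keeping its
skeleton and v-structures and closing under the Meek orientation rules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


@dataclass(frozen=True)
class Cpdag:
    """Immutable CPDAG: node list, directed pairs and undirected pairs."""

    nodes: tuple[str, ...]
    directed: frozenset  # of (u, v) tuples, u -> v
    undirected: frozenset  # of frozenset({u, v})

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        und_pairs = set()
        for e in self.undirected:
            u, v = tuple(e)
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            und_pairs.add(e)
            if not {u, v} <= nodeset:
                raise ValueError(f"undirected edge {u!r}-{v!r} uses unknown node")
        for u, v in self.directed:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if not {u, v} <= nodeset:
                raise ValueError(f"directed edge {u!r}->{v!r} uses unknown node")
            if (v, u) in self.directed:
                raise ValueError(f"2-cycle between {u!r} and {v!r}")
            if frozenset({u, v}) in und_pairs:
                raise ValueError(f"edge {u!r},{v!r} is both directed and undirected")
        # the directed part must be acyclic
        PDAG.from_cpdag(self).topological_check()

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def skeleton(self) -> frozenset:
        return frozenset(frozenset({u, v}) for u, v in self.directed) | self.undirected

    def neighbors(self, v: str) -> set[str]:
        out = set()
        for a, b in self.directed:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        for e in self.undirected:
            if v in e:
                out |= set(e) - {v}
        return out

    def v_structures(self) -> frozenset:
        """Colliders a->c<-b with a, b non-adjacent, as (a, b, c), a<b."""
        par: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.directed:
            par[v].add(u)
        skel = self.skeleton()
        out = set()
        for c, ps in par.items():
            for a in ps:
                for b in ps:
                    if a < b and frozenset({a, b}) not in skel:
                        out.add((a, b, c))
        return frozenset(out)


class PDAG:
    """Mutable partially directed graph used inside the search."""

    def __init__(self, nodes: Iterable[str]):
        self.nodes: list[str] = list(nodes)
        self.par: dict[str, set[str]] = {v: set() for v in self.nodes}
        self.ch: dict[str, set[str]] = {v: set() for v in self.nodes}
        self.und: dict[str, set[str]] = {v: set() for v in self.nodes}

    # -- construction -------------------------------------------------
    @classmethod
    def from_cpdag(cls, g: Cpdag) -> "PDAG":
        p = cls(g.nodes)
        for u, v in g.directed:
            p.add_directed(u, v)
        for e in g.undirected:
            u, v = tuple(e)
            p.add_undirected(u, v)
        return p

    def copy(self) -> "PDAG":
        p = PDAG(self.nodes)
        for v in self.nodes:
            p.par[v] = set(self.par[v])
            p.ch[v] = set(self.ch[v])
            p.und[v] = set(self.und[v])
        return p

    def to_cpdag(self) -> Cpdag:
        directed = frozenset((u, v) for v in self.nodes for u in self.par[v])
        undirected = frozenset(frozenset({u, v}) for v in self.nodes for u in self.und[v])
        return Cpdag(tuple(self.nodes), directed, undirected)

    # -- edits --------------------------------------------------------
    def add_directed(self, u: str, v: str) -> None:
        self.par[v].add(u)
        self.ch[u].add(v)

    def add_undirected(self, u: str, v: str) -> None:
        self.und[u].add(v)
        self.und[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        self.par[v].discard(u)
        self.ch[u].discard(v)
        self.par[u].discard(v)
        self.ch[v].discard(u)
        self.und[u].discard(v)
        self.und[v].discard(u)

    def orient(self, u: str, v: str) -> None:
        """Turn the undirected edge u-v into u->v."""
        self.und[u].discard(v)
        self.und[v].discard(u)
        self.add_directed(u, v)

    # -- queries ------------------------------------------------------
    def adjacent(self, u: str, v: str) -> bool:
        return v in self.par[u] or v in self.ch[u] or v in self.und[u]

    def neighbors(self, v: str) -> set[str]:
        return self.par[v] | self.ch[v] | self.und[v]

    def is_clique(self, nodes) -> bool:
        ns = list(nodes)
        return all(self.adjacent(a, b) for i, a in enumerate(ns) for b in ns[i + 1:])

    def has_semidirected_path(self, src: str, dst: str, blocked: set[str]) -> bool:
        """Path src ~> dst along directed (forward) or undirected edges,
        avoiding ``blocked`` as interior/terminal nodes."""
        if src == dst:
            return True
        seen = {src}
        stack = [src]
        while stack:
            v = stack.pop()
            for w in self.ch[v] | self.und[v]:
                if w == dst:
                    return True
                if w not in seen and w not in blocked:
                    seen.add(w)
                    stack.append(w)
        return False

    def topological_check(self) -> None:
        """Raise if the directed subgraph contains a cycle."""
        indeg = {v: len(self.par[v]) for v in self.nodes}
        queue = [v for v in self.nodes if indeg[v] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for w in self.ch[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen != len(self.nodes):
            raise ValueError("directed subgraph contains a cycle")


def pdag_to_dag(pdag: PDAG) -> dict[str, set[str]]:
    """Consistent DAG extension of a PDAG (Dor-Tarsi).

    Returns a parents dict for the full DAG. Raises ValueError when no
    consistent extension exists.
    """
    work = pdag.copy()
    parents = {v: set(pdag.par[v]) for v in pdag.nodes}
    remaining = sorted(pdag.nodes)
    while remaining:
        for v in remaining:
            if work.ch[v]:
                continue
            nb_all = work.neighbors(v)
            ok = all(work.adjacent(u, w)
                     for u in work.und[v] for w in nb_all if w != u)
            if not ok:
                continue
            for u in sorted(work.und[v]):
                parents[v].add(u)
            for u in list(work.neighbors(v)):
                work.remove_edge(u, v)
            remaining.remove(v)
            break
        else:
            raise ValueError("PDAG admits no consistent DAG extension")
    return parents


def dag_to_cpdag(nodes: Iterable[str], parents: dict[str, set[str]]) -> Cpdag:
    """Equivalence class (CPDAG) of a DAG: v-structures stay directed,
    everything else starts undirected, then Meek rules close the set of
    compelled orientations."""
    nodes = list(nodes)
    adjacent = {v: set() for v in nodes}
    for v, ps in parents.items():
        for u in ps:
            adjacent[u].add(v)
            adjacent[v].add(u)
    p = PDAG(nodes)
    compelled = set()
    for v in nodes:
        for a in parents[v]:
            for b in parents[v]:
                if a < b and b not in adjacent[a]:
                    compelled.add((a, v))
                    compelled.add((b, v))
    seen = set()
    for v in nodes:
        for u in parents[v]:
            if (u, v) in compelled:
                p.add_directed(u, v)
            elif frozenset({u, v}) not in seen:
                p.add_undirected(u, v)
                seen.add(frozenset({u, v}))
    _meek_closure(p)
    return p.to_cpdag()


def _meek_closure(p: PDAG) -> None:
    """Apply Meek rules R1-R3 until no undirected edge can be oriented."""
    changed = True
    while changed:
        changed = False
        for v in p.nodes:
            for w in sorted(p.und[v]):
                # R1: a -> v, v - w, a and w non-adjacent  =>  v -> w
                if any(not p.adjacent(a, w) for a in p.par[v]):
                    p.orient(v, w)
                    changed = True
                    continue
                # R2: v -> c -> w and v - w  =>  v -> w
                if p.ch[v] & p.par[w]:
                    p.orient(v, w)
                    changed = True
                    continue
                # R3: v - c, v - d, c -> w, d -> w, c and d non-adjacent => v -> w
                cands = sorted(p.und[v] & p.par[w])
                done = False
                for i, c in enumerate(cands):
                    for d in cands[i + 1:]:
                        if not p.adjacent(c, d):
                            p.orient(v, w)
                            changed = True
                            done = True
                            break
                    if done:
                        break


def empty_cpdag(nodes: Iterable[str]) -> Cpdag:
    return Cpdag(tuple(nodes), frozenset(), frozenset())
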