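"""Pathway expansion through condition-specific network neighbourhoods.

A pathway gene set is expanded by one step by adding, for every member
gene, all genes adjacent to it in the learned network — regulators and
regulatees alike, and undirected (orientation-undetermined) neighbours.
Repeating the step k times yields the k-ball of the raw set in the
network's adjacency graph. With two condition-specific networks and
``max_steps`` = 3 this produces seven collections: the raw sets plus
three expansions per condition.

Expansion inflates pathway sizes quickly (the member count grows with
the neighbourhood ball), so downstream significance grows with steps;
reports therefore default to the one-step expansion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import GeneSetCollection
from .graph import Cpdag

logger = logging.getLogger("altpath")

RAW = "raw"
GROUP1 = "group1"
GROUP2 = "group2"


def _adjacency(net: Cpdag, universe: set[str]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    outside = {v for v in net.nodes if v not in universe}
    if outside:
        logger.warning("%d network nodes outside the universe are ignored", len(outside))
    for u, v in net.directed:
        if u in universe and v in universe:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
    for e in net.undirected:
        u, v = tuple(e)
        if u in universe and v in universe:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
    return adj


def expand_once(sets: GeneSetCollection, net: Cpdag) -> GeneSetCollection:
    """One expansion step: union every set with its members' neighbours."""
    universe = set(sets.universe)
    adj = _adjacency(net, universe)
    new_sets = {}
    for name, members in sets.sets.items():
        grown = set(members)
        for g in members:
            grown |= adj.get(g, set())
        new_sets[name] = frozenset(grown)
    return GeneSetCollection(new_sets, sets.universe, dict(sets.descriptions))


@dataclass
class ExpansionResult:
    """Collections keyed by (condition, steps) plus per-gene provenance."""

    collections: dict[tuple[str, int], GeneSetCollection]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __getitem__(self, key: tuple[str, int]) -> GeneSetCollection:
        return self.collections[key]

    def __len__(self) -> int:
        return len(self.collections)


def build_expansion(sets: GeneSetCollection, net_group1: Cpdag, net_group2: Cpdag,
                    max_steps: int = 3) -> ExpansionResult:
    """Produce the raw collection plus ``max_steps`` expansions per condition.

    With the default three steps this yields seven collections. Each
    step's sets contain the previous step's (monotone growth); the
    provenance frame records at which step each added gene entered each
    pathway under each condition.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    collections = {(RAW, 0): sets}
    records = []
    for condition, net in ((GROUP1, net_group1), (GROUP2, net_group2)):
        current = sets
        for step in range(1, max_steps + 1):
            grown = expand_once(current, net)
            for name in grown.sets:
                for gene in sorted(grown.sets[name] - current.sets[name]):
                    records.append((condition, name, gene, step))
            collections[(condition, step)] = grown
            current = grown
    provenance = pd.DataFrame(records,
                              columns=["condition", "pathway", "gene", "step_added"])
    return ExpansionResult(collections, provenance)
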