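"""Pathway crosstalk network.

Nodes are the pathways found differentially active (either direction)
in the two-step analysis; an edge joins two pathways whose gene-set
overlap is larger than chance under a hypergeometric null drawn from
the union of all pathway gene sets. p-values over all tested pairs are
Benjamini-Hochberg adjusted and edges kept at q below the threshold.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import GeneSetCollection
from .stats import bh_fdr, overlap_pvalue

logger = logging.getLogger("altpath")


@dataclass(frozen=True)
class PathwayOverlapEdge:
    pathway_a: str
    pathway_b: str
    na: int
    nb: int
    nab: int
    nall: int
    p: float
    q: float


@dataclass
class PathwayNetwork:
    """Significant-overlap graph over differentially-active pathways."""

    nodes: dict[str, str]  # pathway -> class in {group1, group2, both}
    edges: list[PathwayOverlapEdge]
    tested: pd.DataFrame = field(default_factory=pd.DataFrame)

    def edge_keys(self) -> set[frozenset]:
        return {frozenset({e.pathway_a, e.pathway_b}) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pathway_a, e.pathway_b, e.na, e.nb, e.nab, e.p, e.q)
             for e in self.edges],
            columns=["pathway_a", "pathway_b", "na", "nb", "nab", "p", "q"])


def _node_class(row) -> str:
    if row["significant_g1"] and row["significant_g2"]:
        return "both"
    return "group1" if row["significant_g1"] else "group2"


def build_pathway_network(collection: GeneSetCollection,
                          pathway_classes: pd.DataFrame,
                          fdr_threshold: float = 0.05,
                          variant: str = "standard") -> PathwayNetwork:
    """Overlap-test every unordered pair of significant pathways.

    ``pathway_classes`` must have been computed on the same collection.
    The hypergeometric pool nall is the union of *all* pathway gene
    sets in the collection (not the measured universe). The
    multiple-testing family is exactly the set of pairs tested, i.e.
    pairs of significant pathways.
    """
    sig = pathway_classes[(pathway_classes["significant_g1"]) |
                          (pathway_classes["significant_g2"])]
    nodes = {name: _node_class(row) for name, row in sig.iterrows()
             if name in collection.sets}
    pool = set()
    for members in collection.sets.values():
        pool |= members
    nall = len(pool)
    names = sorted(nodes)
    if len(names) < 2:
        logger.warning("fewer than 2 significant pathways; empty network")
        return PathwayNetwork(nodes, [], pd.DataFrame(
            columns=["pathway_a", "pathway_b", "na", "nb", "nab", "p", "q"]))
    rows = []
    for a, b in itertools.combinations(names, 2):
        sa, sb = collection.sets[a], collection.sets[b]
        rows.append((a, b, len(sa), len(sb), len(sa & sb)))
    tested = pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "na", "nb", "nab"])
    tested["p"] = [overlap_pvalue(na, nb, nab, nall, variant)
                   for na, nb, nab in zip(tested["na"], tested["nb"], tested["nab"])]
    tested["q"] = bh_fdr(tested["p"])
    edges = [PathwayOverlapEdge(r.pathway_a, r.pathway_b, r.na, r.nb, r.nab,
                                nall, r.p, r.q)
             for r in tested.itertuples() if r.q < fdr_threshold]
    return PathwayNetwork(nodes, edges, tested)


def compare_networks(net_a: PathwayNetwork, net_b: PathwayNetwork):
    """Set algebra on two networks' unordered edge keys plus hub report.

    Returns (common, a_specific, b_specific, hubs) where hubs maps
    "a"/"b" to (pathway, degree) pairs ranked by degree within that
    network's specific edges.
    """
    keys_a, keys_b = net_a.edge_keys(), net_b.edge_keys()
    common = keys_a & keys_b
    a_spec = keys_a - keys_b
    b_spec = keys_b - keys_a

    def _hubs(spec: set[frozenset]) -> list[tuple[str, int]]:
        deg: dict[str, int] = {}
        for e in spec:
            for v in e:
                deg[v] = deg.get(v, 0) + 1
        return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))

    return common, a_spec, b_spec, {"a": _hubs(a_spec), "b": _hubs(b_spec)}
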