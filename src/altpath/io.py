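"""Readers and writers for every on-disk format the pipeline touches.

Tabular formats are plain TSV; gene sets use the MSigDB GMT dialect
(name, description, tab-separated members); networks can be exported as
GraphML (Cytoscape-loadable), SIF or edge-list TSV.
"""
from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import (ActivityProfile, GeneSetCollection, PmaCallTable,
                   ProbeGeneMap, SampleGroups)

logger = logging.getLogger("altpath")


# -- PMA calls and groups ---------------------------------------------

def read_pma_table(path, groups_path) -> tuple[PmaCallTable, SampleGroups]:
    """Read a probe x sample call table plus its two-group sample file.

    Calls are case-insensitive on read. Every sample column must carry
    a group label; unknown calls are hard errors naming the cell.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame = frame.apply(lambda col: col.str.upper())
    table = PmaCallTable(frame)
    groups = read_groups(groups_path)
    missing = [s for s in table.sample_ids if s not in groups.labels]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no group label")
    return table, groups


def write_pma_table(table: PmaCallTable, path) -> None:
    table.calls.to_csv(path, sep="\t", index_label="probe_id")


def read_groups(path) -> SampleGroups:
    """Read the sample-group TSV (columns sample_id, group).

    The two group roles come from optional directive lines
    ``#group1=NAME`` / ``#group2=NAME`` at the top of the file; without
    directives, group1 is the label of the first listed sample.
    """
    directives = {}
    rows = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                directives[key.strip()] = val.strip()
                continue
            if not header_seen:
                header_seen = True  # "sample_id\tgroup" header
                continue
            sample, _, group = line.partition("\t")
            rows.append((sample, group))
    labels = dict(rows)
    if len(labels) != len(rows):
        raise ValueError("duplicate sample in groups file")
    seen = list(dict.fromkeys(g for _, g in rows))
    if len(seen) != 2:
        raise ValueError(f"expected exactly two group labels, found {seen}")
    group1 = directives.get("group1")
    group2 = directives.get("group2")
    if group1 is None and group2 is None:
        group1, group2 = seen
    elif group1 is None:
        group1 = next(g for g in seen if g != group2)
    elif group2 is None:
        group2 = next(g for g in seen if g != group1)
    if {group1, group2} != set(seen):
        raise ValueError("group directives do not match the labels present")
    return SampleGroups(labels, group1, group2)


def write_groups(groups: SampleGroups, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#group1={groups.group1}\n#group2={groups.group2}\n")
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.labels.items():
            fh.write(f"{sample}\t{group}\n")


# -- probe map, activity ----------------------------------------------

def read_probe_map(path) -> ProbeGeneMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene"} <= set(frame.columns):
        raise ValueError("probe map needs columns probe_id and gene")
    if frame["probe_id"].duplicated().any():
        dup = frame["probe_id"][frame["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate probe id {dup!r}")
    return ProbeGeneMap(dict(zip(frame["probe_id"], frame["gene"])))


def write_probe_map(pm: ProbeGeneMap, path) -> None:
    pd.DataFrame(sorted(pm.mapping.items()), columns=["probe_id", "gene"]).to_csv(
        path, sep="\t", index=False)


def read_activity(path) -> ActivityProfile:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityProfile(frame)


def write_activity(profile: ActivityProfile, path) -> None:
    profile.activity.to_csv(path, sep="\t", index_label="gene")


# -- gene sets ---------------------------------------------------------

def read_gmt(path, universe) -> GeneSetCollection:
    """Read a GMT file, intersecting every set with the universe.

    Sets empty after intersection are dropped with a warning; a
    duplicated set name is an error. Descriptions are preserved.
    """
    uni = set(universe)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets or (name in descriptions):
                raise ValueError(f"duplicate gene set name {name!r}")
            kept = frozenset(m for m in members if m in uni)
            descriptions[name] = desc
            if not kept:
                logger.warning("gene set %s empty after universe intersection; dropped",
                               name)
                continue
            sets[name] = kept
    return GeneSetCollection(sets, tuple(universe),
                             {n: descriptions[n] for n in sets})


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# -- pathway topology inputs ------------------------------------------

def read_pair_list(path) -> pd.DataFrame:
    """Pathway edge list TSV: columns (pathway, geneA, geneB)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway", "geneA", "geneB"} <= set(frame.columns):
        raise ValueError("pair list needs columns pathway, geneA, geneB")
    return frame


def read_node_map(path) -> pd.DataFrame:
    """Node membership TSV: columns (pathway, node, gene)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway", "node", "gene"} <= set(frame.columns):
        raise ValueError("node map needs columns pathway, node, gene")
    return frame


# -- network export ----------------------------------------------------

def write_network(nodes: dict, edges, path, fmt: str = "graphml") -> None:
    """Export a network with node/edge attributes.

    ``nodes`` maps node id -> attribute dict (e.g. activation class);
    ``edges`` is an iterable of (u, v, attrs). Formats: graphml
    (Cytoscape-loadable), sif ("u interacts v" triples) or tsv.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for node, attrs in nodes.items():
            g.add_node(node, **attrs)
        for u, v, attrs in edges:
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            linked = set()
            for u, v, _ in edges:
                fh.write(f"{u}\tinteracts\t{v}\n")
                linked |= {u, v}
            for node in nodes:
                if node not in linked:
                    fh.write(f"{node}\n")
    elif fmt == "tsv":
        rows = [{"source": u, "target": v, **attrs} for u, v, attrs in edges]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
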