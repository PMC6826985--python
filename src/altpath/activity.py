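"""Probe-level PMA calls to gene-level binary activity.

A gene is active in a sample iff at least one of its probes carries a
Present (P) call there; Marginal and Absent both count as inactive.
Merging probes of one gene is therefore a logical OR — adding a probe
can only keep or increase a gene's active-sample count.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ActivityProfile, PmaCallTable, ProbeGeneMap, SampleGroups

logger = logging.getLogger("altpath")


def probes_to_gene_activity(pma: PmaCallTable, probe_map: ProbeGeneMap,
                            groups: SampleGroups) -> ActivityProfile:
    """Collapse probe calls to gene activity (OR over a gene's probes).

    Probes absent from the map are dropped (logged); genes whose probes
    are all missing from the table are excluded (logged). Sample order
    of the input table is preserved.
    """
    for s in pma.sample_ids:
        if s not in groups.labels:
            raise ValueError(f"sample {s!r} has no group label")
    mapped = [p for p in pma.probe_ids if p in probe_map.mapping]
    n_dropped = len(pma.probe_ids) - len(mapped)
    if n_dropped:
        logger.info("dropped %d probes absent from the probe-gene map", n_dropped)
    if not mapped:
        raise ValueError("no probe in the table maps to a gene")
    present = (pma.calls.loc[mapped] == "P").astype(np.int8)
    gene_of = pd.Series({p: probe_map.mapping[p] for p in mapped})
    act = present.groupby(gene_of).max()
    act = act.sort_index()
    missing = probe_map.genes() - set(act.index)
    if missing:
        logger.info("excluded %d genes with no probe in the table", len(missing))
    return ActivityProfile(act)


def merge_pma_tables(first: PmaCallTable, second: PmaCallTable,
                     require_all: bool = False) -> PmaCallTable:
    """Union two platforms' call tables over the union of samples.

    A probe measured on one platform only is treated as Absent in the
    other platform's samples (absent samples count as inactive), unless
    ``require_all`` is set, in which case probes not shared by both
    platforms are dropped.
    """
    shared_samples = set(first.sample_ids) & set(second.sample_ids)
    if shared_samples:
        raise ValueError(f"sample(s) present in both tables: {sorted(shared_samples)[:3]}")
    if require_all:
        probes = [p for p in first.probe_ids if p in set(second.probe_ids)]
        merged = pd.concat([first.calls.loc[probes], second.calls.loc[probes]], axis=1)
    else:
        merged = pd.concat([first.calls, second.calls], axis=1)
        merged = merged.fillna("A")
    return PmaCallTable(merged)


def activity_counts(profile: ActivityProfile, groups: SampleGroups) -> pd.DataFrame:
    """Per-gene (n11, n12, n21, n22) table; rows sum to the group sizes."""
    return profile.counts(groups)
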