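"""Core in-memory containers for the activity-call pipeline.

The method operates on binary gene activity: a gene is *active* in a
sample when at least one of its probes received a Present (P) detection
call. Everything downstream — differential testing, pattern recognition,
network learning — consumes these containers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("altpath")

#: Legal PMA detection calls (Present / Marginal / Absent).
VALID_CALLS = frozenset({"P", "M", "A"})


@dataclass(frozen=True)
class SampleGroups:
    """Two-group sample assignment.

    ``group1`` plays the role of the reference condition (primary tumour
    in the motivating application) and ``group2`` the contrast condition
    (metastasis). The method is symmetric in the mathematics but the two
    roles must be named explicitly because every report is phrased in
    terms of "group1-active" vs "group2-active".
    """

    labels: Mapping[str, str]
    group1: str
    group2: str

    def __post_init__(self) -> None:
        seen = set(self.labels.values())
        if seen != {self.group1, self.group2}:
            raise ValueError(
                f"group labels {sorted(seen)} do not match designated "
                f"roles ({self.group1!r}, {self.group2!r})"
            )
        if self.group1 == self.group2:
            raise ValueError("group1 and group2 must be distinct labels")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    @property
    def group1_samples(self) -> list[str]:
        return self.samples_in(self.group1)

    @property
    def group2_samples(self) -> list[str]:
        return self.samples_in(self.group2)

    def swapped(self) -> "SampleGroups":
        """Exchange the two group roles (labels untouched)."""
        return SampleGroups(self.labels, group1=self.group2, group2=self.group1)


@dataclass(frozen=True)
class ProbeGeneMap:
    """probe_id -> gene symbol; many probes may map to one gene."""

    mapping: Mapping[str, str]

    def genes(self) -> set[str]:
        return set(self.mapping.values())

    def probes_for(self, gene: str) -> list[str]:
        return [p for p, g in self.mapping.items() if g == gene]


@dataclass
class GeneSetCollection:
    """Named gene sets over an ordered measured universe.

    ``universe`` is the enrichment background N: the genes actually
    measured, not the union of set members (a flag elsewhere offers the
    alternative).
    """

    sets: dict[str, frozenset[str]]
    universe: tuple[str, ...]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if not members <= uni:
                raise ValueError(f"gene set {name!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restricted(self, names: Iterable[str]) -> "GeneSetCollection":
        keep = {n: self.sets[n] for n in names}
        return GeneSetCollection(keep, self.universe,
                                 {n: self.descriptions.get(n, "") for n in keep})


@dataclass
class PmaCallTable:
    """Probe-level detection calls: probes x samples, entries in {P, M, A}."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")
        bad = ~self.calls.isin(VALID_CALLS)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            probe, sample = self.calls.index[r], self.calls.columns[c]
            raise ValueError(
                f"invalid call {self.calls.iat[r, c]!r} at probe {probe!r}, "
                f"sample {sample!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class ActivityProfile:
    """Gene-level binary activity: genes x samples, entries in {0, 1}."""

    activity: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.activity.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("activity matrix must be binary")
        self.activity = self.activity.astype(np.int8)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.columns)

    def counts(self, groups: SampleGroups) -> pd.DataFrame:
        """Per-gene 2x2 activity counts against the two groups.

        Returns a frame indexed by gene with columns n11 (group1 active),
        n12 (group1 inactive), n21 (group2 active), n22 (group2 inactive).
        Rows always sum to the two group sizes.
        """
        g1 = [s for s in self.sample_ids if groups.labels[s] == groups.group1]
        g2 = [s for s in self.sample_ids if groups.labels[s] == groups.group2]
        if not g1 or not g2:
            raise ValueError("both groups must contain at least one sample")
        a1 = self.activity[g1].to_numpy().sum(axis=1)
        a2 = self.activity[g2].to_numpy().sum(axis=1)
        return pd.DataFrame(
            {
                "n11": a1,
                "n12": len(g1) - a1,
                "n21": a2,
                "n22": len(g2) - a2,
            },
            index=self.activity.index.copy(),
        )
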