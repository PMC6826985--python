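"""Gene-pair activity alteration patterns.

For a pair (geneA, geneB) each sample occupies one of four joint
activity states — 00, 01, 10, 11 — where the first bit is geneA's
activity. A transition X->Y between the two groups is evidence that the
pair's joint state shifts from X (over-represented in group1) to Y
(over-represented in group2). Transitions fall into three pattern
types:

* type 2 — one gene's activity changes (one bit differs; 8 transitions)
* type 3 — both change concordantly (00<->11; 2 transitions)
* type 4 — both change inversely (01<->10; 2 transitions)

Pairs in which neither gene is differentially active are assigned
PATTERN1 (no change) without testing. For eligible pairs all 12 ordered
transitions are tested and the significant transition with minimal
p-value is the pair's assigned alteration pattern.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import ActivityProfile, SampleGroups
from .differential import NS
from .stats import fisher_one_tailed

logger = logging.getLogger("altpath")

STATES = ("00", "01", "10", "11")
#: the 12 ordered state transitions, lexicographic
TRANSITIONS = tuple((a, b) for a, b in itertools.product(STATES, STATES) if a != b)

PATTERN1 = "PATTERN1"


def pattern_type(from_state: str, to_state: str) -> int:
    """Pattern type of an ordered transition: 2, 3 or 4."""
    if from_state not in STATES or to_state not in STATES:
        raise ValueError(f"unknown state in transition {from_state}->{to_state}")
    if from_state == to_state:
        raise ValueError("transition states must differ")
    nbits = sum(x != y for x, y in zip(from_state, to_state))
    if nbits == 1:
        return 2
    return 3 if {from_state, to_state} == {"00", "11"} else 4


@dataclass(frozen=True)
class PairStateCounts:
    gene_a: str
    gene_b: str
    group1: dict  # state -> sample count in group1
    group2: dict


@dataclass(frozen=True)
class TransitionTest:
    from_state: str
    to_state: str
    p_value: float

    @property
    def pattern_type(self) -> int:
        return pattern_type(self.from_state, self.to_state)


@dataclass(frozen=True)
class PatternAssignment:
    gene_a: str
    gene_b: str
    assigned: str  # PATTERN1 or "X->Y"
    min_p: float | None
    significant: tuple[TransitionTest, ...] = field(default=())

    @property
    def pattern_type(self) -> int | str:
        if self.assigned == PATTERN1:
            return 1
        frm, to = self.assigned.split("->")
        return pattern_type(frm, to)


def pair_state_counts(profile: ActivityProfile, gene_a: str, gene_b: str,
                      groups: SampleGroups) -> PairStateCounts:
    """Tally the joint activity state of a gene pair per group."""
    for g in (gene_a, gene_b):
        if g not in profile.activity.index:
            raise ValueError(f"gene {g!r} not in activity profile")
    a = profile.activity.loc[gene_a]
    b = profile.activity.loc[gene_b]
    joint = a.astype(str) + b.astype(str)
    out = {}
    for role, label in (("group1", groups.group1), ("group2", groups.group2)):
        samples = [s for s in profile.sample_ids if groups.labels[s] == label]
        tally = joint[samples].value_counts()
        out[role] = {s: int(tally.get(s, 0)) for s in STATES}
    return PairStateCounts(gene_a, gene_b, out["group1"], out["group2"])


def test_transition(counts: PairStateCounts, from_state: str, to_state: str,
                    alpha: float = 0.05) -> TransitionTest:
    """One-tailed Fisher test for the shift from_state -> to_state.

    Conditions on samples sitting in either of the two states only:
    the 2x2 table is [[c1[from], c1[to]], [c2[from], c2[to]]], and the
    alternative is that the from-state is over-represented in group1
    (greater tail on the first cell).
    """
    if from_state == to_state:
        raise ValueError("transition states must differ")
    p = fisher_one_tailed(counts.group1[from_state], counts.group1[to_state],
                          counts.group2[from_state], counts.group2[to_state],
                          tail="greater_first_cell")
    return TransitionTest(from_state, to_state, p)


def assign_pattern(counts: PairStateCounts, class_a: str, class_b: str,
                   alpha: float = 0.05, gate: bool = True) -> PatternAssignment:
    """Assign the pair's alteration pattern.

    With the eligibility gate on (default), a pair whose genes are both
    non-differential (NS) is PATTERN1 without testing. Otherwise all 12
    ordered transitions are tested; the significant one with minimal p
    wins (ties broken lexicographically by (from, to)).
    """
    if gate and class_a == NS and class_b == NS:
        return PatternAssignment(counts.gene_a, counts.gene_b, PATTERN1, None)
    tests = [test_transition(counts, frm, to, alpha) for frm, to in TRANSITIONS]
    sig = tuple(t for t in tests if t.p_value < alpha)
    if not sig:
        return PatternAssignment(counts.gene_a, counts.gene_b, PATTERN1, None)
    best = min(sig, key=lambda t: (t.p_value, t.from_state, t.to_state))
    return PatternAssignment(counts.gene_a, counts.gene_b,
                             f"{best.from_state}->{best.to_state}",
                             best.p_value, sig)


def pattern_scan(profile: ActivityProfile, pairs, gene_classes: pd.DataFrame,
                 groups: SampleGroups, alpha: float = 0.05,
                 gate: bool = True) -> list[PatternAssignment]:
    """Assign a pattern to every (geneA, geneB) pair in ``pairs``.

    Pairs involving unmeasured genes are skipped with a warning. The
    result is sorted by min_p (PATTERN1 pairs last, then by gene names).
    """
    measured = set(profile.activity.index)
    out = []
    for gene_a, gene_b in pairs:
        if gene_a not in measured or gene_b not in measured:
            logger.warning("pair (%s, %s) involves unmeasured gene(s); skipped",
                           gene_a, gene_b)
            continue
        counts = pair_state_counts(profile, gene_a, gene_b, groups)
        cls_a = gene_classes.loc[gene_a, "class"] if gene_a in gene_classes.index else NS
        cls_b = gene_classes.loc[gene_b, "class"] if gene_b in gene_classes.index else NS
        out.append(assign_pattern(counts, cls_a, cls_b, alpha, gate))
    out.sort(key=lambda a: (a.min_p is None, a.min_p if a.min_p is not None else 0.0,
                            a.gene_a, a.gene_b))
    return out


def assignments_frame(assignments) -> pd.DataFrame:
    """Tabular view of a list of :class:`PatternAssignment`."""
    rows = []
    for a in assignments:
        rows.append({
            "geneA": a.gene_a,
            "geneB": a.gene_b,
            "assigned": a.assigned,
            "pattern_type": a.pattern_type,
            "min_p": a.min_p if a.min_p is not None else "",
            "significant_transitions": ";".join(
                f"{t.from_state}->{t.to_state}:{t.p_value:.3g}" for t in a.significant),
        })
    return pd.DataFrame(rows, columns=["geneA", "geneB", "assigned", "pattern_type",
                                       "min_p", "significant_transitions"])


@dataclass(frozen=True)
class NodeActivityReport:
    pathway: str
    node: str
    members: tuple[str, ...]
    group1_active: tuple[str, ...]
    group2_active: tuple[str, ...]

    @property
    def alternative(self) -> bool:
        """Alternatively-activated node: members active in both groups."""
        return bool(self.group1_active) and bool(self.group2_active)


def node_activity_report(node_map: pd.DataFrame,
                         gene_classes: pd.DataFrame) -> list[NodeActivityReport]:
    """Per-node breakdown of member-gene differential activity.

    ``node_map`` has columns (pathway, node, gene); nodes are KEGG-style
    multi-gene nodes (e.g. a CALM node covering several calmodulin
    genes). A node whose members include both group1-active and
    group2-active genes is flagged as alternatively activated.
    """
    for col in ("pathway", "node", "gene"):
        if col not in node_map.columns:
            raise ValueError(f"node map lacks column {col!r}")
    reports = []
    for (pathway, node), sub in node_map.groupby(["pathway", "node"], sort=True):
        members = tuple(sorted(set(sub["gene"]) & set(gene_classes.index)))
        cls = gene_classes.loc[list(members), "class"] if members else pd.Series(dtype=object)
        g1 = tuple(g for g in members if cls[g] == "GROUP1_ACTIVE")
        g2 = tuple(g for g in members if cls[g] == "GROUP2_ACTIVE")
        reports.append(NodeActivityReport(pathway, node, members, g1, g2))
    return reports
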