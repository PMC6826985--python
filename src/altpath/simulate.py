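"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: per-gene
Bernoulli activity with group-specific activity probabilities and
planted differential genes, a probe layer emitting P/M/A calls on top
of the activity, pathway collections with planted enrichment, and
binary samples drawn ancestrally from a known DAG for structure
recovery experiments. Activity is sampled independently across genes
and samples — exactly the exchangeability the Fisher exact tests
assume; gene-gene dependence is available only through the DAG
sampler. All generators are deterministic given their seed.

Default sizes mirror the motivating study's scale knobs (balanced
43/43 groups; an imbalanced 150/43 design for robustness work) at
reduced gene counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivityProfile, GeneSetCollection, PmaCallTable, ProbeGeneMap, SampleGroups


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run."""

    p1: pd.Series  # per-gene activity probability in group1
    p2: pd.Series
    planted: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down"
    enriched_pathways: list[str] = field(default_factory=list)
    dag_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0


def _group_frame(n1: int, n2: int) -> SampleGroups:
    labels = {f"p{i:03d}": "group1" for i in range(n1)}
    labels.update({f"m{i:03d}": "group2" for i in range(n2)})
    return SampleGroups(labels, "group1", "group2")


def simulate_activity(n_genes: int = 1000, n1: int = 43, n2: int = 43,
                      base_prob: float = 0.3, n_diff: int = 50,
                      effect: float = 0.4, seed: int = 1
                      ) -> tuple[ActivityProfile, SampleGroups, SimulationTruth]:
    """Independent Bernoulli activity with planted differential genes.

    The first ``n_diff`` genes are planted: half get p1 = base + effect
    (more active in group1, "up"), half the reverse ("down"); all other
    genes share p1 = p2 = base_prob.
    """
    if not (0 <= base_prob <= 1 and 0 <= base_prob + effect <= 1):
        raise ValueError("base_prob and base_prob + effect must lie in [0, 1]")
    if n_diff > n_genes:
        raise ValueError("n_diff exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    groups = _group_frame(n1, n2)
    p1 = np.full(n_genes, base_prob)
    p2 = np.full(n_genes, base_prob)
    planted: dict[str, str] = {}
    n_up = n_diff - n_diff // 2
    for i in range(n_diff):
        if i < n_up:
            p1[i] = base_prob + effect
            planted[genes[i]] = "up"
        else:
            p2[i] = base_prob + effect
            planted[genes[i]] = "down"
    mat = np.concatenate([
        (rng.random((n_genes, n1)) < p1[:, None]).astype(np.int8),
        (rng.random((n_genes, n2)) < p2[:, None]).astype(np.int8),
    ], axis=1)
    samples = groups.group1_samples + groups.group2_samples
    profile = ActivityProfile(pd.DataFrame(mat, index=genes, columns=samples))
    truth = SimulationTruth(pd.Series(p1, index=genes), pd.Series(p2, index=genes),
                            planted, seed=seed)
    return profile, groups, truth


def simulate_pma(profile: ActivityProfile, probes_per_gene: int = 2,
                 flip_prob: float = 0.0, seed: int = 1
                 ) -> tuple[PmaCallTable, ProbeGeneMap]:
    """Emit a probe layer above a gene activity profile.

    Every active (gene, sample) cell gets at least one Present probe;
    inactive cells get Marginal/Absent calls except for a spurious
    Present with probability ``flip_prob`` per probe (call noise). With
    flip_prob = 0 the gene layer is recovered exactly by the OR rule.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    act = profile.activity.to_numpy()
    n_genes, n_samples = act.shape
    k = probes_per_gene
    # candidate P assignment, then force one P where active and none landed
    p_mask = rng.random((n_genes, k, n_samples)) < 0.5
    forced = rng.integers(0, k, size=(n_genes, n_samples))
    none_p = ~p_mask.any(axis=1)
    for j in range(k):
        p_mask[:, j, :] |= (forced == j) & none_p
    p_mask &= act[:, None, :].astype(bool)  # only active cells may carry real P
    spurious = rng.random((n_genes, k, n_samples)) < flip_prob
    p_mask |= spurious & ~act[:, None, :].astype(bool)
    ma = np.where(rng.random((n_genes, k, n_samples)) < 0.5, "M", "A")
    calls = np.where(p_mask, "P", ma)
    probes = [f"{g}_pr{j}" for g in profile.gene_ids for j in range(k)]
    frame = pd.DataFrame(calls.reshape(n_genes * k, n_samples),
                         index=probes, columns=profile.sample_ids)
    mapping = {f"{g}_pr{j}": g for g in profile.gene_ids for j in range(k)}
    return PmaCallTable(frame), ProbeGeneMap(mapping)


def simulate_pathways(truth: SimulationTruth, n_pathways: int = 50,
                      set_size_range: tuple[int, int] = (10, 25),
                      n_enriched: int = 5, enrichment_frac: float = 0.5,
                      seed: int = 1) -> GeneSetCollection:
    """Pathway collection with planted enrichment.

    The first ``n_enriched`` pathways draw ``enrichment_frac`` of their
    members from the planted differential genes and the rest from the
    background; other pathways draw uniformly from all genes. The
    enriched pathway names are appended to ``truth.enriched_pathways``.
    """
    if not 0 <= enrichment_frac <= 1:
        raise ValueError("enrichment_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(truth.p1.index)
    planted = [g for g in genes if g in truth.planted]
    background = [g for g in genes if g not in truth.planted]
    lo, hi = set_size_range
    sets: dict[str, frozenset[str]] = {}
    truth.enriched_pathways = []
    for i in range(n_pathways):
        name = f"PW{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            n_from_planted = min(round(enrichment_frac * size), len(planted))
            chosen = list(rng.choice(planted, size=n_from_planted, replace=False))
            chosen += list(rng.choice(background, size=size - n_from_planted,
                                      replace=False))
            truth.enriched_pathways.append(name)
        else:
            chosen = list(rng.choice(genes, size=size, replace=False))
        sets[name] = frozenset(chosen)
    return GeneSetCollection(sets, tuple(genes))


def simulate_from_dag(parents: dict[str, tuple[str, ...]], cpd_strength: float = 0.9,
                      n_samples: int = 1000, seed: int = 1) -> ActivityProfile:
    """Ancestral binary sampling from a given DAG.

    Roots are fair coins. A child follows the majority of its parents
    with probability ``cpd_strength`` (ties count as active), otherwise
    flips — for a single parent this is a noisy copy.
    """
    if not 0.5 <= cpd_strength <= 1:
        raise ValueError("cpd_strength must lie in [0.5, 1]")
    rng = np.random.default_rng(seed)
    order = _topological(parents)
    samples = [f"s{i:04d}" for i in range(n_samples)]
    data = {}
    for v in order:
        ps = parents[v]
        if not ps:
            data[v] = (rng.random(n_samples) < 0.5).astype(np.int8)
        else:
            stacked = np.stack([data[p] for p in ps])
            target = (stacked.sum(axis=0) * 2 >= len(ps)).astype(np.int8)
            follow = rng.random(n_samples) < cpd_strength
            data[v] = np.where(follow, target, 1 - target).astype(np.int8)
    names = sorted(parents)
    frame = pd.DataFrame(np.stack([data[v] for v in names]),
                         index=names, columns=samples)
    return ActivityProfile(frame)


def simulate_dag_data(n_nodes: int = 10, edge_prob: float = 0.25,
                      cpd_strength: float = 0.9, n_samples: int = 1000,
                      seed: int = 1) -> tuple[ActivityProfile, SimulationTruth]:
    """Random ordered Erdos-Renyi DAG plus ancestral binary samples."""
    rng = np.random.default_rng(seed)
    nodes = [f"g{i:04d}" for i in range(n_nodes)]
    parents: dict[str, tuple[str, ...]] = {}
    for j, v in enumerate(nodes):
        ps = [nodes[i] for i in range(j) if rng.random() < edge_prob]
        parents[v] = tuple(ps)
    profile = simulate_from_dag(parents, cpd_strength, n_samples,
                                seed=int(rng.integers(0, 2**31 - 1)))
    const = pd.Series(0.5, index=nodes)
    truth = SimulationTruth(const, const.copy(), dag_parents=parents, seed=seed)
    return profile, truth


def _topological(parents: dict[str, tuple[str, ...]]) -> list[str]:
    order: list[str] = []
    done: set[str] = set()

    def visit(v: str, stack: set[str]) -> None:
        if v in done:
            return
        if v in stack:
            raise ValueError("parent structure contains a cycle")
        stack.add(v)
        for p in parents[v]:
            visit(p, stack)
        stack.discard(v)
        done.add(v)
        order.append(v)

    for v in sorted(parents):
        visit(v, set())
    return order
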