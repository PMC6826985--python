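"""Group-imbalance robustness analysis.

When one group is much larger than the other, the two-step analysis is
re-run on repeated balanced subsamples: each iteration draws, without
replacement, ``subsample_size`` samples from the larger group, keeps
the smaller group whole, and re-classifies genes and pathways. Overlap
with the full-data result and the correlation of pathway significance
profiles summarise how stable the calls are under balancing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivityProfile, GeneSetCollection, SampleGroups
from .differential import GROUP1_ACTIVE, GROUP2_ACTIVE, classify_genes, classify_pathways

logger = logging.getLogger("altpath")


@dataclass
class RobustnessSummary:
    per_iteration: pd.DataFrame
    means: pd.Series
    n_iterations: int


def _called(frame: pd.DataFrame, cls: str) -> set[str]:
    return set(frame.index[frame["class"] == cls])


def _sig_pathways(frame: pd.DataFrame, col: str) -> set[str]:
    return set(frame.index[frame[col]])


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        # a constant profile is perfectly reproduced only by itself
        return 1.0 if np.allclose(x, y) else float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def run_robustness(profile: ActivityProfile, collection: GeneSetCollection,
                   groups: SampleGroups, n_iter: int = 10,
                   subsample_size: int | None = None, alpha: float = 0.05,
                   seed: int = 1) -> RobustnessSummary:
    """Balanced-subsampling robustness of the two-step analysis.

    The larger group is subsampled without replacement to
    ``subsample_size`` (default: the smaller group's size). Per
    iteration the summary records, per direction, the differential-gene
    and significant-pathway counts, their overlap with the full-data
    result (count and proportion of the subsample calls recovered in
    the full calls), and the Pearson correlation of -log10 pathway
    p-values against the full run.
    """
    g1 = groups.group1_samples
    g2 = groups.group2_samples
    larger, larger_label = (g1, groups.group1) if len(g1) >= len(g2) else (g2, groups.group2)
    smaller = g2 if larger is g1 else g1
    if subsample_size is None:
        subsample_size = len(smaller)
    if subsample_size > len(larger):
        raise ValueError("subsample_size exceeds the larger group size")

    full_genes = classify_genes(profile.counts(groups), alpha)
    full_paths = classify_pathways(collection, full_genes, alpha)
    full_sets = {
        "g1_genes": _called(full_genes, GROUP1_ACTIVE),
        "g2_genes": _called(full_genes, GROUP2_ACTIVE),
        "g1_paths": _sig_pathways(full_paths, "significant_g1"),
        "g2_paths": _sig_pathways(full_paths, "significant_g2"),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        chosen = list(rng.choice(larger, size=subsample_size, replace=False))
        kept = chosen + list(smaller)
        sub_labels = {s: groups.labels[s] for s in kept}
        sub_groups = SampleGroups(sub_labels, groups.group1, groups.group2)
        sub_profile = ActivityProfile(profile.activity[kept])
        genes = classify_genes(sub_profile.counts(sub_groups), alpha)
        paths = classify_pathways(collection, genes, alpha)
        row = {"iteration": it}
        for direction, gene_cls, path_col in (
                ("g1", GROUP1_ACTIVE, "significant_g1"),
                ("g2", GROUP2_ACTIVE, "significant_g2")):
            sub_g = _called(genes, gene_cls)
            sub_p = _sig_pathways(paths, path_col)
            full_g = full_sets[f"{direction}_genes"]
            full_p = full_sets[f"{direction}_paths"]
            row[f"{direction}_genes"] = len(sub_g)
            row[f"{direction}_gene_overlap"] = len(sub_g & full_g)
            row[f"{direction}_gene_overlap_prop"] = (
                len(sub_g & full_g) / len(sub_g) if sub_g else float("nan"))
            row[f"{direction}_pathways"] = len(sub_p)
            row[f"{direction}_pathway_overlap"] = len(sub_p & full_p)
            row[f"{direction}_pathway_overlap_prop"] = (
                len(sub_p & full_p) / len(sub_p) if sub_p else float("nan"))
            pcol = "p_g1" if direction == "g1" else "p_g2"
            joint = full_paths[[pcol]].join(paths[[pcol]], rsuffix="_sub", how="inner")
            row[f"{direction}_pathway_corr"] = _safe_corr(
                -np.log10(joint[pcol].to_numpy()),
                -np.log10(joint[f"{pcol}_sub"].to_numpy()))
        rows.append(row)
    per_iteration = pd.DataFrame(rows).set_index("iteration")
    means = per_iteration.mean()
    logger.info("robustness over %d iterations of %d/%d samples (subsampled %s)",
                n_iter, subsample_size, len(smaller), larger_label)
    return RobustnessSummary(per_iteration, means, n_iter)
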