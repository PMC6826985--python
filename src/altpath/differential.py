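"""Two-step differential-activation analysis.

Step 1 classifies every gene by a pair of one-tailed Fisher exact tests
on its activity counts: p_left tests H1: p1 > p2 (more active in
group1), p_right tests H1: p1 < p2, where p1 = n11/(n11+n12) and
p2 = n21/(n21+n22). A gene is GROUP1_ACTIVE when p_left < alpha,
GROUP2_ACTIVE when p_right < alpha, NS otherwise.

Step 2 tests every pathway, per direction, for over-representation of
the direction's differential genes among its members: a greater-tail
Fisher test on [[mp, m-mp], [Np-mp, (N-m)-(Np-mp)]] where m is the
pathway size, mp its group1-active members, Np the genome-wide
group1-active count and N the measured universe; analogously with
mm and Nm for group2. A pathway may be significant in both directions
simultaneously.

No multiple-testing correction is applied at either step by default:
the method uses raw p < 0.05 throughout. An optional FDR switch exists
for users who want it.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import GeneSetCollection
from .stats import bh_fdr, fisher_tails

logger = logging.getLogger("altpath")

GROUP1_ACTIVE = "GROUP1_ACTIVE"
GROUP2_ACTIVE = "GROUP2_ACTIVE"
NS = "NS"


def classify_genes(counts: pd.DataFrame, alpha: float = 0.05,
                   fdr: bool = False) -> pd.DataFrame:
    """Step 1: per-gene differential-activity classification.

    ``counts`` is indexed by gene with columns n11, n12, n21, n22.
    Returns the counts augmented with p_left, p_right and class.
    """
    for col in ("n11", "n12", "n21", "n22"):
        if col not in counts.columns:
            raise ValueError(f"counts table lacks column {col!r}")
    if counts.empty:
        raise ValueError("empty counts table")
    if (counts["n11"] + counts["n12"]).nunique() != 1 or \
       (counts["n21"] + counts["n22"]).nunique() != 1:
        raise ValueError("rows do not share common group sizes")
    p_left, p_right = fisher_tails(counts["n11"], counts["n12"],
                                   counts["n21"], counts["n22"])
    out = counts.copy()
    out["p_left"] = p_left
    out["p_right"] = p_right
    ql = bh_fdr(p_left) if fdr else p_left
    qr = bh_fdr(p_right) if fdr else p_right
    cls = np.where(ql < alpha, GROUP1_ACTIVE, np.where(qr < alpha, GROUP2_ACTIVE, NS))
    out["class"] = cls
    return out


def classify_pathways(collection: GeneSetCollection, gene_classes: pd.DataFrame,
                      alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Step 2: per-pathway differential-activation tests, both directions.

    ``gene_classes`` is the output of :func:`classify_genes`. The
    background N is the collection's universe; genes classified but not
    in the universe are ignored with a log message.
    """
    universe = set(collection.universe)
    classed = gene_classes.loc[[g for g in gene_classes.index if g in universe]]
    if len(classed) < len(gene_classes):
        logger.info("ignored %d classified genes outside the universe",
                    len(gene_classes) - len(classed))
    g1 = set(classed.index[classed["class"] == GROUP1_ACTIVE])
    g2 = set(classed.index[classed["class"] == GROUP2_ACTIVE])
    N = len(collection.universe)
    Np, Nm = len(g1), len(g2)

    rows = []
    for name, members in collection.sets.items():
        m = len(members)
        if m == 0:
            logger.warning("pathway %s has no measured members; skipped", name)
            continue
        mp = len(members & g1)
        mm = len(members & g2)
        rows.append((name, m, mp, mm))
    if not rows:
        return pd.DataFrame(columns=["m", "mp", "mm", "Np", "Nm", "N",
                                     "p_g1", "p_g2", "significant_g1",
                                     "significant_g2"])
    frame = pd.DataFrame(rows, columns=["pathway", "m", "mp", "mm"]).set_index("pathway")
    m, mp, mm = frame["m"], frame["mp"], frame["mm"]
    p_g1, _ = fisher_tails(mp, m - mp, Np - mp, (N - m) - (Np - mp))
    p_g2, _ = fisher_tails(mm, m - mm, Nm - mm, (N - m) - (Nm - mm))
    frame["Np"], frame["Nm"], frame["N"] = Np, Nm, N
    frame["p_g1"] = p_g1
    frame["p_g2"] = p_g2
    q1 = bh_fdr(p_g1) if fdr else p_g1
    q2 = bh_fdr(p_g2) if fdr else p_g2
    frame["significant_g1"] = q1 < alpha
    frame["significant_g2"] = q2 < alpha
    return frame
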