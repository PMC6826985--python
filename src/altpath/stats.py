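"""Exact-test primitives shared across the pipeline.

All tests are one-tailed Fisher exact tests, i.e. hypergeometric tail
probabilities with every margin of the 2x2 table fixed. The pathway
overlap test additionally exists in two variants because the printed
formula in the source method starts its summation at i=1, which differs
from the standard upper-tail hypergeometric probability by exactly the
probability of zero overlap; both are exposed so the discrepancy is
testable.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_one_tailed",
    "fisher_tails",
    "overlap_pvalue",
    "bh_fdr",
]


def fisher_one_tailed(a: int, b: int, c: int, d: int, tail: str) -> float:
    """One-tailed Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    tail="greater_first_cell" returns P(X >= a) and "less_first_cell"
    returns P(X <= a), where X is hypergeometric with the observed
    margins. A table with a zero row or column margin carries no
    information and returns 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    if tail == "greater_first_cell":
        return float(hypergeom.sf(a - 1, n, row1, col1))
    if tail == "less_first_cell":
        return float(hypergeom.cdf(a, n, row1, col1))
    raise ValueError(f"unknown tail {tail!r}")


def fisher_tails(n11, n12, n21, n22) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pair of one-tailed Fisher p-values per 2x2 table.

    Returns (p_left, p_right): p_left tests H1: p1 > p2 (first-row
    proportion larger, upper tail on the first cell) and p_right tests
    H1: p1 < p2 (lower tail). Degenerate tables (a zero margin) get 1.
    """
    n11, n12, n21, n22 = (np.asarray(x, dtype=np.int64) for x in (n11, n12, n21, n22))
    if (n11 < 0).any() or (n12 < 0).any() or (n21 < 0).any() or (n22 < 0).any():
        raise ValueError("counts must be non-negative")
    n = n11 + n12 + n21 + n22
    row1 = n11 + n12
    col1 = n11 + n21
    ok = (n > 0) & (row1 > 0) & (row1 < n) & (col1 > 0) & (col1 < n)
    p_left = np.ones(np.broadcast(n11, n).shape, dtype=float)
    p_right = np.ones_like(p_left)
    if ok.any():
        p_left[ok] = hypergeom.sf(n11[ok] - 1, n[ok], row1[ok], col1[ok])
        p_right[ok] = hypergeom.cdf(n11[ok], n[ok], row1[ok], col1[ok])
    return p_left, p_right


def overlap_pvalue(na: int, nb: int, nab: int, nall: int,
                   variant: str = "standard") -> float:
    """Significance of the overlap of two gene sets of sizes na, nb
    drawn from a pool of nall genes, observed intersection nab.

    variant="standard": p = P(X >= nab) for X ~ Hypergeom(nall, na, nb).
    variant="as_printed": the literal published formula, whose summation
    starts at i=1 and therefore exceeds the standard value by P(X = 0).
    """
    if not (0 <= nab <= min(na, nb) <= nall):
        raise ValueError(f"infeasible overlap counts na={na} nb={nb} nab={nab} nall={nall}")
    if nb - nab > nall - na:
        raise ValueError("infeasible counts: nb - nab exceeds nall - na")
    if nab == 0:
        return 1.0  # empty sum in both variants
    p = float(hypergeom.sf(nab - 1, nall, na, nb))
    if variant == "standard":
        return p
    if variant == "as_printed":
        return p + float(hypergeom.pmf(0, nall, na, nb))
    raise ValueError(f"unknown variant {variant!r}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
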