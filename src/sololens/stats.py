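"""Shared statistical primitives: the one-sided exact enrichment test and
false-discovery-rate step-up corrections.

Both the pathway-level and the hub/cluster-level enrichment stages call the
same :func:`hypergeom_tail`, so identical 2x2 tables always yield identical
p values across the pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def hypergeom_tail(overlap: int, set_size: int, n_marked: int, n_universe: int) -> float:
    """One-sided (greater) Fisher exact p value for a 2x2 enrichment table.

    P(X >= overlap) with X ~ Hypergeom(N=n_universe, K=set_size, n=n_marked):
    the probability of drawing at least ``overlap`` set members when
    ``n_marked`` genes are drawn from a universe of ``n_universe`` containing
    ``set_size`` set members.
    """
    if not (0 <= set_size <= n_universe and 0 <= n_marked <= n_universe):
        raise ValueError("inconsistent 2x2 margins")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    return float(hypergeom.sf(overlap - 1, n_universe, set_size, n_marked))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ad/bc; +inf when bc = 0 with ad > 0, 0 when ad = 0.

    The fully degenerate table (ad = bc = 0) is reported as nan.
    """
    ad, bc = a * d, b * c
    if bc == 0:
        return float("nan") if ad == 0 else float("inf")
    return ad / bc


def _check_pvalues(p: np.ndarray) -> None:
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p values must lie in [0, 1]")


def _step_up(p: np.ndarray, scale: float) -> np.ndarray:
    """Generic FDR step-up: adj(i) = min(1, min_{j>=i} scale * p(j) / j)."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * scale / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float).ravel()
    _check_pvalues(p)
    if p.size == 0:
        return p.copy()
    return _step_up(p, float(p.size))


def adjust_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p values, in input order.

    Valid under arbitrary dependence between tests: inflates BH by
    c(m) = sum_{k=1..m} 1/k.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return p.copy()
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    return _step_up(p, m * c_m)
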