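"""Shared fixtures: small in-memory tables and graphs built at test time."""

import math

import networkx as nx
import numpy as np
import pytest

from sololens.io import CountTable, GeneSetCollection, InteractionTable


def hypergeom_tail_bruteforce(overlap: int, set_size: int, n_marked: int, n_universe: int) -> float:
    """Independent right-tail enumeration by binomial coefficients."""
    total = math.comb(n_universe, n_marked)
    lo = max(overlap, max(0, set_size + n_marked - n_universe))
    hi = min(set_size, n_marked)
    num = sum(
        math.comb(set_size, k) * math.comb(n_universe - set_size, n_marked - k)
        for k in range(lo, hi + 1)
    )
    return num / total


def by_stepup_bruteforce(p):
    """Direct Benjamini-Yekutieli step-up, written independently."""
    p = list(map(float, p))
    m = len(p)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m * c_m / rank)
        adj[i] = min(1.0, running)
    return adj


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["U", "T"],
        counts=np.array([[10, 20], [0, 0], [5, 5]]),
        condition_of_sample={"U": "untreated", "T": "treated"},
    )


@pytest.fixture
def small_genesets() -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            "S1": ("first", ["g1", "g2", "g3", "g4", "g5"]),
            "S2": ("second", ["g6", "g7", "g8", "g9", "g10"]),
        }
    )


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two disjoint unit-weight 5-cliques."""
    g = nx.Graph()
    for names in ("abcde", "vwxyz"):
        for i, u in enumerate(names):
            for v in names[i + 1 :]:
                g.add_edge(u, v, weight=1.0)
    return g


@pytest.fixture
def toy_interactions() -> InteractionTable:
    """The 4-interaction example used for network-construction checks."""
    return InteractionTable.from_records(
        [("A", "B", 800), ("A", "C", 750), ("C", "D", 900), ("B", "E", 650)]
    )
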