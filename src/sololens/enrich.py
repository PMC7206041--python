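"""Functional enrichment of gene lists (hubs, cluster members) against a
GMT collection, e.g. a GO Biological Process export.

Shares its exact-test core with the pathway stage
(:func:`sololens.stats.hypergeom_tail`), so identical 2x2 tables always
give identical p values. The default significance rule is uncorrected
p < 0.05; BH or BY correction is available because uncorrected term scans
are anticonservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ConfigError, GeneSetCollection
from .stats import adjust_bh, adjust_by, hypergeom_tail

log = logging.getLogger(__name__)

CORRECTIONS = ("none", "bh", "by")


class EnrichmentError(ValueError):
    pass


@dataclass
class SetEnrichmentReport:
    """Enrichment of one query gene list against every term in a collection.

    ``frame`` columns: term, description, overlap, term_size, query_size,
    universe_size, p_raw, p_adj, significant.
    """

    query_label: str
    frame: pd.DataFrame
    alpha: float
    correction: str

    def significant_terms(self) -> list[str]:
        return self.frame.loc[self.frame["significant"], "term"].tolist()


def enrich_gene_set(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    correction: str = "none",
    query_label: str = "query",
) -> SetEnrichmentReport:
    """One-sided hypergeometric enrichment of ``query`` per term.

    The universe defaults to all genes annotated in the collection; query
    ids outside the universe are dropped with a warning. Terms are tested
    on (query n term) against the universe; the significance flag uses
    p_raw when ``correction='none'``, otherwise the corrected p.
    """
    if correction not in CORRECTIONS:
        raise ConfigError(f"unknown correction {correction!r}")
    universe_set = set(universe) if universe is not None else sets.annotated_genes()
    query_set = set(query)
    if not query_set:
        raise EnrichmentError("empty query gene list")
    dropped = query_set - universe_set
    if dropped:
        log.warning(
            "%d query id(s) outside the universe dropped (e.g. %s)",
            len(dropped),
            sorted(dropped)[:5],
        )
    query_set &= universe_set
    if not query_set:
        raise EnrichmentError("no query gene lies in the universe")

    n_universe, n_query = len(universe_set), len(query_set)
    rows = []
    for term in sets.set_ids:
        members = set(sets.members(term)) & universe_set
        if not members:
            continue
        overlap = len(members & query_set)
        rows.append(
            {
                "term": term,
                "description": sets.description(term),
                "overlap": overlap,
                "term_size": len(members),
                "query_size": n_query,
                "universe_size": n_universe,
                "p_raw": hypergeom_tail(overlap, len(members), n_query, n_universe),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term", "description", "overlap", "term_size",
            "query_size", "universe_size", "p_raw",
        ],
    )
    if correction == "none":
        frame["p_adj"] = frame["p_raw"]
    elif correction == "bh":
        frame["p_adj"] = adjust_bh(frame["p_raw"].to_numpy()) if len(frame) else []
    else:
        frame["p_adj"] = adjust_by(frame["p_raw"].to_numpy()) if len(frame) else []
    key = "p_raw" if correction == "none" else "p_adj"
    frame["significant"] = frame[key] < alpha
    frame = frame.sort_values(["p_raw", "term"], kind="mergesort").reset_index(drop=True)
    return SetEnrichmentReport(
        query_label=query_label, frame=frame, alpha=alpha, correction=correction
    )
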