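"""Single-subject differential-expression analysis for one paired profile.

Given one untreated (U) and one treated (T) expression profile from the
same subject, this stage (i) normalizes the pair, (ii) computes signed and
absolute log2 fold changes, (iii) clusters genes into dysregulated vs
unaltered with a two-component Gaussian mixture on |log2FC| fitted by EM,
splitting dysregulated genes into up/down by the sign of the fold change,
and (iv) tests gene sets for enrichment of dysregulated genes
(bidirectionally: up and down counted together) with a one-sided Fisher
exact test, Benjamini-Yekutieli adjusted across the set collection.

Sign convention: lfc_signed = log2(T/U), so positive means higher under
treatment ("up"). The magnitude |log2FC| is identical under either
orientation of the ratio, which is all the mixture ever sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, CountTable, DegTable, GeneSetCollection
from .stats import adjust_by, hypergeom_tail, odds_ratio

log = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("upper_quartile", "total_count", "none")


class NormalizationError(ValueError):
    """A sample cannot be normalized (e.g. all-zero counts)."""


@dataclass
class NormalizedPair:
    gene_ids: list[str]
    u_norm: np.ndarray
    t_norm: np.ndarray
    normalization_method: str
    scale_factors: dict[str, float]


@dataclass
class FoldChangeProfile:
    gene_ids: list[str]
    lfc_signed: np.ndarray
    lfc_abs: np.ndarray
    pseudocount: float


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture over |log2FC|.

    Component 0 is the unaltered (small-|log2FC|) component, component 1
    the dysregulated one; ``posterior_dysregulated`` holds each gene's
    responsibility under component 1. ``degenerate`` marks fits that
    collapsed (vanishing sd or weight, or too few distinct values) and
    were replaced by an all-unaltered call.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    posterior_dysregulated: np.ndarray
    loglik_trace: list[float]
    converged: bool
    degenerate: bool
    seed: int
    n_iter: int


@dataclass
class GeneClassTable:
    """Per-gene dysregulation calls: up / down / unaltered."""

    frame: pd.DataFrame  # gene_id, gene_class, posterior_dysregulated, lfc_signed, lfc_abs

    def genes_in_class(self, gene_class: str) -> list[str]:
        return self.frame.loc[self.frame["gene_class"] == gene_class, "gene_id"].tolist()

    def dysregulated_genes(self) -> set[str]:
        mask = self.frame["gene_class"].isin(["up", "down"])
        return set(self.frame.loc[mask, "gene_id"])

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()


@dataclass
class EnrichmentResult:
    """One gene set's 2x2 enrichment summary."""

    set_id: str
    description: str
    a: int  # dysregulated, in set
    b: int  # unaltered, in set
    c: int  # dysregulated, out of set
    d: int  # unaltered, out of set
    odds_ratio: float
    p_raw: float
    p_adj: float
    n_up: int
    n_down: int


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Normalization and fold changes


def _pick_pair(
    table: CountTable, untreated: str | None, treated: str | None
) -> tuple[str, str]:
    if untreated is None:
        candidates = table.samples_with_condition("untreated")
        if len(candidates) != 1:
            raise ConfigError(
                f"expected exactly one untreated sample, found {candidates}"
            )
        untreated = candidates[0]
    if treated is None:
        candidates = table.samples_with_condition("treated")
        if len(candidates) != 1:
            raise ConfigError(f"expected exactly one treated sample, found {candidates}")
        treated = candidates[0]
    return untreated, treated


def normalize_pair(
    table: CountTable,
    method: str = "upper_quartile",
    untreated_sample: str | None = None,
    treated_sample: str | None = None,
) -> NormalizedPair:
    """Normalize one U/T pair of count columns.

    ``upper_quartile`` (default) divides each sample by the 75th percentile
    of its nonzero counts and rescales both to the mean of the two factors,
    so a pure global scaling of one library cancels exactly.
    ``total_count`` does the same with library totals; ``none`` returns the
    raw counts.
    """
    if method not in NORMALIZATION_METHODS:
        raise ConfigError(f"unknown normalization method {method!r}")
    u_id, t_id = _pick_pair(table, untreated_sample, treated_sample)
    u = table.sample_column(u_id).astype(float)
    t = table.sample_column(t_id).astype(float)

    def factor(x: np.ndarray, sample: str) -> float:
        nonzero = x[x > 0]
        if nonzero.size == 0:
            raise NormalizationError(f"sample {sample!r} is all zeros")
        if method == "upper_quartile":
            return float(np.percentile(nonzero, 75))
        return float(x.sum())

    if method == "none":
        f_u = f_t = 1.0
        u_norm, t_norm = u, t
    else:
        f_u, f_t = factor(u, u_id), factor(t, t_id)
        target = 0.5 * (f_u + f_t)
        u_norm = u / f_u * target
        t_norm = t / f_t * target
    return NormalizedPair(
        gene_ids=list(table.gene_ids),
        u_norm=u_norm,
        t_norm=t_norm,
        normalization_method=method,
        scale_factors={u_id: f_u, t_id: f_t},
    )


def compute_fold_changes(pair: NormalizedPair, pseudocount: float = 0.5) -> FoldChangeProfile:
    """Signed log2((T + c)/(U + c)) and its absolute value, per gene."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    lfc = np.log2((pair.t_norm + pseudocount) / (pair.u_norm + pseudocount))
    return FoldChangeProfile(
        gene_ids=list(pair.gene_ids),
        lfc_signed=lfc,
        lfc_abs=np.abs(lfc),
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# Mixture clustering


def _degenerate_fit(n: int, seed: int, trace: list[float] | None = None) -> MixtureFit:
    log.warning("degenerate mixture fit: calling all %d genes unaltered", n)
    return MixtureFit(
        weights=np.array([1.0, 0.0]),
        means=np.array([0.0, 0.0]),
        sds=np.array([0.0, 0.0]),
        posterior_dysregulated=np.zeros(n),
        loglik_trace=trace or [],
        converged=True,
        degenerate=True,
        seed=seed,
        n_iter=0,
    )


def _log_normal_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def fit_dysregulation_mixture(
    profile: FoldChangeProfile | np.ndarray,
    K: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to the |log2FC| values.

    Component means are initialized at the 50th and 95th percentiles;
    convergence is declared when the log-likelihood gain drops below
    ``tol`` (the trace is non-decreasing, a property the tests check).
    The larger-mean component is labelled dysregulated. Fits with a
    component sd below 1e-6 or weight below 1e-4, or with fewer distinct
    values than components, fall back to an all-unaltered call.
    """
    if K != 2:
        raise ConfigError("only the two-component magnitude mixture is supported")
    x = profile.lfc_abs if isinstance(profile, FoldChangeProfile) else np.asarray(profile, float)
    n = x.size
    if np.unique(x).size < K:
        return _degenerate_fit(n, seed)

    means = np.array([np.percentile(x, 50), np.percentile(x, 95)])
    if means[1] - means[0] < 1e-12:
        return _degenerate_fit(n, seed)
    sds = np.full(2, max(float(np.std(x)), 1e-3))
    weights = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    it = 0
    resp = np.zeros((n, 2))
    for it in range(1, max_iter + 1):
        # E step
        log_comp = np.column_stack(
            [np.log(weights[k]) + _log_normal_pdf(x, means[k], sds[k]) for k in range(2)]
        )
        log_norm = np.logaddexp(log_comp[:, 0], log_comp[:, 1])
        trace.append(float(np.sum(log_norm)))
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk / n < 1e-4):
            return _degenerate_fit(n, seed, trace)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < 1e-6):
            return _degenerate_fit(n, seed, trace)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            converged = True
            break

    # order components: 0 = unaltered (small mean), 1 = dysregulated
    order = np.argsort(means)
    weights, means, sds = weights[order], means[order], sds[order]
    resp = resp[:, order]
    return MixtureFit(
        weights=weights,
        means=means,
        sds=sds,
        posterior_dysregulated=resp[:, 1],
        loglik_trace=trace,
        converged=converged,
        degenerate=False,
        seed=seed,
        n_iter=it,
    )


def classify_genes(
    fit: MixtureFit, profile: FoldChangeProfile, threshold: float = 0.5
) -> GeneClassTable:
    """Call each gene up / down / unaltered from the mixture posterior.

    A gene is dysregulated iff its posterior under the dysregulated
    component exceeds ``threshold``; the sign of lfc_signed splits up from
    down. A gene with lfc_signed exactly 0 stays unaltered whatever the
    posterior says.
    """
    posterior = fit.posterior_dysregulated
    classes = np.where(
        (posterior > threshold) & (profile.lfc_signed > 0),
        "up",
        np.where((posterior > threshold) & (profile.lfc_signed < 0), "down", "unaltered"),
    )
    frame = pd.DataFrame(
        {
            "gene_id": profile.gene_ids,
            "gene_class": classes,
            "posterior_dysregulated": posterior,
            "lfc_signed": profile.lfc_signed,
            "lfc_abs": profile.lfc_abs,
        }
    )
    return GeneClassTable(frame=frame)


# ---------------------------------------------------------------------------
# Pathway enrichment


def pathway_fet(
    classes: GeneClassTable,
    sets: GeneSetCollection,
    universe_policy: str = "measured",
    min_set_size: int = 5,
) -> list[EnrichmentResult]:
    """Bidirectional dysregulation enrichment per gene set.

    For each set, a one-sided (greater) Fisher exact test on the 2x2 table
    (dysregulated = up + down vs unaltered; in-set vs out-of-set) over the
    measured universe (``universe_policy='annotated'`` restricts it to
    genes annotated in at least one set). Sets with fewer than
    ``min_set_size`` measured members are skipped. p values are BY-adjusted
    across all tested sets in one batch.
    """
    if universe_policy not in ("measured", "annotated"):
        raise ConfigError(f"unknown universe policy {universe_policy!r}")
    universe = set(classes.gene_ids)
    if universe_policy == "annotated":
        universe &= sets.annotated_genes()
    dysregulated = classes.dysregulated_genes() & universe
    up = set(classes.genes_in_class("up"))
    down = set(classes.genes_in_class("down"))
    n_universe, n_dys = len(universe), len(dysregulated)
    if n_universe == 0 or n_dys == 0:
        log.warning("no dysregulated genes in the universe; all enrichment p = 1")

    results: list[EnrichmentResult] = []
    for set_id in sets.set_ids:
        members = set(sets.members(set_id)) & universe
        if len(members) < min_set_size:
            continue
        a = len(members & dysregulated)
        b = len(members) - a
        c = n_dys - a
        d = (n_universe - len(members)) - c
        p = hypergeom_tail(a, len(members), n_dys, n_universe) if n_universe else 1.0
        results.append(
            EnrichmentResult(
                set_id=set_id,
                description=sets.description(set_id),
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=odds_ratio(a, b, c, d),
                p_raw=p,
                p_adj=np.nan,
                n_up=len(members & up),
                n_down=len(members & down),
            )
        )
    if results:
        adjusted = adjust_by([r.p_raw for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_adj = float(p_adj)
    return results


# ---------------------------------------------------------------------------
# DEG selection


def select_degs(
    source: DegTable | GeneClassTable,
    lfc_threshold: float = 1.0,
    p_adj_threshold: float = 0.05,
) -> DegTable:
    """Threshold a DEG table or a single-subject gene-class table.

    For an externally computed DEG table: keep |log2FC| > lfc_threshold AND
    p_adj < p_adj_threshold. For a single-subject gene-class table: keep
    up/down genes with |log2FC| > lfc_threshold; 1 - posterior fills the
    p_adj column of the result.
    """
    if isinstance(source, DegTable):
        f = source.frame
        keep = (f["log2fc"].abs() > lfc_threshold) & (f["p_adj"] < p_adj_threshold)
        return DegTable(frame=f.loc[keep].reset_index(drop=True))
    f = source.frame
    keep = f["gene_class"].isin(["up", "down"]) & (f["lfc_abs"] > lfc_threshold)
    out = pd.DataFrame(
        {
            "gene_id": f.loc[keep, "gene_id"],
            "log2fc": f.loc[keep, "lfc_signed"],
            "p_adj": 1.0 - f.loc[keep, "posterior_dysregulated"],
        }
    ).reset_index(drop=True)
    return DegTable(frame=out)
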