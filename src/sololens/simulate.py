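"""Synthetic paired transcriptomes and planted-community interactomes.

The count generator emulates the structure of the study design every
downstream stage expects: one subject, one untreated and one treated
profile per time point, a pathway (gene-set) collection in which a chosen
subset of pathways carries implanted bidirectional dysregulation, and a
ground-truth record for recovery tests. Counts follow a negative binomial
with a shared dispersion; treated means are shifted by a signed log2
effect for dysregulated genes and globally scaled by a library-size ratio
so that normalization is actually exercised.

The interactome generator plants dense communities in a sparse background
graph with STRING-style integer confidence scores, giving the network
stage a fixture with known modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, CountTable, GeneSetCollection, InteractionTable

GENE_CLASSES = ("up", "down", "unaltered")


@dataclass
class SimulationConfig:
    """Knobs for the paired-count generator.

    Defaults describe the reference condition used throughout the test
    suite: 5,000 genes, 100 pathways of 30-50 genes, 10 of them implanted
    with 50% member dysregulation over a 5% background, log2 effect sizes
    |N(2.5, 0.4)| with balanced sign, NB dispersion 0.05, baseline mean
    counts log-uniform on [e^3, e^8] (~20-3000), and a 1.3-fold treated
    library-size imbalance.
    """

    n_genes: int = 5000
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (30, 50)
    n_implanted_pathways: int = 10
    within_implanted_dysreg_frac: float = 0.5
    background_dysreg_frac: float = 0.05
    effect_mean: float = 2.5
    effect_sd: float = 0.4
    nb_dispersion: float = 0.05
    baseline_mean_log_range: tuple[float, float] = (3.0, 8.0)
    library_size_ratio: float = 1.3
    up_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("within_implanted_dysreg_frac", "background_dysreg_frac", "up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_implanted_pathways > self.n_pathways:
            raise ConfigError("more implanted pathways than pathways")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ConfigError("pathway larger than the gene universe")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.library_size_ratio <= 0:
            raise ConfigError("library_size_ratio must be > 0")
        if self.baseline_mean_log_range[0] > self.baseline_mean_log_range[1]:
            raise ConfigError("invalid baseline_mean_log_range")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated dataset."""

    true_class: dict[str, str] = field(default_factory=dict)
    implanted_pathway_ids: list[str] = field(default_factory=list)
    planted_communities: list[list[str]] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in GENE_CLASSES}
        for c in self.true_class.values():
            counts[c] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.true_class), "true_class": list(self.true_class.values())}
        )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with var = mu + dispersion * mu^2 (size r = 1/dispersion)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_paired_counts(
    config: SimulationConfig,
) -> tuple[CountTable, GeneSetCollection, SyntheticTruth]:
    """Simulate one untreated/treated pair plus pathways and ground truth.

    Per-gene baseline means are log-uniform; untreated counts are
    NB(mean, dispersion) and treated counts NB(mean * 2^delta * ratio,
    dispersion), where delta = sign * |N(effect_mean, effect_sd)| for
    dysregulated genes and 0 otherwise. Genes inside implanted pathways are
    dysregulated at ``within_implanted_dysreg_frac``, everything else at
    ``background_dysreg_frac``. Fully deterministic under ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    lo, hi = config.pathway_size_range
    sets: dict[str, tuple[str, list[str]]] = {}
    members_of: dict[str, np.ndarray] = {}
    for j in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        idx = np.sort(rng.choice(config.n_genes, size=size, replace=False))
        set_id = f"PW{j:03d}"
        sets[set_id] = (f"synthetic pathway {j}", [genes[i] for i in idx])
        members_of[set_id] = idx
    implanted = sorted(
        f"PW{j:03d}"
        for j in rng.choice(config.n_pathways, size=config.n_implanted_pathways, replace=False)
    )

    in_implanted = np.zeros(config.n_genes, dtype=bool)
    for set_id in implanted:
        in_implanted[members_of[set_id]] = True
    dysreg_prob = np.where(
        in_implanted, config.within_implanted_dysreg_frac, config.background_dysreg_frac
    )
    dysregulated = rng.random(config.n_genes) < dysreg_prob
    up = rng.random(config.n_genes) < config.up_fraction
    magnitude = np.abs(rng.normal(config.effect_mean, config.effect_sd, config.n_genes))
    delta = np.where(dysregulated, np.where(up, magnitude, -magnitude), 0.0)

    log_lo, log_hi = config.baseline_mean_log_range
    baseline = np.exp(rng.uniform(log_lo, log_hi, config.n_genes))
    u_counts = _nb_sample(rng, baseline, config.nb_dispersion)
    t_mean = baseline * np.exp2(delta) * config.library_size_ratio
    t_counts = _nb_sample(rng, t_mean, config.nb_dispersion)

    table = CountTable(
        gene_ids=genes,
        sample_ids=["U", "T"],
        counts=np.column_stack([u_counts, t_counts]),
        condition_of_sample={"U": "untreated", "T": "treated"},
        time_label=None,
    )
    true_class = {
        g: ("up" if up[i] else "down") if dysregulated[i] else "unaltered"
        for i, g in enumerate(genes)
    }
    truth = SyntheticTruth(true_class=true_class, implanted_pathway_ids=implanted)
    return table, GeneSetCollection(sets=sets), truth


def simulate_interactome(
    n_nodes: int,
    n_communities: int,
    community_size: int,
    p_in: float = 0.9,
    p_out: float = 0.01,
    score_in_range: tuple[int, int] = (701, 999),
    score_out_range: tuple[int, int] = (150, 400),
    seed: int = 0,
    node_labels: list[str] | None = None,
) -> tuple[InteractionTable, SyntheticTruth]:
    """Planted-partition interactome with STRING-style confidence scores.

    The first ``n_communities * community_size`` nodes (in label order) form
    consecutive dense communities wired with probability ``p_in`` and scores
    uniform over ``score_in_range``; every other node pair is wired with
    probability ``p_out`` and scores over ``score_out_range``. Deterministic
    under ``seed``.
    """
    if community_size * n_communities > n_nodes:
        raise ConfigError("communities do not fit in the node universe")
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ConfigError("edge probabilities must lie in [0, 1]")
    if node_labels is None:
        node_labels = [f"P{i:04d}" for i in range(n_nodes)]
    elif len(node_labels) != n_nodes:
        raise ConfigError("node_labels length must equal n_nodes")

    rng = np.random.default_rng(seed)
    community = np.full(n_nodes, -1)
    for k in range(n_communities):
        community[k * community_size : (k + 1) * community_size] = k

    ii, jj = np.triu_indices(n_nodes, k=1)
    same = (community[ii] >= 0) & (community[ii] == community[jj])
    draw = rng.random(ii.size)
    keep = np.where(same, draw < p_in, draw < p_out)
    scores = np.where(
        same,
        rng.integers(score_in_range[0], score_in_range[1] + 1, ii.size),
        rng.integers(score_out_range[0], score_out_range[1] + 1, ii.size),
    )
    labels = np.asarray(node_labels, dtype=object)
    records = list(zip(labels[ii[keep]], labels[jj[keep]], scores[keep].tolist()))
    table = InteractionTable.from_records(records)
    truth = SyntheticTruth(
        planted_communities=[
            [node_labels[i] for i in range(k * community_size, (k + 1) * community_size)]
            for k in range(n_communities)
        ]
    )
    return table, truth
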