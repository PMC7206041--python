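"""End-to-end orchestration: simulate -> ssa -> select_degs -> network -> enrich.

One YAML-loadable config and one global seed drive the whole run. The
global seed fans out to per-stage seeds by fixed offsets so stages stay
independently reproducible. Every stage writes TSV (or GraphML) outputs
under the run directory; a JSON manifest records the config snapshot,
seed, and a SHA-256 digest per output file, so two runs with the same
config can be compared digest-by-digest.

The interactome fixture is generated inside the simulate stage with node
labels drawn from implanted-pathway genes (which form the planted
communities) plus background genes. Implanted genes are enriched for
dysregulation, so the DEG seeds of the network stage are present in the
interaction table without the simulator having to peek at SSA output.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import enrich_gene_set
from .io import (
    ConfigError,
    CountTable,
    read_counts,
    read_deg_table,
    read_gmt,
    read_interactions,
    write_counts,
    write_deg_table,
    write_gmt,
    write_interactions,
)
from .network import (
    annotate_significance,
    build_network,
    find_hubs,
    grow_clusters,
    merge_overlapping,
    write_edge_list,
    write_graphml,
)
from .simulate import SimulationConfig, simulate_interactome, simulate_paired_counts
from .ssa import (
    classify_genes,
    compute_fold_changes,
    enrichment_frame,
    fit_dysregulation_mixture,
    normalize_pair,
    pathway_fet,
    select_degs,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "ssa", "select_degs", "network", "enrich")

# fixed per-stage seed offsets fanning out from the global seed
SEED_OFFSETS = {"simulate": 11, "interactome": 23, "ssa": 37}


def default_config() -> dict:
    """Bundled demo configuration: small enough to run in seconds."""
    return {
        "seed": 0,
        "simulate": {
            "n_genes": 5000,
            "n_pathways": 100,
            "pathway_size_range": [30, 50],
            "n_implanted_pathways": 10,
            "within_implanted_dysreg_frac": 0.5,
            "background_dysreg_frac": 0.05,
            "effect_mean": 2.5,
            "effect_sd": 0.4,
            "nb_dispersion": 0.05,
            "baseline_mean_log_range": [3.0, 8.0],
            "library_size_ratio": 1.3,
            "up_fraction": 0.5,
            "interactome": {
                "n_nodes": 150,
                "n_communities": 4,
                "community_size": 20,
                "p_in": 0.9,
                "p_out": 0.01,
                "score_in_range": [701, 999],
                "score_out_range": [150, 400],
            },
        },
        "ssa": {
            "normalization": "upper_quartile",
            "pseudocount": 0.5,
            "min_set_size": 5,
            "alpha": 0.05,
        },
        "select_degs": {"lfc_threshold": 1.0, "p_adj_threshold": 0.05},
        "network": {
            "score_min": 700,
            "expansion": "first_shell",
            "hub_fraction": 0.10,
            "penalty": 2.0,
            "min_size": 3,
            "min_density": 0.5,
            "omega_threshold": 0.8,
            "alpha": 0.05,
        },
        "enrich": {"alpha": 0.05, "correction": "none"},
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def stage_digests(self) -> dict[str, dict[str, str]]:
        """Per-stage mapping of output file name -> SHA-256; timestamps excluded."""
        return {s["name"]: s["outputs"] for s in self.stages}

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    """Overlay a (possibly partial) user config onto the demo defaults."""
    def merge(base: dict, over: dict) -> dict:
        out = dict(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                out[k] = merge(base[k], v)
            else:
                out[k] = v
        return out

    cfg = merge(default_config(), user)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    missing = [s for s in ("seed", *STAGES) if s not in cfg and s != "select_degs"]
    unknown = set(cfg) - {"seed", *STAGES, "inputs"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    if missing:
        raise ConfigError(f"config missing section(s): {missing}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute every stage in order, writing outputs and a manifest.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    cfg = copy.deepcopy(config)
    _validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = RunManifest(
        config=cfg,
        seed=seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def record(stage: str, files: list[Path]) -> None:
        manifest.stages.append(
            {"name": stage, "outputs": {f.name: _sha256(f) for f in files}}
        )

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = {k: v for k, v in cfg["simulate"].items() if k != "interactome"}
        sim_cfg = {
            k: tuple(v) if isinstance(v, list) else v for k, v in sim_cfg.items()
        }
        sc = SimulationConfig(**sim_cfg, seed=seed + SEED_OFFSETS["simulate"])
        counts, genesets, truth = simulate_paired_counts(sc)

        icfg = cfg["simulate"]["interactome"]
        implanted_genes = sorted(
            {g for pw in truth.implanted_pathway_ids for g in genesets.members(pw)}
        )
        rng = np.random.default_rng(seed + SEED_OFFSETS["interactome"])
        n_nodes = icfg["n_nodes"]
        n_comm_nodes = icfg["n_communities"] * icfg["community_size"]
        labels = list(rng.permutation(implanted_genes))[:n_comm_nodes]
        background = [g for g in counts.gene_ids if g not in set(labels)]
        labels += list(rng.permutation(background))[: n_nodes - len(labels)]
        interactions, net_truth = simulate_interactome(
            n_nodes=n_nodes,
            n_communities=icfg["n_communities"],
            community_size=icfg["community_size"],
            p_in=icfg["p_in"],
            p_out=icfg["p_out"],
            score_in_range=tuple(icfg["score_in_range"]),
            score_out_range=tuple(icfg["score_out_range"]),
            seed=seed + SEED_OFFSETS["interactome"],
            node_labels=labels,
        )
        truth.planted_communities = net_truth.planted_communities

        write_counts(counts, out / "counts.tsv")
        write_gmt(genesets, out / "pathways.gmt")
        write_interactions(interactions, out / "interactions.tsv")
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        record(stage, [out / "counts.tsv", out / "pathways.gmt",
                       out / "interactions.tsv", out / "truth.tsv"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- ssa ---------------------------------------------------------------
    stage = "ssa"
    try:
        s = cfg["ssa"]
        pair = normalize_pair(counts, method=s["normalization"])
        profile = compute_fold_changes(pair, pseudocount=s["pseudocount"])
        fit = fit_dysregulation_mixture(profile, seed=seed + SEED_OFFSETS["ssa"])
        classes = classify_genes(fit, profile)
        results = pathway_fet(classes, genesets, min_set_size=s["min_set_size"])
        classes.frame.to_csv(out / "gene_classes.tsv", sep="\t", index=False,
                             float_format="%.10g")
        ef = enrichment_frame(results).sort_values(["p_adj", "set_id"], kind="mergesort")
        ef.to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False,
                  float_format="%.10g")
        record(stage, [out / "gene_classes.tsv", out / "pathway_enrichment.tsv"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- select_degs -------------------------------------------------------
    stage = "select_degs"
    try:
        d = cfg["select_degs"]
        degs = select_degs(classes, lfc_threshold=d["lfc_threshold"],
                           p_adj_threshold=d["p_adj_threshold"])
        write_deg_table(degs, out / "degs.tsv")
        record(stage, [out / "degs.tsv"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- network -----------------------------------------------------------
    stage = "network"
    try:
        n = cfg["network"]
        net = build_network(degs, interactions, score_min=n["score_min"],
                            expansion=n["expansion"])
        hubs = find_hubs(net, fraction=n["hub_fraction"])
        clusters = grow_clusters(net, penalty=n["penalty"], min_size=n["min_size"],
                                 min_density=n["min_density"])
        clusters = merge_overlapping(clusters, net, omega_threshold=n["omega_threshold"],
                                     penalty=n["penalty"])
        clusters = annotate_significance(net, clusters, alpha=n["alpha"])

        write_graphml(net, out / "network.graphml")
        write_edge_list(net, out / "edges.tsv")
        pd.DataFrame(
            {"node": hubs.node_ids, "degree": [hubs.degrees[v] for v in hubs.node_ids]}
        ).to_csv(out / "hubs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "cluster": f"C{i + 1}",
                    "size": cl.size,
                    "cohesiveness": cl.cohesiveness,
                    "p_value": cl.p_value,
                    "significant": cl.significant,
                    "members": ",".join(sorted(cl.nodes)),
                }
                for i, cl in enumerate(clusters)
            ],
            columns=["cluster", "size", "cohesiveness", "p_value", "significant", "members"],
        ).to_csv(out / "clusters.tsv", sep="\t", index=False, float_format="%.10g")
        record(stage, [out / "network.graphml", out / "edges.tsv",
                       out / "hubs.tsv", out / "clusters.tsv"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- enrich ------------------------------------------------------------
    stage = "enrich"
    try:
        e = cfg["enrich"]
        hub_report = enrich_gene_set(
            hubs.node_ids, genesets, alpha=e["alpha"], correction=e["correction"],
            query_label="hubs",
        )
        hub_report.frame.to_csv(out / "enrichment_hubs.tsv", sep="\t", index=False,
                                float_format="%.10g")
        cluster_rows = []
        for i, cl in enumerate(clusters):
            if not cl.significant:
                continue
            rep = enrich_gene_set(
                sorted(cl.nodes), genesets, alpha=e["alpha"],
                correction=e["correction"], query_label=f"C{i + 1}",
            )
            f = rep.frame.copy()
            f.insert(0, "cluster", f"C{i + 1}")
            cluster_rows.append(f)
        if cluster_rows:
            cluster_frame = pd.concat(cluster_rows, ignore_index=True)
        else:
            cluster_frame = pd.DataFrame(
                columns=["cluster", "term", "description", "overlap", "term_size",
                         "query_size", "universe_size", "p_raw", "p_adj", "significant"]
            )
        cluster_frame.to_csv(out / "enrichment_clusters.tsv", sep="\t", index=False,
                             float_format="%.10g")
        record(stage, [out / "enrichment_hubs.tsv", out / "enrichment_clusters.tsv"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.save(out / "manifest.json")
    return manifest
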