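"""Readers and writers for the tabular formats the pipeline touches.

Conventions shared by every format here: UTF-8, tab-separated values,
``#``-prefixed comment lines ignored, decimal point (never comma).
Identifier namespaces (gene symbols vs protein ids) are the caller's
responsibility; :func:`read_alias_map` supports an explicit gene->protein
translation for the DEG-seeding step, defaulting to the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONDITIONS = ("untreated", "treated")


class ParseError(ValueError):
    """A file violated its format contract."""


class ConfigError(ValueError):
    """A configuration value or mapping is invalid or incomplete."""


# ---------------------------------------------------------------------------
# CountTable


@dataclass
class CountTable:
    """Per-gene integer counts for one subject, genes x samples.

    Each sample is labelled either ``untreated`` or ``treated``;
    ``time_label`` is free text such as ``"5h"`` identifying the
    treatment time point the pair belongs to.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    condition_of_sample: dict[str, str]
    time_label: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ConfigError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ParseError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ParseError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            gene = self.gene_ids[int(np.argwhere(self.counts < 0)[0][0])]
            raise ParseError(f"negative count in row for gene {gene!r}")
        for s in self.sample_ids:
            cond = self.condition_of_sample.get(s)
            if cond not in CONDITIONS:
                raise ConfigError(
                    f"sample {s!r} has no valid condition label (got {cond!r})"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def samples_with_condition(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of_sample[s] == condition]


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate found")


def read_counts(
    path: str | Path,
    condition_map: Mapping[str, str],
    time_label: str | None = None,
) -> CountTable:
    """Read a counts TSV (header = sample ids, first column = gene ids).

    Every sample in the header must appear in ``condition_map`` with value
    ``untreated`` or ``treated``.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a gene column plus at least one sample")
    gene_ids = df.iloc[:, 0].tolist()
    sample_ids = list(df.columns[1:])
    for s in sample_ids:
        if s not in condition_map:
            raise ConfigError(f"sample {s!r} missing from condition map")
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad_row = int(numeric.isna().any(axis=1).idxmax())
        raise ParseError(
            f"{path}: non-numeric count in row for gene {gene_ids[bad_row]!r}"
        )
    return CountTable(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=numeric.to_numpy(),
        condition_of_sample={s: condition_map[s] for s in sample_ids},
        time_label=time_label,
    )


def write_counts(table: CountTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, columns=table.sample_ids)
    df.insert(0, "gene_id", table.gene_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection / GMT


@dataclass
class GeneSetCollection:
    """Gene sets keyed by set id; each value is (description, member ids)."""

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ConfigError(f"gene set {set_id!r} has no members")
            if len(set(members)) != len(members):
                raise ConfigError(f"gene set {set_id!r} has duplicate members")

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def annotated_genes(self) -> set[str]:
        genes: set[str] = set()
        for _, members in self.sets.values():
            genes.update(members)
        return genes


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB gene1 TAB gene2 ...``.

    Member lists are deduplicated preserving order; sets left empty after
    deduplication are dropped with a warning.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, desc = fields[0], fields[1]
            if set_id in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                log.warning("dropping empty gene set %r (%s:%d)", set_id, path, lineno)
                continue
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# InteractionTable (STRING links dialect)


@dataclass
class InteractionTable:
    """Undirected scored protein interactions.

    ``frame`` columns: ``protein_a``, ``protein_b``, ``combined_score``
    (integer 0-999) plus any per-evidence-channel score columns
    (e.g. ``experiments``, ``database``). Pairs are stored once, in
    lexicographic order, self-interactions removed.
    """

    frame: pd.DataFrame
    n_self_loops_dropped: int = 0
    n_duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        req = {"protein_a", "protein_b", "combined_score"}
        if not req.issubset(self.frame.columns):
            raise ConfigError(f"interaction frame missing columns {req - set(self.frame.columns)}")
        s = self.frame["combined_score"]
        if len(s) and (s.min() < 0 or s.max() > 999):
            raise ParseError("combined_score outside 0-999")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def channel_columns(self) -> list[str]:
        return [
            c for c in self.frame.columns
            if c not in ("protein_a", "protein_b", "combined_score")
        ]

    def proteins(self) -> set[str]:
        return set(self.frame["protein_a"]) | set(self.frame["protein_b"])

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], channel_names: Sequence[str] = ()
    ) -> "InteractionTable":
        """Build from (a, b, combined_score[, channel scores...]) tuples."""
        cols = ["protein_a", "protein_b", "combined_score", *channel_names]
        df = pd.DataFrame.from_records(list(records), columns=cols)
        return _canonicalize_interactions(df)


def _canonicalize_interactions(df: pd.DataFrame) -> InteractionTable:
    score = pd.to_numeric(df["combined_score"], errors="coerce")
    if score.isna().any():
        raise ParseError("non-numeric combined_score")
    if len(score) and (score.min() < 0 or score.max() > 999):
        raise ParseError("combined_score outside 0-999")
    df = df.copy()
    df["combined_score"] = score.astype(np.int64)

    self_loops = df["protein_a"] == df["protein_b"]
    n_self = int(self_loops.sum())
    if n_self:
        log.warning("dropped %d self-interaction(s)", n_self)
        df = df[~self_loops]

    a = df["protein_a"].to_numpy(dtype=object)
    b = df["protein_b"].to_numpy(dtype=object)
    flip = a > b
    df.loc[flip, ["protein_a", "protein_b"]] = df.loc[
        flip, ["protein_b", "protein_a"]
    ].to_numpy()

    before = len(df)
    df = (
        df.sort_values("combined_score", ascending=False, kind="mergesort")
        .drop_duplicates(subset=["protein_a", "protein_b"], keep="first")
        .sort_values(["protein_a", "protein_b"], kind="mergesort")
        .reset_index(drop=True)
    )
    return InteractionTable(
        frame=df,
        n_self_loops_dropped=n_self,
        n_duplicates_collapsed=before - len(df),
    )


def read_interactions(
    path: str | Path, score_column: str = "combined_score"
) -> InteractionTable:
    """Read a STRING-links-style table (whitespace or TAB delimited).

    The first two columns are the protein pair; ``score_column`` names the
    combined confidence score (0-999). Unordered duplicate pairs are
    collapsed keeping the maximum score; self-loops are dropped (logged).
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need two protein columns and a score column")
    if score_column not in df.columns:
        raise ParseError(f"{path}: no column named {score_column!r}")
    prot_a, prot_b = df.columns[0], df.columns[1]
    out = df.rename(
        columns={prot_a: "protein_a", prot_b: "protein_b", score_column: "combined_score"}
    )
    # keep evidence channels after the canonical three
    ordered = ["protein_a", "protein_b", "combined_score"] + [
        c for c in out.columns if c not in ("protein_a", "protein_b", "combined_score")
    ]
    try:
        return _canonicalize_interactions(out[ordered])
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DegTable


@dataclass
class DegTable:
    """Differentially expressed genes: gene_id, log2fc, p_adj."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"gene_id", "log2fc", "p_adj"}
        if not req.issubset(self.frame.columns):
            raise ConfigError(f"DEG frame missing columns {req - set(self.frame.columns)}")
        if self.frame["gene_id"].duplicated().any():
            dup = self.frame["gene_id"][self.frame["gene_id"].duplicated()].iloc[0]
            raise ParseError(f"duplicate gene id in DEG table: {dup!r}")
        p = self.frame["p_adj"]
        if len(p) and ((p < 0).any() or (p > 1).any()):
            raise ParseError("p_adj outside [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()


def read_deg_table(path: str | Path) -> DegTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return DegTable(frame=df[["gene_id", "log2fc", "p_adj"]])


def write_deg_table(table: DegTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Alias map (gene id -> protein id)


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping gene ids to interactome protein ids."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: alias map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
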