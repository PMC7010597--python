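"""Domain containers and plain-text readers/writers.

Expression matrices are genes x samples DataFrames; gene sets come from GMT;
pathway graphs and the protein-interaction network are undirected
:class:`networkx.Graph` objects read from two-column edge lists (SIF
accepted); mutation profiles are long-format record tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "PathwayGraph",
    "InteractionNetwork",
    "MutationProfile",
    "SampleGroupSet",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_pathway",
    "read_mutations",
    "write_mutations",
    "read_groups",
    "write_groups",
    "intersect_genes",
    "filter_mutations",
    "summarize_mutation_combinations",
    "DEFAULT_EXCLUDED_MUTATION_TYPES",
]

DEFAULT_EXCLUDED_MUTATION_TYPES = ("Silent", "Intron", "5'UTR")


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values in arbitrary units.

    Gene and sample identifiers are unique, case-sensitive symbols; all
    values are finite.
    """

    values: pd.DataFrame  # index: gene symbols, columns: sample ids

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.shape[0] < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        arr = df.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PathwayGraph:
    """A connected, undirected pathway graph with per-gene degrees.

    Disconnected pathways are rejected at construction, mirroring the
    upstream filter that keeps only pathways whose genes form a single
    connected component.
    """

    name: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise ValueError(f"pathway {self.name!r} has no genes")
        if any(u == v for u, v in g.edges()):
            raise ValueError(f"pathway {self.name!r} contains self-loops")
        if not nx.is_connected(g):
            raise ValueError(
                f"pathway {self.name!r} is not connected; disconnected "
                "pathways are excluded"
            )

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes())

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected, simple protein-interaction network."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges()):
            raise ValueError("interaction network contains self-loops")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class MutationProfile:
    """Long-format somatic mutation records (sample_id, gene, mutation_type)."""

    records: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "mutation_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation records missing columns: {missing}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def mutated_genes(self, sample_id: str) -> frozenset[str]:
        sub = self.records[self.records["sample_id"] == sample_id]
        return frozenset(sub["gene"])


@dataclass(frozen=True)
class SampleGroupSet:
    """Sample groups, each with an ordered driver-mutation gene list.

    The driver list may be empty (e.g. a normal group).
    """

    groups: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]]
    # label -> (sample_ids, mutated_driver_genes)

    def sample_ids(self, label: str) -> tuple[str, ...]:
        return self.groups[label][0]

    def drivers(self, label: str) -> tuple[str, ...]:
        return self.groups[label][1]

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        known = set(expr.sample_ids)
        for label, (samples, _) in self.groups.items():
            unknown = [s for s in samples if s not in known]
            if unknown:
                raise ValueError(
                    f"group {label!r} references samples absent from the "
                    f"expression matrix: {unknown[:5]}"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV (header = sample ids, first column = genes).

    Duplicate gene rows (multiple probes of one gene) are collapsed by the
    arithmetic mean of their raw values before any rank transform.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header line declares no samples")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        rows = np.nonzero(numeric.isna().any(axis=1).to_numpy())[0]
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(
            f"{path}: non-numeric or missing value at line {rows[0] + 2}"
        )
    numeric.index = numeric.index.astype(str)
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format: name <tab> description <tab> members..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one member"
                )
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set has no members")
            sets.append(GeneSet(parts[0], members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


def _read_edges(path: str | Path) -> list[tuple[str, str]]:
    """Two-column edge-list TSV; a middle SIF relation column is tolerated."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:  # SIF (a relation b) or weighted (a b w)
                try:
                    float(parts[2])
                    a, b = parts[0], parts[1]
                except ValueError:
                    a, b = parts[0], parts[2]
            else:
                raise FormatError(f"{path}: line {lineno}: expected 2-3 columns")
            edges.append((a, b))
    return edges


def read_network(path: str | Path) -> InteractionNetwork:
    g = nx.Graph()
    for a, b in _read_edges(path):
        if a != b:
            g.add_edge(a, b)
    return InteractionNetwork(g)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_pathway(path: str | Path, name: str | None = None) -> PathwayGraph:
    g = nx.Graph()
    for a, b in _read_edges(path):
        if a != b:
            g.add_edge(a, b)
    return PathwayGraph(name or Path(path).stem, g)


def write_pathway(pw: PathwayGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in pw.graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_mutations(path: str | Path) -> MutationProfile:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return MutationProfile(df)


def write_mutations(m: MutationProfile, path: str | Path) -> None:
    m.records.to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path, drivers: Mapping[str, Sequence[str]] | None = None) -> SampleGroupSet:
    """Read sample_id/group_label TSV; ``drivers`` maps label -> driver list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group_label"} <= set(df.columns):
        raise FormatError(f"{path}: needs sample_id and group_label columns")
    drivers = drivers or {}
    groups = {}
    for label, sub in df.groupby("group_label", sort=False):
        groups[label] = (
            tuple(sub["sample_id"]),
            tuple(drivers.get(label, ())),
        )
    return SampleGroupSet(groups)


def write_groups(groups: SampleGroupSet, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "group_label": label}
        for label in groups.labels
        for s in groups.sample_ids(label)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in sorted order.

    Joint cross-platform analysis operates on the shared gene universe;
    downstream rank scores use its size as N.
    """
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("expression matrices share no genes")
    if len(common) < 2:
        raise ValueError("fewer than 2 common genes")
    return (
        ExpressionMatrix(a.values.loc[common]),
        ExpressionMatrix(b.values.loc[common]),
    )


def filter_mutations(
    m: MutationProfile,
    excluded_types: Iterable[str] = DEFAULT_EXCLUDED_MUTATION_TYPES,
) -> MutationProfile:
    """Drop records whose mutation type is excluded (case-insensitive match).

    The default removes silent, intronic and 5'UTR records, which do not
    alter the protein product.
    """
    excluded = {t.lower() for t in excluded_types}
    if not excluded:
        raise ValueError("excluded_types must be a non-empty list")
    keep = ~m.records["mutation_type"].str.lower().isin(excluded)
    return MutationProfile(m.records[keep].reset_index(drop=True))


def summarize_mutation_combinations(
    m: MutationProfile, driver_genes: Sequence[str]
) -> pd.DataFrame:
    """Tabulate which subset of the driver genes each sample mutates.

    Samples with no driver mutation are excluded from the denominator;
    fractions sum to 1 over samples carrying at least one driver mutation.
    Returns columns: combination_pattern (comma-joined in driver order),
    sample_count, fraction.
    """
    if not driver_genes:
        raise ValueError("driver_genes must be non-empty")
    driver_order = {g: i for i, g in enumerate(driver_genes)}
    patterns: dict[tuple[str, ...], int] = {}
    for sample in m.samples:
        hit = m.mutated_genes(sample) & set(driver_genes)
        if not hit:
            continue
        key = tuple(sorted(hit, key=driver_order.__getitem__))
        patterns[key] = patterns.get(key, 0) + 1
    if not patterns:
        raise ValueError("no sample mutates any driver gene")
    total = sum(patterns.values())
    rows = [
        {
            "combination_pattern": ",".join(key),
            "sample_count": count,
            "fraction": count / total,
        }
        for key, count in sorted(
            patterns.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return pd.DataFrame(rows)
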