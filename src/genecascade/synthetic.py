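"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of the study data without downloads:
a scale-free protein-interaction network (preferential attachment),
connected pathway subgraphs (breadth-first balls), two sample groups whose
log-expression differs by an additive shift on the genes of planted
"dysregulated" pathways, and per-sample driver-mutation records with decoy
silent mutations. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    GeneSet,
    InteractionNetwork,
    MutationProfile,
    PathwayGraph,
    SampleGroupSet,
    write_expression,
    write_gmt,
    write_groups,
    write_mutations,
    write_network,
    write_pathway,
)
from .propagation import select_seeds

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticBundle",
    "generate_network",
    "generate_pathways",
    "generate_expression",
    "generate_mutations",
    "generate_bundle",
    "write_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the synthetic generators.

    ``delta`` is the tumor-group log-scale shift in units of the
    within-gene standard deviation ``sigma``; ``m`` is the preferential-
    attachment parameter. The seed is mandatory: all generators are
    deterministic given (config, seed).
    """

    n_genes: int = 5000
    n_samples: int = 10  # per group
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 30)
    m: int = 3
    delta: float = 3.0
    sigma: float = 1.0
    frac_dysregulated: float = 0.10
    n_key_genes: int = 5
    n_drivers: int = 2
    decoy_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= self.m or self.m < 1:
            raise ValueError("need n_genes > m >= 1")
        lo, hi = self.pathway_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError("pathway size range must fit inside the gene universe")
        if self.delta < 0 or self.sigma <= 0:
            raise ValueError("delta must be >= 0 and sigma > 0")
        for name in ("n_samples", "n_pathways", "n_key_genes", "n_drivers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: dysregulated pathways, key genes, group drivers."""

    dysregulated_pathways: tuple[str, ...]
    key_genes: tuple[str, ...]
    drivers_by_group: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete, self-consistent input set for the whole pipeline."""

    network: InteractionNetwork
    pathways: list[PathwayGraph]
    gene_sets: list[GeneSet]
    expr_organoid: ExpressionMatrix
    expr_tumor: ExpressionMatrix
    groups: SampleGroupSet
    mutations: MutationProfile
    truth: GroundTruth


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(cfg: SyntheticConfig) -> InteractionNetwork:
    """Scale-free network by preferential attachment.

    Growth starts from a clique on m+1 nodes; each subsequent node attaches
    m edges to distinct existing nodes with probability proportional to
    current degree. The graph is connected by construction and has exactly
    ``m(n-m-1) + m(m+1)/2`` edges.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = _gene_names(cfg.n_genes)
    g = nx.Graph()
    core = genes[: cfg.m + 1]
    g.add_nodes_from(core)
    for i, a in enumerate(core):
        for b in core[i + 1 :]:
            g.add_edge(a, b)
    existing = list(core)
    degree = {node: cfg.m for node in core}
    for new in genes[cfg.m + 1 :]:
        weights = np.array([degree[n] for n in existing], dtype=float)
        targets: list[int] = []
        while len(targets) < cfg.m:
            pick = int(rng.choice(len(existing), p=weights / weights.sum()))
            if pick not in targets:
                targets.append(pick)
        for t in targets:
            tgt = existing[t]
            g.add_edge(new, tgt)
            degree[tgt] += 1
        degree[new] = cfg.m
        existing.append(new)
    return InteractionNetwork(g)


def generate_pathways(
    network: InteractionNetwork, cfg: SyntheticConfig, max_retries: int = 50
) -> list[PathwayGraph]:
    """Connected pathway subgraphs: BFS balls around random roots, truncated
    to a target size drawn from the configured range.

    Pathways are grown over mutually disjoint node sets so that planting a
    shift on one pathway's genes never leaks signal into another — the
    ground truth stays identifiable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    nodes = sorted(network.nodes)
    lo, hi = cfg.pathway_size_range
    width = len(str(cfg.n_pathways))
    used: set[str] = set()
    pathways = []
    for i in range(1, cfg.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members: list[str] | None = None
        for _ in range(max_retries):
            root = nodes[int(rng.integers(len(nodes)))]
            if root in used:
                continue
            order = [root]
            seen = {root}
            for node in order:  # BFS over unused nodes, sorted expansion
                if len(order) >= size:
                    break
                for nb in sorted(network.graph.neighbors(node)):
                    if nb not in seen and nb not in used:
                        seen.add(nb)
                        order.append(nb)
                        if len(order) >= size:
                            break
            if len(order) >= size:
                members = order[:size]
                used.update(members)
                break
        if members is None:
            raise RuntimeError(
                f"could not grow a connected pathway of size {size} "
                f"after {max_retries} roots"
            )
        sub = network.graph.subgraph(members).copy()
        pathways.append(PathwayGraph(f"PW{i:0{width}d}", sub))
    return pathways


def _planted_key_genes(
    network: InteractionNetwork,
    dysregulated: Sequence[PathwayGraph],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Key genes are non-seed network neighbors of dysregulated-pathway hubs,
    so recovering them exercises the propagation stage. Neighbors touching
    the hubs of several dysregulated pathways are preferred: proximity to
    many seed sets is what the Fisher combination rewards."""
    seed_sets = [set(select_seeds(pw, network).seeds) for pw in dysregulated]
    all_seeds = set().union(*seed_sets)
    counts: dict[str, int] = {}
    for seeds in seed_sets:
        touched = {
            nb
            for s in seeds
            for nb in network.graph.neighbors(s)
            if nb not in all_seeds
        }
        for nb in touched:
            counts[nb] = counts.get(nb, 0) + 1
    pool = sorted(counts, key=lambda g: (-counts[g], g))
    if len(pool) < cfg.n_key_genes:
        raise ValueError("too few hub neighbors to plant the requested key genes")
    # random choice within the top count tier, then descend tiers
    chosen: list[str] = []
    i = 0
    while len(chosen) < cfg.n_key_genes:
        tier = [g for g in pool if counts[g] == counts[pool[i]]]
        need = cfg.n_key_genes - len(chosen)
        if len(tier) <= need:
            chosen.extend(tier)
        else:
            picks = rng.choice(len(tier), size=need, replace=False)
            chosen.extend(tier[j] for j in sorted(picks))
        i += len(tier)
    return tuple(sorted(chosen))


def generate_expression(
    pathways: Sequence[PathwayGraph],
    cfg: SyntheticConfig,
    network: InteractionNetwork | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Organoid and tumor expression with planted dysregulation.

    Gene g's log-expression is Normal(mu_g, sigma) with mu_g ~ Normal(0, 1);
    values are exponentiated (log-normal), which leaves within-sample ranks
    unchanged. The tumor group receives an extra +delta*sigma on the log
    scale for every gene belonging to a dysregulated pathway.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    genes = _gene_names(cfg.n_genes)
    n_dys = max(1, round(cfg.frac_dysregulated * len(pathways)))
    dys_idx = sorted(rng.choice(len(pathways), size=n_dys, replace=False))
    dysregulated = [pathways[i] for i in dys_idx]
    shifted_genes = sorted(set().union(*(pw.nodes for pw in dysregulated)))

    mu = rng.normal(0.0, 1.0, size=cfg.n_genes)
    org = mu[:, None] + rng.normal(0.0, cfg.sigma, size=(cfg.n_genes, cfg.n_samples))
    tum = mu[:, None] + rng.normal(0.0, cfg.sigma, size=(cfg.n_genes, cfg.n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    shift_rows = [gene_index[g] for g in shifted_genes if g in gene_index]
    tum[shift_rows, :] += cfg.delta * cfg.sigma

    key_genes: tuple[str, ...] = ()
    if network is not None:
        key_genes = _planted_key_genes(network, dysregulated, cfg, rng)

    org_samples = [f"ORG{j:02d}" for j in range(1, cfg.n_samples + 1)]
    tum_samples = [f"TUM{j:02d}" for j in range(1, cfg.n_samples + 1)]
    expr_org = ExpressionMatrix(
        pd.DataFrame(np.exp(org), index=genes, columns=org_samples)
    )
    expr_tum = ExpressionMatrix(
        pd.DataFrame(np.exp(tum), index=genes, columns=tum_samples)
    )
    truth = GroundTruth(
        dysregulated_pathways=tuple(pw.name for pw in dysregulated),
        key_genes=key_genes,
    )
    return expr_org, expr_tum, truth


def generate_mutations(
    groups: SampleGroupSet, cfg: SyntheticConfig
) -> MutationProfile:
    """Missense records for every group's declared drivers in every sample,
    plus decoy Silent records for exercising the mutation-type filter."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    rows = []
    for label in groups.labels:
        for sample in groups.sample_ids(label):
            for gene in groups.drivers(label):
                rows.append(
                    {"sample_id": sample, "gene": gene, "mutation_type": "Missense"}
                )
                if rng.random() < cfg.decoy_fraction:
                    rows.append(
                        {"sample_id": sample, "gene": gene, "mutation_type": "Silent"}
                    )
    return MutationProfile(pd.DataFrame(rows))


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a full consistent input set with recorded ground truth.

    Group drivers are the top-degree (seed) genes of the first dysregulated
    pathway, so cascade paths have sensible mutant starting points.
    """
    network = generate_network(cfg)
    pathways = generate_pathways(network, cfg)
    expr_org, expr_tum, truth = generate_expression(pathways, cfg, network)
    by_name = {pw.name: pw for pw in pathways}
    first_dys = by_name[truth.dysregulated_pathways[0]]
    drivers = tuple(select_seeds(first_dys, network).seeds[: cfg.n_drivers])
    groups = SampleGroupSet(
        {
            "organoid": (tuple(expr_org.sample_ids), drivers),
            "tumor": (tuple(expr_tum.sample_ids), drivers),
        }
    )
    truth = replace(
        truth, drivers_by_group={"organoid": drivers, "tumor": drivers}
    )
    mutations = generate_mutations(groups, cfg)
    gene_sets = [GeneSet(pw.name, frozenset(pw.nodes)) for pw in pathways]
    return SyntheticBundle(
        network=network,
        pathways=pathways,
        gene_sets=gene_sets,
        expr_organoid=expr_org,
        expr_tumor=expr_tum,
        groups=groups,
        mutations=mutations,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the bundle as plain-text files (TSV/GMT) plus a pathway manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expr_organoid, out / "expression_organoid.tsv")
    write_expression(bundle.expr_tumor, out / "expression_tumor.tsv")
    write_network(bundle.network, out / "network.tsv")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    pw_dir = out / "pathways"
    pw_dir.mkdir(exist_ok=True)
    manifest = []
    for pw in bundle.pathways:
        write_pathway(pw, pw_dir / f"{pw.name}.tsv")
        manifest.append({"name": pw.name, "file": f"pathways/{pw.name}.tsv"})
    pd.DataFrame(manifest).to_csv(out / "pathway_manifest.tsv", sep="\t", index=False)
    write_mutations(bundle.mutations, out / "mutations.tsv")
    write_groups(bundle.groups, out / "groups.tsv")
    drivers = pd.DataFrame(
        [
            {"group_label": label, "drivers": ",".join(bundle.groups.drivers(label))}
            for label in bundle.groups.labels
        ]
    )
    drivers.to_csv(out / "group_drivers.tsv", sep="\t", index=False)
    truth = bundle.truth
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("kind\tvalue\n")
        for name in truth.dysregulated_pathways:
            fh.write(f"dysregulated_pathway\t{name}\n")
        for g in truth.key_genes:
            fh.write(f"key_gene\t{g}\n")
        for label, ds in truth.drivers_by_group.items():
            fh.write(f"drivers:{label}\t{','.join(ds)}\n")
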