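"""Functional-coherence networks and gene cascading paths.

Candidate key genes and the organoid's mutant driver genes are connected by
pairwise functional coherence — by default the cosine similarity of their
binary function-membership vectors over the loaded pathway/gene-set
annotation (a declared, pluggable substitute for annotation-based coherence
measures). Pairs at coherence >= 0.4 (inclusive) form the functional
consistency network, which is then sparsified by keeping each gene's two
highest-coherence neighbors. A gene cascading path starts at the mutant
genes and ends at the reachable candidate whose shortest distance from the
mutant set is maximal, tracing one deterministic shortest path.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SparseCoherenceNetwork",
    "CascadePath",
    "cosine_coherence",
    "functional_coherence",
    "coherence_matrix",
    "build_coherence_network",
    "sparsify_top2",
    "extract_cascade_path",
    "annotation_from_gene_sets",
]

CoherenceMeasure = Callable[[frozenset[str], frozenset[str]], float]


@dataclass(frozen=True)
class SparseCoherenceNetwork:
    """Top-2-per-node sparsification of the coherence network.

    ``selected_by`` records which endpoint(s) kept each edge; every node
    contributes at most two selections, though its final degree may exceed
    two through its neighbors' selections.
    """

    graph: nx.Graph
    selected_by: dict[tuple[str, str], frozenset[str]]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes())


@dataclass(frozen=True)
class CascadePath:
    """Ordered gene path from a mutant gene to the selected candidate."""

    genes: tuple[str, ...]
    start: str
    end: str
    distance: int

    def __post_init__(self) -> None:
        if self.genes[0] != self.start or self.genes[-1] != self.end:
            raise ValueError("path endpoints inconsistent with gene list")
        if len(self.genes) - 1 != self.distance:
            raise ValueError("path length must equal the endpoint distance")

    @property
    def length(self) -> int:
        return len(self.genes) - 1


def cosine_coherence(a: frozenset[str], b: frozenset[str]) -> float:
    """Cosine similarity of binary membership vectors: |A∩B| / sqrt(|A||B|)."""
    if not a or not b:
        return 0.0
    return len(a & b) / float(np.sqrt(len(a) * len(b)))


def annotation_from_gene_sets(
    gene_sets: Iterable, genes: Iterable[str] | None = None
) -> dict[str, frozenset[str]]:
    """Build gene -> {function names} from GeneSet/PathwayGraph collections."""
    ann: dict[str, set[str]] = {}
    for gs in gene_sets:
        members = gs.members if hasattr(gs, "members") else gs.nodes
        for g in members:
            ann.setdefault(g, set()).add(gs.name)
    if genes is not None:
        ann = {g: ann.get(g, set()) for g in genes}
    return {g: frozenset(v) for g, v in ann.items()}


def neighborhood_annotation(
    gene_sets: Iterable, network, genes: Iterable[str] | None = None
) -> dict[str, frozenset[str]]:
    """Annotate genes with the functions they belong to *or border*.

    A gene bordering a function (a direct interaction-network neighbor of
    one of its members) is taken to participate in it. This yields the
    overlapping annotation that real functional catalogs have even when the
    loaded gene sets themselves are disjoint.
    """
    from .data_model import InteractionNetwork

    ann: dict[str, set[str]] = {}
    graph = network.graph if isinstance(network, InteractionNetwork) else network
    for gs in gene_sets:
        members = set(gs.members if hasattr(gs, "members") else gs.nodes)
        touched = set(members)
        for m in members:
            if m in graph:
                touched.update(graph.neighbors(m))
        for g in touched:
            ann.setdefault(g, set()).add(gs.name)
    if genes is not None:
        ann = {g: ann.get(g, set()) for g in genes}
    return {g: frozenset(v) for g, v in ann.items()}


def functional_coherence(
    gene_a: str,
    gene_b: str,
    annotation: Mapping[str, frozenset[str]],
    measure: CoherenceMeasure = cosine_coherence,
) -> float:
    """Pairwise functional coherence in [0, 1] under the given measure."""
    for g in (gene_a, gene_b):
        if g not in annotation or not annotation[g]:
            raise ValueError(f"gene {g!r} has no functional annotation")
    if gene_a == gene_b:
        return 1.0
    return float(measure(frozenset(annotation[gene_a]), frozenset(annotation[gene_b])))


def coherence_matrix(
    genes: Sequence[str],
    annotation: Mapping[str, frozenset[str]],
    measure: CoherenceMeasure = cosine_coherence,
) -> pd.DataFrame:
    """Symmetric gene x gene coherence matrix with unit diagonal."""
    genes = list(dict.fromkeys(genes))
    n = len(genes)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = functional_coherence(
                genes[i], genes[j], annotation, measure
            )
    return pd.DataFrame(mat, index=genes, columns=genes)


def build_coherence_network(
    genes: Sequence[str], coherence: pd.DataFrame, threshold: float = 0.4
) -> nx.Graph:
    """Edge (a, b) iff coherence(a, b) >= threshold (inclusive), a != b."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            w = float(coherence.loc[a, b])
            if w >= threshold:
                g.add_edge(a, b, weight=w)
    return g


def sparsify_top2(g: nx.Graph) -> SparseCoherenceNetwork:
    """Keep, per node, its two highest-coherence incident edges (union over nodes).

    Ties are broken by weight descending then neighbor symbol ascending, so
    the result is independent of node iteration order.
    """
    selected: dict[tuple[str, str], set[str]] = {}
    for node in g.nodes():
        nbrs = sorted(
            g.neighbors(node),
            key=lambda nb: (-g[node][nb]["weight"], nb),
        )
        for nb in nbrs[:2]:
            key = tuple(sorted((node, nb)))
            selected.setdefault(key, set()).add(node)
    sparse = nx.Graph()
    sparse.add_nodes_from(g.nodes())
    for (a, b), pickers in selected.items():
        sparse.add_edge(a, b, weight=g[a][b]["weight"])
    return SparseCoherenceNetwork(
        sparse, {k: frozenset(v) for k, v in selected.items()}
    )


def _bfs_from_set(graph: nx.Graph, sources: Sequence[str]) -> tuple[dict, dict]:
    """Deterministic multi-source BFS: alphabetical source and neighbor order."""
    dist: dict[str, int] = {}
    parent: dict[str, str | None] = {}
    queue: deque[str] = deque()
    for s in sorted(sources):
        dist[s] = 0
        parent[s] = None
        queue.append(s)
    while queue:
        node = queue.popleft()
        for nb in sorted(graph.neighbors(node)):
            if nb not in dist:
                dist[nb] = dist[node] + 1
                parent[nb] = node
                queue.append(nb)
    return dist, parent


def extract_cascade_path(
    net: SparseCoherenceNetwork,
    mutant_genes: Iterable[str],
    candidates: Mapping[str, float] | Sequence[str],
) -> tuple[CascadePath, pd.DataFrame]:
    """Path from the mutant set to the maximally distant reachable candidate.

    ``candidates`` maps candidate genes to their key-gene q-values (a bare
    sequence is treated as equal q). Each candidate's distance is the
    minimum shortest-path length from any mutant gene; the endpoint
    maximizes this distance, with ties resolved by smaller q then by gene
    symbol. Returns the path plus a table of all candidates (gene,
    distance, q, chosen) where unreachable candidates have missing distance.
    """
    if not isinstance(candidates, Mapping):
        candidates = {g: float("nan") for g in candidates}
    mutants = sorted(set(mutant_genes) & net.nodes)
    if not mutants:
        raise ValueError("no mutant gene is present in the coherence network")
    cand_in = sorted(set(candidates) & net.nodes)
    if not cand_in:
        raise ValueError("no candidate gene is present in the coherence network")

    dist, parent = _bfs_from_set(net.graph, mutants)
    reachable = [c for c in cand_in if c in dist]
    if not reachable:
        comps = [sorted(c) for c in nx.connected_components(net.graph)]
        raise ValueError(
            f"no candidate reachable from mutant genes; components: {comps}"
        )

    def sort_key(c: str):
        q = candidates[c]
        return (-dist[c], q if q == q else float("inf"), c)  # NaN q sorts last

    endpoint = min(reachable, key=sort_key)
    chain = [endpoint]
    while parent[chain[-1]] is not None:
        chain.append(parent[chain[-1]])
    chain.reverse()
    path = CascadePath(
        genes=tuple(chain), start=chain[0], end=endpoint, distance=dist[endpoint]
    )
    table = pd.DataFrame(
        {
            "candidate": cand_in,
            "distance": [dist.get(c, np.nan) for c in cand_in],
            "q": [candidates[c] for c in cand_in],
            "chosen": [c == endpoint for c in cand_in],
        }
    ).sort_values(
        ["distance", "candidate"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return path, table
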