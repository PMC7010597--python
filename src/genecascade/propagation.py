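"""Random walk with restart and subsequent-key-gene inference.

For each dysregulated pathway, its top-degree genes (degree computed within
the pathway graph) seed a random walk with restart (RWR) on the
protein-interaction network:

    P_{t+1} = (1 - r) W P_t + r P_0

with restart probability ``r`` (default 0.7), column-stochastic transfer
matrix ``W``, and ``P_0`` uniform over the seeds. The walk stops when
``max|P_{t+1} - P_t|`` drops below the tolerance (default 1e-8). Per-gene
significance is empirical against pseudo-seed walks (random seed sets of
the same size); per-pathway p-values are combined across the K dysregulated
pathways with Fisher's method (chi-square with 2K degrees of freedom), and
genes at Benjamini-Hochberg FDR <= 0.05 are called subsequent key genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .data_model import InteractionNetwork, PathwayGraph

__all__ = [
    "RWRParams",
    "SeedSet",
    "PropagationVector",
    "CombinedSignificance",
    "select_seeds",
    "rwr",
    "function_pvalues",
    "combine_significance",
    "infer_key_genes",
]


@dataclass(frozen=True)
class RWRParams:
    """Restart probability, convergence tolerance and iteration cap."""

    restart: float = 0.7
    tolerance: float = 1e-8
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart probability must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass(frozen=True)
class SeedSet:
    """Seed genes for one pathway, with their within-pathway degrees."""

    function: str
    seeds: tuple[str, ...]
    source_degrees: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seed set is empty")


@dataclass(frozen=True)
class PropagationVector:
    """Steady-state RWR probabilities over the network's genes."""

    probabilities: pd.Series  # gene -> probability, sums to 1
    iterations: int


@dataclass(frozen=True)
class CombinedSignificance:
    """Fisher chi-square combination of one gene's per-pathway p-values."""

    gene: str
    p_values: tuple[float, ...]
    chi2: float
    df: int
    p_combined: float
    q_value: float
    is_key: bool
    excluded_reason: str = ""


def select_seeds(
    pathway: PathwayGraph,
    network: InteractionNetwork,
    fraction: float = 0.10,
) -> SeedSet:
    """Pick the pathway's top-degree genes as propagation seeds.

    Degree is computed within the pathway graph. ``ceil(fraction * size)``
    genes are taken (at least one), ties at the cutoff broken by gene
    symbol; seeds absent from the interaction network are then dropped.
    """
    if fraction <= 0:
        raise ValueError("seed fraction must be positive")
    if not (pathway.nodes & network.nodes):
        raise ValueError(
            f"pathway {pathway.name!r} shares no gene with the network"
        )
    degree = pathway.degree
    n_seed = max(1, math.ceil(fraction * len(degree)))
    ranked = sorted(degree, key=lambda g: (-degree[g], g))
    chosen = ranked[:n_seed]
    in_network = tuple(g for g in chosen if g in network.nodes)
    if not in_network:
        raise ValueError(
            f"all seeds of pathway {pathway.name!r} are absent from the network"
        )
    return SeedSet(pathway.name, in_network, {g: degree[g] for g in in_network})


def _node_order(network: InteractionNetwork) -> list[str]:
    return sorted(network.nodes)


def transfer_matrix(network: InteractionNetwork) -> tuple[sp.csc_matrix, list[str]]:
    """Column-stochastic adjacency; isolated nodes get a unit self-loop."""
    nodes = _node_order(network)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b in network.graph.edges():
        ia, ib = index[a], index[b]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
    adj = sp.csc_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    isolated = np.nonzero(col_sums == 0)[0]
    if isolated.size:
        adj = adj + sp.csc_matrix(
            (np.ones(isolated.size), (isolated, isolated)), shape=(n, n)
        )
        col_sums[isolated] = 1.0
    w = adj @ sp.diags(1.0 / col_sums)
    return sp.csc_matrix(w), nodes


def _p0(seeds: Sequence[str], nodes: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(nodes)}
    missing = [g for g in seeds if g not in index]
    if missing:
        raise ValueError(f"seeds not in network: {missing[:5]}")
    p0 = np.zeros(len(nodes))
    p0[[index[g] for g in seeds]] = 1.0 / len(seeds)
    return p0


def _iterate(
    w: sp.csc_matrix, p0: np.ndarray, params: RWRParams
) -> tuple[np.ndarray, int]:
    r = params.restart
    p = p0.copy()
    for it in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (w @ p) + r * p0
        resid = np.max(np.abs(p_next - p))
        p = p_next
        if resid < params.tolerance:
            return p, it
    raise RuntimeError(
        f"RWR did not converge in {params.max_iter} iterations "
        f"(last residual {resid:.3e})"
    )


def _solve(w: sp.csc_matrix, p0: np.ndarray, params: RWRParams) -> np.ndarray:
    r = params.restart
    a = sp.eye(w.shape[0], format="csc") - (1.0 - r) * w
    return r * splu(a).solve(p0)


def rwr(
    network: InteractionNetwork,
    seeds: SeedSet,
    params: RWRParams = RWRParams(),
    method: str = "iterative",
) -> PropagationVector:
    """Propagate from the seed set to a steady state.

    ``method="iterative"`` runs the power iteration to the declared
    tolerance; ``method="solve"`` evaluates the closed form
    ``P = r (I - (1-r) W)^{-1} P_0`` by a direct sparse solve. Both agree
    to within the iteration tolerance.
    """
    w, nodes = transfer_matrix(network)
    p0 = _p0(seeds.seeds, nodes)
    if method == "iterative":
        p, iters = _iterate(w, p0, params)
    elif method == "solve":
        p, iters = _solve(w, p0, params), 0
    else:
        raise ValueError(f"unknown method {method!r}")
    return PropagationVector(pd.Series(p, index=nodes), iters)


def function_pvalues(
    network: InteractionNetwork,
    pathway: PathwayGraph,
    params: RWRParams = RWRParams(),
    n_random: int = 1000,
    seed: int | None = None,
    fraction: float = 0.10,
    method: str = "iterative",
    degree_matched: bool = False,
) -> pd.Series:
    """Empirical per-gene significance of proximity to one pathway's seeds.

    ``n_random`` pseudo seed sets of the same size are drawn uniformly
    without replacement from the network's genes (``degree_matched=True``
    instead resamples each seed from its degree-decile bin) and the walk is
    re-run for each. For gene j,
    ``p_j = (1 + #{pseudo steady-state value >= observed}) / (n_random + 1)``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for pseudo-seed sampling")
    seed_set = select_seeds(pathway, network, fraction)
    w, nodes = transfer_matrix(network)
    n = len(nodes)
    k = len(seed_set.seeds)
    if k >= n:
        raise ValueError("seed set must be smaller than the network")

    # factor once; every pseudo-seed run is still an exact independent solve
    lu = splu(sp.csc_matrix(sp.eye(n) - (1.0 - params.restart) * w)) if (
        method == "solve"
    ) else None

    def steady(p0: np.ndarray) -> np.ndarray:
        if method == "solve":
            return params.restart * lu.solve(p0)
        return _iterate(w, p0, params)[0]

    observed = steady(_p0(seed_set.seeds, nodes))

    rng = np.random.default_rng(seed)
    node_arr = np.arange(n)
    if degree_matched:
        degrees = np.array([network.graph.degree(g) for g in nodes])
        bins = np.searchsorted(
            np.quantile(degrees, np.linspace(0.1, 0.9, 9)), degrees, side="right"
        )
        index = {g: i for i, g in enumerate(nodes)}
        seed_bins = [bins[index[g]] for g in seed_set.seeds]
        pools = {b: node_arr[bins == b] for b in set(bins)}
    pseudo0 = np.zeros((n, n_random))
    for t in range(n_random):
        if degree_matched:
            picks: list[int] = []
            for b in seed_bins:
                pool = pools[b]
                pick = int(rng.choice(pool))
                while pick in picks:
                    pick = int(rng.choice(pool))
                picks.append(pick)
            idx = np.array(picks)
        else:
            idx = rng.choice(n, size=k, replace=False)
        pseudo0[idx, t] = 1.0 / k
    if method == "solve":
        # one exact solve per pseudo-seed set, batched over right-hand sides
        null = params.restart * lu.solve(pseudo0)
    else:
        # full power iteration for every pseudo-seed set, run in one batch;
        # each column is an independent walk iterated to the tolerance
        null = pseudo0.copy()
        r = params.restart
        for _ in range(params.max_iter):
            nxt = (1.0 - r) * (w @ null) + r * pseudo0
            resid = np.max(np.abs(nxt - null))
            null = nxt
            if resid < params.tolerance:
                break
        else:
            raise RuntimeError(
                f"pseudo-seed RWR did not converge (residual {resid:.3e})"
            )
    exceed = (null >= observed[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_random + 1.0)
    return pd.Series(p, index=nodes, name=pathway.name)


def combine_significance(
    per_function_p: pd.DataFrame,
    fdr: float = 0.05,
    mutated_genes: Iterable[str] = (),
) -> list[CombinedSignificance]:
    """Fisher-combine each gene's K per-pathway p-values.

    ``chi2 = -2 sum_k ln p_k`` is referred to the chi-square distribution
    with 2K degrees of freedom; Benjamini-Hochberg runs across genes. Genes
    already mutated in the organoid are reported but never called key.
    """
    if per_function_p.shape[1] < 1:
        raise ValueError("need at least one function's p-values (K >= 1)")
    values = per_function_p.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError(
            "p-value of 0 encountered; use pseudocount p-values upstream"
        )
    if np.any(values > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = values.shape[1]
    chi2 = -2.0 * np.log(values).sum(axis=1)
    p_comb = chi2_dist.sf(chi2, df=2 * k)
    q = multipletests(p_comb, method="fdr_bh")[1]
    mutated = set(mutated_genes)
    out = []
    for i, gene in enumerate(per_function_p.index):
        excluded = "driver_mutated" if gene in mutated else ""
        out.append(
            CombinedSignificance(
                gene=str(gene),
                p_values=tuple(float(v) for v in values[i]),
                chi2=float(chi2[i]),
                df=2 * k,
                p_combined=float(p_comb[i]),
                q_value=float(q[i]),
                is_key=bool(q[i] <= fdr and not excluded),
                excluded_reason=excluded,
            )
        )
    return out


def infer_key_genes(
    network: InteractionNetwork,
    dysregulated_pathways: Sequence[PathwayGraph],
    params: RWRParams = RWRParams(),
    n_random: int = 1000,
    fdr: float = 0.05,
    seed: int | None = None,
    mutated_genes: Iterable[str] = (),
    fraction: float = 0.10,
    method: str = "iterative",
) -> pd.DataFrame:
    """Rank candidate subsequent key genes across K dysregulated pathways.

    Composes seed selection, pseudo-seed propagation significance per
    pathway, and Fisher combination; the result is sorted by q then chi2
    (descending). Columns: gene, K, chi2, df, p_combined, q, is_key,
    excluded_reason, plus one p_<pathway> column per pathway.
    """
    if not dysregulated_pathways:
        raise ValueError("at least one dysregulated pathway is required")
    if seed is None:
        raise ValueError("a seed is required")
    streams = np.random.SeedSequence(seed).spawn(len(dysregulated_pathways))
    per_fun = pd.DataFrame(
        {
            pw.name: function_pvalues(
                network,
                pw,
                params,
                n_random=n_random,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                fraction=fraction,
                method=method,
            )
            for pw, ss in zip(dysregulated_pathways, streams)
        }
    )
    combined = combine_significance(per_fun, fdr=fdr, mutated_genes=mutated_genes)
    frame = pd.DataFrame(
        {
            "gene": [c.gene for c in combined],
            "K": [len(c.p_values) for c in combined],
            "chi2": [c.chi2 for c in combined],
            "df": [c.df for c in combined],
            "p_combined": [c.p_combined for c in combined],
            "q": [c.q_value for c in combined],
            "is_key": [c.is_key for c in combined],
            "excluded_reason": [c.excluded_reason for c in combined],
        }
    )
    for col in per_fun.columns:
        frame[f"p_{col}"] = per_fun[col].to_numpy()
    frame = frame.sort_values(
        ["q", "chi2", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return frame
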