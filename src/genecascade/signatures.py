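"""Hallmark-signature activity via a running-sum enrichment statistic.

The enrichment score (ES) of a gene set against a ranked gene list is the
classical weighted Kolmogorov-Smirnov running sum: walking down the ranking,
hits increment by ``|metric|^p`` normalized over the set's genes and misses
decrement by ``1/(N - |set|)``; the ES is the signed maximum deviation.

Stepwise organoid comparisons rank genes by the difference of group-mean
rank scores (organoid with more mutations minus the other) and test the
observed ES of each signature against a null obtained by permuting gene
labels within each sample's score vector. Single-sample activity uses each
sample's own rank-score vector as the ranking metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import GeneSet, SampleGroupSet
from .rank_activity import RankScoreMatrix, _permute_columns

__all__ = [
    "RankedGeneList",
    "ActivationCall",
    "make_ranking",
    "enrichment_score",
    "pairwise_signature_test",
    "sample_signature_activity",
    "group_activity_correlation",
    "calls_to_frame",
]


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by a real-valued metric, descending, ties broken by symbol."""

    gene_ids: tuple[str, ...]
    metric: np.ndarray  # aligned with gene_ids, non-increasing

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ActivationCall:
    """Two-tailed permutation verdict on one signature's activity difference."""

    signature: str
    es_a: float
    es_b: float
    es_diff: float
    p_activation: float
    p_inactivation: float
    q_activation: float
    q_inactivation: float
    call: str  # "activated" | "inactivated" | "ns"


def make_ranking(gene_ids: Sequence[str], metric: np.ndarray) -> RankedGeneList:
    """Order genes by metric descending; ties broken by gene symbol."""
    genes = np.asarray(gene_ids)
    metric = np.asarray(metric, dtype=float)
    if genes.shape != metric.shape:
        raise ValueError("gene_ids and metric lengths differ")
    lexpos = np.argsort(np.argsort(genes))
    order = np.lexsort((lexpos, -metric))
    return RankedGeneList(tuple(genes[order]), metric[order])


def _es_from_order(
    hit_mask: np.ndarray, metric_ordered: np.ndarray, p: float
) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = hit_mask.size
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("gene set has no gene in the ranking")
    if k == n:
        raise ValueError("gene set covers the entire ranking")
    if p == 0:
        hit_w = np.where(hit_mask, 1.0 / k, 0.0)
    else:
        w = np.where(hit_mask, np.abs(metric_ordered) ** p, 0.0)
        total = w.sum()
        if total == 0:  # all in-set metrics are zero; fall back to flat hits
            hit_w = np.where(hit_mask, 1.0 / k, 0.0)
        else:
            hit_w = w / total
    step = hit_w - np.where(hit_mask, 0.0, 1.0 / (n - k))
    running = np.cumsum(step)
    mx, mn = float(running.max()), float(running.min())
    # signed maximum deviation; an exact +/- tie prefers the positive side
    return mx if mx >= -mn - 1e-12 else mn


def enrichment_score(
    ranking: RankedGeneList, sig: GeneSet, p: float = 1.0
) -> float:
    """ES of ``sig`` against ``ranking`` with hit weight exponent ``p``."""
    hit = np.isin(np.asarray(ranking.gene_ids), list(sig.members))
    return _es_from_order(hit, np.asarray(ranking.metric), p)


def _es_all_signatures(
    genes: np.ndarray,
    lexpos: np.ndarray,
    metric: np.ndarray,
    masks: np.ndarray,
    p: float,
) -> np.ndarray:
    order = np.lexsort((lexpos, -metric))
    metric_ord = metric[order]
    return np.array(
        [_es_from_order(masks[i][order], metric_ord, p) for i in range(masks.shape[0])]
    )


def pairwise_signature_test(
    rs_a: RankScoreMatrix,
    rs_b: RankScoreMatrix,
    signatures: Sequence[GeneSet],
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> list[ActivationCall]:
    """Call signatures activated/inactivated in B relative to A.

    B is by convention the organoid carrying more mutations. The ranking
    metric is the per-gene difference of group-mean rank scores (B - A); the
    null permutes gene labels within each sample's score vector.
    Activation and inactivation p-values are the two tails, each carrying
    the add-one pseudocount; Benjamini-Hochberg runs within each tail.
    """
    if list(rs_a.gene_ids) != list(rs_b.gene_ids):
        raise ValueError("A and B must share an identical gene universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    if len(signatures) < 2:
        if len(signatures) == 0:
            raise ValueError("at least one signature is required")
        warnings.warn("FDR over a single signature is degenerate", stacklevel=2)

    genes = np.asarray(rs_a.gene_ids)
    lexpos = np.argsort(np.argsort(genes))
    masks = np.array([np.isin(genes, list(s.members)) for s in signatures])
    for sig, mask in zip(signatures, masks):
        if mask.sum() == 0 or mask.sum() == len(genes):
            raise ValueError(
                f"signature {sig.name!r} is empty or covers the whole universe"
            )

    scores_a = rs_a.scores.to_numpy(dtype=float)
    scores_b = rs_b.scores.to_numpy(dtype=float)
    metric = scores_b.mean(axis=1) - scores_a.mean(axis=1)
    es_obs = _es_all_signatures(genes, lexpos, metric, masks, weight_p)
    es_a = _es_all_signatures(genes, lexpos, scores_a.mean(axis=1), masks, weight_p)
    es_b = _es_all_signatures(genes, lexpos, scores_b.mean(axis=1), masks, weight_p)

    ge = np.zeros(len(signatures), dtype=np.int64)
    le = np.zeros(len(signatures), dtype=np.int64)
    for ss in np.random.SeedSequence(seed).spawn(n_perm):
        rng = np.random.default_rng(ss)
        perm_metric = (
            _permute_columns(scores_b, rng).mean(axis=1)
            - _permute_columns(scores_a, rng).mean(axis=1)
        )
        es_null = _es_all_signatures(genes, lexpos, perm_metric, masks, weight_p)
        ge += es_null >= es_obs
        le += es_null <= es_obs

    p_act = (1.0 + ge) / (n_perm + 1.0)
    p_inact = (1.0 + le) / (n_perm + 1.0)
    q_act = multipletests(p_act, method="fdr_bh")[1]
    q_inact = multipletests(p_inact, method="fdr_bh")[1]

    calls = []
    for i, sig in enumerate(signatures):
        act = q_act[i] <= fdr
        inact = q_inact[i] <= fdr
        if act and inact:  # resolve to the stronger tail; never report both
            act = p_act[i] < p_inact[i]
            inact = not act
        label = "activated" if act else ("inactivated" if inact else "ns")
        calls.append(
            ActivationCall(
                signature=sig.name,
                es_a=float(es_a[i]),
                es_b=float(es_b[i]),
                es_diff=float(es_obs[i]),
                p_activation=float(p_act[i]),
                p_inactivation=float(p_inact[i]),
                q_activation=float(q_act[i]),
                q_inactivation=float(q_inact[i]),
                call=label,
            )
        )
    return calls


def sample_signature_activity(
    rs: RankScoreMatrix, signatures: Sequence[GeneSet], weight_p: float = 1.0
) -> pd.DataFrame:
    """Per-sample signature activity: ES of each signature against the
    sample's own rank-score vector (single-sample enrichment)."""
    genes = np.asarray(rs.gene_ids)
    lexpos = np.argsort(np.argsort(genes))
    masks = np.array([np.isin(genes, list(s.members)) for s in signatures])
    scores = rs.scores.to_numpy(dtype=float)
    cols = {}
    for j, sample in enumerate(rs.sample_ids):
        cols[sample] = _es_all_signatures(genes, lexpos, scores[:, j], masks, weight_p)
    return pd.DataFrame(cols, index=[s.name for s in signatures])


def group_activity_correlation(
    activity: pd.DataFrame, groups: SampleGroupSet
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group-mean activity plus Pearson correlations at group and sample level.

    Zero-variance activity vectors yield missing (NaN) correlations.
    """
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 signatures to correlate activities")
    group_means = pd.DataFrame(
        {
            label: activity[list(groups.sample_ids(label))].mean(axis=1)
            for label in groups.labels
        }
    )
    group_corr = group_means.corr(method="pearson")
    sample_corr = activity.corr(method="pearson")
    return group_means, group_corr, sample_corr


def calls_to_frame(calls: Sequence[ActivationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "signature": [c.signature for c in calls],
            "es_A": [c.es_a for c in calls],
            "es_B": [c.es_b for c in calls],
            "es_diff": [c.es_diff for c in calls],
            "p_act": [c.p_activation for c in calls],
            "p_inact": [c.p_inactivation for c in calls],
            "q_act": [c.q_activation for c in calls],
            "q_inact": [c.q_inactivation for c in calls],
            "call": [c.call for c in calls],
        }
    )
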