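"""End-to-end orchestration: rank scores -> dysregulation -> signatures ->
key genes -> coherence network -> cascade paths.

A single :class:`PipelineConfig` names the inputs and the per-stage
parameters (permutation counts, FDR levels, restart probability, coherence
threshold, master seed). Each stochastic stage receives a seed derived
deterministically from the master seed and the stage name, so adding a
stage never perturbs an earlier stage's randomness and reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .cascade import (
    build_coherence_network,
    coherence_matrix,
    extract_cascade_path,
    neighborhood_annotation,
    sparsify_top2,
)
from .data_model import (
    read_expression,
    read_gmt,
    read_groups,
    read_mutations,
    read_network,
    read_pathway,
    intersect_genes,
    filter_mutations,
)
from .propagation import RWRParams, infer_key_genes
from .rank_activity import (
    dysregulation_test,
    rank_transform,
    records_to_frame,
)
from .signatures import (
    calls_to_frame,
    pairwise_signature_test,
    sample_signature_activity,
)

__all__ = ["PipelineConfig", "run_all", "stage_seed", "load_config"]

log = logging.getLogger("genecascade")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths to the input bundle plus per-stage parameters.

    Parameter defaults are the study's stated operating points: 1,000
    permutations, FDR 0.01 for dysregulated functions, FDR 0.05 for key
    genes and signature calls, restart probability 0.7 with tolerance 1e-8,
    coherence threshold 0.4.
    """

    expression_organoid: str
    expression_tumor: str
    network: str
    gene_sets: str
    pathway_manifest: str
    mutations: str
    groups: str
    group_drivers: str
    out_dir: str = "pipeline_out"
    n_perm: int = 1000
    n_random: int = 1000
    fdr_dysreg: float = 0.01
    fdr_key: float = 0.05
    fdr_signature: float = 0.05
    restart: float = 0.7
    tolerance: float = 1e-8
    coherence_threshold: float = 0.4
    seed: int = 0

    def digest(self) -> str:
        """Digest of the analytic configuration (the output path is not
        part of the analysis identity)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed keyed by stage name, below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def bundle_config(bundle_dir: str | Path, out_dir: str | Path, **overrides) -> PipelineConfig:
    """Config pointing at a directory written by ``write_bundle``."""
    b = Path(bundle_dir)
    return PipelineConfig(
        expression_organoid=str(b / "expression_organoid.tsv"),
        expression_tumor=str(b / "expression_tumor.tsv"),
        network=str(b / "network.tsv"),
        gene_sets=str(b / "gene_sets.gmt"),
        pathway_manifest=str(b / "pathway_manifest.tsv"),
        mutations=str(b / "mutations.tsv"),
        groups=str(b / "groups.tsv"),
        group_drivers=str(b / "group_drivers.tsv"),
        out_dir=str(out_dir),
        **overrides,
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index=False, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_digest={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _file_digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Emits rank scores, the dysregulation table, signature activation calls,
    per-sample signature activity, the key-gene table, the sparsified
    coherence network, cascade-path candidates/paths, and a JSON manifest.
    """
    inputs = {
        name: getattr(cfg, name)
        for name in (
            "expression_organoid",
            "expression_tumor",
            "network",
            "gene_sets",
            "pathway_manifest",
            "mutations",
            "groups",
            "group_drivers",
        )
    }
    missing = [p for p in inputs.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "version": __version__,
        "inputs": {k: _file_digest(v) for k, v in inputs.items()},
        "stages": {},
    }

    def record(stage: str, t0: float, count: int) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "records": count,
        }
        log.info("stage=%s records=%d", stage, count)

    # --- load & cross-validate -------------------------------------------
    expr_org = read_expression(cfg.expression_organoid)
    expr_tum = read_expression(cfg.expression_tumor)
    expr_org, expr_tum = intersect_genes(expr_org, expr_tum)
    network = read_network(cfg.network)
    gene_sets = read_gmt(cfg.gene_sets)
    pw_manifest = pd.read_csv(cfg.pathway_manifest, sep="\t")
    base = Path(cfg.pathway_manifest).parent
    pathways = {
        row["name"]: read_pathway(base / row["file"], name=row["name"])
        for _, row in pw_manifest.iterrows()
    }
    mutations = filter_mutations(read_mutations(cfg.mutations))
    drivers_df = pd.read_csv(cfg.group_drivers, sep="\t").fillna("")
    drivers = {
        row["group_label"]: tuple(g for g in str(row["drivers"]).split(",") if g)
        for _, row in drivers_df.iterrows()
    }
    groups = read_groups(cfg.groups, drivers=drivers)

    # --- rank transform ---------------------------------------------------
    t0 = time.perf_counter()
    rs_org = rank_transform(expr_org)
    rs_tum = rank_transform(expr_tum)
    _write_tsv(rs_org.scores, out / "rank_scores_organoid.tsv", cfg, index=True, index_label="gene")
    _write_tsv(rs_tum.scores, out / "rank_scores_tumor.tsv", cfg, index=True, index_label="gene")
    record("rank", t0, rs_org.n_genes)

    # --- dysregulated functions ------------------------------------------
    t0 = time.perf_counter()
    records = dysregulation_test(
        rs_org,
        rs_tum,
        gene_sets,
        n_perm=cfg.n_perm,
        fdr=cfg.fdr_dysreg,
        seed=stage_seed(cfg.seed, "dysreg"),
    )
    dys_frame = records_to_frame(records)
    _write_tsv(dys_frame, out / "dysregulation.tsv", cfg)
    dys_names = [r.function for r in records if r.dysregulated]
    record("dysreg", t0, len(records))

    # --- signature dynamics ----------------------------------------------
    t0 = time.perf_counter()
    calls = pairwise_signature_test(
        rs_org,
        rs_tum,
        gene_sets,
        n_perm=cfg.n_perm,
        fdr=cfg.fdr_signature,
        seed=stage_seed(cfg.seed, "signatures"),
    )
    _write_tsv(calls_to_frame(calls), out / "signature_calls.tsv", cfg)
    activity = sample_signature_activity(rs_org, gene_sets)
    _write_tsv(activity, out / "signature_activity_organoid.tsv", cfg, index=True, index_label="signature")
    record("signatures", t0, len(calls))

    # --- subsequent key genes --------------------------------------------
    t0 = time.perf_counter()
    dys_pathways = [pathways[n] for n in dys_names if n in pathways]
    if not dys_pathways:
        raise RuntimeError("no dysregulated pathway available for key-gene inference")
    mutated = set(groups.drivers("organoid")) if "organoid" in groups.labels else set()
    key_table = infer_key_genes(
        network,
        dys_pathways,
        RWRParams(restart=cfg.restart, tolerance=cfg.tolerance),
        n_random=cfg.n_random,
        fdr=cfg.fdr_key,
        seed=stage_seed(cfg.seed, "keygenes"),
        mutated_genes=mutated,
    )
    _write_tsv(key_table, out / "key_genes.tsv", cfg)
    record("keygenes", t0, len(key_table))

    # --- coherence network & cascade paths -------------------------------
    t0 = time.perf_counter()
    key_rows = key_table[key_table["is_key"]]
    candidates = dict(zip(key_rows["gene"], key_rows["q"]))
    if not candidates:  # fall back to the best-ranked non-driver genes
        top = key_table[key_table["excluded_reason"] == ""].head(10)
        candidates = dict(zip(top["gene"], top["q"]))
    mutants = sorted(mutated) or sorted(
        set(mutations.records["gene"]) & set(rs_org.gene_ids)
    )
    node_set = sorted(set(candidates) | set(mutants))
    annotation = neighborhood_annotation(gene_sets, network)
    usable = [g for g in node_set if annotation.get(g)]
    coher = coherence_matrix(usable, annotation)
    net = build_coherence_network(usable, coher, threshold=cfg.coherence_threshold)
    sparse = sparsify_top2(net)
    edges = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "coherence": d["weight"]}
            for a, b, d in sorted(sparse.graph.edges(data=True))
        ]
    )
    _write_tsv(edges, out / "coherence_network.tsv", cfg)
    path, cand_table = extract_cascade_path(sparse, mutants, candidates)
    _write_tsv(cand_table, out / "cascade_candidates.tsv", cfg)
    path_frame = pd.DataFrame(
        {
            "position": range(len(path.genes)),
            "gene": path.genes,
            "role": [
                "mutant"
                if g in mutants
                else ("candidate" if g in candidates else "intermediate")
                for g in path.genes
            ],
        }
    )
    _write_tsv(path_frame, out / "cascade_path.tsv", cfg)
    record("paths", t0, len(path.genes))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
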