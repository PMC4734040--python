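"""End-to-end orchestration of the four phases: CONF -> INF -> CLUS -> EVAL.

Every intermediate artifact is persisted, and a YAML manifest records the
full configuration so a run can be reproduced bit-for-bit from the
manifest alone.  The threshold sweep re-clusters one similarity matrix
over a grid of merge/extension thresholds and tabulates cluster counts,
singleton counts and largest-cluster sizes (optionally, enrichment counts
when ontology inputs are present).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as artifacts
from .clustering import cluster_metrics, two_stage_cluster
from .dataset import TimeSeriesDataset, read_expression_matrix
from .enrichment import (
    enrichment_table,
    evaluate_clusters,
    parse_gaf,
    parse_obo,
    propagate_annotations,
)
from .inference import ChainConfig, IMPLSHyperParams, run_chains
from .segmentation import (
    build_design_matrix,
    parse_manual_segmentation,
    segment_timepoints,
    timepoint_distance_matrix,
    write_pls_model,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "sweep_thresholds"]


@dataclass
class PipelineConfig:
    """All phase parameters, with the tool's defaults where they exist."""

    input_path: str = ""
    output_dir: str = "plsmix_out"
    # CONF
    segmentation_threshold: float | None = None
    manual_segments: str | None = None
    # INF
    n_chains: int = 20
    n_iterations: int = 10_000
    n_skip: int = 2500
    seed: int = 0
    a: float = 2.1
    b: float = 0.24
    alpha_pyp: float = 100.0
    d: float = 0.001
    v_init: float = 100.0
    v_jump: float = 100.0
    v_slope: float = 100.0
    b_prior: str = "literal"
    # CLUS
    merge_threshold: float = 0.5
    extension_threshold: float = 0.5
    # EVAL
    obo_path: str | None = None
    gaf_path: str | None = None
    alpha: float = 0.01
    correction: str = "bonferroni"
    background: str = "dataset"
    family: str = "cluster"

    def chain_config(self) -> ChainConfig:
        return ChainConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            n_skip=self.n_skip,
            seed=self.seed,
            b_prior=self.b_prior,
        )

    def hyperparams(self) -> IMPLSHyperParams:
        return IMPLSHyperParams(
            alpha=self.alpha_pyp, d=self.d, a=self.a, b=self.b,
            v_init=self.v_init, v_jump=self.v_jump, v_slope=self.v_slope,
        )


def _banner(phase: str) -> None:
    logger.info("=== %s | %s ===", time.strftime("%Y-%m-%d %H:%M:%S"), phase)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the phases in order; returns a name -> path map of artifacts.

    The EVAL phase is skipped with a warning when ontology or annotation
    inputs are absent.  A failing phase aborts with the phase named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    manifest = {"config": asdict(config)}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    paths["manifest"] = str(out / "manifest.yaml")

    try:
        _banner("CONF: segmentation and design matrix")
        dataset = read_expression_matrix(config.input_path)
        if config.manual_segments:
            seg = parse_manual_segmentation(config.manual_segments, dataset.n_timepoints)
        elif config.segmentation_threshold is not None:
            seg = segment_timepoints(
                timepoint_distance_matrix(dataset), config.segmentation_threshold
            )
        else:
            raise ValueError("either a segmentation threshold or manual segments required")
        model = build_design_matrix(seg, dataset.timestamps)
        write_pls_model(model, out / "model.json")
        paths["model"] = str(out / "model.json")
        logger.info("segments: %s", seg)
    except Exception as exc:
        raise RuntimeError(f"CONF phase failed: {exc}") from exc

    try:
        _banner("INF: MCMC over the mixture posterior")
        sim, trace = run_chains(dataset, model, config.chain_config(), config.hyperparams())
        artifacts.write_similarity_matrix(sim, dataset.identifiers, out / "similarity.tsv")
        trace.trace.to_csv(out / "trace.tsv", sep="\t", index=False)
        paths["similarity"] = str(out / "similarity.tsv")
        paths["trace"] = str(out / "trace.tsv")
        logger.info("MH acceptance rates: %s", trace.acceptance_rates)
    except Exception as exc:
        raise RuntimeError(f"INF phase failed: {exc}") from exc

    try:
        _banner("CLUS: two-stage clustering")
        clusters = two_stage_cluster(sim, config.merge_threshold, config.extension_threshold)
        artifacts.write_clusters(clusters, dataset.identifiers, out / "clusters.tsv")
        paths["clusters"] = str(out / "clusters.tsv")
        metrics = cluster_metrics(clusters, dataset)
        pd.DataFrame([metrics]).to_csv(out / "metrics.tsv", sep="\t", index=False)
        paths["metrics"] = str(out / "metrics.tsv")
        logger.info(
            "clusters: %d (%d singletons, largest %d)",
            clusters.n_clusters, clusters.n_singletons, clusters.largest_size,
        )
    except Exception as exc:
        raise RuntimeError(f"CLUS phase failed: {exc}") from exc

    if not config.obo_path or not config.gaf_path:
        logger.warning("EVAL skipped: ontology or annotation file not provided")
        return paths

    try:
        _banner("EVAL: GO enrichment")
        onto = parse_obo(config.obo_path)
        annot = propagate_annotations(onto, parse_gaf(config.gaf_path))
        rows = evaluate_clusters(
            clusters, dataset.identifiers, onto, annot,
            alpha=config.alpha, method=config.correction,
            background=config.background, family=config.family,
        )
        artifacts.write_enrichment_table(enrichment_table(rows), out / "enrichment.tsv")
        paths["enrichment"] = str(out / "enrichment.tsv")
    except Exception as exc:
        raise RuntimeError(f"EVAL phase failed: {exc}") from exc
    return paths


def sweep_thresholds(
    sim,
    m_grid=None,
    e_grid=None,
    identifiers: list[str] | None = None,
    onto=None,
    annot=None,
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Cluster one similarity matrix over a (merge, extension) grid.

    For each grid cell the table reports the number of unique clusters,
    singleton count, largest-cluster size and the count and percentage of
    clusters with two or more members; when ontology inputs are given it
    also counts clusters enriched with at least one significant term.
    Default grids run 0.1..0.9 in steps of 0.1.
    """
    grid = np.round(np.arange(0.1, 0.95, 0.1), 10)
    m_grid = grid if m_grid is None else m_grid
    e_grid = grid if e_grid is None else e_grid
    rows = []
    for m in m_grid:
        for e in e_grid:
            cs = two_stage_cluster(sim, float(m), float(e))
            multi = [c for c in cs.clusters if len(c) >= 2]
            row = {
                "m": float(m),
                "e": float(e),
                "n_clusters": cs.n_clusters,
                "n_singletons": cs.n_singletons,
                "largest_cluster_size": cs.largest_size,
                "n_multi_member": len(multi),
                "pct_multi_member": 100.0 * len(multi) / cs.n_clusters,
            }
            if onto is not None and annot is not None and identifiers is not None:
                res = evaluate_clusters(
                    cs, identifiers, onto, annot, alpha=alpha, method=correction
                )
                enriched = {r.cluster_id for r in res if r.significant}
                row["n_enriched"] = len(enriched)
            rows.append(row)
    return pd.DataFrame(rows)
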