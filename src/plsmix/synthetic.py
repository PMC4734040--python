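"""Synthetic data drawn from the generative model, plus GO test fixtures.

Datasets are produced by running the mixture model forward: pick a
partition, draw (or accept) a PLS parameter vector and a noise precision
per cluster, and emit ``x_i = C mu_{z_i} + noise``.  Because the generator
and the sampler share the same model, parameter-recovery experiments have
a well-defined ground truth.

The default temporal design mimics a short perturbation-response
time-course: unequally spaced time stamps sampled densely early and
sparsely late.  What the generator does not emulate: platform-specific
noise (dye bias, count overdispersion), missing values, replicate
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import TimeSeriesDataset
from .segmentation import PLSModel, Segmentation, build_design_matrix

__all__ = [
    "SyntheticTruth",
    "default_model",
    "glu_like_model",
    "generate_impls_dataset",
    "generate_fixture_ontology",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated dataset: cluster labels per entity,
    the per-cluster PLS parameter vectors and noise precisions, and the
    design model used."""

    labels: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    model: PLSModel


def default_model() -> PLSModel:
    """Small two-segment design: 8 unequally spaced time points (minutes),
    an early response segment (0-20) and a late segment (40-120)."""
    timestamps = np.array([0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 90.0, 120.0])
    seg = Segmentation(((0, 4), (4, 8)), threshold_used="manual")
    return build_design_matrix(seg, timestamps)


def glu_like_model() -> PLSModel:
    """Larger seven-segment design over 15 unequally spaced time points,
    shaped like a glucose-pulse transcriptome experiment (dense sampling
    in the first minutes, then hours apart)."""
    timestamps = np.array(
        [0.0, 1 / 3, 2 / 3, 1.0, 8.0, 16.0, 24.0, 32.0, 60.0, 120.0, 180.0,
         240.0, 300.0, 420.0, 4800.0]
    )
    seg = Segmentation(
        ((0, 1), (1, 4), (4, 8), (8, 9), (9, 11), (11, 14), (14, 15)),
        threshold_used="manual",
    )
    return build_design_matrix(seg, timestamps)


def generate_impls_dataset(
    model: PLSModel | None = None,
    n_clusters: int = 3,
    sizes: list[int] | None = None,
    mu: np.ndarray | None = None,
    mu_scale: float = 2.0,
    lam: np.ndarray | float | None = 25.0,
    min_separation_sd: float = 3.0,
    seed: int = 0,
) -> tuple[TimeSeriesDataset, SyntheticTruth]:
    """Draw a clustered dataset from the piecewise-linear mixture model.

    Parameters
    ----------
    model
        PLS design model; the two-segment :func:`default_model` if omitted.
    n_clusters, sizes
        Number of clusters and members per cluster (default 20 each).
    mu
        Explicit per-cluster parameter vectors (n_clusters x L).  When
        omitted, vectors are drawn from N(0, mu_scale^2) per coordinate and
        redrawn until every pair of cluster mean profiles is separated by
        at least ``min_separation_sd`` noise standard deviations in RMS
        distance per time point, so the planted structure is recoverable.
    lam
        Noise precision per cluster, or a scalar shared by all clusters
        (default 25, i.e. noise SD 0.2).
    seed
        Drives all randomness; identical seeds give identical datasets.
    """
    if model is None:
        model = default_model()
    if sizes is None:
        sizes = [20] * n_clusters
    if len(sizes) != n_clusters or any(s < 1 for s in sizes):
        raise ValueError("sizes must give a positive count per cluster")
    rng = np.random.default_rng(seed)
    L = model.n_params
    lam_arr = np.broadcast_to(np.asarray(lam, dtype=float), (n_clusters,)).copy()
    if np.any(lam_arr <= 0):
        raise ValueError("noise precisions must be positive")
    noise_sd = float(np.max(1.0 / np.sqrt(lam_arr)))
    if mu is None:
        m = model.n_timepoints
        for _ in range(1000):
            cand = mu_scale * rng.standard_normal((n_clusters, L))
            means = cand @ model.C.T
            ok = True
            for i in range(n_clusters):
                for j in range(i + 1, n_clusters):
                    rms = np.linalg.norm(means[i] - means[j]) / np.sqrt(m)
                    if rms < min_separation_sd * noise_sd:
                        ok = False
            if ok:
                mu = cand
                break
        else:
            raise RuntimeError("could not find sufficiently separated cluster means")
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (n_clusters, L):
        raise ValueError(f"mu must have shape ({n_clusters}, {L})")
    labels = np.repeat(np.arange(n_clusters), sizes)
    means = mu @ model.C.T
    noise_sds = 1.0 / np.sqrt(lam_arr)
    X = means[labels] + noise_sds[labels, None] * rng.standard_normal(
        (labels.size, model.n_timepoints)
    )
    identifiers = [f"g{i + 1:04d}" for i in range(labels.size)]
    dataset = TimeSeriesDataset(identifiers, X, model.timestamps)
    return dataset, SyntheticTruth(labels=labels, mu=mu, lam=lam_arr, model=model)


def generate_fixture_ontology(
    n_genes: int = 20,
    enriched_size: int = 5,
    n_terms_per_namespace: int = 3,
    depth: int = 2,
    include_not: bool = False,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """Emit a small OBO 1.2 ontology and GAF 2.0 annotation fixture.

    The fixture plants one enriched association: genes ``g1..g<enriched>``
    are exactly the genes annotated with the planted term, so the
    hypergeometric p-value of a cluster equal to that subset is the
    analytically known 1 / C(n_genes, enriched_size).  Every gene carries
    at least one annotation (a root term per namespace), so the background
    is all ``n_genes`` genes.  Each namespace holds a chain of
    ``n_terms_per_namespace`` terms of the requested depth linked by
    ``is_a`` (first namespace) or ``part_of`` (second), exercising both
    propagation relations.

    Returns (obo_text, gaf_text, truth) where ``truth`` records the
    planted term, gene subset and expected raw p-value.
    """
    from math import comb

    rng = np.random.default_rng(seed)
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    terms: list[dict] = []
    term_id = 1

    def next_id() -> str:
        nonlocal term_id
        out = f"GO:{term_id:07d}"
        term_id += 1
        return out

    roots: dict[str, str] = {}
    chains: dict[str, list[str]] = {}
    for ns_i, ns in enumerate(namespaces):
        chain = []
        for level in range(min(depth + 1, n_terms_per_namespace)):
            tid = next_id()
            rec = {"id": tid, "name": f"{ns} level {level}", "namespace": ns}
            if level > 0:
                relation = "part_of" if ns_i == 1 else "is_a"
                rec[relation] = chain[-1]
            chain.append(tid)
            terms.append(rec)
        roots[ns] = chain[0]
        chains[ns] = chain
    planted = chains["biological_process"][-1]

    obo_lines = ["format-version: 1.2", ""]
    for rec in terms:
        obo_lines += ["[Term]", f"id: {rec['id']}", f"name: {rec['name']}",
                      f"namespace: {rec['namespace']}"]
        if "is_a" in rec:
            obo_lines.append(f"is_a: {rec['is_a']}")
        if "part_of" in rec:
            obo_lines.append(f"relationship: part_of {rec['part_of']}")
        obo_lines.append("")
    obo_text = "\n".join(obo_lines)

    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    enriched = genes[:enriched_size]
    gaf_rows = []

    def gaf_row(gene: str, term: str, aspect: str, qualifier: str = "") -> str:
        fields = [
            "FIX", gene, gene.upper(), qualifier, term, "PMID:0", "IDA", "",
            aspect, "", f"syn_{gene}", "gene", "taxon:0", "20140101", "FIX", "", "",
        ]
        return "\t".join(fields)

    aspect = {"biological_process": "P", "molecular_function": "F",
              "cellular_component": "C"}
    for gene in genes:
        ns = namespaces[int(rng.integers(1, 3))]
        gaf_rows.append(gaf_row(gene, roots[ns], aspect[ns]))
    for gene in enriched:
        gaf_rows.append(gaf_row(gene, planted, "P"))
    if include_not:
        gaf_rows.append(gaf_row(genes[-1], planted, "P", qualifier="NOT"))
    gaf_text = "!gaf-version: 2.0\n" + "\n".join(gaf_rows) + "\n"

    truth = {
        "planted_term": planted,
        "enriched_genes": enriched,
        "background_size": n_genes,
        "expected_p_raw": 1.0 / comb(n_genes, enriched_size),
    }
    return obo_text, gaf_text, truth
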