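"""GO-term enrichment of clusters.

An ontology (OBO 1.2) and an annotation set (GAF 2.0) are parsed, direct
annotations are propagated to all ancestors along ``is_a`` and ``part_of``
edges, and each cluster with two or more members is tested for
over-representation of every term annotating at least one member.  The
p-value is the upper tail of the hypergeometric distribution,

    P(X >= k) with  N  background genes,
                    M  background genes carrying the term,
                    n  cluster genes in the background,
                    k  cluster genes carrying the term,

corrected for multiple testing by Bonferroni (default) or
Benjamini-Hochberg across all hypotheses of a cluster, spanning the three
GO namespaces jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio.UniProt import GOA
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterSet

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "AnnotationSet",
    "parse_obo",
    "parse_gaf",
    "propagate_annotations",
    "hypergeom_pvalue",
    "adjust_pvalues",
    "evaluate_clusters",
]

_PROPAGATION_RELATIONS = ("is_a", "part_of")


@dataclass
class Ontology:
    """GO term DAG with child-to-parent ``is_a``/``part_of`` edges.

    ``graph`` nodes are primary term ids with ``name``/``namespace``
    attributes; obsolete terms are kept as nodes but carry no propagation
    edges.  ``alt_ids`` maps secondary ids to their primary term.
    """

    graph: nx.DiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    def resolve(self, term_id: str) -> str | None:
        if term_id in self.graph:
            return term_id
        return self.alt_ids.get(term_id)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via is_a/part_of edges."""
        primary = self.resolve(term_id)
        if primary is None:
            raise KeyError(term_id)
        return set(nx.descendants(self.graph, primary))

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", "")

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("namespace", "")


@dataclass
class AnnotationSet:
    """Gene-to-GO-term assignments.

    ``direct`` maps a canonical gene id to its directly annotated terms;
    ``propagated`` additionally contains every ancestor term (filled in by
    :func:`propagate_annotations`).  Lookup indices map lower-cased object
    ids, symbols and synonyms to the canonical id so that dataset
    identifiers can be matched case-insensitively, preferring id over
    symbol over synonym.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)
    by_id: dict[str, str] = field(default_factory=dict)
    by_symbol: dict[str, str] = field(default_factory=dict)
    by_synonym: dict[str, str] = field(default_factory=dict)

    def match(self, identifier: str) -> str | None:
        """Canonical gene id for a dataset identifier, or None."""
        key = identifier.lower()
        for index in (self.by_id, self.by_symbol, self.by_synonym):
            if key in index:
                return index[key]
        return None


def parse_obo(path) -> Ontology:
    """Parse an OBO 1.2 ontology file.

    Term stanzas contribute nodes (id, name, namespace, alt_id,
    is_obsolete) and child-to-parent edges for ``is_a`` and
    ``relationship: part_of``; other stanza types and relations are
    ignored.  A ``[Term]`` stanza without an id is a parse error reported
    with its line number.
    """
    if isinstance(path, (str, Path)):
        _validate_obo_stanzas(Path(path))
    multigraph = obonet.read_obo(path, ignore_obsolete=False)
    graph = nx.DiGraph()
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, relation in multigraph.edges(keys=True):
        if relation not in _PROPAGATION_RELATIONS:
            continue
        if child in obsolete or parent in obsolete:
            continue
        graph.add_edge(child, parent, relation=relation)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology is_a/part_of graph contains a cycle")
    return Ontology(graph=graph, alt_ids=alt_ids, obsolete=obsolete)


def _validate_obo_stanzas(path: Path) -> None:
    stanza_line = None
    saw_id = True
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line == "[Term]":
                if not saw_id:
                    raise ValueError(f"{path.name}:{stanza_line}: [Term] stanza without id")
                stanza_line, saw_id = lineno, False
            elif line.startswith("[") and line.endswith("]"):
                if not saw_id:
                    raise ValueError(f"{path.name}:{stanza_line}: [Term] stanza without id")
                saw_id = True
            elif line.startswith("id:") and stanza_line is not None:
                saw_id = True
    if not saw_id:
        raise ValueError(f"{path.name}:{stanza_line}: [Term] stanza without id")


def parse_gaf(path) -> AnnotationSet:
    """Parse a GAF 2.0 annotation file into direct annotations.

    Comment lines start with ``!``.  Rows whose Qualifier contains ``NOT``
    are excluded.  Annotations are keyed by the DB Object ID and indexed by
    id, symbol and synonyms (case-insensitive) for later matching against
    dataset identifiers.  A data row with fewer than 15 columns is a parse
    error reported with its line number.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 15:
                raise ValueError(
                    f"{path.name}:{lineno}: expected >= 15 tab-separated columns"
                )
    annot = AnnotationSet()
    with path.open() as fh:
        for rec in GOA.gafiterator(fh):
            if any("NOT" in q for q in rec["Qualifier"]):
                continue
            gene = rec["DB_Object_ID"]
            annot.direct.setdefault(gene, set()).add(rec["GO_ID"])
            annot.by_id.setdefault(gene.lower(), gene)
            symbol = rec["DB_Object_Symbol"]
            if symbol:
                annot.by_symbol.setdefault(symbol.lower(), gene)
            for syn in rec["Synonym"]:
                if syn:
                    annot.by_synonym.setdefault(syn.lower(), gene)
    return annot


def propagate_annotations(onto: Ontology, annot: AnnotationSet) -> AnnotationSet:
    """Fill in ``propagated`` = direct terms plus all their ancestors.

    Term ids are resolved through alt_id; unresolvable or obsolete term
    ids are logged and dropped.
    """
    for gene, terms in annot.direct.items():
        out: set[str] = set()
        for term in terms:
            primary = onto.resolve(term)
            if primary is None:
                logger.warning("unknown GO term %s for gene %s dropped", term, gene)
                continue
            if primary in onto.obsolete:
                logger.warning("obsolete GO term %s for gene %s dropped", term, gene)
                continue
            out.add(primary)
            out |= onto.ancestors(primary)
        annot.propagated[gene] = out
    return annot


def hypergeom_pvalue(N_bg: int, M_term: int, n_clu: int, k_hit: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k_hit)."""
    if not (0 <= M_term <= N_bg):
        raise ValueError("need 0 <= M_term <= N_bg")
    if not (0 <= k_hit <= n_clu <= N_bg):
        raise ValueError("need 0 <= k_hit <= n_clu <= N_bg")
    return float(hypergeom.sf(k_hit - 1, N_bg, M_term, n_clu))


def adjust_pvalues(pvalues, method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni`` multiplies by the family size (capped at 1);
    ``bh`` applies the Benjamini-Hochberg step-up adjustment.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method: {method!r}")
    _, adjusted, _, _ = multipletests(p, alpha=0.5, method=key)
    return [float(q) for q in adjusted]


@dataclass(frozen=True)
class EnrichmentRow:
    cluster_id: str
    term_id: str
    term_name: str
    namespace: str
    N_bg: int
    M_term: int
    n_clu: int
    k_hit: int
    p_raw: float
    p_adj: float
    significant: bool


def evaluate_clusters(
    clusters: ClusterSet,
    identifiers: list[str],
    onto: Ontology,
    annot: AnnotationSet,
    alpha: float = 0.01,
    method: str = "bonferroni",
    background: str = "dataset",
    family: str = "cluster",
) -> list[EnrichmentRow]:
    """Hypergeometric GO enrichment of every cluster with >= 2 members.

    The background universe is the set of dataset identifiers with at
    least one propagated annotation (``background="dataset"``), or every
    annotated gene in the GAF (``background="annotation"``).  Hypotheses
    for a cluster are all terms annotating at least one member, spanning
    the three namespaces; correction is applied per cluster
    (``family="cluster"``) or across all clusters (``family="global"``).
    A term is significant when its adjusted p-value is below ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if background not in ("dataset", "annotation"):
        raise ValueError("background must be 'dataset' or 'annotation'")
    if family not in ("cluster", "global"):
        raise ValueError("family must be 'cluster' or 'global'")
    if not annot.propagated:
        propagate_annotations(onto, annot)

    matched: dict[int, str] = {}
    for idx, ident in enumerate(identifiers):
        gene = annot.match(ident)
        if gene is None or not annot.propagated.get(gene):
            logger.warning("identifier %s has no annotation; excluded from background", ident)
            continue
        matched[idx] = gene

    if background == "dataset":
        bg_genes = set(matched.values())
    else:
        bg_genes = {g for g, terms in annot.propagated.items() if terms}
    if not bg_genes:
        raise ValueError("empty background: no dataset identifier carries an annotation")
    n_bg = len(bg_genes)

    term_counts: dict[str, int] = {}
    for gene in bg_genes:
        for term in annot.propagated.get(gene, ()):
            term_counts[term] = term_counts.get(term, 0) + 1

    raw_rows: list[EnrichmentRow] = []
    family_slices: list[tuple[int, int]] = []
    for ci, members in enumerate(clusters.clusters):
        if len(members) < 2:
            continue
        genes = {matched[i] for i in members if i in matched}
        n_clu = len(genes)
        if n_clu == 0:
            continue
        hypotheses: dict[str, int] = {}
        for gene in genes:
            for term in annot.propagated.get(gene, ()):
                hypotheses[term] = hypotheses.get(term, 0) + 1
        start = len(raw_rows)
        for term in sorted(hypotheses):
            k_hit = hypotheses[term]
            m_term = term_counts[term]
            raw_rows.append(
                EnrichmentRow(
                    cluster_id=f"C{ci + 1}",
                    term_id=term,
                    term_name=onto.name(term),
                    namespace=onto.namespace(term),
                    N_bg=n_bg,
                    M_term=m_term,
                    n_clu=n_clu,
                    k_hit=k_hit,
                    p_raw=hypergeom_pvalue(n_bg, m_term, n_clu, k_hit),
                    p_adj=1.0,
                    significant=False,
                )
            )
        family_slices.append((start, len(raw_rows)))

    if family == "global":
        family_slices = [(0, len(raw_rows))]
    out = list(raw_rows)
    for start, stop in family_slices:
        adjusted = adjust_pvalues([r.p_raw for r in raw_rows[start:stop]], method=method)
        for offset, p_adj in enumerate(adjusted):
            row = raw_rows[start + offset]
            out[start + offset] = EnrichmentRow(
                **{
                    **row.__dict__,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    return out


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view with the output column contract."""
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "namespace": r.namespace,
                "N": r.N_bg,
                "M": r.M_term,
                "n": r.n_clu,
                "k": r.k_hit,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=[
            "cluster_id", "term_id", "term_name", "namespace",
            "N", "M", "n", "k", "p_raw", "p_adj", "significant",
        ],
    )
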