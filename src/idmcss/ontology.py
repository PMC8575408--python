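"""Gene Ontology DAG, annotation propagation and information content.

The semantic similarity score needs, for every gene, the set of GO terms
annotating it *including all ancestors* (true-path propagation), and for
every term t the information content

    I(t) = -ln pro(t),       pro(t) = |genes annotated to t or a descendant|
                                      / |annotated genes|

pro() is computed from the propagated annotation corpus, so it already counts
descendant annotations.  The natural logarithm is used throughout; any fixed
base would do because the semantic score is a ratio of IC sums, but one base
has to be fixed and e is it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger("idmcss")

__all__ = [
    "Ontology",
    "AnnotationMap",
    "InformationContent",
    "read_obo",
    "read_annotations",
    "build_annotation_map",
    "compute_ic",
    "protein_information",
]

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


class OntologyError(ValueError):
    """Raised for structural problems in the ontology or annotations."""


@dataclass
class Ontology:
    """A term DAG with is_a and part_of parent links.

    ``parents`` maps each term to its direct parents; roots map to the empty
    set.  ``alt_ids`` maps secondary identifiers to canonical ones.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise OntologyError(f"term {term} has unresolved parent {p}")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.terms)
        dag.add_edges_from(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        if not nx.is_directed_acyclic_graph(dag):
            raise OntologyError("ontology hierarchy contains a cycle")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def term_count(self) -> int:
        return len(self.terms)

    def canonical(self, term: str) -> str | None:
        """Resolve a (possibly secondary) id to a canonical term, else None."""
        if term in self.terms:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` via is_a/part_of, excluding term itself."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.parents.get(term, ()):
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}


@dataclass
class AnnotationMap:
    """Gene -> term annotations, both direct and ancestor-propagated.

    ``term_genes[t]`` is the set of genes annotated to t or to any descendant
    of t, i.e. the transpose of the propagated map.
    """

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    term_genes: dict[str, frozenset[str]]

    @property
    def background_size(self) -> int:
        return len(self.propagated)

    @property
    def genes(self) -> set[str]:
        return set(self.propagated)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.propagated.get(gene, frozenset())


@dataclass
class InformationContent:
    """Per-term presence probability pro(t) and information I(t) = -ln pro(t)."""

    prob: dict[str, float]
    info: dict[str, float]

    def __getitem__(self, term: str) -> float:
        return self.info[term]

    def get(self, term: str, default: float = 0.0) -> float:
        return self.info.get(term, default)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def read_obo(path: str | Path, namespaces: Iterable[str] | None = None) -> Ontology:
    """Parse an OBO 1.2/1.4 ontology into an :class:`Ontology`.

    Obsolete terms are excluded, ``alt_id`` entries are mapped to their
    canonical id, and both ``is_a`` and ``relationship: part_of`` become
    parent links.  ``namespaces`` optionally restricts the DAG to a subset of
    {"BP", "MF", "CC"}.
    """
    graph = obonet.read_obo(path)  # MultiDiGraph, child -> parent, obsolete dropped
    keep_ns = set(namespaces) if namespaces else None

    terms: set[str] = set()
    namespace: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        if not data:
            # referenced but never declared: leave out so the parent check
            # below reports the dangling reference
            continue
        ns = _NAMESPACE_CODES.get(data.get("namespace", ""), data.get("namespace", ""))
        if keep_ns is not None and ns not in keep_ns:
            continue
        terms.add(term)
        if ns:
            namespace[term] = ns
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term

    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, rel in graph.edges(keys=True):
        if rel not in ("is_a", "part_of") or child not in terms:
            continue
        parents[child].add(parent)  # unresolved parents caught by Ontology
    return Ontology(terms=terms, parents=parents, namespace=namespace, alt_ids=alt_ids)


def build_annotation_map(
    direct: Mapping[str, Iterable[str]], ontology: Ontology
) -> AnnotationMap:
    """Propagate direct gene->term annotations up the DAG and transpose.

    Terms unknown to the ontology are dropped (count logged); genes left with
    no surviving term are excluded from the corpus.
    """
    clean_direct: dict[str, frozenset[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    term_genes: dict[str, set[str]] = {}
    n_dropped = 0
    for gene in sorted(direct):
        kept: set[str] = set()
        for term in direct[gene]:
            canon = ontology.canonical(term)
            if canon is None:
                n_dropped += 1
                continue
            kept.add(canon)
        if not kept:
            continue
        closure = set(kept)
        for t in kept:
            closure |= ontology.ancestors(t)
        clean_direct[gene] = frozenset(kept)
        propagated[gene] = frozenset(closure)
        for t in closure:
            term_genes.setdefault(t, set()).add(gene)
    if n_dropped:
        logger.info("dropped %d annotation(s) to unknown terms", n_dropped)
    if not propagated:
        raise OntologyError("no surviving annotations")
    return AnnotationMap(
        direct=clean_direct,
        propagated=propagated,
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
    )


def read_annotations(
    path: str | Path,
    ontology: Ontology,
    format: str | None = None,
    universe: Iterable[str] | None = None,
    evidence_codes: Iterable[str] | None = None,
) -> AnnotationMap:
    """Read gene->GO annotations from GAF 2.x or a two-column gene/term TSV.

    GAF rows with a NOT qualifier are dropped.  ``universe`` optionally
    restricts the corpus to a gene subset (typically the network's node set,
    so that pro(t) is computed against network proteins).  ``evidence_codes``
    optionally whitelists GAF evidence codes (column 7); by default all are
    kept.
    """
    path = Path(path)
    if format is None:
        format = "gaf" if path.suffix.lower() in (".gaf", ".gpa") else "tsv"
    if format not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation format: {format!r}")
    keep = set(universe) if universe is not None else None
    evid = set(evidence_codes) if evidence_codes is not None else None

    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("!", "#")):
                continue
            fields = raw.rstrip("\n").split("\t")
            if format == "gaf":
                if len(fields) < 5:
                    continue
                gene, qualifier, term = fields[2], fields[3], fields[4]
                if "NOT" in qualifier.split("|"):
                    continue
                if evid is not None and (len(fields) < 7 or fields[6] not in evid):
                    continue
            else:
                if len(fields) < 2:
                    continue
                gene, term = fields[0], fields[1]
            if keep is not None and gene not in keep:
                continue
            direct.setdefault(gene, set()).add(term)
    return build_annotation_map(direct, ontology)


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------


def compute_ic(annotations: AnnotationMap) -> InformationContent:
    """Compute pro(t) and I(t) = -ln pro(t) over the annotated-gene corpus.

    Terms with no annotated gene are excluded (their IC is undefined, never
    reported as 0).  A root term annotating every gene gets pro = 1, I = 0.
    """
    n = annotations.background_size
    if n < 1:
        raise OntologyError("empty annotation corpus")
    prob: dict[str, float] = {}
    info: dict[str, float] = {}
    for term, genes in annotations.term_genes.items():
        if not genes:
            continue
        p = len(genes) / n
        prob[term] = p
        info[term] = -math.log(p)
    return InformationContent(prob=prob, info=info)


def protein_information(
    gene: str, annotations: AnnotationMap, ic: InformationContent
) -> float:
    """Total information of a protein: sum of I(t) over its propagated terms.

    Returns 0 for unannotated genes and for genes annotated only to terms of
    zero information (e.g. the root).
    """
    return sum(ic.get(t, 0.0) for t in annotations.terms_of(gene))
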