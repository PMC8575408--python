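"""Enrichment testing, module closeness and robustness evaluation.

The enrichment test backing the stopping rule is the one-sided
hypergeometric over-representation test (equivalent to a one-sided Fisher
exact test on the 2x2 table).  Module quality is summarised by the
*closeness* — the ratio of links inside the module to links crossing its
boundary — compared against uniformly drawn random node subsets of the same
size with a one-sided t-test, and by the recall of the detected module when
a fraction of the known seeds is withheld.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ontology import AnnotationMap, InformationContent
from .ppi_io import GeneSet, Network

__all__ = [
    "EnrichmentResult",
    "ClosenessReport",
    "enrichment_test",
    "closeness",
    "closeness_ratio",
    "closeness_null_test",
    "recall_experiment",
    "derive_go_reference",
]


@dataclass(frozen=True)
class EnrichmentResult:
    query_size: int
    reference_size: int
    overlap: int
    background_size: int
    p_value: float


@dataclass(frozen=True)
class ClosenessReport:
    inner_links: int
    external_links: int
    closeness: float
    null_mean: float | None = None
    t_statistic: float | None = None
    p_value: float | None = None


def enrichment_test(
    query: set[str] | frozenset[str],
    reference: set[str] | frozenset[str],
    background: set[str] | frozenset[str],
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    P(overlap >= observed) when |query| genes are drawn without replacement
    from a background containing |reference| successes.  reference =
    background gives p = 1; overlap = 0 gives p = 1 (P(X >= 0)).
    """
    if not background:
        raise ValueError("enrichment background must be non-empty")
    if not set(query) <= set(background):
        raise ValueError("query must be a subset of the background")
    if not set(reference) <= set(background):
        raise ValueError("reference must be a subset of the background")
    q, r, bg = len(query), len(reference), len(background)
    overlap = len(set(query) & set(reference))
    p = float(stats.hypergeom.sf(overlap - 1, bg, r, q))
    return EnrichmentResult(
        query_size=q,
        reference_size=r,
        overlap=overlap,
        background_size=bg,
        p_value=min(p, 1.0),
    )


def closeness_ratio(inner_links: int, external_links: int) -> float:
    """closeness = inner / external; undefined (error) without external links."""
    if external_links <= 0:
        raise ValueError("closeness undefined: module has no external links")
    return inner_links / external_links


def _count_links(network: Network, module_nodes: set[str]) -> tuple[int, int]:
    inner = external = 0
    for u, v in network.graph.edges:
        inside = (u in module_nodes) + (v in module_nodes)
        if inside == 2:
            inner += 1
        elif inside == 1:
            external += 1
    return inner, external


def closeness(network: Network, module_nodes: set[str] | frozenset[str]) -> ClosenessReport:
    """Inner-to-external link ratio of a node set within a network."""
    module_nodes = set(module_nodes)
    if not module_nodes <= network.nodes:
        raise ValueError("module nodes must belong to the network")
    inner, external = _count_links(network, module_nodes)
    return ClosenessReport(
        inner_links=inner,
        external_links=external,
        closeness=closeness_ratio(inner, external),
    )


def closeness_null_test(
    network: Network,
    module_nodes: set[str] | frozenset[str],
    n_samples: int = 100,
    rng_seed: int = 0,
) -> ClosenessReport:
    """Is the module closer-knit than random same-size node subsets?

    Draws ``n_samples`` uniform node subsets of the module's size (subsets
    without external links are resampled), computes their closeness, and runs
    a one-sided one-sample t-test of the observed closeness against that null
    sample.  Positive t means the module is denser than the null; small p
    supports it.
    """
    if n_samples < 30:
        raise ValueError("need at least 30 null samples for the t-test")
    observed = closeness(network, module_nodes)
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(network.nodes)
    m = len(set(module_nodes))
    null_vals: list[float] = []
    attempts = 0
    while len(null_vals) < n_samples:
        attempts += 1
        if attempts > 50 * n_samples:
            raise RuntimeError("could not sample subsets with external links")
        subset = set(rng.choice(nodes, size=m, replace=False))
        inner, external = _count_links(network, subset)
        if external == 0:
            continue
        null_vals.append(inner / external)
    null = np.asarray(null_vals)
    if np.allclose(null.std(ddof=1), 0.0):
        raise ValueError("degenerate null: zero variance in sampled closeness")
    # ttest_1samp tests mean(null) against the observed value; alternative
    # 'less' => small p when the observed closeness exceeds the null mean.
    t, p = stats.ttest_1samp(null, observed.closeness, alternative="less")
    return ClosenessReport(
        inner_links=observed.inner_links,
        external_links=observed.external_links,
        closeness=observed.closeness,
        null_mean=float(null.mean()),
        t_statistic=float(-t),
        p_value=float(p),
    )


def derive_go_reference(
    seeds: GeneSet,
    annotations: AnnotationMap,
    background: set[str] | frozenset[str],
    alpha: float = 0.05,
) -> GeneSet:
    """Disease-related GO reference: genes annotated to seed-enriched terms.

    Every ontology term is tested for over-representation in the seed set;
    the union of genes annotated to the terms with p < alpha forms the
    reference gene set the go_terms stopping signal is checked against.
    """
    bg = set(background)
    seed_genes = set(seeds.members) & bg
    members: set[str] = set()
    for term in sorted(annotations.term_genes):
        term_genes = set(annotations.term_genes[term]) & bg
        if not term_genes:
            continue
        res = enrichment_test(seed_genes, term_genes, bg)
        if res.p_value < alpha:
            members |= term_genes
    return GeneSet("go_reference", frozenset(members))


def go_term_min_bh_p(
    query: set[str] | frozenset[str],
    annotations: AnnotationMap,
    background: set[str] | frozenset[str],
    terms: Sequence[str] | None = None,
) -> float:
    """Per-term GO enrichment variant: minimum Benjamini–Hochberg adjusted p.

    Tests the query against every term's annotated gene set (or a supplied
    term list), corrects the p-values with Benjamini–Hochberg and returns
    the smallest adjusted value — a multiplicity-aware alternative to the
    union-reference GO signal.
    """
    from statsmodels.stats.multitest import multipletests

    bg = set(background)
    q = set(query) & bg
    term_ids = sorted(terms) if terms is not None else sorted(annotations.term_genes)
    pvals = []
    for t in term_ids:
        genes = set(annotations.term_genes.get(t, ())) & bg
        if not genes:
            continue
        pvals.append(enrichment_test(q, genes, bg).p_value)
    if not pvals:
        raise ValueError("no testable terms against this background")
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return float(min(adjusted))


def recall_experiment(
    network: Network,
    seeds: GeneSet,
    annotations: AnnotationMap,
    ic: InformationContent,
    deletion_fraction: float,
    n_repeats: int,
    rng_seed: int,
    stopping=None,
    adjust_config=None,
    signal_sets: Mapping[str, object] | None = None,
    connectivity_only: bool = False,
    reference_module: frozenset[str] | None = None,
) -> tuple[float, list[float]]:
    """Mean recall of the detected module when a fraction of seeds is withheld.

    The reference module comes from a run with the full seed set (or is
    supplied).  Each repeat deletes ``floor(fraction * |seeds|)`` seeds
    uniformly at random, reruns the detector, and scores
    ``|module ∩ reference| / |reference|``.  Returns (mean, per-repeat list).
    """
    from .expansion import run_idmcss  # local import: avoids a module cycle

    if not (0.0 <= deletion_fraction < 1.0):
        raise ValueError("deletion_fraction must lie in [0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    from .similarity import SemanticScorer

    common = dict(
        annotations=annotations,
        ic=ic,
        stopping=stopping,
        adjust_config=adjust_config,
        signal_sets=signal_sets,
        connectivity_only=connectivity_only,
        # one shared semantic cache across repeats: the corpus is static
        scorer=SemanticScorer(annotations, ic, connectivity_only=connectivity_only),
    )
    if reference_module is None:
        _, ref_mod = run_idmcss(network, seeds, **common)
        reference_module = ref_mod.nodes
    if not reference_module:
        raise ValueError("reference module is empty")

    seed_list = sorted(seeds.members)
    n_delete = int(deletion_fraction * len(seed_list))
    if n_delete >= len(seed_list):
        raise ValueError("deletion would leave zero seeds")
    rng = np.random.default_rng(rng_seed)
    recalls: list[float] = []
    for _ in range(n_repeats):
        if n_delete == 0:
            kept = seed_list
        else:
            drop = {str(g) for g in rng.choice(seed_list, size=n_delete, replace=False)}
            kept = [s for s in seed_list if s not in drop]
        _, mod = run_idmcss(network, GeneSet(seeds.name, frozenset(kept)), **common)
        recalls.append(len(mod.nodes & reference_module) / len(reference_module))
    return float(np.mean(recalls)), recalls
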