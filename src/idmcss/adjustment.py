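"""Local network adjustment around the seed set: add missing / remove spurious links.

Neighbours of the seed set S are split by connective similarity into
strong-linked nodes (cs above a fixed threshold, default 0.99) and
weak-linked nodes (cs strictly below the neighbour-set mean).  The mean is
always below 0.99 whenever both classes exist, so the classes are disjoint.

For a strong node p', a missing link to a seed p it is not yet connected to
is added when the pairwise semantic similarity ss(p', p) strictly exceeds
phi1, the mean pairwise ss between p' and the seeds it IS connected to.
For a weak node p'', an existing link to a seed p is removed when ss(p'', p)
is strictly below phi2, the mean pairwise ss between p'' and the seeds it is
NOT connected to; if every seed is connected to p'' the threshold is
undefined and nothing is removed.

All edit decisions in one pass are taken against a single adjacency snapshot
and applied afterwards, so the outcome does not depend on node order.  Every
edit has exactly one endpoint in S — the strategy is strictly local to the
seed boundary and never creates or deletes nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Sequence

from .ontology import AnnotationMap, InformationContent
from .ppi_io import EdgeEditLog, Network, _canon
from .similarity import NeighborScore, SemanticScorer

__all__ = [
    "AdjustConfig",
    "AdjustmentPlan",
    "classify_neighbors",
    "adding_decision",
    "removing_decision",
    "add_links",
    "remove_links",
    "adjust_network",
]


@dataclass(frozen=True)
class AdjustConfig:
    """Tunables of the adjustment strategy (defaults as published)."""

    strong_threshold: float = 0.99
    enable_add: bool = True
    enable_remove: bool = True

    def __post_init__(self):
        if not (0.0 < self.strong_threshold < 1.0):
            raise ValueError("strong_threshold must lie in (0, 1)")


@dataclass
class AdjustmentPlan:
    """Classified neighbours plus the edge edits decided in one pass."""

    strong: set[str] = field(default_factory=set)
    weak: set[str] = field(default_factory=set)
    additions: set[tuple[str, str]] = field(default_factory=set)
    removals: set[tuple[str, str]] = field(default_factory=set)
    phi1: dict[str, float] = field(default_factory=dict)
    phi2: dict[str, float] = field(default_factory=dict)


def classify_neighbors(
    scores: Sequence[NeighborScore], strong_threshold: float = 0.99
) -> tuple[set[str], set[str]]:
    """Split NS into strong-linked (cs > threshold) and weak-linked (cs < mean)."""
    if not scores:
        raise ValueError("cannot classify an empty neighbour list")
    if not (0.0 < strong_threshold < 1.0):
        raise ValueError("strong_threshold must lie in (0, 1)")
    mean_cs = fmean(s.cs for s in scores)
    strong = {s.gene for s in scores if s.cs > strong_threshold}
    weak = {s.gene for s in scores if s.cs < mean_cs}
    return strong, weak


def adding_decision(ss_connected: Sequence[float], ss_candidate: float) -> tuple[bool, float]:
    """Add-link rule: candidate ss must strictly exceed phi1 = mean over connected seeds.

    Returns (add?, phi1).
    """
    phi1 = fmean(ss_connected)
    return ss_candidate > phi1, phi1


def removing_decision(
    ss_not_connected: Sequence[float], ss_connected: float
) -> tuple[bool, float]:
    """Remove-link rule: existing link drops when ss is strictly below phi2.

    phi2 is the mean pairwise ss to the seeds the weak node is NOT connected
    to.  Returns (remove?, phi2).
    """
    phi2 = fmean(ss_not_connected)
    return ss_connected < phi2, phi2


def add_links(
    network: Network,
    p_strong: str,
    S: set[str] | frozenset[str],
    annotations: AnnotationMap,
    ic: InformationContent,
    scorer: SemanticScorer | None = None,
) -> tuple[set[tuple[str, str]], float | None]:
    """Missing links from a strong node into S, per the adding-link operator.

    Decided against the network as passed; returns (pairs, phi1) without
    mutating.  phi1 is None when the strong node already touches all of S.
    """
    if scorer is None:
        scorer = SemanticScorer(annotations, ic)
    connected = sorted(p for p in S if network.has_edge(p_strong, p))
    unconnected = sorted(p for p in S if not network.has_edge(p_strong, p))
    if not connected or not unconnected:
        return set(), None
    _, phi1 = adding_decision([scorer.pairwise(p_strong, q) for q in connected], 0.0)
    added = {
        _canon(p_strong, p)
        for p in unconnected
        if scorer.pairwise(p_strong, p) > phi1
    }
    return added, phi1


def remove_links(
    network: Network,
    p_weak: str,
    S: set[str] | frozenset[str],
    annotations: AnnotationMap,
    ic: InformationContent,
    scorer: SemanticScorer | None = None,
) -> tuple[set[tuple[str, str]], float | None]:
    """Spurious links from a weak node into S, per the removing-link operator.

    When every seed is already connected to the weak node the threshold phi2
    is a mean over an empty set; the conservative reading applies and nothing
    is removed (phi2 returned as None).
    """
    if scorer is None:
        scorer = SemanticScorer(annotations, ic)
    connected = sorted(p for p in S if network.has_edge(p_weak, p))
    not_connected = sorted(p for p in S if not network.has_edge(p_weak, p))
    if not connected or not not_connected:
        return set(), None
    _, phi2 = removing_decision(
        [scorer.pairwise(p_weak, q) for q in not_connected], 0.0
    )
    removed = {
        _canon(p_weak, p) for p in connected if scorer.pairwise(p_weak, p) < phi2
    }
    return removed, phi2


def adjust_network(
    network: Network,
    S: set[str] | frozenset[str],
    scores: Sequence[NeighborScore],
    annotations: AnnotationMap,
    ic: InformationContent,
    config: AdjustConfig | None = None,
    scorer: SemanticScorer | None = None,
    log: EdgeEditLog | None = None,
    iteration: int = 0,
) -> tuple[Network, AdjustmentPlan]:
    """Apply both operators around S and return the edited graph plus the plan.

    Strong nodes are processed with add_links and weak nodes with
    remove_links, in lexicographic order, all against the adjacency snapshot
    taken at call time; edits are then applied to a copy.  Edits land in
    ``log`` (when given) tagged with ``iteration`` and the pairwise semantic
    similarity that justified them.
    """
    if config is None:
        config = AdjustConfig()
    if scorer is None:
        scorer = SemanticScorer(annotations, ic)
    plan = AdjustmentPlan()
    if not scores:
        return network.copy(), plan

    strong, weak = classify_neighbors(scores, config.strong_threshold)
    plan.strong, plan.weak = strong, weak

    if config.enable_add:
        for b in sorted(strong):
            added, phi1 = add_links(network, b, S, annotations, ic, scorer)
            if phi1 is not None:
                plan.phi1[b] = phi1
            plan.additions |= added
    if config.enable_remove:
        for b in sorted(weak):
            removed, phi2 = remove_links(network, b, S, annotations, ic, scorer)
            if phi2 is not None:
                plan.phi2[b] = phi2
            plan.removals |= removed

    new = network.copy()
    for u, v in sorted(plan.additions):
        new.graph.add_edge(u, v)
        if log is not None:
            outside = u if u not in S else v
            seed = v if outside == u else u
            log.record_added(u, v, iteration, scorer.pairwise(outside, seed))
    for u, v in sorted(plan.removals):
        new.graph.remove_edge(u, v)
        if log is not None:
            outside = u if u not in S else v
            seed = v if outside == u else u
            log.record_removed(u, v, iteration, scorer.pairwise(outside, seed))
    return new, plan
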