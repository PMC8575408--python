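"""Seed expansion with local network adjustment — the disease-module detector.

Starting from the known disease proteins S0, each iteration

1. collects the current neighbour set NS of S,
2. locally adjusts the network around S (adding likely-missing and removing
   likely-spurious seed-boundary links),
3. recomputes and scores NS on the adjusted network,
4. accretes the neighbour with the largest combined similarity sv into S and
   into the candidate set C = S \\ S0,

and repeats until a configured disease signal (GO terms, differential
expression, pathways) stops being significantly enriched in C, the neighbour
set empties, or an iteration cap is reached.  The stopping test runs after
each accretion; when it fails the offending accretion is rolled back, so the
returned state is the last one in which every signal was still enriched.
The network edits of the failing iteration are kept — adjustment precedes
accretion within an iteration.

The module finally reported is the connected component of the subgraph
induced on S (in the final adjusted network) with the most disease proteins;
since every node of that subgraph is in S this is the largest component,
with ties broken by edge count and then by smallest node label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .adjustment import AdjustConfig, adjust_network
from .evaluation import enrichment_test
from .ontology import AnnotationMap, InformationContent
from .ppi_io import EdgeEditLog, GeneSet, Network, _canon
from .similarity import NeighborScore, SemanticScorer, score_neighbors

logger = logging.getLogger("idmcss")

__all__ = [
    "StoppingConfig",
    "ExpansionState",
    "DiseaseModule",
    "TraceRow",
    "select_candidate",
    "check_stopping",
    "run_idmcss",
    "extract_module",
]


@dataclass(frozen=True)
class StoppingConfig:
    """When to stop accreting candidates.

    ``signals`` names the disease evidence tested for enrichment in C
    (subset of {"go_terms", "de_genes", "pathways"}); expansion stops as soon
    as ANY configured signal's enrichment p-value reaches ``alpha``.  With no
    signals configured, ``max_iterations`` must be finite and is the only
    brake.
    """

    signals: tuple[str, ...] = ("de_genes",)
    alpha: float = 0.05
    max_iterations: int | None = None

    def __post_init__(self):
        if not self.signals and self.max_iterations is None:
            raise ValueError("need at least one signal or a finite max_iterations")
        for s in self.signals:
            if s not in ("go_terms", "de_genes", "pathways"):
                raise ValueError(f"unknown stopping signal: {s!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class TraceRow:
    """One line of the per-iteration expansion trace."""

    iteration: int
    accreted_gene: str
    cs: float
    ss: float
    sv: float
    n_added: int
    n_removed: int
    p_values: dict[str, float]
    rolled_back: bool = False


@dataclass
class ExpansionState:
    """Evolving bookkeeping of the expansion loop."""

    S: set[str]
    S0: frozenset[str]
    C: set[str] = field(default_factory=set)
    NS: set[str] = field(default_factory=set)
    iteration: int = 0
    network: Network | None = None
    log: EdgeEditLog = field(default_factory=EdgeEditLog)
    trace: list[TraceRow] = field(default_factory=list)
    dropped_seeds: frozenset[str] = frozenset()


@dataclass
class DiseaseModule:
    """The extracted module: one connected component of the induced subgraph."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seed_members: frozenset[str]
    components_considered: int


def select_candidate(scores: Sequence[NeighborScore]) -> str:
    """The neighbour most likely to be a disease protein: argmax sv.

    Ties go to the lexicographically smallest gene identifier.
    """
    if not scores:
        raise ValueError("no candidates to select from")
    return min(scores, key=lambda s: (-s.sv, s.gene)).gene


def _signal_reference(sets: GeneSet | Sequence[GeneSet]) -> set[str]:
    """Union of member genes across one signal's gene set(s)."""
    if isinstance(sets, GeneSet):
        return set(sets.members)
    out: set[str] = set()
    for gs in sets:
        out |= set(gs.members)
    return out


def check_stopping(
    C: set[str] | frozenset[str],
    signal_sets: Mapping[str, GeneSet | Sequence[GeneSet]],
    background: set[str] | frozenset[str],
    config: StoppingConfig,
) -> tuple[bool, dict[str, float]]:
    """Test each configured signal for enrichment in the candidate set C.

    Returns (stop, per-signal p-values).  stop is True iff any configured
    signal has p >= alpha.  An empty C never stops (there is nothing to
    test yet).  Multi-set signals are tested against the union of their
    member genes.
    """
    if len(C) > len(background):
        raise ValueError("candidate set larger than the enrichment background")
    p_values: dict[str, float] = {}
    if not C:
        return False, p_values
    for signal in config.signals:
        if signal not in signal_sets:
            raise KeyError(f"no reference gene sets supplied for signal {signal!r}")
        reference = _signal_reference(signal_sets[signal]) & set(background)
        result = enrichment_test(set(C), reference, set(background))
        p_values[signal] = result.p_value
    stop = any(p >= config.alpha for p in p_values.values())
    return stop, p_values


def extract_module(
    network: Network,
    S: set[str] | frozenset[str],
    seed_members: set[str] | frozenset[str] | None = None,
) -> DiseaseModule:
    """Induce the subgraph on S and keep the component with most disease proteins.

    Every node of the induced subgraph is a disease protein, so the rule is
    the largest component; ties break to the component with more edges, then
    to the one containing the smallest node label.  Singleton components are
    valid modules.
    """
    if not S:
        raise ValueError("cannot extract a module from an empty protein set")
    import networkx as nx

    sub = network.graph.subgraph(S)
    components = list(nx.connected_components(sub))
    isolated = set(S) - set(sub.nodes)
    components.extend({n} for n in isolated)

    def keyfunc(comp: set[str]):
        edges = sub.subgraph(comp).number_of_edges()
        return (-len(comp), -edges, min(comp))

    best = min(components, key=keyfunc)
    best_sub = sub.subgraph(best)
    edges = frozenset(_canon(u, v) for u, v in best_sub.edges)
    seeds = frozenset(seed_members if seed_members is not None else S) & frozenset(best)
    return DiseaseModule(
        nodes=frozenset(best),
        edges=edges,
        seed_members=seeds,
        components_considered=len(components),
    )


def run_idmcss(
    network: Network,
    seeds: GeneSet,
    annotations: AnnotationMap,
    ic: InformationContent,
    stopping: StoppingConfig | None = None,
    adjust_config: AdjustConfig | None = None,
    signal_sets: Mapping[str, GeneSet | Sequence[GeneSet]] | None = None,
    connectivity_only: bool = False,
    scorer: SemanticScorer | None = None,
) -> tuple[ExpansionState, DiseaseModule]:
    """Detect a disease module by iterative seed expansion on an adjusted network.

    Seeds absent from the network are dropped with a warning; at least one
    must survive.  ``connectivity_only`` zeroes every semantic score — the
    ablation in which ranking is purely hypergeometric and the adjustment
    operators never fire.  A prebuilt ``scorer`` may be passed to share the
    semantic-similarity cache across repeated runs on the same annotation
    corpus (results are unchanged; only speed differs).

    Returns the final :class:`ExpansionState` (including the per-iteration
    trace and the edge-edit log) and the extracted :class:`DiseaseModule`.
    """
    if stopping is None:
        stopping = StoppingConfig(signals=(), max_iterations=network.node_count)
    signal_sets = signal_sets or {}

    surviving = frozenset(seeds.members) & network.nodes
    dropped = frozenset(seeds.members) - surviving
    if dropped:
        logger.warning("%d seed gene(s) absent from the network; dropped", len(dropped))
    if not surviving:
        raise ValueError("no seed gene is present in the network")

    max_iter = (
        stopping.max_iterations
        if stopping.max_iterations is not None
        else network.node_count
    )
    if scorer is None:
        scorer = SemanticScorer(annotations, ic, connectivity_only=connectivity_only)
    elif scorer.connectivity_only != connectivity_only:
        raise ValueError("shared scorer disagrees with connectivity_only flag")
    background = network.nodes

    state = ExpansionState(
        S=set(surviving),
        S0=surviving,
        network=network.copy(),
        dropped_seeds=dropped,
    )

    while state.iteration < max_iter:
        g = state.network
        # step 2: neighbours of S on the current network
        scores = score_neighbors(g, state.S, annotations, ic, scorer=scorer)
        # step 3: local adjustment around S
        g_new, plan = adjust_network(
            g,
            state.S,
            scores,
            annotations,
            ic,
            config=adjust_config,
            scorer=scorer,
            log=state.log,
            iteration=state.iteration + 1,
        )
        state.network = g_new
        # step 4: neighbours recomputed on the adjusted network
        scores = score_neighbors(g_new, state.S, annotations, ic, scorer=scorer)
        state.NS = {s.gene for s in scores}
        if not scores:
            break
        # step 5: accrete the best candidate
        best = select_candidate(scores)
        best_score = next(s for s in scores if s.gene == best)
        state.S.add(best)
        state.C.add(best)
        state.iteration += 1

        stop, p_values = check_stopping(state.C, signal_sets, background, stopping)
        row = TraceRow(
            iteration=state.iteration,
            accreted_gene=best,
            cs=best_score.cs,
            ss=best_score.ss,
            sv=best_score.sv,
            n_added=len(plan.additions),
            n_removed=len(plan.removals),
            p_values=p_values,
        )
        state.trace.append(row)
        if stop:
            # the failing accretion is rolled back; its iteration's network
            # edits stand (adjustment happened before the accretion)
            row.rolled_back = True
            state.S.discard(best)
            state.C.discard(best)
            state.iteration -= 1
            break

    module = extract_module(state.network, state.S, seed_members=state.S0)
    state.NS = set()
    if state.S:
        neigh = set().union(*(state.network.neighbors(p) for p in state.S))
        state.NS = neigh - state.S
    return state, module


def write_trace(state: ExpansionState, path) -> None:
    """Write the per-iteration trace as TSV (deterministic byte layout)."""
    signals = sorted({s for row in state.trace for s in row.p_values})
    with open(path, "w") as fh:
        header = ["iteration", "accreted_gene", "cs", "ss", "sv", "n_added",
                  "n_removed", "rolled_back"] + [f"p_{s}" for s in signals]
        fh.write("\t".join(header) + "\n")
        for row in state.trace:
            cells = [
                str(row.iteration),
                row.accreted_gene,
                f"{row.cs:.6g}",
                f"{row.ss:.6g}",
                f"{row.sv:.6g}",
                str(row.n_added),
                str(row.n_removed),
                str(int(row.rolled_back)),
            ] + [f"{row.p_values.get(s, float('nan')):.6g}" for s in signals]
            fh.write("\t".join(cells) + "\n")
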