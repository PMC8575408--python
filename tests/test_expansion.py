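"""The expansion loop: candidate selection, stopping rule, module extraction."""

import math

import pytest

from idmcss.adjustment import AdjustConfig
from idmcss.expansion import (
    StoppingConfig,
    check_stopping,
    extract_module,
    run_idmcss,
    select_candidate,
)
from idmcss.ppi_io import GeneSet, Network
from idmcss.similarity import NeighborScore, connective_similarity
from idmcss.synthetic import benchmark_stopping


def _score(gene, sv):
    return NeighborScore(gene=gene, cs=0.0, ss=0.0, sv=sv, k=1, k_s=1, n=1)


class TestSelectCandidate:
    def test_single_candidate(self):
        assert select_candidate([_score("x", 0.2)]) == "x"

    def test_ties_break_lexicographically(self):
        scores = [_score("b", 0.9), _score("a", 0.9), _score("c", 0.1)]
        assert select_candidate(scores) == "a"

    def test_empty_scores_is_an_error(self):
        with pytest.raises(ValueError):
            select_candidate([])


def enrichment_p_by_enumeration(background, reference, query):
    """P(overlap >= observed) by exhaustive counting over equal-size draws."""
    import itertools

    observed = len(query & reference)
    hits = total = 0
    for draw in itertools.combinations(sorted(background), len(query)):
        total += 1
        if len(reference.intersection(draw)) >= observed:
            hits += 1
    return hits / total


class TestCheckStopping:
    def test_empty_candidate_set_never_stops(self):
        cfg = StoppingConfig(signals=("de_genes",))
        stop, p = check_stopping(set(), {"de_genes": GeneSet("de", {"a"})},
                                 {"a", "b"}, cfg)
        assert stop is False and p == {}

    def test_full_overlap_on_tiny_background_keeps_going(self):
        bg = {f"g{i}" for i in range(8)}
        de = GeneSet("de", {"g0", "g1"})
        cfg = StoppingConfig(signals=("de_genes",), alpha=0.05)
        stop, p = check_stopping({"g0", "g1"}, {"de_genes": de}, bg, cfg)
        assert p["de_genes"] == pytest.approx(1 / math.comb(8, 2))
        assert stop is False

    def test_candidates_larger_than_background_is_an_error(self):
        cfg = StoppingConfig(signals=("de_genes",))
        with pytest.raises(ValueError):
            check_stopping({"a", "b"}, {"de_genes": GeneSet("de", {"a"})}, {"a"}, cfg)

    def test_flip_iteration_matches_stepwise_enumeration_oracle(self):
        # accrete DE genes first, then drift: find where enrichment dies by
        # brute-force enumeration and confirm check_stopping flips there
        bg = {f"g{i}" for i in range(10)}
        de = GeneSet("de", {"g0", "g1", "g2"})
        order = ["g0", "g1", "g5", "g6", "g7", "g8"]
        cfg = StoppingConfig(signals=("de_genes",), alpha=0.05)
        flips, oracle_flips = [], []
        C = set()
        for gene in order:
            C.add(gene)
            stop, _ = check_stopping(C, {"de_genes": de}, bg, cfg)
            flips.append(stop)
            oracle_flips.append(
                enrichment_p_by_enumeration(bg, set(de.members), C) >= 0.05
            )
        assert flips == oracle_flips
        assert True in flips  # the drift does eventually trip the rule

    def test_any_failing_signal_stops(self):
        bg = {f"g{i}" for i in range(30)}
        cfg = StoppingConfig(signals=("de_genes", "pathways"), alpha=0.05)
        sets = {
            "de_genes": GeneSet("de", {"g0"}),
            "pathways": [GeneSet("pw", {"g5"})],
        }
        stop, p = check_stopping({"g0"}, sets, bg, cfg)
        assert p["de_genes"] < 0.05 <= p["pathways"]
        assert stop is True


class TestExtractModule:
    def test_connected_subgraph_is_returned_whole(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        mod = extract_module(net, {"a", "b", "c"})
        assert mod.nodes == {"a", "b", "c"} and mod.components_considered == 1

    def test_largest_component_wins(self):
        net = Network.from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("x", "y"), ("y", "z")]
        )
        mod = extract_module(net, {"a", "b", "c", "d", "e", "x", "y", "z"})
        assert mod.nodes == {"a", "b", "c", "d", "e"}

    def test_edge_count_breaks_size_ties(self):
        net = Network.from_edges(
            # two 4-node components: a path (3 edges) vs a cycle (4 edges)
            [("a", "b"), ("b", "c"), ("c", "d"),
             ("w", "x"), ("x", "y"), ("y", "z"), ("z", "w")]
        )
        mod = extract_module(net, set("abcdwxyz"))
        assert mod.nodes == {"w", "x", "y", "z"}

    def test_isolated_protein_is_a_valid_module(self):
        net = Network.from_edges([("a", "b")], nodes=["lone"])
        mod = extract_module(net, {"lone"})
        assert mod.nodes == {"lone"} and mod.edges == frozenset()

    def test_seed_members_are_recorded(self):
        net = Network.from_edges([("a", "b")])
        mod = extract_module(net, {"a", "b"}, seed_members={"a"})
        assert mod.seed_members == {"a"}


class TestRunIdmcss:
    def test_zero_iterations_returns_the_seed_component(self, planted):
        stop = StoppingConfig(signals=(), max_iterations=0)
        state, mod = run_idmcss(
            planted.network, planted.seeds, planted.annotations, planted.ic,
            stopping=stop,
        )
        assert state.S == set(planted.seeds.members) and state.C == set()
        assert mod.nodes <= set(planted.seeds.members)

    def test_one_accretion_per_iteration_and_monotone_growth(self, planted):
        state, mod = run_idmcss(
            planted.network, planted.seeds, planted.annotations, planted.ic,
            stopping=benchmark_stopping(planted), signal_sets=planted.signal_sets,
        )
        kept = [r for r in state.trace if not r.rolled_back]
        assert len(state.S) == len(planted.seeds.members) + state.iteration
        assert state.iteration == len(kept) == len(state.C)
        assert state.C == {r.accreted_gene for r in kept}
        assert [r.iteration for r in kept] == list(range(1, len(kept) + 1))
        assert not state.NS & state.S

    def test_returned_module_is_connected_subgraph_of_final_network(self, planted):
        import networkx as nx

        state, mod = run_idmcss(
            planted.network, planted.seeds, planted.annotations, planted.ic,
            stopping=benchmark_stopping(planted), signal_sets=planted.signal_sets,
        )
        sub = state.network.graph.subgraph(mod.nodes)
        assert nx.is_connected(sub)
        for u, v in mod.edges:
            assert state.network.has_edge(u, v)

    def test_identical_inputs_are_deterministic(self, planted):
        runs = [
            run_idmcss(
                planted.network, planted.seeds, planted.annotations, planted.ic,
                stopping=benchmark_stopping(planted),
                signal_sets=planted.signal_sets,
            )
            for _ in range(2)
        ]
        (s1, m1), (s2, m2) = runs
        assert m1.nodes == m2.nodes and m1.edges == m2.edges
        assert [(e.u, e.v, e.iteration) for e in s1.log.all_edits()] == [
            (e.u, e.v, e.iteration) for e in s2.log.all_edits()
        ]

    def test_missing_seeds_dropped_but_all_missing_is_fatal(self, planted):
        seeds = GeneSet("s", set(planted.seeds.members) | {"NOT_A_GENE"})
        state, _ = run_idmcss(
            planted.network, seeds, planted.annotations, planted.ic,
            stopping=StoppingConfig(signals=(), max_iterations=0),
        )
        assert state.dropped_seeds == {"NOT_A_GENE"}
        with pytest.raises(ValueError):
            run_idmcss(
                planted.network, GeneSet("s", {"NOT_A_GENE"}),
                planted.annotations, planted.ic,
                stopping=StoppingConfig(signals=(), max_iterations=0),
            )

    def test_ablation_matches_pure_hypergeometric_greedy_oracle(self, planted):
        """With edits off and semantics zeroed, accretion order is plain
        greedy expansion by the hypergeometric connectivity score."""
        n_steps = 6
        state, _ = run_idmcss(
            planted.network, planted.seeds, planted.annotations, planted.ic,
            stopping=StoppingConfig(signals=(), max_iterations=n_steps),
            adjust_config=AdjustConfig(enable_add=False, enable_remove=False),
            connectivity_only=True,
        )
        got = [r.accreted_gene for r in state.trace if not r.rolled_back]

        g = planted.network
        S = set(planted.seeds.members)
        expected = []
        for _ in range(n_steps):
            ns = sorted(set().union(*(g.neighbors(p) for p in S)) - S)
            best = min(
                ns,
                key=lambda b: (
                    -connective_similarity(
                        g.degree(b), len(g.neighbors(b) & S), len(S), g.node_count
                    ),
                    b,
                ),
            )
            expected.append(best)
            S.add(best)
        assert got == expected
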