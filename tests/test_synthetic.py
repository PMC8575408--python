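"""The planted-module fixture generator and its statistical contracts."""

import itertools
import math

import numpy as np
import pytest

from idmcss.ontology import compute_ic, read_annotations, read_obo
from idmcss.ppi_io import read_gene_set, read_gmt, read_network
from idmcss.similarity import SemanticScorer
from idmcss.synthetic import (
    GeneratorConfig,
    designate_seeds,
    generate_ontology_and_annotations,
    generate_planted_network,
    generate_signal_sets,
    make_fixture,
    perturb_network,
    write_fixture,
)


class TestPlantedNetwork:
    def test_deterministic_module_is_a_clique_component(self):
        cfg = GeneratorConfig(n_nodes=40, module_sizes=(4,), p_in=1.0, p_out=0.0)
        net, truth = generate_planted_network(cfg)
        module = sorted(g for g, m in truth.items() if m == 0)
        for u, v in itertools.combinations(module, 2):
            assert net.has_edge(u, v)
        assert all(net.neighbors(g) <= set(module) for g in module)

    def test_fixed_seed_reproduces_the_graph(self):
        cfg = GeneratorConfig(n_nodes=60, module_sizes=(6,))
        nets = [generate_planted_network(cfg) for _ in range(2)]
        assert sorted(nets[0][0].edges()) == sorted(nets[1][0].edges())
        assert nets[0][1] == nets[1][1]

    def test_within_module_edge_count_is_binomial(self):
        m, trials = 8, 60
        pairs = m * (m - 1) // 2
        total = 0
        for s in range(trials):
            cfg = GeneratorConfig(
                n_nodes=40, module_sizes=(m,), rng_seed=s, p_in=0.6, p_out=0.02
            )
            net, truth = generate_planted_network(cfg)
            module = {g for g, mod in truth.items() if mod == 0}
            total += sum(
                1 for u, v in itertools.combinations(sorted(module), 2)
                if net.has_edge(u, v)
            )
        n_trials = trials * pairs
        expected = 0.6 * n_trials
        sd = math.sqrt(n_trials * 0.6 * 0.4)
        assert abs(total - expected) <= 3 * sd

    def test_degenerate_parameters_are_an_error(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_in=0.1, p_out=0.2)
        with pytest.raises(ValueError):
            GeneratorConfig(n_nodes=5, module_sizes=(10,))


class TestPerturbNetwork:
    def _setup(self, rng_seed=0):
        cfg = GeneratorConfig(n_nodes=80, module_sizes=(10,), rng_seed=rng_seed)
        net, truth = generate_planted_network(cfg)
        seeds = designate_seeds(truth, cfg, np.random.default_rng(1))
        return cfg, net, truth, seeds

    def test_zero_rates_are_the_identity(self):
        _, net, truth, seeds = self._setup()
        out, deleted, injected = perturb_network(net, truth, seeds, 0.0, 0, 7)
        assert sorted(out.edges()) == sorted(net.edges())
        assert deleted == [] and injected == []

    def test_injection_count_is_exact(self):
        _, net, truth, seeds = self._setup()
        out, _, injected = perturb_network(net, truth, seeds, 0.0, 3, 7)
        assert len(injected) == 3 * len(seeds.members)
        for u, v in injected:
            outside = v if u in seeds.members else u
            inside = u if u in seeds.members else v
            assert truth[outside] != truth[inside]

    def test_seeds_keep_at_least_one_edge(self):
        for s in range(5):
            _, net, truth, seeds = self._setup(rng_seed=s)
            out, deleted, _ = perturb_network(net, truth, seeds, 0.9, 0, s)
            for seed in seeds.members:
                assert out.degree(seed) >= 1

    def test_deletions_are_true_seed_adjacent_module_edges(self):
        _, net, truth, seeds = self._setup()
        out, deleted, _ = perturb_network(net, truth, seeds, 0.3, 0, 7)
        for u, v in deleted:
            assert net.has_edge(u, v) and not out.has_edge(u, v)
            assert truth[u] is not None and truth[u] == truth[v]
            assert u in seeds.members or v in seeds.members


class TestOntologyAndAnnotations:
    def test_full_coherence_separates_within_from_between(self):
        cfg = GeneratorConfig(
            n_nodes=60, module_sizes=(8, 8), coherence=1.0, rng_seed=2
        )
        _, truth = generate_planted_network(cfg)
        ontology, ann = generate_ontology_and_annotations(cfg, truth, 5)
        ic = compute_ic(ann)
        scorer = SemanticScorer(ann, ic)
        mod0 = sorted(g for g, m in truth.items() if m == 0)
        mod1 = sorted(g for g, m in truth.items() if m == 1)
        within = [scorer.pairwise(a, b) for a, b in itertools.combinations(mod0, 2)]
        between = [scorer.pairwise(a, b) for a in mod0 for b in mod1]
        assert min(within) > float(np.mean(between))

    def test_zero_coherence_shows_no_within_module_signal(self):
        cfg = GeneratorConfig(
            n_nodes=60, module_sizes=(8, 8), coherence=0.0, rng_seed=2
        )
        _, truth = generate_planted_network(cfg)
        _, ann = generate_ontology_and_annotations(cfg, truth, 5)
        ic = compute_ic(ann)
        scorer = SemanticScorer(ann, ic)
        mod0 = sorted(g for g, m in truth.items() if m == 0)
        others = sorted(g for g, m in truth.items() if m != 0)
        within = np.array(
            [scorer.pairwise(a, b) for a, b in itertools.combinations(mod0, 2)]
        )
        between = np.array([scorer.pairwise(a, b) for a in mod0 for b in others[:30]])
        # permutation test on the mean difference, alpha 0.05
        rng = np.random.default_rng(0)
        pooled = np.concatenate([within, between])
        observed = within.mean() - between.mean()
        n_within = len(within)
        null = []
        for _ in range(400):
            rng.shuffle(pooled)
            null.append(pooled[:n_within].mean() - pooled[n_within:].mean())
        p = (1 + sum(1 for d in null if d >= observed)) / 401
        assert p > 0.05

    def test_fixed_seed_reproduces_annotations(self):
        cfg = GeneratorConfig(n_nodes=50, module_sizes=(6,))
        _, truth = generate_planted_network(cfg)
        a = generate_ontology_and_annotations(cfg, truth, 9)[1]
        b = generate_ontology_and_annotations(cfg, truth, 9)[1]
        assert a.direct == b.direct

    def test_annotation_invariants_hold(self, planted):
        ann = planted.annotations
        for g in ann.direct:
            assert ann.direct[g] <= ann.propagated[g]
        for t, genes in ann.term_genes.items():
            for g in genes:
                assert t in ann.propagated[g]


class TestSignalSets:
    def test_zero_noise_de_set_equals_the_modules(self):
        cfg = GeneratorConfig(n_nodes=60, module_sizes=(8,), de_noise_genes=0)
        _, truth = generate_planted_network(cfg)
        _, ann = generate_ontology_and_annotations(cfg, truth, 5)
        signals = generate_signal_sets(truth, ann, cfg, 5)
        assert signals["de_genes"].members == {g for g, m in truth.items() if m == 0}

    def test_pathways_of_disjoint_modules_are_disjoint(self):
        cfg = GeneratorConfig(n_nodes=80, module_sizes=(8, 8), coherence=1.0)
        _, truth = generate_planted_network(cfg)
        _, ann = generate_ontology_and_annotations(cfg, truth, 5)
        signals = generate_signal_sets(truth, ann, cfg, 5)
        pw = signals["pathways"]
        assert len(pw) == 2
        assert not pw[0].members & pw[1].members

    def test_fixture_bundles_are_reproducible(self):
        cfg = GeneratorConfig(n_nodes=80, module_sizes=(8,))
        a, b = make_fixture(cfg), make_fixture(cfg)
        assert sorted(a.network.edges()) == sorted(b.network.edges())
        assert a.seeds.members == b.seeds.members
        assert a.deleted_edges == b.deleted_edges
        assert a.injected_edges == b.injected_edges
        assert a.annotations.direct == b.annotations.direct


class TestFixtureSerialization:
    def test_round_trip_through_the_standard_formats(self, tmp_path, planted):
        write_fixture(planted, tmp_path)
        net = read_network(tmp_path / "network.tsv")
        assert sorted(net.edges()) == sorted(planted.network.edges())

        ontology = read_obo(tmp_path / "ontology.obo")
        assert ontology.terms == planted.ontology.terms
        assert ontology.parents == planted.ontology.parents

        ann = read_annotations(tmp_path / "annotations.tsv", ontology, format="tsv")
        assert ann.direct == planted.annotations.direct
        assert ann.propagated == planted.annotations.propagated

        seeds = read_gene_set(tmp_path / "seeds.txt")
        assert seeds.members == planted.seeds.members

        de = read_gene_set(tmp_path / "de_genes.txt")
        assert de.members == planted.signal_sets["de_genes"].members

        gmt = read_gmt(tmp_path / "pathways.gmt")
        assert [g.members for g in gmt] == [
            g.members for g in planted.signal_sets["pathways"]
        ]
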