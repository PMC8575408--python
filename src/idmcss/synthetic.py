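"""Synthetic planted-module benchmarks for the detector.

Real interactomes are both incomplete (missing true links) and noisy
(spurious links), which is exactly the failure mode the adjustment operators
target.  The generator emulates that situation with three coupled pieces:

* a planted-partition graph — dense modules (p_in) on a sparse background
  (p_out), with designated seed genes inside each module;
* a perturbation step that deletes a fraction of the true within-module
  edges incident to seeds (false negatives) and injects decoy edges from
  seeds to out-module nodes (false positives), returning both lists so
  recovery can be scored;
* a toy ontology (balanced DAG) whose root-level subtrees act as per-module
  "term pools": module members draw their annotations from their pool with
  probability ``coherence``, otherwise (and for background genes) uniformly —
  so semantic similarity carries module signal exactly when coherence does;
* planted signal gene sets: a differential-expression set (module members
  plus noise genes) and pathway sets (term pools projected to the genes that
  draw most of their annotations from the pool).

Everything is driven by one integer seed through a SeedSequence, so a fixture
is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .ontology import AnnotationMap, InformationContent, Ontology, build_annotation_map, compute_ic
from .ppi_io import GeneSet, Network, _canon

__all__ = [
    "GeneratorConfig",
    "PlantedFixture",
    "generate_planted_network",
    "designate_seeds",
    "perturb_network",
    "generate_ontology_and_annotations",
    "generate_signal_sets",
    "make_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-module benchmark.

    Defaults are the benchmark's study conditions: one 10-gene module with
    two designated seeds (one in five true disease proteins known, matching
    the premise that most disease associations are undiscovered) inside a
    1000-node background, within-module wiring p_in = 0.6 against
    p_out = 0.02, 30% of seed-incident true module edges deleted, 2 decoy
    edges injected per seed, and annotation coherence 0.8.  With so few
    known seeds a member's surviving seed links are genuinely ambiguous
    connectivity evidence — the regime the semantic score and the
    adjustment operators exist for.
    """

    n_nodes: int = 1000
    module_sizes: tuple[int, ...] = (10,)
    p_in: float = 0.6
    p_out: float = 0.02
    fn_rate: float = 0.3
    fp_rate: int = 2
    ontology_depth: int = 5
    branching: int = 5
    coherence: float = 0.8
    terms_per_gene: int = 5
    seed_fraction: float = 0.2
    de_noise_genes: int = 6
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.fn_rate < 1.0):
            raise ValueError("fn_rate must lie in [0, 1)")
        if not (0.0 <= self.coherence <= 1.0):
            raise ValueError("coherence must lie in [0, 1]")
        if sum(self.module_sizes) > self.n_nodes:
            raise ValueError("modules cannot exceed the node budget")
        if self.ontology_depth < 2 or self.branching < 2:
            raise ValueError("ontology needs depth >= 2 and branching >= 2")
        if len(self.module_sizes) > self.branching:
            raise ValueError("need one root subtree per module: modules <= branching")


@dataclass
class PlantedFixture:
    """A full generated benchmark with its ground truth."""

    config: GeneratorConfig
    network: Network  # perturbed network the detector sees
    clean_network: Network  # pre-perturbation graph
    truth: dict[str, int | None]  # gene -> module index (None = background)
    modules: list[frozenset[str]]
    seeds: GeneSet
    ontology: Ontology
    annotations: AnnotationMap
    ic: InformationContent
    signal_sets: dict[str, object]
    deleted_edges: list[tuple[str, str]] = field(default_factory=list)
    injected_edges: list[tuple[str, str]] = field(default_factory=list)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_planted_network(
    config: GeneratorConfig, rng_seed: int | None = None
) -> tuple[Network, dict[str, int | None]]:
    """Planted-partition graph plus the ground-truth membership map.

    Module blocks are wired with p_in internally; every other pair (module to
    background, background to background, module to module) with p_out.
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    sizes = list(config.module_sizes)
    rest = config.n_nodes - sum(sizes)
    blocks = sizes + ([rest] if rest else [])
    k = len(blocks)
    probs = [[config.p_out] * k for _ in range(k)]
    for i in range(len(sizes)):
        probs[i][i] = config.p_in
    g = nx.stochastic_block_model(blocks, probs, seed=int(seed) % (2**31))
    mapping = {i: _gene_name(i) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    g = nx.Graph(g)  # drop SBM block bookkeeping graph subclass

    truth: dict[str, int | None] = {}
    offset = 0
    for m, size in enumerate(sizes):
        for i in range(offset, offset + size):
            truth[_gene_name(i)] = m
        offset += size
    for i in range(offset, config.n_nodes):
        truth[_gene_name(i)] = None
    network = Network(g)
    if network.edge_count == 0:
        raise ValueError("generator parameters produced an empty graph")
    return network, truth


def designate_seeds(
    truth: Mapping[str, int | None],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> GeneSet:
    """Pick the known-disease seeds: a fixed fraction of each planted module."""
    members: set[str] = set()
    for m in range(len(config.module_sizes)):
        genes = sorted(g for g, mod in truth.items() if mod == m)
        n_seed = max(2, round(config.seed_fraction * len(genes)))
        members |= {str(g) for g in rng.choice(genes, size=n_seed, replace=False)}
    return GeneSet("seeds", frozenset(members))


def perturb_network(
    network: Network,
    truth: Mapping[str, int | None],
    seeds: GeneSet,
    fn_rate: float,
    fp_rate: int,
    rng_seed: int,
) -> tuple[Network, list[tuple[str, str]], list[tuple[str, str]]]:
    """Hide true seed-module edges and inject decoy seed edges.

    Deletes ``floor(fn_rate * count)`` of the within-module edges incident to
    a seed, never leaving a seed with zero edges (such deletions are skipped
    and another candidate drawn).  Injects exactly ``fp_rate`` decoy edges
    per seed, each to a non-adjacent node outside the seed's module.  Returns
    the perturbed network plus the deleted and injected edge lists.
    """
    if not (0.0 <= fn_rate < 1.0):
        raise ValueError("fn_rate must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    g = network.graph.copy()
    seed_set = set(seeds.members)

    candidates = sorted(
        _canon(u, v)
        for u, v in g.edges
        if truth.get(u) is not None
        and truth.get(u) == truth.get(v)
        and (u in seed_set or v in seed_set)
    )
    n_delete = int(fn_rate * len(candidates))
    order = list(rng.permutation(len(candidates)))
    deleted: list[tuple[str, str]] = []
    for idx in order:
        if len(deleted) >= n_delete:
            break
        u, v = candidates[idx]
        safe = all(g.degree(x) > 1 for x in (u, v) if x in seed_set)
        if safe and g.has_edge(u, v):
            g.remove_edge(u, v)
            deleted.append((u, v))

    injected: list[tuple[str, str]] = []
    all_nodes = sorted(g.nodes)
    for s in sorted(seed_set):
        placed = 0
        guard = 0
        while placed < fp_rate:
            guard += 1
            if guard > 1000 * max(1, fp_rate):
                raise RuntimeError("could not place decoy edges")
            t = all_nodes[int(rng.integers(len(all_nodes)))]
            if t == s or g.has_edge(s, t) or truth.get(t) == truth.get(s):
                continue
            g.add_edge(s, t)
            injected.append(_canon(s, t))
            placed += 1
    return Network(g), deleted, injected


def _build_toy_dag(depth: int, branching: int) -> tuple[Ontology, list[str]]:
    """Balanced term DAG of the given depth and branching; returns (ontology, leaves).

    Term identifiers encode the path from the root ("T:2.0.1" is the child 1
    of child 0 of root child 2), so subtree membership is a prefix test.
    """
    root = "T:R"
    terms = {root}
    parents: dict[str, set[str]] = {root: set()}
    all_leaves: list[str] = []

    def grow(parent: str, prefix: str, level: int) -> None:
        for j in range(branching):
            term = f"T:{prefix}{j}"
            terms.add(term)
            parents[term] = {parent}
            if level == depth:
                all_leaves.append(term)
            else:
                grow(term, f"{prefix}{j}.", level + 1)

    for i in range(branching):
        top = f"T:{i}"
        terms.add(top)
        parents[top] = {root}
        grow(top, f"{i}.", 2)
    ontology = Ontology(terms=terms, parents=parents,
                        namespace={t: "BP" for t in terms})
    return ontology, all_leaves


def _module_pools(
    config: GeneratorConfig, all_leaves: Sequence[str]
) -> list[list[str]]:
    """Deterministic per-module term pools: the leaves of one specific subtree.

    Module m owns the subtree rooted two levels above the leaves inside root
    branch m (branching^2 leaves) — a small, specific process, so coherent
    members share rare, high-information terms while genes annotated at
    random almost never hit the pool.  Shallow ontologies fall back to the
    whole root branch.
    """
    pools: list[list[str]] = []
    for m in range(len(config.module_sizes)):
        if config.ontology_depth >= 4:
            prefix = f"T:{m}." + "0." * (config.ontology_depth - 3)
            pool = [t for t in all_leaves if t.startswith(prefix)]
        else:
            pool = [t for t in all_leaves if t.startswith(f"T:{m}.")]
        pools.append(pool)
    return pools


def generate_ontology_and_annotations(
    config: GeneratorConfig,
    truth: Mapping[str, int | None],
    rng_seed: int,
) -> tuple[Ontology, AnnotationMap]:
    """Toy DAG plus module-coherent gene annotations.

    Module m owns the leaf pool of root subtree m.  A module member draws
    each of its ``terms_per_gene`` direct terms from its pool with
    probability ``coherence``, otherwise uniformly from all leaves;
    background genes always draw uniformly.
    """
    rng = np.random.default_rng(rng_seed)
    ontology, all_leaves = _build_toy_dag(config.ontology_depth, config.branching)
    pools = _module_pools(config, all_leaves)
    direct: dict[str, set[str]] = {}
    for gene in sorted(truth):
        module = truth[gene]
        picks: set[str] = set()
        for _ in range(config.terms_per_gene):
            if module is not None and rng.random() < config.coherence:
                pool = pools[module]
                picks.add(pool[int(rng.integers(len(pool)))])
            else:
                picks.add(all_leaves[int(rng.integers(len(all_leaves)))])
        direct[gene] = picks
    annotations = build_annotation_map(direct, ontology)
    return ontology, annotations


def generate_signal_sets(
    truth: Mapping[str, int | None],
    annotations: AnnotationMap,
    config: GeneratorConfig,
    rng_seed: int,
) -> dict[str, object]:
    """Planted stopping signals: a DE gene set and per-module pathway sets.

    The DE set is the union of module members plus ``de_noise_genes`` random
    background genes.  Each pathway is its module's term pool projected to
    genes: the genes whose direct annotations are majority-pool.
    """
    rng = np.random.default_rng(rng_seed)
    module_genes: set[str] = {g for g, m in truth.items() if m is not None}
    background = sorted(g for g, m in truth.items() if m is None)
    n_noise = min(config.de_noise_genes, len(background))
    noise = (
        {str(g) for g in rng.choice(background, size=n_noise, replace=False)}
        if n_noise
        else set()
    )
    de = GeneSet("de_genes", frozenset(module_genes | noise))

    _, all_leaves = _build_toy_dag(config.ontology_depth, config.branching)
    pools = _module_pools(config, all_leaves)
    pathways: list[GeneSet] = []
    for m in range(len(config.module_sizes)):
        pool = set(pools[m])
        members = {
            gene
            for gene, terms in annotations.direct.items()
            if len(terms & pool) * 2 > len(terms)
        }
        pathways.append(GeneSet(f"pathway_module{m}", frozenset(members)))
    return {"de_genes": de, "pathways": pathways}


def make_fixture(config: GeneratorConfig | None = None) -> PlantedFixture:
    """Generate a complete, internally consistent benchmark fixture."""
    if config is None:
        config = GeneratorConfig()
    ss = np.random.SeedSequence(config.rng_seed)
    s_net, s_seed, s_pert, s_onto, s_sig = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    clean, truth = generate_planted_network(config, rng_seed=s_net)
    seeds = designate_seeds(truth, config, np.random.default_rng(s_seed))
    perturbed, deleted, injected = perturb_network(
        clean, truth, seeds, config.fn_rate, config.fp_rate, s_pert
    )
    ontology, annotations = generate_ontology_and_annotations(config, truth, s_onto)
    ic = compute_ic(annotations)
    signals = generate_signal_sets(truth, annotations, config, s_sig)
    modules = [
        frozenset(g for g, m in truth.items() if m == i)
        for i in range(len(config.module_sizes))
    ]
    return PlantedFixture(
        config=config,
        network=perturbed,
        clean_network=clean,
        truth=truth,
        modules=modules,
        seeds=seeds,
        ontology=ontology,
        annotations=annotations,
        ic=ic,
        signal_sets=signals,
        deleted_edges=deleted,
        injected_edges=injected,
    )


# ---------------------------------------------------------------------------
# Benchmark protocol
# ---------------------------------------------------------------------------


def benchmark_stopping(fixture: PlantedFixture):
    """The fixed detection protocol used on planted fixtures.

    Expansion stops when the differential-expression signal loses enrichment
    (alpha 0.05) or after an accretion cap, whichever comes first.  The cap
    encodes the benchmark's design premise: if a fraction f of the true
    module is known, completing it requires up to (1 - f)/f discoveries per
    known seed — four per seed at the default f = 0.2.
    """
    import math

    from .expansion import StoppingConfig

    f = fixture.config.seed_fraction
    per_seed = max(1, math.ceil((1.0 - f) / f - 1e-9))
    return StoppingConfig(
        signals=("de_genes",),
        alpha=0.05,
        max_iterations=per_seed * len(fixture.seeds.members),
    )


def detect_planted(
    fixture: PlantedFixture,
    connectivity_only: bool = False,
    adjust_config=None,
):
    """Run the detector on a fixture and score it against the planted truth.

    Returns (state, module, recall, precision) where recall and precision
    compare the detected module's nodes with the planted module(s).
    """
    from .expansion import run_idmcss

    planted: set[str] = set().union(*fixture.modules)
    state, module = run_idmcss(
        fixture.network,
        fixture.seeds,
        fixture.annotations,
        fixture.ic,
        stopping=benchmark_stopping(fixture),
        adjust_config=adjust_config,
        signal_sets=fixture.signal_sets,
        connectivity_only=connectivity_only,
    )
    hit = len(module.nodes & planted)
    recall = hit / len(planted)
    precision = hit / len(module.nodes)
    return state, module, recall, precision


def benchmark_recovery(
    n_fixtures: int = 20,
    base_seed: int = 0,
    n_permutations: int = 200,
    **config_overrides,
) -> dict:
    """Planted-module recovery benchmark over several generated fixtures.

    For each fixture the detector runs twice — full method and the
    connectivity-only ablation — and is scored against the planted truth.
    The deleted-true-edge recovery of the adjustment operators is tested
    against a seed-matched random-addition null: the same number of
    seed-incident additions drawn uniformly from the seed-boundary non-edges
    of the perturbed network, pooled over fixtures (one-sided permutation
    test).

    Returns a dict with per-fixture recall/precision arrays for both
    variants, the pooled recovered-edge count and its permutation p-value.
    """
    fixture_seeds = [
        int(s % (2**31))
        for s in np.random.SeedSequence(base_seed).generate_state(n_fixtures)
    ]
    full_r, full_p, abl_r, abl_p = [], [], [], []
    observed_recovered = 0
    null_draw_specs: list[tuple[int, list[tuple[str, str]], set[tuple[str, str]]]] = []
    edits_added = edits_removed = 0
    for fs in fixture_seeds:
        fx = make_fixture(GeneratorConfig(rng_seed=fs, **config_overrides))
        state, module, r, p = detect_planted(fx)
        full_r.append(r)
        full_p.append(p)
        _, _, r2, p2 = detect_planted(fx, connectivity_only=True)
        abl_r.append(r2)
        abl_p.append(p2)
        edits_added += state.log.n_added
        edits_removed += state.log.n_removed

        S0 = set(fx.seeds.members)
        deleted = set(fx.deleted_edges)
        added_seed = {
            (e.u, e.v)
            for e in state.log.added
            if e.u in S0 or e.v in S0
        }
        observed_recovered += len(added_seed & deleted)
        candidates = sorted(
            _canon(u, s)
            for s in S0
            for u in fx.network.nodes
            if u != s and u not in S0 and not fx.network.has_edge(u, s)
        )
        null_draw_specs.append((len(added_seed), candidates, deleted))

    rng = np.random.default_rng(base_seed)
    exceed = 0
    for _ in range(n_permutations):
        total = 0
        for n_draw, candidates, deleted in null_draw_specs:
            if n_draw == 0:
                continue
            idx = rng.choice(len(candidates), size=min(n_draw, len(candidates)),
                             replace=False)
            total += sum(1 for i in idx if candidates[i] in deleted)
        if total >= observed_recovered:
            exceed += 1
    recovery_p = (1 + exceed) / (n_permutations + 1)

    return {
        "full_recall": full_r,
        "full_precision": full_p,
        "ablation_recall": abl_r,
        "ablation_precision": abl_p,
        "recovered_deleted_edges": observed_recovered,
        "recovery_null_p": recovery_p,
        "edits_added": edits_added,
        "edits_removed": edits_removed,
        "n_fixtures": n_fixtures,
    }


# ---------------------------------------------------------------------------
# Fixture serialization (the exact external formats the readers consume)
# ---------------------------------------------------------------------------


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write a minimal OBO 1.2 file round-trippable through read_obo."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(ontology.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            ns = ontology.namespace.get(term)
            if ns:
                full = {"BP": "biological_process", "MF": "molecular_function",
                        "CC": "cellular_component"}.get(ns, ns)
                fh.write(f"namespace: {full}\n")
            for parent in sorted(ontology.parents.get(term, ())):
                fh.write(f"is_a: {parent}\n")


def write_fixture(fixture: PlantedFixture, outdir: str | Path) -> None:
    """Serialise a fixture as the plain-text formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    from .ppi_io import write_network

    write_network(fixture.network, outdir / "network.tsv")
    with open(outdir / "seeds.txt", "w") as fh:
        for g in sorted(fixture.seeds.members):
            fh.write(g + "\n")
    write_obo(fixture.ontology, outdir / "ontology.obo")
    with open(outdir / "annotations.tsv", "w") as fh:
        for gene in sorted(fixture.annotations.direct):
            for term in sorted(fixture.annotations.direct[gene]):
                fh.write(f"{gene}\t{term}\n")
    de: GeneSet = fixture.signal_sets["de_genes"]  # type: ignore[assignment]
    with open(outdir / "de_genes.txt", "w") as fh:
        for g in sorted(de.members):
            fh.write(g + "\n")
    pathways: Sequence[GeneSet] = fixture.signal_sets["pathways"]  # type: ignore[assignment]
    with open(outdir / "pathways.gmt", "w") as fh:
        for gs in pathways:
            fh.write("\t".join([gs.name, "synthetic"] + sorted(gs.members)) + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\tmodule\tis_seed\n")
        for gene in sorted(fixture.truth):
            m = fixture.truth[gene]
            fh.write(
                f"{gene}\t{'background' if m is None else m}\t"
                f"{int(gene in fixture.seeds.members)}\n"
            )
    with open(outdir / "perturbation.tsv", "w") as fh:
        fh.write("u\tv\tkind\n")
        for u, v in sorted(fixture.deleted_edges):
            fh.write(f"{u}\t{v}\tdeleted_true\n")
        for u, v in sorted(fixture.injected_edges):
            fh.write(f"{u}\t{v}\tinjected_decoy\n")
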