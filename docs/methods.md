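# Methods

This note documents the model implemented by `idmcss`, the choices made
where the procedure is genuinely open, what the synthetic benchmark does and
does not emulate, and the package's known limitations.

## Scores

**Connective similarity.** For a neighbour *b* of the disease set S with
degree k and k_s links into S, `cs(b,S) = 1 − P(X ≥ k_s)` where
X ~ Hypergeometric(N, n, k), n = |S| and N the node count of the *current*
adjusted network (both n and N evolve as the module grows and edges are
edited). The tail is evaluated through `scipy.stats.hypergeom`
(`cdf(k_s − 1)`), which computes in log space, so interactome-scale N is
numerically safe. `cs = 0` when k_s = 0 and increases monotonically with
k_s; it is NOT monotone in n in general, and the test suite deliberately
asserts only the k_s monotonicity.

**Semantic similarity.** Annotation sets are the *propagated* closure
(direct GO terms plus all is_a/part_of ancestors), matching a term
probability `pro(t)` that counts a term together with its descendants:
`pro(t)` = fraction of annotated genes carrying t or a descendant, and
`I(t) = −ln pro(t)`. The natural logarithm is fixed by convention; because
`ss` is a ratio of IC sums, any base gives identical scores as long as one
base is used throughout. Terms annotating no gene have undefined IC and are
excluded from the maps rather than reported as 0. All three GO namespaces
participate by default; a namespace filter is available when reading the
ontology. Evidence codes are not filtered by default (an inclusion list is
accepted).

`ss(b,S)` sums shared-term information over *every* seed and divides by the
information of the single most informative seed, so it may exceed 1 for
large, annotation-coherent seed sets. It is not clamped: clamping would
change candidate rankings, and the combined score `sv = (cs + ss)/2` is a
halved sum, not a guarantee of a [0,1] range. Degenerate cases (unannotated
gene, empty intersections, zero-information seeds) all return 0.

The IC corpus defaults to the genes present in both the annotation source
and the network (configurable through the `universe` argument of
`read_annotations`); the corpus is computed once and held static during
expansion, since adjustment never creates or deletes nodes.

## Network adjustment

Neighbours with `cs` above a fixed threshold (default 0.99) are
strong-linked; neighbours strictly below the neighbour-set mean cs are
weak-linked. Both classes are processed against a single adjacency snapshot
per iteration, in lexicographic node order, and the edits applied
afterwards — the outcome is therefore independent of processing order.
Pairwise semantic similarity between two proteins is the seed-set formula
with a singleton set (so `ss(x, {y}) = Σ_{t∈A_x∩A_y} I(t) / I(y)`), which
reproduces the worked threshold arithmetic: connected-seed similarities
{0.68, 0.79} give φ₁ = 0.735 and a candidate at 0.83 gains its link;
non-connected similarities {0.35, 0.28} give φ₂ = 0.315 and a connected seed
at 0.14 loses its link. Both thresholds are strict inequalities. A weak node
connected to every seed has no reference set for φ₂; the conservative
behaviour is to skip removal. Every edit crosses the seed boundary — one
endpoint in S, one outside — and is recorded with its iteration and the
semantic similarity that justified it. An edge added at one iteration may
legitimately be removed at a later one (and vice versa); the log keeps both
events.

## Expansion and stopping

Each iteration: compute neighbours of S, adjust the network around S,
recompute and score neighbours on the adjusted network, accrete the argmax
of `sv` (ties to the smallest identifier). The enrichment stopping test runs
after each accretion; expansion stops when any configured signal's one-sided
hypergeometric enrichment p-value in the candidate set C = S \ S₀ reaches α
(default 0.05). The failing accretion is rolled back so the returned state
is the last one in which every signal was still enriched; the failing
iteration's network edits are kept, because adjustment precedes accretion
within an iteration. An empty C never stops the loop, and seeds absent from
the network are dropped with a warning rather than failing the run.

Signals backed by several gene sets (pathways; the derived GO reference,
which is the union of genes annotated to terms enriched in S₀ at α) are
tested against the union of their members. A per-term variant for the GO
signal (minimum Benjamini–Hochberg-adjusted p over terms) is available
through `statsmodels` but is not the default, since the union test matches
the other signals' semantics.

A practical property of the cumulative enrichment test is worth stating:
when the reference set contains essentially the whole true module, the
overlap accumulated during correct expansion makes the p-value extremely
small, and subsequent drift cannot raise it to α within any realistic number
of accretions — the test is "sticky". The enrichment stop therefore guards
mainly the early iterations (a first accretion outside the signal stops the
run immediately), and the iteration cap is the effective late brake. The
benchmark protocol sizes that cap from its design premise: if a fraction f
of the true module is known, completing it needs up to `ceil((1−f)/f)`
discoveries per seed — four per seed at the default f = 0.2. For real
analyses `max_iterations` defaults to the network's node count and should be
set deliberately.

The reported module is the connected component of the subgraph induced on S
(in the final adjusted network) containing the most disease proteins; since
every induced node is in S this is the largest component, with ties broken
by edge count and then smallest node label, so extraction is deterministic.
Known disease proteins falling outside the chosen component are visible in
the trace but are not part of the module.

## Synthetic benchmark

The generator emulates the statistical situation the method assumes: an
incomplete, noisy interactome around a functionally coherent disease module.

* **Graph**: a planted-partition network — module blocks wired at
  p_in = 0.6, every other pair at p_out = 0.02. Defaults plant one 10-gene
  module in 1000 nodes.
* **Known seeds**: 20% of the module (2 genes at the default size),
  reflecting the premise that most true disease associations are
  undiscovered. This regime is what motivates the method: with two seeds, a
  member's surviving seed links (often 0–2 after perturbation) are genuinely
  ambiguous connectivity evidence, and ranking needs the semantic score.
  With many seeds per module the hypergeometric score alone is nearly
  sufficient and adjustment has little to contribute.
* **Perturbation**: 30% of the within-module seed-incident edges are deleted
  (never disconnecting a seed entirely) and exactly 2 decoy edges per seed
  are injected to out-module nodes; both lists are returned for recovery
  scoring.
* **Ontology**: a balanced DAG (depth 5, branching 5; 3,906 terms). Each
  module owns a small deep subtree of 25 leaves as its term pool; members
  draw each of their 5 direct terms from the pool with probability
  `coherence` = 0.8, otherwise uniformly from all leaves; background genes
  draw uniformly. Pools are deliberately specific: coherent genes share
  rare, high-information terms, while random pairs share only shallow
  ancestors of low information — mirroring how real GO annotation separates
  functional neighbours from random pairs. A pool spanning a whole root
  branch would instead give background genes substantial shared information
  with seeds and drown the member signal.
* **Signals**: the DE set is the module plus 6 random background genes
  (small enough that a single in-signal accretion is already significant at
  α = 0.05 against the background); pathway sets are the term pools
  projected to the genes whose direct annotations are majority-pool.

What the generator does **not** emulate: scale-free degree heterogeneity,
overlapping modules, annotation-depth bias toward well-studied genes,
evidence-code structure, and expression data (DE genes are provided as a
set, not derived from a matrix). Passing benchmarks therefore demonstrates
correct mechanics and the intended qualitative behaviour under the modelled
regime, not performance guarantees on any particular real interactome.

The recovery benchmark runs the detector and its connectivity-only ablation
(every semantic score forced to 0, which also disables both edit operators
through the strict thresholds) on 20 generated fixtures. The headline
comparison between the variants is module *recall*; precision is reported
but is not a meaningful head-to-head statistic, because an ablation run that
stops after one or two accretions returns a tiny all-seed module whose
precision is 1 by construction. Deleted-edge recovery is tested against a
seed-matched random-addition null (same number of seed-incident additions,
drawn uniformly from the seed-boundary non-edges, pooled over fixtures,
one-sided permutation test). Decoy *removal* is intentionally not compared
against a null: an injected decoy is distributionally identical to an
original background seed edge, so no operator can prefer one over the
other; the operator's real protective property — true member–seed edges are
removed at a much lower rate than other seed edges — is what the tests
assert.

## Evaluation

Enrichment is the one-sided hypergeometric over-representation test
(equivalent to one-sided Fisher on the 2×2 table). Module closeness is the
inner/external link ratio; its significance is a one-sided one-sample t-test
of the observed closeness against uniformly sampled same-size node subsets
(subsets with no external links are resampled; a degree-matched null is out
of scope). The seed-deletion recall experiment deletes
`floor(fraction · |seeds|)` seeds per repeat, reruns detection with an
unchanged configuration, and scores recall against the full-seed reference
module; the robustness fixture uses 10 seeds (a 30-gene module at
seed_fraction 1/3) so that a 10% deletion withholds at least one seed.

## Numerical and reproducibility notes

* All stochastic components derive from one integer seed through
  `numpy.random.SeedSequence`; fixture generation, detection and evaluation
  are bit-reproducible, and all output files are written in sorted order so
  repeated runs are byte-identical.
* Deterministic iteration is in lexicographic identifier order everywhere a
  tie could otherwise depend on hash or insertion order.
* Gene identifiers are opaque case-sensitive strings; mapping between
  identifier schemes is the caller's responsibility.
* Problem sizes in the shipped benchmarks (1000-node fixtures, 20 recovery
  fixtures, 30 recall repeats) were chosen to characterise behaviour at
  desk scale; all sizes are plain parameters and scale up unchanged.

## Limitations

* The method edits only seed-boundary edges; it cannot repair missing links
  between two non-seed proteins, and module extraction inherits whatever
  fragmentation remains.
* `ss` grows with |S|, so the combined score progressively weights semantics
  over topology as expansion proceeds; this matches the defining formulas
  but means the two terms are not on a common scale.
* With a signal reference that nearly contains the true module, the
  cumulative enrichment stop cannot fire late (see above); the iteration cap
  must be chosen with care.
* Complexity per iteration is O(d_max·n) for neighbour collection plus
  O(n′²) for adjustment over n′ neighbours; with memoised pairwise
  semantics the benchmark fixtures run in under a second per detection.
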