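"""Connective, semantic and combined similarity between a protein and a seed set.

Three scores drive both the network adjustment and the expansion ranking:

* ``cs(b, S)`` — connective similarity: one minus the upper hypergeometric
  tail of b's link count into S.  For a node of degree k with k_s links into
  the n-node seed set S inside an N-node network,

      cs = 1 - P(X >= k_s),   X ~ Hypergeometric(N, n, k)

  Large cs means b touches S more often than a random degree-k node would.

* ``ss(b, S)`` — semantic similarity: the information-content-weighted GO
  overlap between b and every seed, normalised by the most informative seed:

      ss = [ sum_i sum_{t in A_b ∩ A_{p_i}} I(t) ] / max_p I(p)

  A_x is the *propagated* annotation set of x.  ss is NOT clamped to [0, 1]:
  the double sum over n seeds is divided by a single protein's information,
  so coherent neighbours of large seed sets legitimately score above 1.

* ``sv = (cs + ss) / 2`` — the combined similarity used to rank candidates.

n is |S| at the current iteration and N the node count of the current
adjusted network; both evolve as the module grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .ontology import AnnotationMap, InformationContent, protein_information
from .ppi_io import Network

__all__ = [
    "NeighborScore",
    "connective_similarity",
    "semantic_similarity",
    "combined_similarity",
    "score_neighbors",
    "SemanticScorer",
]


@dataclass(frozen=True)
class NeighborScore:
    """Scores of one neighbour of the seed set."""

    gene: str
    cs: float
    ss: float
    sv: float
    k: int
    k_s: int
    n: int


def connective_similarity(k: int, k_s: int, n: int, N: int) -> float:
    """cs(b, S) = 1 - P(X >= k_s) for X ~ Hypergeometric(N, n, k).

    Equals the lower tail P(X <= k_s - 1); 0 when k_s = 0 (the upper tail
    then sums all outcomes).  Evaluated through scipy's hypergeometric CDF,
    which works in log-space, so interactome-scale N is safe.
    """
    if not (0 <= k_s <= k <= N):
        raise ValueError(f"require 0 <= k_s <= k <= N, got k_s={k_s}, k={k}, N={N}")
    if not (0 < n < N):
        raise ValueError(f"require 0 < n < N, got n={n}, N={N}")
    return float(hypergeom.cdf(k_s - 1, N, n, k))


def _connective_similarity_many(
    k: np.ndarray, k_s: np.ndarray, n: int, N: int
) -> np.ndarray:
    """Vectorised cs over aligned degree / in-seed-degree arrays."""
    return hypergeom.cdf(k_s - 1, N, n, k)


def semantic_similarity(
    gene: str,
    S: Sequence[str] | Iterable[str],
    annotations: AnnotationMap,
    ic: InformationContent,
) -> float:
    """ss(b, S): IC-weighted annotation overlap with every seed, over I_max(S).

    Returns 0 when the gene is unannotated, every pairwise term intersection
    is empty, or no seed carries information (I_max = 0).  Invariant under
    permutation of S.
    """
    seeds = list(S)
    if not seeds:
        raise ValueError("seed set S must be non-empty")
    i_max = max(protein_information(p, annotations, ic) for p in seeds)
    if i_max <= 0.0:
        return 0.0
    terms_b = annotations.terms_of(gene)
    if not terms_b:
        return 0.0
    total = 0.0
    for p in seeds:
        for t in terms_b & annotations.terms_of(p):
            total += ic.get(t, 0.0)
    return total / i_max


def combined_similarity(cs: float, ss: float) -> float:
    """sv = (cs + ss) / 2, the rank statistic for candidate accretion."""
    return (cs + ss) / 2.0


class SemanticScorer:
    """Memoising helper for repeated semantic-similarity evaluations.

    The expansion loop scores hundreds of neighbours against a growing seed
    set every iteration; protein information and pairwise shared IC depend
    only on the (static) annotation corpus, so both are cached.

    With ``connectivity_only=True`` every semantic score is 0 — the ablation
    used to isolate the contribution of GO information.
    """

    def __init__(
        self,
        annotations: AnnotationMap,
        ic: InformationContent,
        connectivity_only: bool = False,
    ):
        self.annotations = annotations
        self.ic = ic
        self.connectivity_only = connectivity_only
        self._info: dict[str, float] = {}
        self._shared: dict[tuple[str, str], float] = {}

    def protein_info(self, gene: str) -> float:
        val = self._info.get(gene)
        if val is None:
            val = protein_information(gene, self.annotations, self.ic)
            self._info[gene] = val
        return val

    def shared_ic(self, a: str, b: str) -> float:
        """Sum of I(t) over the propagated-term intersection of a and b."""
        key = (a, b) if a <= b else (b, a)
        val = self._shared.get(key)
        if val is None:
            ta = self.annotations.terms_of(a)
            tb = self.annotations.terms_of(b)
            val = sum(self.ic.get(t, 0.0) for t in ta & tb) if ta and tb else 0.0
            self._shared[key] = val
        return val

    def ss(self, gene: str, S: Iterable[str]) -> float:
        if self.connectivity_only:
            return 0.0
        seeds = list(S)
        i_max = max((self.protein_info(p) for p in seeds), default=0.0)
        if i_max <= 0.0:
            return 0.0
        return sum(self.shared_ic(gene, p) for p in seeds) / i_max

    def pairwise(self, x: str, y: str) -> float:
        """ss between two proteins: the seed-set formula with S = {y}."""
        if self.connectivity_only:
            return 0.0
        i_y = self.protein_info(y)
        if i_y <= 0.0:
            return 0.0
        return self.shared_ic(x, y) / i_y


def score_neighbors(
    network: Network,
    S: set[str] | frozenset[str],
    annotations: AnnotationMap,
    ic: InformationContent,
    scorer: SemanticScorer | None = None,
) -> list[NeighborScore]:
    """Score every neighbour of S (NS = neighbours(S) \\ S), sorted by gene id.

    cs is evaluated in one vectorised hypergeometric call; ss goes through a
    (possibly shared) :class:`SemanticScorer`.
    """
    if not S:
        raise ValueError("seed set S must be non-empty")
    missing = S - network.nodes
    if missing:
        raise ValueError(f"seed gene(s) not in network: {sorted(missing)[:5]}")
    if scorer is None:
        scorer = SemanticScorer(annotations, ic)

    ns = sorted(set().union(*(network.neighbors(p) for p in S)) - set(S))
    if not ns:
        return []
    n, N = len(S), network.node_count
    k = np.array([network.degree(b) for b in ns])
    k_s = np.array([sum(1 for nb in network.neighbors(b) if nb in S) for b in ns])
    cs_vals = _connective_similarity_many(k, k_s, n, N)

    seeds = sorted(S)
    out = []
    for i, b in enumerate(ns):
        cs = float(cs_vals[i])
        ss = scorer.ss(b, seeds)
        out.append(
            NeighborScore(
                gene=b,
                cs=cs,
                ss=ss,
                sv=combined_similarity(cs, ss),
                k=int(k[i]),
                k_s=int(k_s[i]),
                n=n,
            )
        )
    return out
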