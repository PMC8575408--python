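"""Read/write protein-protein interaction networks, gene sets and module output.

Gene identifiers are opaque, case-sensitive strings; no symbol normalisation
or aliasing is attempted.  Networks are simple undirected graphs: self-loops
and duplicate edges in the input are dropped (and counted) because the
hypergeometric connectivity score assumes a simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger("idmcss")

__all__ = [
    "Network",
    "GeneSet",
    "EdgeEditLog",
    "read_network",
    "read_gene_set",
    "read_gmt",
    "write_module",
]


class NetworkParseError(ValueError):
    """Raised for malformed network / gene-set input files."""


def _canon(u: str, v: str) -> tuple[str, str]:
    """Canonical (lexicographically ordered) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


class Network:
    """A simple undirected PPI network.

    Thin wrapper over :class:`networkx.Graph` that enforces the invariants the
    scoring functions rely on: no self-loops, no parallel edges, every edge
    endpoint present in the node set.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "Network":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dropped_loops = dropped_dups = 0
        for u, v in edges:
            if u == v:
                dropped_loops += 1
                continue
            if g.has_edge(u, v):
                dropped_dups += 1
                continue
            g.add_edge(u, v)
        if dropped_loops or dropped_dups:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s)",
                dropped_loops,
                dropped_dups,
            )
        return cls(g)

    # -- container protocol -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def edges(self) -> Iterator[tuple[str, str]]:
        for u, v in self.graph.edges:
            yield _canon(u, v)

    def copy(self) -> "Network":
        return Network(self.graph.copy())

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network(n={self.node_count}, m={self.edge_count})"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (seeds, DE genes, a pathway...)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if any(not m for m in self.members):
            raise ValueError("gene identifiers must be non-empty strings")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass
class EdgeEdit:
    """One recorded edge edit (always stored with lexicographic endpoints)."""

    u: str
    v: str
    action: str  # "added" | "removed"
    iteration: int
    semantic_similarity: float


@dataclass
class EdgeEditLog:
    """Provenance of every link added to / removed from the network."""

    added: list[EdgeEdit] = field(default_factory=list)
    removed: list[EdgeEdit] = field(default_factory=list)

    def record_added(self, u: str, v: str, iteration: int, ss: float) -> None:
        a, b = _canon(u, v)
        self.added.append(EdgeEdit(a, b, "added", iteration, ss))

    def record_removed(self, u: str, v: str, iteration: int, ss: float) -> None:
        a, b = _canon(u, v)
        self.removed.append(EdgeEdit(a, b, "removed", iteration, ss))

    @property
    def n_added(self) -> int:
        return len(self.added)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def all_edits(self) -> list[EdgeEdit]:
        return sorted(
            self.added + self.removed,
            key=lambda e: (e.iteration, e.action, e.u, e.v),
        )

    def validate(self) -> None:
        """No pair may be both added and removed at the same iteration."""
        seen: set[tuple[str, str, int]] = set()
        for e in self.added:
            seen.add((e.u, e.v, e.iteration))
        for e in self.removed:
            if (e.u, e.v, e.iteration) in seen:
                raise ValueError(
                    f"edge ({e.u},{e.v}) both added and removed at iteration {e.iteration}"
                )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_network(path: str | Path, format: str | None = None) -> Network:
    """Read an undirected network from a two-column TSV or a SIF file.

    ``format`` is ``"tsv"`` or ``"sif"``; when ``None`` it is inferred from
    the file suffix (``.sif`` -> SIF, anything else -> TSV).  In SIF each row
    is ``source relation target [target ...]`` and fans out to one edge per
    target.  Self-loops and duplicates are dropped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format: {format!r}")

    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            n_data_lines += 1
            if format == "tsv":
                if len(fields) < 2:
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                    )
                edges.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) == 1:
                    nodes.append(fields[0])  # isolated node, legal SIF
                elif len(fields) < 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: SIF row needs source, relation and >=1 target"
                    )
                else:
                    src = fields[0]
                    for tgt in fields[2:]:
                        edges.append((src, tgt))
    if n_data_lines == 0:
        raise NetworkParseError(f"{path}: empty network file")
    return Network.from_edges(edges, nodes=nodes)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain gene list, one identifier per line.

    Blank lines and ``#`` comments are ignored; duplicates collapse.
    """
    path = Path(path)
    members: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members.add(line.split()[0])
    if not members:
        raise NetworkParseError(f"{path}: no gene identifiers found")
    return GeneSet(name or path.stem, frozenset(members))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: GMT row needs name, description and >=1 member"
                )
            sets.append(GeneSet(fields[0], frozenset(fields[2:])))
    return sets


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_network(network: Network, path: str | Path) -> None:
    """Write a network as a sorted two-column TSV edge list."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            fh.write(f"{u}\t{v}\n")


def write_module(module, log: EdgeEditLog, path: str | Path) -> None:
    """Write a detected disease module and its edit log under directory `path`.

    Emits ``module_nodes.tsv`` (node, role), ``module_edges.tsv``
    (u, v, origin) and ``edge_edits.tsv`` (u, v, action, iteration,
    semantic_similarity).  Output rows are sorted, so files are byte-identical
    across runs with the same inputs and seed.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    added = {(e.u, e.v) for e in log.added}

    with open(outdir / "module_nodes.tsv", "w") as fh:
        fh.write("node\trole\n")
        for node in sorted(module.nodes):
            role = "seed" if node in module.seed_members else "expanded"
            fh.write(f"{node}\t{role}\n")

    with open(outdir / "module_edges.tsv", "w") as fh:
        fh.write("u\tv\torigin\n")
        for u, v in sorted(_canon(a, b) for a, b in module.edges):
            origin = "added" if (u, v) in added else "original"
            fh.write(f"{u}\t{v}\t{origin}\n")

    with open(outdir / "edge_edits.tsv", "w") as fh:
        fh.write("u\tv\taction\titeration\tsemantic_similarity\n")
        for e in log.all_edits():
            fh.write(
                f"{e.u}\t{e.v}\t{e.action}\t{e.iteration}\t{e.semantic_similarity:.6g}\n"
            )
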