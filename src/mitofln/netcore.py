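"""Shared graph model, pair containers, statistics and file I/O.

The weighted functional linkage network (FLN) is represented as an
undirected simple :class:`networkx.Graph` whose edges carry a positive
``weight`` attribute (the composite likelihood ratio of the linkage).
This module owns everything the pipeline stages share: canonical pair
keys, the gold-standard pair container, sparse per-evidence score
tables, pair counting under both conventions, summary statistics, and
the TSV / GraphML / GMT readers and writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Tuple

import networkx as nx

Pair = Tuple[str, str]

EDGELIST_HEADER = ("gene_a", "gene_b", "weight")


class EdgeListFormatError(ValueError):
    """Raised on malformed edge-list rows; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical sorted order.

    Self-pairs are rejected: a linkage relates two distinct gene
    products.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GoldStandardPairs:
    """Gold standard positive (GSP) and negative (GSN) gene pairs.

    Positives share at least one pathway/complex annotation; negatives
    are pairs of annotated genes sharing none.  Pairs are stored in
    canonical order and the two sets are disjoint by construction.
    """

    positives: FrozenSet[Pair]
    negatives: FrozenSet[Pair]

    def __post_init__(self):
        for p in self.positives | self.negatives:
            if p != canonical_pair(*p):
                raise ValueError(f"pair not canonical: {p}")
        if self.positives & self.negatives:
            raise ValueError("positive and negative pair sets overlap")

    @property
    def all_pairs(self) -> FrozenSet[Pair]:
        return self.positives | self.negatives

    def label(self, pair: Pair) -> int:
        """1 for a gold positive, 0 for a gold negative; KeyError otherwise."""
        if pair in self.positives:
            return 1
        if pair in self.negatives:
            return 0
        raise KeyError(pair)


@dataclass
class EvidenceTable:
    """A named sparse mapping from unordered gene pairs to scores.

    One table per evidence dataset.  Scores may be continuous or
    categorical; ``scale_tag`` distinguishes genome-scale surveys from
    mitochondria-specific ones for grouped integration.
    """

    name: str
    scores: Dict[Pair, float] = field(default_factory=dict)
    scale_tag: str = "genome-scale"

    def __post_init__(self):
        for p in self.scores:
            if p != canonical_pair(*p):
                raise ValueError(f"pair not canonical: {p}")

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.scores


# ---------------------------------------------------------------------------
# pair counting and statistics


def pair_count(n: int, convention: str = "combinatorial") -> int:
    """Number of potential linkages among ``n`` genes.

    ``combinatorial`` counts unordered distinct pairs, n(n-1)/2.
    ``paper`` reproduces the n^2/2 convention used in the original
    inventory report (floor division).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if convention == "combinatorial":
        return n * (n - 1) // 2
    if convention == "paper":
        return n * n // 2
    raise ValueError(f"unknown convention: {convention!r}")


def average_neighbors(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N; 0 for an empty graph."""
    return 0.0 if n_nodes == 0 else 2.0 * n_edges / n_nodes


def density(n_nodes: int, n_edges: int) -> float:
    """Edge density 2E/(N(N-1)); 0 when N < 2."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def graph_stats(g: nx.Graph) -> Dict[str, float]:
    """Summary record: node count, edge count, average neighbors, density."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    return {
        "nodes": n,
        "edges": e,
        "average_neighbors": average_neighbors(n, e),
        "density": density(n, e),
    }


# ---------------------------------------------------------------------------
# graph construction and validation


def make_fln(edges: Iterable[Tuple[str, str, float]], **metadata) -> nx.Graph:
    """Build a weighted FLN from (gene_a, gene_b, weight) triples.

    Enforces the simple-graph contract: no self-loops, no duplicate
    undirected edges, strictly positive weights.
    """
    g = nx.Graph(**metadata)
    for a, b, w in edges:
        a, b = canonical_pair(a, b)
        if g.has_edge(a, b):
            raise ValueError(f"duplicate undirected edge ({a}, {b})")
        w = float(w)
        if not (w > 0) or not math.isfinite(w):
            raise ValueError(f"edge ({a}, {b}) has non-positive weight {w}")
        g.add_edge(a, b, weight=w)
    return g


# ---------------------------------------------------------------------------
# file I/O


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Write a TSV edge list with header gene_a, gene_b, weight."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGELIST_HEADER) + "\n")
        for a, b, data in sorted(g.edges(data=True), key=lambda e: canonical_pair(e[0], e[1])):
            a, b = canonical_pair(a, b)
            fh.write(f"{a}\t{b}\t{data['weight']:.10g}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a TSV edge list (header required) into a weighted graph.

    Duplicate undirected edges — including a row repeating an earlier
    row with the genes swapped — and non-positive weights are rejected
    with the offending line number.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != EDGELIST_HEADER:
            raise EdgeListFormatError(
                f"expected header {EDGELIST_HEADER}, got {tuple(header)}", 1
            )
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise EdgeListFormatError(f"expected 3 fields, got {len(fields)}", lineno)
            a, b, wtext = fields
            try:
                pair = canonical_pair(a, b)
            except ValueError as exc:
                raise EdgeListFormatError(str(exc), lineno) from exc
            try:
                w = float(wtext)
            except ValueError as exc:
                raise EdgeListFormatError(f"bad weight {wtext!r}", lineno) from exc
            if not (w > 0) or not math.isfinite(w):
                raise EdgeListFormatError(f"non-positive weight {w}", lineno)
            if g.has_edge(*pair):
                raise EdgeListFormatError(f"duplicate undirected edge {pair}", lineno)
            g.add_edge(*pair, weight=w)
    return g


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """Export the network as GraphML with ``weight`` as an edge attribute."""
    nx.write_graphml_lxml(g, str(path))


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format (name, description, members...)."""
    descriptions = descriptions or {}
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Read GMT gene sets; returns name -> member list (description dropped)."""
    out: Dict[str, List[str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise EdgeListFormatError("GMT rows need name, description, >=1 member", lineno)
            out[fields[0]] = fields[2:]
    return out
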