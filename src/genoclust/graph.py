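"""Graph-based genospecies clustering over thresholded identity matrices.

The pipeline: symmetrize a pairwise matrix by averaging each directed pair,
binarize it against a user-chosen criterion (e.g. ANI >= 95%), AND several
binary relations into a consensus (e.g. identity AND alignment coverage),
build the undirected relation graph, and read clusters off it at two
granularities:

* **maximal cliques** — candidate genospecies in which *every* genome pair
  exceeds the cutoff; a genome may belong to several overlapping cliques;
* **connected components** — looser clusters in which each genome exceeds
  the cutoff with at least one other member.

Clique enumeration is Bron–Kerbosch with pivoting, seeded by a degeneracy
ordering of the vertices; output order is deterministic (descending size,
then lexicographic) so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .matrix import LabeledMatrix, _scale_max

__all__ = [
    "Criterion",
    "BooleanRelation",
    "RelationGraph",
    "ScaleMismatchError",
    "symmetrize_average",
    "binarize",
    "consensus",
    "build_graph",
    "maximal_cliques",
    "components",
]


class ScaleMismatchError(ValueError):
    """Criterion and matrix are declared on different scales."""


@dataclass(frozen=True)
class Criterion:
    """Threshold + direction used to binarize one matrix.

    ``ge`` keeps pairs at or above the threshold (identity, coverage);
    ``le`` keeps pairs at or below it (distances).  The threshold lives on
    ``scale`` ('percent' by default); comparisons are inclusive.
    """

    threshold: float
    direction: str = "ge"
    scale: str = "percent"

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "le"):
            raise ValueError(f"direction must be 'ge' or 'le', got {self.direction!r}")
        if self.scale not in ("percent", "fraction"):
            raise ValueError(f"scale must be 'percent' or 'fraction', got {self.scale!r}")
        hi = _scale_max(self.scale)
        if not (0.0 <= self.threshold <= hi):
            raise ValueError(
                f"threshold {self.threshold} outside [0, {hi}] for scale={self.scale}"
            )


@dataclass
class BooleanRelation:
    """Symmetric Boolean relation over genome labels with a false diagonal."""

    labels: tuple[str, ...]
    adj: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.adj = np.asarray(self.adj, dtype=bool)
        n = len(self.labels)
        if self.adj.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}, got {self.adj.shape}")
        if not np.array_equal(self.adj, self.adj.T):
            raise ValueError("adjacency must be symmetric")
        if self.adj.diagonal().any():
            raise ValueError("diagonal must be false (no self-relations)")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reordered(self, labels: Sequence[str]) -> "BooleanRelation":
        """Same relation with rows/columns permuted to ``labels``."""
        if set(labels) != set(self.labels):
            raise ValueError("label sets differ")
        perm = [self.labels.index(l) for l in labels]
        return BooleanRelation(tuple(labels), self.adj[np.ix_(perm, perm)])


@dataclass(frozen=True)
class RelationGraph:
    """Simple undirected graph over genome labels.

    Edges are stored as lexicographically sorted 2-tuples; isolated nodes
    are retained (a genome with no partner above the cutoff is still a
    singleton cluster).
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge {(a, b)} not in sorted order")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge {(a, b)} references a missing node")

    @classmethod
    def from_edges(
        cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "RelationGraph":
        norm = frozenset(tuple(sorted(e)) for e in edges)
        return cls(tuple(nodes), norm)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "RelationGraph":
        return cls.from_edges(sorted(g.nodes), g.edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self, node: str) -> int:
        return len(self.adjacency()[node])

    def subgraph(self, keep: Iterable[str]) -> "RelationGraph":
        keep = set(keep)
        nodes = tuple(v for v in self.nodes if v in keep)
        edges = frozenset(e for e in self.edges if e[0] in keep and e[1] in keep)
        return RelationGraph(nodes, edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def symmetrize_average(m: LabeledMatrix) -> LabeledMatrix:
    """Symmetrize by averaging each directed pair: (M + Mᵀ) / 2.

    If exactly one direction of a pair is missing, the present value is
    used; if both are missing the pair stays missing.  The diagonal is
    forced to the scale maximum for identity/coverage (0 for distances).
    Idempotent on already-symmetric matrices.
    """
    a = m.values
    b = a.T
    with np.errstate(invalid="ignore"):
        out = np.where(
            np.isnan(a), b, np.where(np.isnan(b), a, (a + b) / 2.0)
        )
    diag = _scale_max(m.scale) if m.kind in ("identity", "coverage") else 0.0
    np.fill_diagonal(out, diag)
    return LabeledMatrix(m.labels, out, kind=m.kind, scale=m.scale)


def binarize(
    m: LabeledMatrix, c: Criterion, allow_scale_conversion: bool = False
) -> BooleanRelation:
    """Apply a threshold criterion to a matrix, yielding a Boolean relation.

    The matrix is symmetrized first (pair averaging), so the relation is
    symmetric by construction.  Missing values never satisfy the criterion
    and the diagonal is always false.

    Raises
    ------
    ScaleMismatchError
        Criterion scale differs from the matrix scale and
        ``allow_scale_conversion`` is off.  With conversion on, both are
        normalized to percent before comparison.
    """
    if c.scale != m.scale:
        if not allow_scale_conversion:
            raise ScaleMismatchError(
                f"criterion on scale {c.scale!r} vs matrix on {m.scale!r}; "
                "pass allow_scale_conversion=True to normalize both to percent"
            )
        m = m.to_percent()
        thr = c.threshold * 100.0 if c.scale == "fraction" else c.threshold
    else:
        thr = c.threshold
    sym = symmetrize_average(m)
    with np.errstate(invalid="ignore"):
        if c.direction == "ge":
            adj = sym.values >= thr
        else:
            adj = sym.values <= thr
    adj &= np.isfinite(sym.values)  # NaN comparisons are already False; belt-and-braces
    np.fill_diagonal(adj, False)
    return BooleanRelation(sym.labels, adj)


def consensus(relations: Sequence[BooleanRelation]) -> BooleanRelation:
    """Element-wise AND of Boolean relations sharing one label set.

    Mirrors multiplying logical matrices: a pair is related in the
    consensus only if it is related under every criterion (e.g. ANI >= 95%
    *and* alignment coverage >= 50%).  Commutative, associative, and
    monotone — adding a relation never adds an edge.
    """
    if not relations:
        raise ValueError("consensus of an empty relation list")
    first = relations[0]
    adj = first.adj.copy()
    for rel in relations[1:]:
        if set(rel.labels) != set(first.labels):
            diff = sorted(set(rel.labels) ^ set(first.labels))
            raise ValueError(f"relation label sets differ: {diff}")
        if rel.labels != first.labels:
            rel = rel.reordered(first.labels)
        adj &= rel.adj
    return BooleanRelation(first.labels, adj)


def build_graph(r: BooleanRelation) -> RelationGraph:
    """Relation -> simple undirected graph; isolated labels kept as nodes."""
    ii, jj = np.nonzero(np.triu(r.adj, k=1))
    edges = frozenset(
        tuple(sorted((r.labels[i], r.labels[j]))) for i, j in zip(ii, jj)
    )
    return RelationGraph(tuple(r.labels), edges)


def _degeneracy_order(adj: dict[str, set[str]]) -> list[str]:
    """Vertex order by repeatedly removing a minimum-degree vertex."""
    degrees = {v: len(nbrs) for v, nbrs in adj.items()}
    remaining: dict[str, set[str]] = {v: set(nbrs) for v, nbrs in adj.items()}
    order: list[str] = []
    while remaining:
        # lexicographic tie-break keeps the ordering deterministic
        v = min(remaining, key=lambda u: (degrees[u], u))
        order.append(v)
        for u in remaining[v]:
            remaining[u].discard(v)
            degrees[u] -= 1
        del remaining[v]
    return order


def _bron_kerbosch_pivot(
    adj: dict[str, set[str]],
    r: set[str],
    p: set[str],
    x: set[str],
    out: list[frozenset[str]],
) -> None:
    if not p and not x:
        out.append(frozenset(r))
        return
    # pivot: vertex of P ∪ X with most neighbours in P minimizes branching
    pivot = max(p | x, key=lambda u: len(adj[u] & p))
    for v in sorted(p - adj[pivot]):
        _bron_kerbosch_pivot(adj, r | {v}, p & adj[v], x & adj[v], out)
        p.remove(v)
        x.add(v)


def _cluster_sort_key(members: Sequence[str]) -> tuple:
    return (-len(members), tuple(members))


def maximal_cliques(g: RelationGraph) -> list[tuple[str, ...]]:
    """Enumerate every maximal clique exactly once, singletons included.

    Bron–Kerbosch with pivoting over a degeneracy ordering of the outer
    vertices.  Output is deterministic: cliques sorted by descending size
    then lexicographic member order, members sorted within each clique.
    """
    adj = g.adjacency()
    order = _degeneracy_order(adj)
    rank = {v: i for i, v in enumerate(order)}
    out: list[frozenset[str]] = []
    for v in order:
        later = {u for u in adj[v] if rank[u] > rank[v]}
        earlier = {u for u in adj[v] if rank[u] < rank[v]}
        _bron_kerbosch_pivot(adj, {v}, later, earlier, out)
    cliques = [tuple(sorted(c)) for c in out]
    cliques.sort(key=_cluster_sort_key)
    return cliques


def components(g: RelationGraph) -> list[tuple[str, ...]]:
    """Connected components; isolated nodes are singleton components.

    Deterministic order: descending size, then lexicographic.
    """
    comps = [tuple(sorted(c)) for c in nx.connected_components(g.to_networkx())]
    comps.sort(key=_cluster_sort_key)
    return comps
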