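"""Directed flag complexes of filtered digraphs.

A directed ``k``-clique of a digraph is an *ordered* tuple of vertices
``(w0, ..., wk)`` such that the edge ``(wi, wj)`` is present for every
``i < j``.  The collection of all directed cliques is the directed flag
complex; it is an ordered simplicial complex that is closed under taking
faces.  When each edge carries a filtration value, every simplex enters the
filtration at the maximum of its edges' values (vertices at 0), which makes
each sublevel set a face-closed subcomplex and yields the nested family

    dFl(G_t1) <= dFl(G_t2)   whenever t1 <= t2.

Simplices within each dimension are kept in lexicographic order of their
vertex tuples (compared as strings), so the boundary matrices built
downstream are bit-reproducible across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Mapping, Sequence, Tuple

Vertex = Hashable

__all__ = [
    "OrderedSimplex",
    "FilteredDigraph",
    "FlagComplex",
    "build_flag_complex",
    "complex_at_filtration",
    "is_subcomplex",
    "read_edge_list",
    "write_edge_list",
]


def _vkey(v: Vertex) -> str:
    return str(v)


@dataclass(frozen=True)
class OrderedSimplex:
    """An ordered simplex ``(w0, ..., wk)`` with its filtration value.

    The parent digraph must contain the edge ``(wi, wj)`` for every
    ``i < j``; the filtration value is the maximum over those edges
    (0.0 for a vertex).
    """

    vertices: Tuple[Vertex, ...]
    filtration: float = 0.0

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1

    def face(self, i: int) -> Tuple[Vertex, ...]:
        """Vertex tuple obtained by deleting the ``i``-th vertex."""
        return self.vertices[:i] + self.vertices[i + 1 :]


class FilteredDigraph:
    """A simple digraph whose edges carry non-negative filtration values.

    At most one edge is admitted per ordered pair ``(u, v)``; the reversed
    pair ``(v, u)`` may coexist as a distinct edge.  Self-loops are
    rejected, as are non-finite or negative filtration values.
    """

    def __init__(
        self,
        vertices: Iterable[Vertex] = (),
        edges: Mapping[Tuple[Vertex, Vertex], float] | None = None,
    ) -> None:
        self._succ: Dict[Vertex, Dict[Vertex, float]] = {}
        for v in vertices:
            self.add_vertex(v)
        if edges:
            for (u, v), f in edges.items():
                self.add_edge(u, v, f)

    def add_vertex(self, v: Vertex) -> None:
        self._succ.setdefault(v, {})

    def add_edge(self, u: Vertex, v: Vertex, filtration: float = 0.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on vertex {u!r} is not allowed")
        f = float(filtration)
        if not math.isfinite(f) or f < 0.0:
            raise ValueError(
                f"filtration of edge ({u!r}, {v!r}) must be finite and >= 0,"
                f" got {filtration!r}"
            )
        self.add_vertex(u)
        self.add_vertex(v)
        if v in self._succ[u]:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        self._succ[u][v] = f

    @property
    def vertices(self) -> List[Vertex]:
        return list(self._succ)

    @property
    def edges(self) -> Dict[Tuple[Vertex, Vertex], float]:
        return {(u, v): f for u, nbrs in self._succ.items() for v, f in nbrs.items()}

    def out_neighbors(self, u: Vertex) -> Mapping[Vertex, float]:
        return dict(self._succ[u])

    @property
    def n_vertices(self) -> int:
        return len(self._succ)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._succ.values())

    def has_edge(self, u: Vertex, v: Vertex) -> bool:
        return u in self._succ and v in self._succ[u]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FilteredDigraph(|V|={self.n_vertices}, |E|={self.n_edges})"


class FlagComplex:
    """Simplices of a directed flag complex, stratified by dimension.

    Dimensions ``0 .. max_dimension`` are always present (possibly empty);
    within each dimension simplices are sorted lexicographically by their
    vertex tuples so that matrix row/column indexing is deterministic.
    """

    def __init__(
        self,
        simplices: Mapping[int, Sequence[OrderedSimplex]],
        max_dimension: int,
    ) -> None:
        self.max_dimension = int(max_dimension)
        self._dims: Dict[int, List[OrderedSimplex]] = {
            k: sorted(simplices.get(k, ()), key=lambda s: tuple(map(_vkey, s.vertices)))
            for k in range(self.max_dimension + 1)
        }
        self._index_cache: Dict[int, Dict[Tuple[Vertex, ...], int]] = {}

    def simplices(self, k: int) -> List[OrderedSimplex]:
        return self._dims.get(k, [])

    def n_simplices(self, k: int) -> int:
        return len(self._dims.get(k, ()))

    def counts(self) -> List[int]:
        return [len(self._dims[k]) for k in range(self.max_dimension + 1)]

    def index(self, k: int) -> Dict[Tuple[Vertex, ...], int]:
        """Map from vertex tuple to position within dimension ``k``."""
        if k not in self._index_cache:
            self._index_cache[k] = {
                s.vertices: i for i, s in enumerate(self.simplices(k))
            }
        return self._index_cache[k]

    def __contains__(self, vertices: Tuple[Vertex, ...]) -> bool:
        k = len(vertices) - 1
        return k <= self.max_dimension and vertices in self.index(k)

    def euler_characteristic(self) -> int:
        return sum((-1) ** k * n for k, n in enumerate(self.counts()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FlagComplex(counts={self.counts()})"


def build_flag_complex(g: FilteredDigraph, max_dim: int = 2) -> FlagComplex:
    """Enumerate all directed cliques of ``g`` up to dimension ``max_dim``.

    Enumeration proceeds by iterative extension: a simplex
    ``(w0, ..., wk)`` is extended by any vertex ``v`` lying in the
    intersection of the out-neighborhoods of all ``wi``; the new simplex's
    filtration value is the maximum of the parent's value and the edges
    ``(wi, v)``.

    ``max_dim`` defaults to 2, enough for the spectra of ``L0`` and ``L1``;
    raise it for generic digraph analysis.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    succ = {u: g.out_neighbors(u) for u in g.vertices}
    dims: Dict[int, List[OrderedSimplex]] = {k: [] for k in range(max_dim + 1)}
    order = sorted(succ, key=_vkey)
    for v in order:
        dims[0].append(OrderedSimplex((v,), 0.0))

    def grow(prefix: Tuple[Vertex, ...], filt: float, cands: Dict[Vertex, float]) -> None:
        dim = len(prefix)  # dimension of the simplices created here
        for v in sorted(cands, key=_vkey):
            f_new = max(filt, cands[v])
            simplex = prefix + (v,)
            dims[dim].append(OrderedSimplex(simplex, f_new))
            if dim < max_dim:
                sv = succ[v]
                nxt = {
                    w: max(fw, sv[w]) for w, fw in cands.items() if w in sv
                }
                if nxt:
                    grow(simplex, f_new, nxt)

    if max_dim >= 1:
        for u in order:
            if succ[u]:
                grow((u,), 0.0, dict(succ[u]))
    return FlagComplex(dims, max_dim)


def complex_at_filtration(k: FlagComplex, t: float) -> FlagComplex:
    """Sublevel subcomplex of all simplices with filtration value <= ``t``.

    Because every face enters no later than its cofaces, the result is
    itself face-closed.
    """
    if t < 0:
        raise ValueError("filtration threshold must be >= 0")
    dims = {
        d: [s for s in k.simplices(d) if s.filtration <= t]
        for d in range(k.max_dimension + 1)
    }
    return FlagComplex(dims, k.max_dimension)


def is_subcomplex(a: FlagComplex, b: FlagComplex) -> bool:
    """True when every simplex of ``a`` is also a simplex of ``b``."""
    if a.max_dimension > b.max_dimension and any(
        a.n_simplices(d) for d in range(b.max_dimension + 1, a.max_dimension + 1)
    ):
        return False
    for d in range(min(a.max_dimension, b.max_dimension) + 1):
        idx = b.index(d)
        if any(s.vertices not in idx for s in a.simplices(d)):
            return False
    return True


def read_edge_list(path) -> FilteredDigraph:
    """Read a digraph from a plain-text edge list.

    One edge per line as ``u v filtration``; the filtration column may be
    omitted (defaults to 0).  A single token declares an isolated vertex.
    ``#`` starts a comment; vertex ids are arbitrary strings.
    """
    g = FilteredDigraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                if len(parts) == 1:
                    g.add_vertex(parts[0])
                elif len(parts) == 2:
                    g.add_edge(parts[0], parts[1], 0.0)
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[1], float(parts[2]))
                else:
                    raise ValueError("expected 'u v filtration'")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return g


def write_edge_list(g: FilteredDigraph, path) -> None:
    """Write ``g`` in the edge-list format accepted by :func:`read_edge_list`."""
    edges = g.edges
    touched = {u for u, _ in edges} | {v for _, v in edges}
    with open(path, "w") as fh:
        for v in sorted(g.vertices, key=_vkey):
            if v not in touched:
                fh.write(f"{v}\n")
        for (u, v), f in sorted(edges.items(), key=lambda e: (_vkey(e[0][0]), _vkey(e[0][1]))):
            fh.write(f"{u} {v} {f:.12g}\n")
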