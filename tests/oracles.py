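"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's enumeration and linear-algebra code
paths: simplices are found by exhaustive ordered-tuple search, boundary
matrices are rebuilt from scratch, and homology ranks are computed exactly
over the rationals with sympy, so no floating-point tolerance enters the
reference values.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np
import sympy

from pdfl.flag_complex import FilteredDigraph


def brute_force_simplices(
    g: FilteredDigraph, max_dim: int
) -> Dict[int, List[Tuple[Tuple, float]]]:
    """All ordered simplices by exhaustive search over vertex tuples.

    A tuple (w0, ..., wk) qualifies iff the edge (wi, wj) exists for every
    i < j; its filtration value is the max over those edges (0 for a
    vertex).  Output is sorted lexicographically on the stringified tuples,
    matching the library's deterministic order.
    """
    edges = g.edges
    verts = g.vertices
    out: Dict[int, List[Tuple[Tuple, float]]] = {}
    for k in range(max_dim + 1):
        found = []
        for tup in itertools.permutations(verts, k + 1):
            needed = [
                (tup[i], tup[j]) for i in range(k + 1) for j in range(i + 1, k + 1)
            ]
            if all(e in edges for e in needed):
                filt = max((edges[e] for e in needed), default=0.0)
                found.append((tup, filt))
        found.sort(key=lambda s: tuple(map(str, s[0])))
        out[k] = found
    return out


def sublevel(
    simplices: Dict[int, List[Tuple[Tuple, float]]], t: float
) -> Dict[int, List[Tuple[Tuple, float]]]:
    return {k: [s for s in lst if s[1] <= t] for k, lst in simplices.items()}


def oracle_boundary(
    k_simplices: List[Tuple[Tuple, float]],
    km1_simplices: List[Tuple[Tuple, float]],
) -> sympy.Matrix:
    """Integer boundary matrix built independently of the library."""
    index = {tup: i for i, (tup, _) in enumerate(km1_simplices)}
    M = sympy.zeros(len(km1_simplices), len(k_simplices))
    for j, (tup, _) in enumerate(k_simplices):
        for i in range(len(tup)):
            face = tup[:i] + tup[i + 1 :]
            M[index[face], j] += (-1) ** i
    return M


def persistent_betti_oracle(
    g: FilteredDigraph, k: int, a: float, b: float, max_dim: int
) -> int:
    """Exact persistent Betti number beta_k(a, b) by rational rank arithmetic.

    beta_k(a, b) = dim ker d_k^a - dim( im d_{k+1}^b  intersect  C_k^a ),
    where the intersection dimension is rank(B) - rank(B restricted to the
    rows of k-simplices absent from the a-complex).
    """
    S = brute_force_simplices(g, max_dim + 1)
    Sa, Sb = sublevel(S, a), sublevel(S, b)
    n_k_a = len(Sa[k])
    if k == 0:
        nullity = n_k_a
    else:
        Bk_a = oracle_boundary(Sa[k], Sa[k - 1])
        nullity = n_k_a - Bk_a.rank()
    Bk1_b = oracle_boundary(Sb[k + 1], Sb[k])
    a_tuples = {tup for tup, _ in Sa[k]}
    outside = [i for i, (tup, _) in enumerate(Sb[k]) if tup not in a_tuples]
    rank_total = Bk1_b.rank()
    rank_outside = Bk1_b[outside, :].rank() if outside else 0
    return nullity - (rank_total - rank_outside)


def random_digraph(
    rng: np.random.Generator,
    n_max: int = 7,
    edge_prob: float = 0.4,
    filtration_levels: Tuple[float, ...] = (0.0,),
) -> FilteredDigraph:
    """A random simple digraph on up to ``n_max`` vertices with edge
    filtration values drawn from ``filtration_levels``."""
    n = int(rng.integers(2, n_max + 1))
    verts = [f"v{i}" for i in range(n)]
    g = FilteredDigraph(verts)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < edge_prob:
                g.add_edge(verts[i], verts[j], float(rng.choice(filtration_levels)))
    return g


def brute_force_pairs(P: np.ndarray, L: np.ndarray, cutoff: float) -> int:
    """O(n^2) double-loop count of cross pairs within the cutoff."""
    count = 0
    for p in P:
        for l in L:
            if float(np.sqrt(((p - l) ** 2).sum())) <= cutoff:
                count += 1
    return count


def pearson_formula(x, y) -> float:
    """Textbook Pearson correlation, written out independently."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
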