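"""Persistent directed flag Laplacians and their spectra.

For a directed flag complex with real chain groups C_k (the standard basis
of ordered simplices is declared orthonormal), the boundary operator maps a
k-simplex to the alternating sum of its (k-1)-faces.  Given two nested
complexes K_a <= K_b of the same filtration, the persistent boundary
operator in dimension k+1 acts on the subspace

    C_{k+1}(a, b) = { c in C_{k+1}(b) : boundary(c) in C_k(a) },

and the k-th persistent Laplacian is

    L_k(a, b) = D D^T + B_k(a)^T B_k(a),

where D is the matrix of the persistent boundary operator expressed in an
orthonormal basis of C_{k+1}(a, b) and B_k(a) is the ordinary boundary
matrix of K_a.  L_k(a, b) is symmetric positive semidefinite; the
multiplicity of its (numerically) zero eigenvalues equals the persistent
Betti number beta_k(a, b), and for a = b it reduces to the ordinary
directed flag Laplacian  L_k = B_{k+1} B_{k+1}^T + B_k^T B_k.

Orthonormality of the null-space basis used to express D is essential: the
spectrum of D D^T would otherwise depend on the choice of basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, sparse

from .flag_complex import FlagComplex, is_subcomplex

__all__ = [
    "Spectrum",
    "PersistentLaplacian",
    "boundary_matrix",
    "persistent_boundary",
    "persistent_laplacian",
    "spectrum",
    "betti",
    "write_spectra",
    "read_spectra",
]

#: Relative zero threshold: eigenvalues within 1e-8 * max(1, lambda_max) of
#: zero are counted as harmonic.
ZERO_TOL_REL = 1e-8


@dataclass(frozen=True)
class Spectrum:
    """Eigenvalues of a Laplacian, nondecreasing and clipped at zero."""

    eigenvalues: np.ndarray
    zero_tolerance: float

    @property
    def betti(self) -> int:
        """Multiplicity of the (numerically) zero eigenvalue."""
        return int(np.count_nonzero(np.abs(self.eigenvalues) <= self.zero_tolerance))

    @property
    def fiedler(self) -> float:
        """Smallest eigenvalue above the zero tolerance (0.0 if none)."""
        pos = self.eigenvalues[self.eigenvalues > self.zero_tolerance]
        return float(pos[0]) if pos.size else 0.0


@dataclass(frozen=True)
class PersistentLaplacian:
    """The matrix of L_k(a, b) together with its defining dimension."""

    dimension: int
    matrix: np.ndarray
    interval: Optional[Tuple[float, float]] = None

    def spectrum(self, zero_tolerance: Optional[float] = None) -> Spectrum:
        return spectrum(self.matrix, zero_tolerance)


def boundary_matrix(k: int, complex: FlagComplex) -> sparse.csr_matrix:
    """Boundary matrix B_k with rows the (k-1)-simplices, columns the
    k-simplices, and entry (-1)^i where the row simplex is the column
    simplex with its i-th vertex removed.

    For k = 0 the codomain is trivial and a 0 x n_0 matrix is returned.
    Empty dimensions yield zero-shaped matrices.
    """
    n_k = complex.n_simplices(k)
    if k == 0:
        return sparse.csr_matrix((0, n_k))
    n_km1 = complex.n_simplices(k - 1)
    row_index = complex.index(k - 1)
    data: List[float] = []
    rows: List[int] = []
    cols: List[int] = []
    for j, s in enumerate(complex.simplices(k)):
        for i in range(k + 1):
            rows.append(row_index[s.face(i)])
            cols.append(j)
            data.append(1.0 if i % 2 == 0 else -1.0)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_km1, n_k))


def _require_subcomplex(complex_a: FlagComplex, complex_b: FlagComplex) -> None:
    if not is_subcomplex(complex_a, complex_b):
        raise ValueError("complex_a is not a subcomplex of complex_b")


def persistent_boundary(
    k_plus_1: int, complex_b: FlagComplex, complex_a: FlagComplex
) -> np.ndarray:
    """Matrix of the persistent boundary operator on C_{k+1}(a, b).

    Rows are indexed by the k-simplices of ``complex_a`` (in their
    deterministic order); columns by an orthonormal basis of the chains of
    ``complex_b`` whose boundaries lie entirely within ``complex_a``.  The
    basis is computed as the SVD null space of the "outside" row block of
    B_{k+1}(b) (rows indexed by k-simplices of b absent from a).
    """
    _require_subcomplex(complex_a, complex_b)
    k = k_plus_1 - 1
    if k_plus_1 > complex_b.max_dimension:
        return np.zeros((complex_a.n_simplices(k), 0))
    B = boundary_matrix(k_plus_1, complex_b).toarray()
    if k_plus_1 == 0:
        return B
    a_faces = complex_a.index(k)
    inside = np.fromiter(
        (s.vertices in a_faces for s in complex_b.simplices(k)),
        dtype=bool,
        count=complex_b.n_simplices(k),
    )
    B_in = B[inside]
    B_out = B[~inside]
    if B_out.shape[0] == 0 or B.shape[1] == 0:
        return B_in
    Z = linalg.null_space(B_out)
    return B_in @ Z


def persistent_laplacian(
    k: int,
    complex_a: FlagComplex,
    complex_b: Optional[FlagComplex] = None,
    interval: Optional[Tuple[float, float]] = None,
) -> PersistentLaplacian:
    """The k-th persistent directed flag Laplacian of the pair (a, b).

    ``complex_b`` defaults to ``complex_a``, giving the ordinary
    (non-persistent) directed flag Laplacian.  Rows and columns are indexed
    by the k-simplices of ``complex_a``.
    """
    if complex_b is None:
        complex_b = complex_a
    _require_subcomplex(complex_a, complex_b)
    n_k = complex_a.n_simplices(k)
    D = persistent_boundary(k + 1, complex_b, complex_a)
    Bk = boundary_matrix(k, complex_a).toarray()
    L = D @ D.T + Bk.T @ Bk
    if L.shape != (n_k, n_k):  # pragma: no cover - defensive
        raise RuntimeError("Laplacian shape mismatch")
    return PersistentLaplacian(k, L, interval)


def spectrum(L, zero_tolerance: Optional[float] = None) -> Spectrum:
    """Full spectrum of a symmetric PSD matrix via a dense eigensolver.

    Eigenvalues within ``-tol`` of zero are clipped to 0; values more
    negative than the PSD tolerance raise.  ``zero_tolerance`` defaults to
    ``1e-8 * max(1, lambda_max)``.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("expected a square matrix")
    n = L.shape[0]
    if n == 0:
        return Spectrum(np.empty(0), zero_tolerance if zero_tolerance is not None else ZERO_TOL_REL)
    scale = max(1.0, float(np.abs(L).max()))
    if not np.allclose(L, L.T, atol=1e-9 * scale):
        raise ValueError("matrix is not symmetric")
    vals = linalg.eigvalsh((L + L.T) / 2.0)
    lam_max = float(vals[-1])
    tol = (
        float(zero_tolerance)
        if zero_tolerance is not None
        else ZERO_TOL_REL * max(1.0, lam_max)
    )
    psd_tol = max(tol, 1e-7 * scale)
    if float(vals[0]) < -psd_tol:
        raise ValueError(f"matrix is not positive semidefinite (min eig {vals[0]:g})")
    vals = np.maximum(vals, 0.0)
    return Spectrum(vals, tol)


def betti(s: Spectrum) -> int:
    """Number of eigenvalues with magnitude at most the zero tolerance."""
    return s.betti


def write_spectra(
    entries: Iterable[Tuple[int, float, float, Spectrum]], path
) -> None:
    """Export spectra: one tab-separated row ``k  a  b  lam1 lam2 ...``."""
    with open(path, "w") as fh:
        for k, a, b, s in entries:
            vals = "\t".join(f"{v:.12g}" for v in np.asarray(s.eigenvalues))
            fh.write(f"{k}\t{a:.12g}\t{b:.12g}" + ("\t" + vals if vals else "") + "\n")


def read_spectra(path) -> List[Tuple[int, float, float, np.ndarray]]:
    """Inverse of :func:`write_spectra`."""
    out: List[Tuple[int, float, float, np.ndarray]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            k, a, b = int(parts[0]), float(parts[1]), float(parts[2])
            vals = np.array([float(x) for x in parts[3:]])
            out.append((k, a, b, vals))
    return out
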