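"""Statistical spectral features of persistent directed flag Laplacians.

For every kernel x element pair x filtration interval (a, b) x homological
dimension k in {0, 1}, the pair digraph's persistent Laplacian L_k(a, b) is
assembled and ten summary statistics of its spectrum are recorded:

    min_nonzero (the Fiedler value), max, sum, mean, median, variance, std
    (the latter five over the positive eigenvalues), count_positive,
    sum_squares, zero_count.

With the default five filtration intervals this yields the fixed-length
block of 36 * 5 * 2 * 10 = 3600 features per kernel; multi-kernel models
concatenate one block per kernel (7200 for two kernels, 14400 for four).
An empty spectrum (no k-simplices alive at the interval) contributes a row
of ten zeros, so the feature length is an invariant of the schema, not of
the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .flag_complex import build_flag_complex, complex_at_filtration
from .fri_digraph import ElementPair, KernelSpec, build_pair_digraph, element_pairs
from .laplacian_spectra import Spectrum, persistent_laplacian
from .mol_io import ComplexStructure

__all__ = [
    "DEFAULT_INTERVALS",
    "STAT_NAMES",
    "SpectralStats",
    "FeatureVector",
    "spectral_stats",
    "feature_labels",
    "featurize_complex",
    "featurize_many",
    "drop_all_zero_columns",
]

#: Filtration intervals over which spectra are collected; chosen where the
#: Betti-0/Betti-1 activity of kernel-weighted digraphs concentrates.
DEFAULT_INTERVALS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.8),
    (0.8, 0.85),
    (0.85, 0.9),
    (0.9, 0.95),
    (0.95, 1.0),
)

STAT_NAMES: Tuple[str, ...] = (
    "min_nonzero",
    "max",
    "sum",
    "mean",
    "median",
    "variance",
    "std",
    "count_positive",
    "sum_squares",
    "zero_count",
)

DEFAULT_DIMENSIONS: Tuple[int, ...] = (0, 1)


class SpectralStats(NamedTuple):
    min_nonzero: float
    max: float
    sum: float
    mean: float
    median: float
    variance: float
    std: float
    count_positive: float
    sum_squares: float
    zero_count: float


_ZEROS = SpectralStats(*([0.0] * 10))


def spectral_stats(s: Spectrum) -> SpectralStats:
    """The ten spectral summary statistics of one Laplacian spectrum.

    "Positive" means strictly above the spectrum's zero tolerance; an empty
    spectrum yields all zeros, and a spectrum with no positive eigenvalues
    zeros every field except ``zero_count``.
    """
    vals = np.asarray(s.eigenvalues, dtype=float)
    if vals.size == 0:
        return _ZEROS
    pos = vals[vals > s.zero_tolerance]
    zero_count = float(vals.size - pos.size)
    if pos.size == 0:
        return _ZEROS._replace(zero_count=zero_count)
    return SpectralStats(
        min_nonzero=float(pos[0]),
        max=float(pos[-1]),
        sum=float(pos.sum()),
        mean=float(pos.mean()),
        median=float(np.median(pos)),
        variance=float(pos.var()),
        std=float(pos.std()),
        count_positive=float(pos.size),
        sum_squares=float(np.square(pos).sum()),
        zero_count=zero_count,
    )


@dataclass(frozen=True)
class FeatureVector:
    """Deterministically ordered feature values with their schema labels."""

    values: np.ndarray
    labels: Tuple[str, ...]
    kernel_specs: Tuple[KernelSpec, ...]

    def __len__(self) -> int:
        return self.values.size


def _validate_grid(grid: Sequence[Tuple[float, float]]) -> None:
    for a, b in grid:
        if not a < b:
            raise ValueError(f"interval ({a}, {b}) must satisfy a < b")


def feature_labels(
    specs: Sequence[KernelSpec],
    grid: Sequence[Tuple[float, float]] = DEFAULT_INTERVALS,
    dimensions: Sequence[int] = DEFAULT_DIMENSIONS,
) -> Tuple[str, ...]:
    """Schema labels in the fixed order kernel -> element pair -> interval
    -> dimension -> statistic."""
    labels = []
    for spec in specs:
        for pair in element_pairs():
            for a, b in grid:
                for k in dimensions:
                    for stat in STAT_NAMES:
                        labels.append(
                            f"{spec.label}|{pair.label}|{a:g}-{b:g}|dim{k}|{stat}"
                        )
    return tuple(labels)


def featurize_complex(
    c: ComplexStructure,
    specs: Sequence[KernelSpec],
    grid: Sequence[Tuple[float, float]] = DEFAULT_INTERVALS,
    dimensions: Sequence[int] = DEFAULT_DIMENSIONS,
    radii=None,
    electronegativity=None,
) -> FeatureVector:
    """The full spectral feature vector of one complex.

    Length is always ``36 * len(grid) * len(dimensions) * 10 * len(specs)``
    regardless of input; empty pair digraphs contribute zero blocks.
    """
    if not specs:
        raise ValueError("at least one kernel spec is required")
    _validate_grid(grid)
    max_dim = max(dimensions) + 1
    values: List[float] = []
    for spec in specs:
        for pair in element_pairs():
            g = build_pair_digraph(c, pair, spec, radii, electronegativity)
            K = build_flag_complex(g, max_dim=max_dim)
            cache = {}

            def at(t: float):
                if t not in cache:
                    cache[t] = complex_at_filtration(K, t)
                return cache[t]

            for a, b in grid:
                ca, cb = at(a), at(b)
                for k in dimensions:
                    L = persistent_laplacian(k, ca, cb, interval=(a, b))
                    values.extend(spectral_stats(L.spectrum()))
    return FeatureVector(
        np.asarray(values, dtype=float),
        feature_labels(specs, grid, dimensions),
        tuple(specs),
    )


def featurize_many(
    complexes: Sequence[ComplexStructure],
    specs: Sequence[KernelSpec],
    grid: Sequence[Tuple[float, float]] = DEFAULT_INTERVALS,
    dimensions: Sequence[int] = DEFAULT_DIMENSIONS,
    ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Feature matrix for a batch of complexes (rows indexed by complex id)."""
    labels = feature_labels(specs, grid, dimensions)
    rows = [featurize_complex(c, specs, grid, dimensions).values for c in complexes]
    index = list(ids) if ids is not None else [c.id or str(i) for i, c in enumerate(complexes)]
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(labels))),
                        index=index, columns=list(labels))


def drop_all_zero_columns(
    X: Union[pd.DataFrame, np.ndarray],
    labels: Optional[Sequence[str]] = None,
):
    """Remove feature columns that are exactly zero for every complex.

    Returns ``(matrix, kept_labels)``; a column that is nonzero in even a
    single row is kept.  For a bare array without labels the kept column
    indices are returned instead.
    """
    if isinstance(X, pd.DataFrame):
        if X.shape[0] == 0:
            raise ValueError("feature matrix must have at least one row")
        mask = (X != 0).any(axis=0).to_numpy()
        kept = list(np.asarray(X.columns)[mask])
        return X.loc[:, mask], kept
    X = np.asarray(X)
    if X.shape[0] == 0:
        raise ValueError("feature matrix must have at least one row")
    mask = (X != 0).any(axis=0)
    kept = (
        [labels[i] for i in np.flatnonzero(mask)]
        if labels is not None
        else list(np.flatnonzero(mask))
    )
    return X[:, mask], kept
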