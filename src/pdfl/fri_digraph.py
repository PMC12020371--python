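"""Element-specific, kernel-weighted, electronegativity-directed digraphs.

Each protein-ligand complex is decomposed into 36 bipartite digraphs, one
per (protein element, ligand element) pair over protein {C, N, O, S} and
ligand {C, N, O, S, P, F, Cl, Br, I}.  An edge joins every cross pair of
atoms within the distance cutoff (12 A by default); its weight is the
flexibility-rigidity index (FRI) correlation

    mu = Phi(||r_p - r_l||; eta_pl),

with Phi either a generalized Lorentz kernel 1 / (1 + (r/eta)^nu) or a
generalized exponential kernel exp(-(r/eta)^kappa).  The characteristic
distance eta_pl is tau times the sum of the two atoms' van der Waals radii
(Bondi table).  The edge points from the atom of lower Pauling
electronegativity toward the higher one — polarization flows toward the
electron-withdrawing partner — with exact ties resolved protein -> ligand
for determinism.

The filtration value of an edge is 1 - mu, so strong (close) interactions
enter the filtration early and all values lie in [0, 1).  The digraphs are
bipartite, hence triangle-free: their directed flag complexes carry no
simplices of dimension >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

from .flag_complex import FilteredDigraph
from .mol_io import (
    LIGAND_ELEMENTS,
    PROTEIN_ELEMENTS,
    AtomRecord,
    ComplexStructure,
    _pair_indices,
)

__all__ = [
    "KernelSpec",
    "ElementPair",
    "PAULING_ELECTRONEGATIVITY",
    "BONDI_VDW_RADII",
    "element_pairs",
    "kernel_value",
    "characteristic_distance",
    "edge_direction",
    "build_pair_digraph",
    "rigidity_index",
]

#: Pauling electronegativities for the supported elements.
PAULING_ELECTRONEGATIVITY: Dict[str, float] = {
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "S": 2.58,
    "P": 2.19,
    "F": 3.98,
    "Cl": 3.16,
    "Br": 2.96,
    "I": 2.66,
    "H": 2.20,
}

#: Bondi van der Waals radii (Angstrom).
BONDI_VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "H": 1.20,
}


@dataclass(frozen=True)
class KernelSpec:
    """A radial correlation kernel.

    ``family``: 'L' (generalized Lorentz, order nu) or 'E' (generalized
    exponential, order kappa).  ``beta`` is the kernel order, ``tau`` the
    decay (scale) parameter multiplying the vdW-radius sum, ``cutoff`` the
    interaction distance cutoff in Angstroms.  The hyperparameter search
    grid used for model selection spans beta in {0.5, 1.0, ..., 6} and tau
    in {0.5, 1.0, ..., 6} u {10, 15, 20}; arbitrary positive values are
    accepted here.
    """

    family: str
    beta: float
    tau: float
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.family not in ("L", "E"):
            raise ValueError("kernel family must be 'L' (Lorentz) or 'E' (exponential)")
        if self.beta <= 0 or self.tau <= 0 or self.cutoff <= 0:
            raise ValueError("beta, tau and cutoff must all be positive")

    @property
    def label(self) -> str:
        return f"{self.family}b{self.beta:g}t{self.tau:g}"


@dataclass(frozen=True)
class ElementPair:
    protein_element: str
    ligand_element: str

    def __post_init__(self) -> None:
        if self.protein_element not in PROTEIN_ELEMENTS:
            raise ValueError(f"invalid protein element {self.protein_element!r}")
        if self.ligand_element not in LIGAND_ELEMENTS:
            raise ValueError(f"invalid ligand element {self.ligand_element!r}")

    @property
    def label(self) -> str:
        return f"{self.protein_element}-{self.ligand_element}"


def element_pairs() -> List[ElementPair]:
    """The 36 (protein element, ligand element) pairs in deterministic
    order: protein C, N, O, S outer; ligand C, N, O, S, P, F, Cl, Br, I
    inner."""
    return [ElementPair(p, l) for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS]


def kernel_value(r: float, eta: float, spec: KernelSpec) -> float:
    """Kernel correlation Phi(r; eta) in (0, 1]: 1 at contact, strictly
    decreasing with distance."""
    if eta <= 0:
        raise ValueError("characteristic distance eta must be > 0")
    if r < 0:
        raise ValueError("distance must be >= 0")
    x = (r / eta) ** spec.beta
    if spec.family == "E":
        return math.exp(-x)
    return 1.0 / (1.0 + x)


def _element_of(atom) -> str:
    return atom.element if isinstance(atom, AtomRecord) else str(atom)


def characteristic_distance(
    p,
    l,
    tau: float,
    radii: Optional[Mapping[str, float]] = None,
) -> float:
    """eta_pl = tau * (r_vdw(p) + r_vdw(l)); atoms or element symbols accepted."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    table = radii if radii is not None else BONDI_VDW_RADII
    ep, el = _element_of(p), _element_of(l)
    try:
        return tau * (table[ep] + table[el])
    except KeyError as exc:
        raise ValueError(f"element {exc.args[0]!r} missing from vdW radius table") from None


def edge_direction(
    p: AtomRecord,
    l: AtomRecord,
    electronegativity: Optional[Mapping[str, float]] = None,
) -> Tuple[AtomRecord, AtomRecord]:
    """(source, target): the edge points from the atom of lower
    electronegativity to the higher.  Exact ties make the protein atom the
    source."""
    table = electronegativity if electronegativity is not None else PAULING_ELECTRONEGATIVITY
    try:
        chi_p = table[_element_of(p)]
        chi_l = table[_element_of(l)]
    except KeyError as exc:
        raise ValueError(
            f"element {exc.args[0]!r} missing from electronegativity table"
        ) from None
    if chi_l >= chi_p:
        return (p, l)
    return (l, p)


def build_pair_digraph(
    c: ComplexStructure,
    pair: ElementPair,
    spec: KernelSpec,
    radii: Optional[Mapping[str, float]] = None,
    electronegativity: Optional[Mapping[str, float]] = None,
) -> FilteredDigraph:
    """The filtered bipartite digraph of one element pair.

    Vertices are the atoms of the pair's elements that participate in at
    least one retained cross pair (ids ``p<i>`` / ``l<j>`` index into the
    element-filtered atom lists).  Each retained pair contributes a single
    directed edge with filtration value 1 - mu.
    """
    prot = [a for a in c.protein_atoms if a.element == pair.protein_element]
    lig = [a for a in c.ligand_atoms if a.element == pair.ligand_element]
    g = FilteredDigraph()
    if not prot or not lig:
        return g
    eta = characteristic_distance(pair.protein_element, pair.ligand_element, spec.tau, radii)
    # direction depends on elements only, so it is uniform over the digraph
    src_is_protein = (
        edge_direction(prot[0], lig[0], electronegativity)[0].role == "protein"
    )
    for i, j, d in _pair_indices(prot, lig, spec.cutoff):
        mu = kernel_value(d, eta, spec)
        u, v = f"p{i}", f"l{j}"
        if not src_is_protein:
            u, v = v, u
        g.add_edge(u, v, 1.0 - mu)
    return g


def rigidity_index(
    c: ComplexStructure,
    pair: ElementPair,
    spec: KernelSpec,
    radii: Optional[Mapping[str, float]] = None,
) -> float:
    """Summed rigidity index for one element pair: the sum of the kernel
    correlations over all retained cross pairs.  Diagnostic companion to
    :func:`build_pair_digraph` (whose edge weights it sums)."""
    prot = [a for a in c.protein_atoms if a.element == pair.protein_element]
    lig = [a for a in c.ligand_atoms if a.element == pair.ligand_element]
    if not prot or not lig:
        return 0.0
    eta = characteristic_distance(pair.protein_element, pair.ligand_element, spec.tau, radii)
    return sum(
        kernel_value(d, eta, spec) for _, _, d in _pair_indices(prot, lig, spec.cutoff)
    )
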