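"""Deterministic toy digraphs and random protein-ligand-like complexes.

Every generator is a pure function of its spec (the seed is mandatory), so
fixtures are byte-identical across runs.  The random complexes place
protein heavy atoms uniformly in a cubic box and cluster the ligand atoms
near the box center, with element frequencies loosely mimicking real
protein and drug-like compositions; labels come from a planted linear rule
on contact counts.  No claim of physical realism is made — the fixtures
exist to exercise the geometric, spectral and statistical machinery of the
pipeline end to end without any external downloads.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .flag_complex import FilteredDigraph
from .mol_io import AtomRecord, ComplexStructure, _pair_indices

__all__ = [
    "FixtureSpec",
    "directed_clique",
    "directed_cycle",
    "random_complex",
    "make_dataset",
    "write_pdb",
    "write_mol2",
]

#: Rough heavy-atom composition of globular proteins.
DEFAULT_PROTEIN_FREQS: Dict[str, float] = {"C": 0.62, "N": 0.16, "O": 0.20, "S": 0.02}

#: Drug-like ligand composition with occasional halogens/phosphorus.
DEFAULT_LIGAND_FREQS: Dict[str, float] = {
    "C": 0.60,
    "N": 0.12,
    "O": 0.20,
    "S": 0.02,
    "P": 0.01,
    "F": 0.02,
    "Cl": 0.02,
    "Br": 0.005,
    "I": 0.005,
}

#: Planted affinity rule: weight per protein-element contact.
DEFAULT_AFFINITY_WEIGHTS: Dict[str, float] = {"C": 0.1, "N": 0.3, "O": -0.2, "S": 0.5}


def _vertex_labels(n: int) -> List[str]:
    if n <= 26:
        return list(string.ascii_lowercase[:n])
    return [f"v{i}" for i in range(n)]


def directed_clique(n: int) -> FilteredDigraph:
    """Transitive tournament on ``n`` labeled vertices, all edges at
    filtration 0: every pair (i < j) carries the edge (v_i, v_j).

    For n = 4 this is the minimal complete directed 4-clique on vertices
    a, b, c, d with the six edges (a,b), (a,c), (a,d), (b,c), (b,d), (c,d).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = _vertex_labels(n)
    g = FilteredDigraph(labels)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(labels[i], labels[j], 0.0)
    return g


def directed_cycle(n: int) -> FilteredDigraph:
    """Directed n-cycle v0 -> v1 -> ... -> v_{n-1} -> v0 (one loop, beta_1 = 1)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    labels = _vertex_labels(n)
    g = FilteredDigraph(labels)
    for i in range(n):
        g.add_edge(labels[i], labels[(i + 1) % n], 0.0)
    return g


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one random protein-ligand-like complex.

    ``seed`` is mandatory; identical specs produce byte-identical output.
    ``ligand_offset`` displaces the ligand cluster along x from the box
    center (useful to push every cross pair beyond the cutoff).
    ``noise_sigma`` is the absolute Gaussian noise added to the planted
    label of this single complex; batch generation usually leaves it at 0
    and adds noise scaled to the signal spread instead.
    """

    seed: int
    n_protein: int = 50
    n_ligand: int = 10
    box_size: float = 24.0
    ligand_spread: float = 2.0
    ligand_offset: float = 0.0
    cutoff: float = 12.0
    protein_freqs: Tuple[Tuple[str, float], ...] = tuple(DEFAULT_PROTEIN_FREQS.items())
    ligand_freqs: Tuple[Tuple[str, float], ...] = tuple(DEFAULT_LIGAND_FREQS.items())
    affinity_weights: Tuple[Tuple[str, float], ...] = tuple(
        DEFAULT_AFFINITY_WEIGHTS.items()
    )
    noise_sigma: float = 0.0


def random_complex(spec: FixtureSpec) -> Tuple[ComplexStructure, float]:
    """One seed-deterministic complex and its planted affinity label.

    The label is a linear function of per-protein-element contact counts
    within the cutoff, plus Gaussian noise of width ``spec.noise_sigma``.
    """
    rng = np.random.default_rng(spec.seed)
    p_els, p_freqs = zip(*spec.protein_freqs)
    l_els, l_freqs = zip(*spec.ligand_freqs)
    weights = dict(spec.affinity_weights)

    p_pos = rng.uniform(0.0, spec.box_size, size=(spec.n_protein, 3))
    p_elements = rng.choice(p_els, size=spec.n_protein, p=np.asarray(p_freqs))
    center = np.full(3, spec.box_size / 2.0)
    center[0] += spec.ligand_offset
    l_pos = center + rng.normal(0.0, spec.ligand_spread, size=(spec.n_ligand, 3))
    l_elements = rng.choice(l_els, size=spec.n_ligand, p=np.asarray(l_freqs))

    protein = [
        AtomRecord(str(e), tuple(float(v) for v in xyz), "protein")
        for e, xyz in zip(p_elements, p_pos)
    ]
    ligand = [
        AtomRecord(str(e), tuple(float(v) for v in xyz), "ligand")
        for e, xyz in zip(l_elements, l_pos)
    ]
    structure = ComplexStructure(protein, ligand, id=f"synt{spec.seed}")

    signal = sum(
        weights.get(protein[i].element, 0.0)
        for i, _, _ in _pair_indices(protein, ligand, spec.cutoff)
    )
    label = float(signal + rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma else float(signal)
    return structure, label


def make_dataset(
    n: int,
    base_seed: int,
    noise_frac: float = 0.1,
    template: FixtureSpec | None = None,
) -> Tuple[List[ComplexStructure], np.ndarray, List[str]]:
    """A batch of ``n`` complexes with noisy planted labels.

    Complex ``i`` uses seed ``base_seed + i``.  Gaussian label noise has
    standard deviation ``noise_frac`` times the spread of the noiseless
    planted signals, so the attainable correlation is known by
    construction.
    """
    template = template if template is not None else FixtureSpec(seed=base_seed)
    complexes, signals, ids = [], [], []
    for i in range(n):
        spec = replace(template, seed=base_seed + i, noise_sigma=0.0)
        c, signal = random_complex(spec)
        c.id = f"synt{i:04d}"
        complexes.append(c)
        signals.append(signal)
        ids.append(c.id)
    signals = np.asarray(signals)
    rng = np.random.default_rng(base_seed)
    sigma = noise_frac * float(np.std(signals)) if noise_frac else 0.0
    labels = signals + rng.normal(0.0, sigma, size=n) if sigma else signals.copy()
    return complexes, labels, ids


def write_pdb(structure: ComplexStructure, path) -> None:
    """Emit the protein atoms as minimal PDB ATOM records (one residue per
    atom so names never collide)."""
    with open(path, "w") as fh:
        for i, atom in enumerate(structure.protein_atoms):
            el = atom.element
            serial = i + 1
            name = (el + str(i % 100)) if len(el) == 2 else (" " + el + str(i % 100))
            x, y, z = atom.position
            fh.write(
                f"ATOM  {serial:5d} {name:<4.4s} UNK A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{el.upper():>2.2s}\n"
            )
        fh.write("END\n")


def write_mol2(structure: ComplexStructure, path) -> None:
    """Emit the ligand atoms as a minimal TRIPOS MOL2 file."""
    atoms = structure.ligand_atoms
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{structure.id or 'ligand'}\n")
        fh.write(f"{len(atoms)} 0 0 0 0\nSMALL\nNO_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i, atom in enumerate(atoms):
            x, y, z = atom.position
            fh.write(
                f"{i + 1:>7d} {atom.element}{i + 1:<3d} "
                f"{x:10.4f} {y:10.4f} {z:10.4f} {atom.element} 1 LIG 0.0000\n"
            )
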