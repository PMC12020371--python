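"""Heavy-atom extraction from protein (PDB) and ligand (MOL2/SDF) files.

Only the elements that matter for element-specific interaction features are
retained: protein atoms in {C, N, O, S} and ligand atoms in
{C, N, O, S, P, F, Cl, Br, I}.  Hydrogens are always excluded; atoms of any
other element are skipped with a logged count.  Coordinates are in
Angstroms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

PROTEIN_ELEMENTS: Tuple[str, ...] = ("C", "N", "O", "S")
LIGAND_ELEMENTS: Tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "PROTEIN_ELEMENTS",
    "LIGAND_ELEMENTS",
    "read_protein",
    "read_ligand",
    "read_complex",
    "pairs_within_cutoff",
]


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element symbol, position (Angstrom), and role."""

    element: str
    position: Tuple[float, float, float]
    role: str  # "protein" | "ligand"

    def __post_init__(self) -> None:
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be 'protein' or 'ligand', got {self.role!r}")
        whitelist = PROTEIN_ELEMENTS if self.role == "protein" else LIGAND_ELEMENTS
        if self.element not in whitelist:
            raise ValueError(
                f"element {self.element!r} not allowed for role {self.role!r}"
            )
        if not all(np.isfinite(self.position)):
            raise ValueError("atom coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class ComplexStructure:
    """All retained heavy atoms of one protein-ligand complex."""

    protein_atoms: List[AtomRecord]
    ligand_atoms: List[AtomRecord]
    id: str = ""


def _normalize_element(element: str, name: str = "") -> str:
    """Resolve an element symbol from the element column, falling back to
    atom-name heuristics ('CL1' -> Cl).  Returns '' when unresolvable."""
    el = element.strip()
    if el:
        return el.capitalize()
    base = "".join(c for c in name if c.isalpha())
    if not base:
        return ""
    two = base[:2].capitalize()
    if two in ("Cl", "Br", "Se", "Fe", "Zn", "Mg", "Mn", "Na"):
        return two
    return base[:1].upper()


def _filter_atoms(
    raw: Sequence[Tuple[str, Tuple[float, float, float]]],
    role: str,
    source: str,
) -> List[AtomRecord]:
    whitelist = PROTEIN_ELEMENTS if role == "protein" else LIGAND_ELEMENTS
    records: List[AtomRecord] = []
    dropped: Dict[str, int] = {}
    for el, pos in raw:
        if el in ("H", "D", ""):
            dropped[el or "?"] = dropped.get(el or "?", 0) + 1
            continue
        if el not in whitelist:
            dropped[el] = dropped.get(el, 0) + 1
            continue
        records.append(AtomRecord(el, pos, role))
    if dropped:
        log.warning(
            "%s: skipped %d atom(s) outside the %s element whitelist: %s",
            source,
            sum(dropped.values()),
            role,
            ", ".join(f"{k} x{v}" for k, v in sorted(dropped.items())),
        )
    return records


def read_protein(path) -> List[AtomRecord]:
    """Heavy-atom records from the ATOM lines of the first model of a PDB file.

    HETATM records (waters, ions, the co-crystallized ligand) are ignored —
    the ligand is supplied from its own file.  For disordered atoms the
    highest-occupancy altloc is kept (ties resolved to the first
    encountered), following Biopython's selection rule.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models/ATOM records found") from None
    raw: List[Tuple[str, Tuple[float, float, float]]] = []
    for chain in model:
        for res in chain:
            if res.id[0].strip():  # HETATM / water
                continue
            for atom in res:  # disordered atoms yield the selected altloc
                el = _normalize_element(atom.element or "", atom.get_name())
                raw.append((el, tuple(float(c) for c in atom.coord)))
    if not raw:
        raise ValueError(f"{path}: no ATOM records found")
    records = _filter_atoms(raw, "protein", str(path))
    if not records:
        raise ValueError(f"{path}: no usable heavy atoms after filtering")
    return records


def _read_mol2_atoms(path: Path) -> List[Tuple[str, Tuple[float, float, float]]]:
    # TRIPOS MOL2: the SYBYL atom-type column ("C.ar", "N.2", "Cl") carries
    # the element before the first dot.
    raw: List[Tuple[str, Tuple[float, float, float]]] = []
    section = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if stripped.startswith("@<TRIPOS>"):
                section = stripped[9:].upper()
                continue
            if section != "ATOM" or not stripped:
                continue
            parts = stripped.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: malformed MOL2 atom line")
            try:
                x, y, z = (float(v) for v in parts[2:5])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: bad coordinates in MOL2 atom line"
                ) from None
            el = parts[5].split(".")[0].capitalize()
            raw.append((el, (x, y, z)))
    return raw


def _read_sdf_atoms(path: Path) -> List[Tuple[str, Tuple[float, float, float]]]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"{path}: no molecule/atom block found in SDF")
    conf = mol.GetConformer()
    raw = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        raw.append((atom.GetSymbol(), (pos.x, pos.y, pos.z)))
    return raw


def read_ligand(path) -> List[AtomRecord]:
    """Heavy-atom records from a MOL2 (TRIPOS) or SDF (V2000) ligand file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        raw = _read_mol2_atoms(path)
    elif suffix in (".sdf", ".sd", ".mol"):
        raw = _read_sdf_atoms(path)
    else:
        raise ValueError(f"unsupported ligand format: {path.suffix!r}")
    if not raw:
        raise ValueError(f"{path}: empty atom block")
    records = _filter_atoms(raw, "ligand", str(path))
    if not records:
        raise ValueError(f"{path}: no usable heavy atoms after filtering")
    return records


def read_complex(protein_path, ligand_path, id: str | None = None) -> ComplexStructure:
    """Parse a protein PDB and a ligand MOL2/SDF into one complex."""
    cid = id if id is not None else Path(protein_path).stem
    return ComplexStructure(
        protein_atoms=read_protein(protein_path),
        ligand_atoms=read_ligand(ligand_path),
        id=cid,
    )


def _pair_indices(
    protein: Sequence[AtomRecord], ligand: Sequence[AtomRecord], cutoff: float
) -> List[Tuple[int, int, float]]:
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not protein or not ligand:
        return []
    P = np.array([a.position for a in protein], dtype=float)
    L = np.array([a.position for a in ligand], dtype=float)
    D = cdist(P, L)
    return [(int(i), int(j), float(D[i, j])) for i, j in np.argwhere(D <= cutoff)]


def pairs_within_cutoff(
    c: ComplexStructure, cutoff: float = 12.0
) -> List[Tuple[AtomRecord, AtomRecord, float]]:
    """All (protein atom, ligand atom, distance) pairs with Euclidean
    distance <= ``cutoff`` (closed ball).  Intra-protein and intra-ligand
    pairs are never produced."""
    return [
        (c.protein_atoms[i], c.ligand_atoms[j], d)
        for i, j, d in _pair_indices(c.protein_atoms, c.ligand_atoms, cutoff)
    ]
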