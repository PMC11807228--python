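"""Structure input, filtering and atom typing.

Readers for protein PDB files (via gemmi) and ligand SDF files (via RDKit),
plus the affinity-label harmonisation rules used to turn heterogeneous
Kd/Ki/IC50 measurements into a single pK label.

Ligands are kept as heavy-atom graphs: hydrogens are folded into a per-atom
``h_count`` and never become graph nodes.  Ligand elements are restricted to
the whitelist {B, C, N, O, F, P, S, Cl, Br, I}; molecules with other
elements, unparseable records, or bond orders outside
{single, aromatic, double, triple} are rejected with a machine-readable
reason ("parse" / "element" / "bond").

Protein atoms are ECIF-typed by (residue name, atom name) lookup in the
packaged canonical-residue templates; atoms without a template entry
(terminal variants, non-standard residues, ions) are kept in the structure
but flagged as untyped and excluded from environment-vector sums.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit import RDLogger

from .ecif_types import (
    ECIFToken,
    ECIF_PROTEIN_TYPES,
    PROTEIN_TYPE_INDEX,
    RESIDUE_TEMPLATES,
    THREE_TO_ONE,
    token_to_string,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

ELEMENT_WHITELIST = ("H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
#: heavy elements allowed in ligands, in the one-hot encoding order
LIGAND_ELEMENTS = ("B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
BOND_ORDERS = ("single", "aromatic", "double", "triple")

_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.AROMATIC: "aromatic",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
}
_BOND_RDKIT = {v: k for k, v in _RDKIT_BOND.items()}


class ComplexIOError(ValueError):
    """Base error for structure reading problems."""


class ProteinParseError(ComplexIOError):
    pass


class EmptyStructureError(ComplexIOError):
    pass


class LigandRejection(ComplexIOError):
    """Ligand failed a filtering rule; ``reason`` is 'parse', 'element' or 'bond'."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


class AffinityRejection(ComplexIOError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    element: str
    coords: tuple[float, float, float]
    explicit_valence: int
    heavy_degree: int
    h_count: int
    is_aromatic: bool
    in_ring: bool

    def __post_init__(self):
        if self.heavy_degree < 0 or self.h_count < 0:
            raise ValueError("negative degree/h_count")
        if self.explicit_valence < self.heavy_degree:
            raise ValueError("explicit valence below heavy degree")

    @property
    def token(self) -> ECIFToken:
        return (
            self.element,
            self.explicit_valence,
            self.heavy_degree,
            self.h_count,
            self.is_aromatic,
            self.in_ring,
        )


def assign_ecif_type(atom: AtomRecord) -> ECIFToken:
    """ECIF token of a heavy atom: a pure function of its six properties."""
    if atom.element in ("H", "D"):
        raise ValueError("hydrogens carry no ECIF type")
    return atom.token


@dataclass
class ProteinStructure:
    """Typed heavy atoms of a protein plus its chain sequences.

    ``atoms[i]`` pairs each :class:`AtomRecord` with its ECIF token, or
    ``None`` when the atom has no entry in the 22-type table.  ``coords``
    and ``type_index`` are cached arrays for vectorised featurization
    (``type_index`` is -1 for untyped atoms).
    """

    atoms: list[tuple[AtomRecord, Optional[ECIFToken]]]
    chains: list[str]
    untyped: list[int] = field(default_factory=list)
    #: optional per-atom (residue name, atom name), needed to write PDB
    residue_names: Optional[list[tuple[str, str]]] = None

    coords: np.ndarray = field(init=False, repr=False)
    type_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.atoms)
        self.coords = np.array(
            [a.coords for a, _ in self.atoms], dtype=float
        ).reshape(n, 3)
        self.type_index = np.array(
            [PROTEIN_TYPE_INDEX.get(t, -1) if t is not None else -1
             for _, t in self.atoms],
            dtype=int,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class LigandMolecule:
    """Heavy-atom graph of one ligand.

    ``bonds`` holds each covalent bond once as (i, j, order) with order in
    {'single', 'aromatic', 'double', 'triple'}.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, str]]
    mol_weight: float
    n_rotatable_bonds: int
    name: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references missing atom")
            if order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {order!r}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class ComplexRecord:
    protein: ProteinStructure
    ligand: LigandMolecule
    pk: Optional[float] = None
    target_id: str = ""
    series_id: Optional[str] = None
    complex_id: str = ""

    def __post_init__(self):
        if self.pk is not None and not math.isfinite(self.pk):
            raise ValueError("pk must be finite")


# ---------------------------------------------------------------------------
# protein reading / writing
# ---------------------------------------------------------------------------

def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy altloc per atom name; ties broken by altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or " ")) > (prev.occ, -ord(prev.altloc or " ")):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_protein(path: str, include_hetatm: bool = False) -> ProteinStructure:
    """Read a PDB file into a typed :class:`ProteinStructure`.

    Uses the first model, the highest-occupancy altloc, and (by default)
    polymer ATOM records only; waters, ions and other HETATM groups are
    included only with ``include_hetatm=True`` and are left untyped.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ProteinParseError(f"cannot parse PDB {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[0]

    atoms: list[tuple[AtomRecord, Optional[ECIFToken]]] = []
    untyped: list[int] = []
    chains: list[str] = []
    for chain in model:
        seq = []
        for res in chain:
            is_polymer_atom = res.het_flag == "A"
            if not is_polymer_atom and not include_hetatm:
                continue
            if res.name == "HOH":
                continue
            if is_polymer_atom:
                seq.append(THREE_TO_ONE.get(res.name, "X"))
            for atom in _pick_altloc(res):
                elem = atom.element.name
                if elem in ("H", "D"):
                    continue
                token = RESIDUE_TEMPLATES.get((res.name, atom.name))
                if token is not None:
                    e, val, deg, hc, ar, ring = token
                    rec = AtomRecord(e, (atom.pos.x, atom.pos.y, atom.pos.z),
                                     val, deg, hc, ar, ring)
                else:
                    rec = AtomRecord(elem, (atom.pos.x, atom.pos.y, atom.pos.z),
                                     0, 0, 0, False, False)
                    untyped.append(len(atoms))
                atoms.append((rec, token))
        if seq:
            chains.append("".join(seq))
    if not atoms:
        raise EmptyStructureError(f"no ATOM records in {path}")
    if untyped:
        logger.warning(
            "%d atom(s) without an ECIF template (e.g. terminal/non-standard); "
            "they are excluded from AEV sums", len(untyped),
        )
    return ProteinStructure(atoms=atoms, chains=chains, untyped=untyped)


def write_protein(protein: ProteinStructure, path: str,
                  residue_names: Optional[Sequence[tuple[str, str]]] = None) -> None:
    """Write a minimal PDB for a structure whose atoms carry template names.

    ``residue_names`` gives (resname, atomname) per atom; required because
    :class:`ProteinStructure` stores types, not PDB naming.  The synthetic
    generator records these alongside its pockets.
    """
    if residue_names is None:
        residue_names = protein.residue_names
    if residue_names is None or len(residue_names) != protein.n_atoms:
        raise ValueError("write_protein needs one (resname, atomname) per atom")
    lines = []
    for i, ((rec, _), (resname, atomname)) in enumerate(
        zip(protein.atoms, residue_names), start=1
    ):
        x, y, z = rec.coords
        name = atomname if len(atomname) == 4 else f" {atomname:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{resname:>4s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{rec.element:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ligand reading / writing
# ---------------------------------------------------------------------------

def _mol_to_ligand(mol: Chem.Mol, name: str = "") -> LigandMolecule:
    mol = Chem.RemoveHs(mol)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise LigandRejection("parse", "ligand is not a single connected molecule")
    if mol.GetNumConformers() == 0:
        raise LigandRejection("parse", "ligand has no 3D coordinates")
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in LIGAND_ELEMENTS:
            raise LigandRejection("element", f"element {sym} outside whitelist")
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(
            AtomRecord(
                element=sym,
                coords=(pos.x, pos.y, pos.z),
                explicit_valence=atom.GetTotalValence(),
                heavy_degree=atom.GetDegree(),
                h_count=atom.GetTotalNumHs(),
                is_aromatic=atom.GetIsAromatic(),
                in_ring=atom.IsInRing(),
            )
        )
    bonds = []
    for bond in mol.GetBonds():
        order = _RDKIT_BOND.get(bond.GetBondType())
        if order is None:
            raise LigandRejection(
                "bond", f"bond type {bond.GetBondType()} not in {BOND_ORDERS}"
            )
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return LigandMolecule(
        atoms=atoms,
        bonds=bonds,
        mol_weight=Descriptors.MolWt(mol),
        n_rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
    )


def read_ligand(path: str) -> LigandMolecule:
    """Read the first molecule of an SDF file as a heavy-atom graph."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    try:
        mol = next(iter(supplier), None)
    except OSError as exc:
        raise LigandRejection("parse", str(exc)) from exc
    if mol is None:
        raise LigandRejection("parse", f"RDKit could not parse {path}")
    return _mol_to_ligand(mol)


def ligand_to_rdkit(ligand: LigandMolecule) -> Chem.Mol:
    """Rebuild an RDKit molecule (explicit H counts, one 3D conformer)."""
    rw = Chem.RWMol()
    for rec in ligand.atoms:
        a = Chem.Atom(rec.element)
        a.SetNumExplicitHs(rec.h_count)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in ligand.bonds:
        rw.AddBond(i, j, _BOND_RDKIT[order])
        if order == "aromatic":
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(len(ligand.atoms))
    for idx, rec in enumerate(ligand.atoms):
        conf.SetAtomPosition(idx, rec.coords)
    mol.AddConformer(conf)
    if ligand.name:
        mol.SetProp("_Name", ligand.name)
    return mol


def write_ligand(ligand: LigandMolecule, path: str) -> None:
    """Write the ligand as an SDF (V2000) file; inverse of :func:`read_ligand`."""
    mol = ligand_to_rdkit(ligand)
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# affinity harmonisation
# ---------------------------------------------------------------------------

_KIND_PRIORITY = ("Kd", "Ki", "IC50")


def harmonize_affinity(
    measurements: Iterable[tuple],
) -> float:
    """Collapse (kind, molar value[, qualifier]) measurements into one pK.

    Qualified entries (">" or "<") are dropped; of the remainder, only the
    highest-priority kind present (Kd, then Ki, then IC50) is used and the
    median of its values is converted to pK = -log10(value).
    """
    by_kind: dict[str, list[float]] = {k: [] for k in _KIND_PRIORITY}
    saw_any = False
    for m in measurements:
        kind, value = m[0], m[1]
        qualifier = m[2] if len(m) > 2 else ""
        saw_any = True
        if kind not in by_kind:
            raise ValueError(f"unknown measurement kind {kind!r}")
        if qualifier in (">", "<"):
            continue
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"non-positive affinity value {value!r}")
        by_kind[kind].append(float(value))
    if not saw_any:
        raise AffinityRejection("no measurements given")
    for kind in _KIND_PRIORITY:
        if by_kind[kind]:
            return float(-np.log10(np.median(by_kind[kind])))
    raise AffinityRejection("all measurements ambiguous ('>'/'<')")


def rejection_log_frame(rejections: Sequence[tuple[str, str]]):
    """Rejection log as a pandas frame with columns (complex_id, reason)."""
    import pandas as pd

    return pd.DataFrame(rejections, columns=["complex_id", "reason"])
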