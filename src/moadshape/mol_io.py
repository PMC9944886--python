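"""Ligand structure I/O: SDF / MOL2 readers, PDB HETATM extraction, match tables.

Containers are deliberately small: an :class:`Atom` is an element symbol
plus Cartesian coordinates (Angstrom), a :class:`Conformer` is an ordered
atom list, and a :class:`Ligand` is a conformer ensemble sharing one
element composition.  RDKit does the SDF/MOL2 parsing and gemmi the PDB
parsing; no coordinates are re-centered or rescaled at parse time.
"""

from __future__ import annotations

import warnings
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdchem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Conformer",
    "Ligand",
    "LigandParseError",
    "WATER_RESIDUES",
    "read_ligands",
    "write_ligands_sdf",
    "extract_het_ligands",
    "read_protein_atoms",
    "write_match_table",
    "read_match_table",
]

#: HET codes always skipped during PDB ligand extraction.
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O", "OH2"})


class LigandParseError(ValueError):
    """A structure file (or one record in it) could not be parsed."""


@dataclass(frozen=True)
class Atom:
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom coordinates must be finite")
        object.__setattr__(self, "position", pos)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D", "T")


@dataclass
class Conformer:
    atoms: List[Atom]
    source_label: str = ""

    @property
    def n_heavy(self) -> int:
        return sum(a.is_heavy for a in self.atoms)

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)

    def element_multiset(self) -> Counter:
        return Counter(a.element.upper() for a in self.atoms)


@dataclass
class Ligand:
    ligand_id: str
    conformers: List[Conformer]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"ligand {self.ligand_id!r} needs at least one conformer")
        ref = self.conformers[0].element_multiset()
        for k, conf in enumerate(self.conformers[1:], 1):
            if conf.element_multiset() != ref:
                raise ValueError(
                    f"ligand {self.ligand_id!r}: conformer {k} has a different element composition"
                )

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)


# ---------------------------------------------------------------------------
# SDF / MOL2 reading
# ---------------------------------------------------------------------------

def _mol_to_conformer(mol: rdchem.Mol, label: str) -> Conformer:
    conf = mol.GetConformer()
    atoms = [
        Atom(element=atom.GetSymbol(), position=np.array(conf.GetAtomPosition(atom.GetIdx())))
        for atom in mol.GetAtoms()
    ]
    return Conformer(atoms=atoms, source_label=label)


def read_ligands(path, format: Optional[str] = None) -> List[Ligand]:
    """Read ligands from an SDF, MOL2 or PDB file.

    SDF records sharing a title collapse into one multi-conformer ligand
    (atom order preserved); a MOL2 file yields a single single-conformer
    ligand; PDB files are routed through :func:`extract_het_ligands`.
    Records with zero heavy atoms are skipped with a warning; unparsable
    records raise :class:`LigandParseError` naming the record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "SDF":
        return _read_sdf(path)
    if fmt == "MOL2":
        return _read_mol2(path)
    if fmt in ("PDB", "ENT"):
        return extract_het_ligands(path)
    raise ValueError(f"unsupported format {fmt!r} (expected SDF, MOL2 or PDB)")


def _read_sdf(path: Path) -> List[Ligand]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    grouped: "OrderedDict[str, List[Conformer]]" = OrderedDict()
    for index, mol in enumerate(supplier):
        if mol is None:
            raise LigandParseError(f"{path}: SDF record {index} could not be parsed")
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        title = title.strip() or f"record_{index}"
        conformer = _mol_to_conformer(mol, label=f"sdf_record_{index}")
        if conformer.n_heavy == 0:
            warnings.warn(f"{path}: SDF record {index} ({title!r}) has no heavy atoms; skipped")
            continue
        grouped.setdefault(title, []).append(conformer)
    return [Ligand(ligand_id=title, conformers=confs) for title, confs in grouped.items()]


def _read_mol2(path: Path) -> List[Ligand]:
    mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise LigandParseError(f"{path}: MOL2 record 0 could not be parsed")
    title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    title = title.strip() or path.stem
    conformer = _mol_to_conformer(mol, label="mol2")
    if conformer.n_heavy == 0:
        warnings.warn(f"{path}: MOL2 molecule has no heavy atoms; skipped")
        return []
    return [Ligand(ligand_id=title, conformers=[conformer])]


def write_ligands_sdf(ligands: Iterable[Ligand], path) -> None:
    """Write ligands to SDF, one record per conformer, titled by ligand id.

    Records are bond-less coordinate blocks; reading the file back with
    :func:`read_ligands` regroups the conformers by their shared title.
    """
    writer = Chem.SDWriter(str(path))
    try:
        for ligand in ligands:
            for conformer in ligand.conformers:
                mol = rdchem.RWMol()
                for atom in conformer.atoms:
                    mol.AddAtom(rdchem.Atom(atom.element))
                conf = rdchem.Conformer(mol.GetNumAtoms())
                for i, atom in enumerate(conformer.atoms):
                    conf.SetAtomPosition(i, [float(x) for x in atom.position])
                mol.AddConformer(conf)
                mol.SetProp("_Name", ligand.ligand_id)
                writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# PDB extraction
# ---------------------------------------------------------------------------

def _pick_altloc(atoms: List[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties prefer altloc 'A' (then alphabetical)
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def extract_het_ligands(pdb_path) -> List[Ligand]:
    """Extract one single-conformer ligand per HET residue instance.

    Residue identity is (HET code, chain id, residue number, insertion
    code); waters are always skipped and alternate locations resolved to
    the highest-occupancy conformer.  Coordinates are taken verbatim in
    the PDB frame (Angstrom).  A file without HETATM records yields an
    empty list.
    """
    structure = gemmi.read_structure(str(pdb_path))
    ligands: List[Ligand] = []
    if len(structure) == 0:
        return ligands
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag != "H" or residue.name.upper() in WATER_RESIDUES:
                continue
            by_name: "OrderedDict[str, List[gemmi.Atom]]" = OrderedDict()
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = [
                Atom(
                    element=_pick_altloc(group).element.name,
                    position=np.array(_pick_altloc(group).pos.tolist()),
                )
                for group in by_name.values()
            ]
            if not any(a.is_heavy for a in atoms):
                continue
            icode = (residue.seqid.icode or "").strip()
            ligand_id = f"{residue.name}:{chain.name}:{residue.seqid.num}{icode}"
            ligands.append(
                Ligand(ligand_id=ligand_id, conformers=[Conformer(atoms=atoms, source_label="pdb_pose")])
            )
    return ligands


def read_protein_atoms(pdb_path, heavy_only: bool = True) -> List[Atom]:
    """All polymer (ATOM-record) atoms of the first model, for contact checks."""
    structure = gemmi.read_structure(str(pdb_path))
    atoms: List[Atom] = []
    if len(structure) == 0:
        return atoms
    for chain in structure[0]:
        for residue in chain:
            if residue.het_flag == "H":
                continue
            for atom in residue:
                a = Atom(element=atom.element.name, position=np.array(atom.pos.tolist()))
                if heavy_only and not a.is_heavy:
                    continue
                atoms.append(a)
    return atoms


# ---------------------------------------------------------------------------
# Match tables
# ---------------------------------------------------------------------------

_MATCH_COLUMNS = ["query_id", "db_id", "tanimoto", "best_conformer_index", "best_start_family"]


def write_match_table(matches, path) -> None:
    """Write shape matches as TSV, sorted by descending Tanimoto then ids.

    Tanimotos are printed with 6 decimals; the table round-trips losslessly
    through :func:`read_match_table` at that precision.
    """
    rows = [
        {
            "query_id": m.query_id,
            "db_id": m.db_id,
            "tanimoto": f"{m.tanimoto:.6f}",
            "best_conformer_index": m.best_conformer_index,
            "best_start_family": m.best_start_family,
        }
        for m in matches
    ]
    frame = pd.DataFrame(rows, columns=_MATCH_COLUMNS)
    frame = frame.sort_values(
        by=["tanimoto", "query_id", "db_id"], ascending=[False, True, True], kind="mergesort"
    )
    frame.to_csv(path, sep="\t", index=False)


def read_match_table(path) -> list:
    """Read a TSV match table back into :class:`~moadshape.shape_protocol.ShapeMatch`."""
    from .shape_protocol import ShapeMatch

    frame = pd.read_csv(path, sep="\t", dtype={"query_id": str, "db_id": str})
    return [
        ShapeMatch(
            query_id=row.query_id,
            db_id=row.db_id,
            tanimoto=float(row.tanimoto),
            best_conformer_index=int(row.best_conformer_index),
            best_start_family=str(row.best_start_family),
        )
        for row in frame.itertuples(index=False)
    ]
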