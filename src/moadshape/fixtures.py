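"""Deterministic synthetic data: toy ligands, affinity sets, toy complexes.

Everything here is a pure function of its arguments and a seed, so shape,
affinity and curation code can be exercised end-to-end without any
database download.  Toy geometries default to a single element so shape
quantities have closed-form sanity checks; generated PDB files are minimal
but standard-conformant (CRYST1 / ATOM / HETATM / END), so the real
parsers are exercised rather than bypassed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .affinity import AffinityRecord, BIN_LABELS, parse_affinity
from .curation import ComplexRecord, ValidityLabel, classify_ligand
from .mol_io import Atom, Conformer, Ligand
from .transforms import RigidTransform

__all__ = [
    "make_toy_ligand",
    "perturb_ligand",
    "AffinityPlan",
    "SyntheticAffinitySet",
    "make_synthetic_affinity_set",
    "ComplexSpec",
    "make_toy_complex",
]

_BOND = 1.5  # A, toy bond length


def _conformer_from_coords(coords: np.ndarray, element: str, label: str) -> Conformer:
    atoms = [Atom(element=element, position=xyz) for xyz in coords]
    return Conformer(atoms=atoms, source_label=label)


def make_toy_ligand(
    shape: str,
    n_atoms: int,
    element: str = "C",
    seed: int = 0,
    jitter: float = 0.0,
    ligand_id: Optional[str] = None,
) -> Ligand:
    """A single-conformer toy ligand with a deterministic geometry.

    ``linear``: chain along x at 1.5 A spacing; ``ring``: regular planar
    polygon with 1.5 A edges; ``tetrahedral``: central atom plus 4
    neighbors at 1.5 A (n_atoms must be 5).  ``jitter`` adds seeded
    Gaussian coordinate noise (default none).
    """
    if shape == "linear":
        if n_atoms < 1:
            raise ValueError("linear ligand needs n_atoms >= 1")
        coords = np.zeros((n_atoms, 3))
        coords[:, 0] = _BOND * np.arange(n_atoms)
    elif shape == "ring":
        if n_atoms < 3:
            raise ValueError("ring ligand needs n_atoms >= 3")
        radius = _BOND / (2.0 * math.sin(math.pi / n_atoms))
        angles = 2.0 * math.pi * np.arange(n_atoms) / n_atoms
        coords = np.stack([radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_atoms)], axis=1)
    elif shape == "tetrahedral":
        if n_atoms != 5:
            raise ValueError("tetrahedral ligand needs n_atoms == 5 (center + 4 neighbors)")
        directions = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3.0)
        coords = np.vstack([np.zeros(3), _BOND * directions])
    else:
        raise ValueError(f"unknown toy shape {shape!r}")
    if jitter:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    name = ligand_id or f"{shape}{n_atoms}"
    return Ligand(ligand_id=name, conformers=[_conformer_from_coords(coords, element, "generated_0")])


def perturb_ligand(
    ligand: Ligand,
    seed: int = 0,
    max_rotation: float = 180.0,
    max_translation: float = 5.0,
) -> Ligand:
    """A rigidly moved copy (known-answer superposition case).

    Applies one seeded proper rotation (angle uniform in [0, max_rotation]
    degrees about a uniform axis) and translation (componentwise uniform in
    [-max_translation, max_translation] A) to every conformer; the optimal
    shape Tanimoto against the original is 1 by construction.
    """
    rng = np.random.default_rng(seed)
    if max_rotation > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(0.0, max_rotation))
        rotation = Rotation.from_rotvec(angle * axis)
    else:
        rotation = Rotation.identity()
    translation = rng.uniform(-max_translation, max_translation, size=3) if max_translation > 0 else np.zeros(3)
    transform = RigidTransform.from_rotation(rotation, translation)
    conformers = [
        Conformer(
            atoms=[Atom(element=a.element, position=p) for a, p in
                   zip(conf.atoms, transform.apply(conf.coordinates()))],
            source_label=f"{conf.source_label}_perturbed",
        )
        for conf in ligand.conformers
    ]
    return Ligand(ligand_id=f"{ligand.ligand_id}_perturbed", conformers=conformers)


# ---------------------------------------------------------------------------
# Synthetic affinity sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityPlan:
    """Planted counts per discrepancy category and per affinity bin."""

    unit_equivalent_agreement: int = 0
    measurement_type_error: int = 0
    inequality_error: int = 0
    wrong_pair_error: int = 0
    value_error: int = 0
    bins: Dict[str, int] = field(default_factory=dict)  # label -> count


@dataclass
class SyntheticAffinitySet:
    """Paired record tables plus the planted ground truth."""

    left: List[AffinityRecord]
    right: List[AffinityRecord]
    pair_categories: List[str]
    bin_records: List[AffinityRecord]
    bin_labels: List[str]


_UNIT_SCALES = [("nM", 1e-9), ("uM", 1e-6), ("pM", 1e-12)]


def make_synthetic_affinity_set(plan: AffinityPlan, seed: int = 0) -> SyntheticAffinitySet:
    """Generate record pairs realizing exactly the planted category counts.

    Unit-equivalent pairs re-express one value in a different unit;
    error pairs differ in exactly the planted attribute.  ``plan.bins``
    additionally yields single records whose molar values fall in the
    requested distribution bins (log-uniform within each bin).
    """
    rng = np.random.default_rng(seed)
    left: List[AffinityRecord] = []
    right: List[AffinityRecord] = []
    categories: List[str] = []
    counter = 0

    def fresh_ids() -> Tuple[str, str]:
        nonlocal counter
        counter += 1
        return f"P{counter:04d}", f"L{counter:03d}"

    def random_nM() -> float:
        return float(10.0 ** rng.uniform(-1.0, 3.0))  # 0.1 nM .. 1 uM

    for _ in range(plan.unit_equivalent_agreement):
        pdb, lig = fresh_ids()
        v = random_nM()
        left.append(parse_affinity(f"{v!r} nM", "Kd", "=", pdb, lig))
        right.append(parse_affinity(f"{v / 1000.0!r} uM", "Kd", "=", pdb, lig))
        categories.append("unit_equivalent_agreement")
    for _ in range(plan.measurement_type_error):
        pdb, lig = fresh_ids()
        v = random_nM()
        left.append(parse_affinity(f"{v!r} nM", "Kd", "=", pdb, lig))
        right.append(parse_affinity(f"{v!r} nM", "Ki", "=", pdb, lig))
        categories.append("measurement_type_error")
    for _ in range(plan.inequality_error):
        pdb, lig = fresh_ids()
        v = random_nM()
        left.append(parse_affinity(f"{v!r} nM", "Kd", "=", pdb, lig))
        right.append(parse_affinity(f"{v!r} nM", "Kd", "~", pdb, lig))
        categories.append("inequality_error")
    for _ in range(plan.wrong_pair_error):
        pdb, lig = fresh_ids()
        v = random_nM()
        left.append(parse_affinity(f"{v!r} nM", "Kd", "=", pdb, lig))
        right.append(parse_affinity(f"{3.0 * v!r} nM", "Kd", "=", pdb, lig + "_alt"))
        categories.append("wrong_pair_error")
    for _ in range(plan.value_error):
        pdb, lig = fresh_ids()
        v = random_nM()
        left.append(parse_affinity(f"{v!r} nM", "Kd", "=", pdb, lig))
        right.append(parse_affinity(f"{2.0 * v!r} nM", "Kd", "=", pdb, lig))
        categories.append("value_error")

    bin_bounds = {
        BIN_LABELS[0]: (1e-12, 1e-9),
        BIN_LABELS[1]: (1e-9, 1e-6),
        BIN_LABELS[2]: (1e-6, 1e-3),
        BIN_LABELS[3]: (1e-3, 1.0),
    }
    bin_records: List[AffinityRecord] = []
    bin_labels: List[str] = []
    for label, count in plan.bins.items():
        lo, hi = bin_bounds[label]
        for _ in range(count):
            pdb, lig = fresh_ids()
            molar = float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi) - 1e-6))
            bin_records.append(parse_affinity(f"{molar!r} M", "Kd", "=", pdb, lig))
            bin_labels.append(label)
    return SyntheticAffinitySet(left, right, categories, bin_records, bin_labels)


# ---------------------------------------------------------------------------
# Toy complexes (+ PDB files)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for one toy complex."""

    pdb_id: str = "TOY1"
    resolution: float = 2.0
    r_work: float = 0.18
    r_free: float = 0.21
    rsr: float = 0.15
    rscc: float = 0.95
    ligand_codes: Tuple[str, ...] = ("LG1",)
    covalent: bool = False
    n_residues: int = 8
    sequence_letter: str = "A"


_PDB_ATOM = (
    "{record:<6}{serial:>5} {name:<4}{alt:1}{res:>3} {chain:1}{num:>4}{icode:1}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}\n"
)


def _format_atom(record, serial, name, res, chain, num, x, y, z, element):
    return _PDB_ATOM.format(
        record=record, serial=serial, name=f" {name}" if len(name) < 4 else name,
        alt=" ", res=res, chain=chain, num=num, icode=" ",
        x=x, y=y, z=z, occ=1.0, b=0.0, element=element,
    )


def make_toy_complex(spec: ComplexSpec, seed: int = 0) -> Tuple[ComplexRecord, str]:
    """One toy complex: metadata record plus a matching minimal PDB file text.

    The chain is poly-alanine backbone atoms along x; each HET ligand is a
    3-carbon chain placed either within covalent-bond distance of the
    chain (spec.covalent) or ~12 A away.  Validity labels come from
    :func:`~moadshape.curation.classify_ligand` with the shipped lists, so
    planted intentions are recovered by the real pipeline.
    """
    lines = ["CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1\n"]
    serial = 1
    backbone = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    offsets = {"N": (0.0, 1.0, 0.0), "CA": (0.5, 0.0, 0.0), "C": (1.0, 1.0, 0.0), "O": (1.0, 2.2, 0.0)}
    for i in range(spec.n_residues):
        x0 = 3.8 * i
        for name, element in backbone:
            dx, dy, dz = offsets[name]
            lines.append(_format_atom("ATOM", serial, name, "ALA", "A", i + 1,
                                      x0 + dx, dy, dz, element))
            serial += 1
    # ligands: offset in z; covalent ones land 1.3 A from the first CA
    for k, code in enumerate(spec.ligand_codes):
        if spec.covalent:
            base = np.array([0.5, 0.0, 1.3 + 4.0 * k])
        else:
            base = np.array([0.5, 12.0 + 4.0 * k, 0.0])
        for j in range(3):
            pos = base + np.array([_BOND * j, 0.0, 0.0])
            lines.append(_format_atom("HETATM", serial, f"C{j + 1}", code, "A", 100 + k,
                                      pos[0], pos[1], pos[2], "C"))
            serial += 1
    lines.append("END\n")
    pdb_text = "".join(lines)

    sequence = spec.sequence_letter * spec.n_residues
    ligands = [(code, classify_ligand(code, covalent=spec.covalent)) for code in spec.ligand_codes]
    record = ComplexRecord(
        pdb_id=spec.pdb_id,
        resolution=spec.resolution,
        r_work=spec.r_work,
        r_free=spec.r_free,
        rsr=spec.rsr,
        rscc=spec.rscc,
        chains=[("A", sequence)],
        ligands=ligands,
    )
    return record, pdb_text
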