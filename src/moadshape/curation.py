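"""Structure-inclusion pipeline: filters, ligand validity, families, leaders.

The rules mirror a curated protein–ligand database's intake pipeline:

1. structures at resolution worse than 2.5 A are discarded; a structure
   must keep at least one protein chain and at least one valid,
   non-covalently-bound ligand;
2. ligands are annotated ``valid`` / ``invalid`` / ``part_of_protein``
   from shipped (user-editable) HET-code lists — crystallographic
   additives, salts, buffers, metals and solvents are invalid, while HEME
   groups and modified amino acids belong to the protein;
3. the high-quality ("HiQ") subset additionally requires
   R_free - R_work <= 5%, real-space R <= 0.2 and RSCC >= 0.9 (all
   boundaries inclusive);
4. complexes are grouped into families by pairwise sequence identity
   (single-linkage at 90/70/50%), and each 90% family gets a leader —
   the member with the tightest preferred affinity, falling back to best
   resolution, then lexicographic id.

Sequence identity uses an in-repo end-gap-free global aligner (affine
gaps) rather than an external alignment binary; it is deterministic,
including its tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .affinity import AffinityRecord
from .mol_io import Atom, Ligand

__all__ = [
    "ValidityLabel",
    "ComplexRecord",
    "FamilyAssignment",
    "ExclusionLists",
    "DEFAULT_EXCLUSIONS",
    "COVALENT_RADII",
    "RESOLUTION_CUTOFF",
    "filter_complexes",
    "classify_ligand",
    "detect_covalent",
    "pairwise_identity",
    "build_families",
    "select_leader",
]

RESOLUTION_CUTOFF = 2.5  # Angstrom
HIQ_RFREE_RWORK_GAP = 0.05
HIQ_MAX_RSR = 0.2
HIQ_MIN_RSCC = 0.9

FAMILY_THRESHOLDS = (0.90, 0.70, 0.50)

#: Single-bond covalent radii (Angstrom) for contact-based covalency checks.
COVALENT_RADII = {
    "H": 0.37, "B": 0.82, "C": 0.77, "N": 0.75, "O": 0.73, "F": 0.71,
    "P": 1.06, "S": 1.02, "CL": 0.99, "SE": 1.16, "BR": 1.14, "I": 1.33,
    "NA": 1.54, "K": 1.96, "MG": 1.30, "CA": 1.74, "ZN": 1.25, "FE": 1.17,
    "MN": 1.39, "CU": 1.17, "NI": 1.15, "CO": 1.16, "CD": 1.48, "HG": 1.49,
}
_FALLBACK_COVALENT_RADIUS = 1.0  # generous default for elements not tabulated


@dataclass(frozen=True)
class ValidityLabel:
    label: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("valid", "invalid", "part_of_protein"):
            raise ValueError(f"unknown validity label {self.label!r}")


@dataclass
class ComplexRecord:
    """Curation-relevant metadata of one deposited complex."""

    pdb_id: str
    resolution: Optional[float] = None
    r_work: Optional[float] = None
    r_free: Optional[float] = None
    rsr: Optional[float] = None
    rscc: Optional[float] = None
    chains: List[Tuple[str, str]] = field(default_factory=list)
    ligands: List[Tuple[str, ValidityLabel]] = field(default_factory=list)
    affinity: Optional[AffinityRecord] = None

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"{self.pdb_id}: resolution must be positive")
        if self.rscc is not None and not (0.0 <= self.rscc <= 1.0):
            raise ValueError(f"{self.pdb_id}: RSCC must lie in [0, 1]")

    @property
    def valid_ligands(self) -> List[str]:
        return [code for code, label in self.ligands if label.label == "valid"]

    @property
    def longest_chain(self) -> str:
        if not self.chains:
            raise ValueError(f"{self.pdb_id}: no protein chains")
        return max(self.chains, key=lambda c: len(c[1]))[1]


@dataclass
class FamilyAssignment:
    family_id: int
    members: List[str]
    identity_threshold: float
    leader: Optional[str] = None


# ---------------------------------------------------------------------------
# Ligand validity and covalency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionLists:
    """HET-code lists driving validity annotation (user-overridable)."""

    invalid: frozenset = frozenset()
    part_of_protein: frozenset = frozenset()


DEFAULT_EXCLUSIONS = ExclusionLists(
    # crystallization additives, salts, buffers, solvents, metals, halides
    invalid=frozenset({
        "SO4", "PO4", "GOL", "EDO", "PEG", "PG4", "PGE", "MPD", "ACT", "ACY",
        "DMS", "TRS", "MES", "EPE", "BME", "FMT", "NO3", "IMD", "SCN", "AZI",
        "NA", "K", "LI", "CS", "MG", "CA", "SR", "BA", "ZN", "MN", "FE", "CU",
        "NI", "CO", "CD", "HG", "CL", "BR", "IOD", "F",
    }),
    # HEME groups and modified amino acids
    part_of_protein=frozenset({
        "HEM", "HEC", "HEA", "HEB", "MSE", "SEP", "TPO", "PTR", "CSO", "CSS",
        "CME", "MLY", "HYP", "PCA", "KCX", "LLP",
    }),
)


def classify_ligand(
    ligand_id: str,
    covalent: bool = False,
    lists: ExclusionLists = DEFAULT_EXCLUSIONS,
) -> ValidityLabel:
    """Annotate one HET code as valid / invalid / part_of_protein.

    Precedence: part-of-protein list, then covalent attachment, then the
    invalid (additive/salt/buffer/metal/solvent) list; anything unlisted
    and non-covalent is valid.
    """
    code = ligand_id.upper()
    if code in lists.part_of_protein:
        return ValidityLabel("part_of_protein", "listed as protein component")
    if covalent:
        return ValidityLabel("part_of_protein", "covalently bound")
    if code in lists.invalid:
        return ValidityLabel("invalid", "crystallographic additive/salt/buffer/metal/solvent")
    return ValidityLabel("valid", "biologically relevant by default")


def detect_covalent(
    ligand: Ligand,
    protein_atoms: Sequence[Atom],
    tolerance: float = 0.4,
) -> bool:
    """True iff any ligand heavy atom sits within covalent-bond distance
    (sum of covalent radii + tolerance) of any protein heavy atom."""
    if not protein_atoms:
        return False
    lig_atoms = [a for a in ligand.conformers[0].atoms if a.is_heavy]
    prot_atoms = [a for a in protein_atoms if a.is_heavy]
    if not lig_atoms or not prot_atoms:
        return False
    lig_xyz = np.array([a.position for a in lig_atoms])
    prot_xyz = np.array([a.position for a in prot_atoms])
    lig_r = np.array([COVALENT_RADII.get(a.element.upper(), _FALLBACK_COVALENT_RADIUS) for a in lig_atoms])
    prot_r = np.array([COVALENT_RADII.get(a.element.upper(), _FALLBACK_COVALENT_RADIUS) for a in prot_atoms])
    dist = cdist(lig_xyz, prot_xyz)
    limit = lig_r[:, None] + prot_r[None, :] + tolerance
    return bool(np.any(dist < limit))


# ---------------------------------------------------------------------------
# Structure filters
# ---------------------------------------------------------------------------

def _first_failure(record: ComplexRecord, mode: str) -> Optional[str]:
    if record.resolution is None:
        return "missing field: resolution"
    if record.resolution > RESOLUTION_CUTOFF:
        return f"resolution {record.resolution:.2f} A worse than {RESOLUTION_CUTOFF} A"
    if not record.chains:
        return "no protein chain"
    if not record.valid_ligands:
        return "no valid ligand"
    if mode == "hiq":
        for name in ("r_work", "r_free", "rsr", "rscc"):
            if getattr(record, name) is None:
                return f"missing field: {name}"
        # inclusive boundaries, guarded against float rounding of differences
        eps = 1e-9
        if record.r_free - record.r_work > HIQ_RFREE_RWORK_GAP + eps:
            return (
                f"R_free - R_work = {record.r_free - record.r_work:.3f} "
                f"exceeds {HIQ_RFREE_RWORK_GAP}"
            )
        if record.rsr > HIQ_MAX_RSR + eps:
            return f"RSR {record.rsr:.3f} exceeds {HIQ_MAX_RSR}"
        if record.rscc < HIQ_MIN_RSCC - eps:
            return f"RSCC {record.rscc:.3f} below {HIQ_MIN_RSCC}"
    return None


def filter_complexes(
    complexes: Sequence[ComplexRecord],
    mode: str = "standard",
) -> Tuple[List[ComplexRecord], List[Tuple[ComplexRecord, str]]]:
    """Partition complexes into (kept, discarded-with-first-failing-reason).

    ``standard`` applies the resolution cut (<= 2.5 A, inclusive), the
    protein-chain and valid-ligand requirements; ``hiq`` adds the
    refinement-quality cuts, all boundaries inclusive.
    """
    if mode not in ("standard", "hiq"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept: List[ComplexRecord] = []
    discarded: List[Tuple[ComplexRecord, str]] = []
    for record in complexes:
        reason = _first_failure(record, mode)
        if reason is None:
            kept.append(record)
        else:
            discarded.append((record, reason))
    return kept, discarded


# ---------------------------------------------------------------------------
# Sequence identity (end-gap-free global alignment, affine gaps)
# ---------------------------------------------------------------------------

_MATCH = 1.0
_MISMATCH = 0.0
_GAP_OPEN = -5.0
_GAP_EXTEND = -1.0
_NEG = float("-inf")


def _align_identity(a: str, b: str) -> float:
    """Identity fraction of the best end-gap-free alignment of a and b.

    Gotoh dynamic programming with affine gaps (first gap column -5, each
    further column -1); leading/trailing overhangs are free and excluded
    from the alignment length.  Tie-breaks prefer diagonal, then up (gap
    in b), then left.  'X' never counts as identical.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[_NEG] * (m + 1) for _ in range(n + 1)]
    ptr_h = [[0] * (m + 1) for _ in range(n + 1)]  # 1 diag, 2 up, 3 left
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]  # 1 open-from-H, 2 extend
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_h, row_x, row_y = H[i], Ix[i], Iy[i]
        prev_h, prev_x = H[i - 1], Ix[i - 1]
        for j in range(1, m + 1):
            open_x = prev_h[j] + _GAP_OPEN
            extend_x = prev_x[j] + _GAP_EXTEND
            if open_x >= extend_x:
                row_x[j], ptr_x[i][j] = open_x, 1
            else:
                row_x[j], ptr_x[i][j] = extend_x, 2
            open_y = row_h[j - 1] + _GAP_OPEN
            extend_y = row_y[j - 1] + _GAP_EXTEND
            if open_y >= extend_y:
                row_y[j], ptr_y[i][j] = open_y, 1
            else:
                row_y[j], ptr_y[i][j] = extend_y, 2
            diag = prev_h[j - 1] + (_MATCH if (ai == b[j - 1] and ai != "X") else _MISMATCH)
            best, which = diag, 1
            if row_x[j] > best:
                best, which = row_x[j], 2
            if row_y[j] > best:
                best, which = row_y[j], 3
            row_h[j], ptr_h[i][j] = best, which

    # endpoint: best score on the last row/column; (n, m) preferred on ties
    ei, ej, best = n, m, H[n][m]
    for j in range(m - 1, -1, -1):
        if H[n][j] > best:
            ei, ej, best = n, j, H[n][j]
    for i in range(n - 1, -1, -1):
        if H[i][m] > best:
            ei, ej, best = i, m, H[i][m]

    identical = 0
    columns = 0
    i, j, state = ei, ej, "H"
    while i > 0 and j > 0:
        if state == "H":
            which = ptr_h[i][j]
            if which == 1:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != "X":
                    identical += 1
                i -= 1
                j -= 1
            elif which == 2:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            columns += 1
            if ptr_x[i][j] == 1:
                state = "H"
            i -= 1
        else:
            columns += 1
            if ptr_y[i][j] == 1:
                state = "H"
            j -= 1
    return identical / columns if columns else 0.0


_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Sequence identity in [0, 1] under end-gap-free global alignment.

    Symmetric by construction (inputs are canonically ordered before the
    DP so tie-breaking cannot depend on argument order).
    """
    seq_a, seq_b = seq_a.upper().strip(), seq_b.upper().strip()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for seq in (seq_a, seq_b):
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    first, second = sorted((seq_a, seq_b))
    return _align_identity(first, second)


# ---------------------------------------------------------------------------
# Families and leaders
# ---------------------------------------------------------------------------

def build_families(
    complexes: Sequence[ComplexRecord],
    threshold: float,
) -> List[FamilyAssignment]:
    """Single-linkage families at one identity threshold (0.90, 0.70 or 0.50).

    Complexes are compared through their longest chain; families are the
    connected components of the graph with edges identity >= threshold,
    numbered by their lexicographically smallest member.  Leaders are
    assigned only at the 0.90 level.
    """
    if threshold not in FAMILY_THRESHOLDS:
        raise ValueError(f"threshold must be one of {FAMILY_THRESHOLDS}, got {threshold!r}")
    ids = [c.pdb_id for c in complexes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pdb_ids in complex list")
    parent = {pid: pid for pid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    seqs = {c.pdb_id: c.longest_chain for c in complexes}
    for i in range(len(complexes)):
        for j in range(i + 1, len(complexes)):
            a, b = ids[i], ids[j]
            if pairwise_identity(seqs[a], seqs[b]) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: Dict[str, List[str]] = {}
    for pid in ids:
        groups.setdefault(find(pid), []).append(pid)
    lookup = {c.pdb_id: c for c in complexes}
    families = []
    for fid, root in enumerate(sorted(groups, key=lambda r: min(groups[r])), start=1):
        members = sorted(groups[root])
        family = FamilyAssignment(family_id=fid, members=members, identity_threshold=threshold)
        if threshold == 0.90:
            family.leader = select_leader(family, lookup)
        families.append(family)
    return families


def select_leader(family: FamilyAssignment, complexes: Mapping[str, ComplexRecord]) -> str:
    """Leader of one family: tightest preferred affinity, then resolution, then id.

    Members without binding data rank after every member that has it; a
    missing resolution ranks after any measured one.
    """
    if not family.members:
        raise ValueError("family has no members")

    def key(pdb_id: str):
        record = complexes[pdb_id]
        molar = record.affinity.molar_value if record.affinity is not None else None
        return (
            0 if molar is not None else 1,
            molar if molar is not None else float("inf"),
            record.resolution if record.resolution is not None else float("inf"),
            pdb_id,
        )

    return min(family.members, key=key)
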