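"""Binding-affinity records: parsing, normalization, preference, binning.

A record is one measurement (Kd, Ka, Ki or IC50) with a relation symbol, a
positive value and a unit.  All values are normalized to a molar scale:
concentration units through the usual SI factors, and association
constants (Ka, in M^-1) stored as their reciprocal so that every
``molar_value`` is comparable on the dissociation scale.

The module also implements the database's selection and bookkeeping rules:

* preference Kd (including converted Ka) > Ki > IC50 when several
  measurements exist for one complex;
* the four-bin distribution (<1 nM, 1 nM-1 uM, 1 uM-1 mM, >1 mM);
* the cross-database discrepancy classifier, which first recognizes
  unit-equivalent agreements (same type/relation/ligand, values equal
  within 0.5% relative — absorbing rounding like 0.003 uM vs 3.0 nM) and
  otherwise assigns exactly one error category with fixed precedence
  measurement type > inequality > wrong pair > value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "MEASUREMENT_TYPES",
    "RELATIONS",
    "UNIT_FACTORS",
    "BIN_LABELS",
    "AffinityRecord",
    "DiscrepancyVerdict",
    "AffinityParseError",
    "parse_affinity",
    "format_affinity",
    "select_preferred",
    "bin_value",
    "bin_distribution",
    "classify_discrepancy",
    "read_affinity_table",
    "write_affinity_table",
    "compare_affinity_tables",
]

MEASUREMENT_TYPES = ("Kd", "Ka", "Ki", "IC50")

#: Canonical relation symbols (unicode <=/>= are normalized to ASCII).
RELATIONS = ("=", "~", "<", ">", "<=", ">=")

_RELATION_ALIASES = {"≤": "<=", "≥": ">=", "=<": "<=", "=>": ">="}

#: Molar factors for concentration units; Ka uses the reciprocal unit M^-1.
UNIT_FACTORS = {
    "fM": 1e-15,
    "pM": 1e-12,
    "nM": 1e-9,
    "uM": 1e-6,
    "mM": 1e-3,
    "M": 1.0,
}

_UNIT_ALIASES = {"μM": "uM", "µM": "uM"}
_KA_UNITS = {"M^-1", "M⁻¹", "M-1", "1/M", "/M"}

#: Ordered labels of the affinity-distribution bins.
BIN_LABELS = ("<1 nM", "1 nM-1 uM", "1 uM-1 mM", ">1 mM")

DISCREPANCY_CATEGORIES = (
    "unit_equivalent_agreement",
    "measurement_type_error",
    "inequality_error",
    "wrong_pair_error",
    "value_error",
)

#: Relative tolerance under which two molar values count as the same number.
AGREEMENT_RTOL = 0.005

# preference rank; Ka converts to the dissociation scale so it ranks with Kd
_TYPE_RANK = {"Kd": 0, "Ka": 0, "Ki": 1, "IC50": 2}


class AffinityParseError(ValueError):
    """A raw affinity field could not be interpreted."""


@dataclass(frozen=True)
class AffinityRecord:
    """One binding measurement, normalized to molar scale."""

    pdb_id: str
    ligand_id: str
    measurement_type: str
    relation: str
    value: float
    unit: str
    molar_value: float

    def __post_init__(self) -> None:
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise AffinityParseError(f"unknown measurement type {self.measurement_type!r}")
        if self.relation not in RELATIONS:
            raise AffinityParseError(f"unknown relation {self.relation!r}")
        if not self.value > 0:
            raise AffinityParseError(f"affinity value must be positive, got {self.value!r}")
        if self.measurement_type == "Ka":
            if self.unit != "M^-1":
                raise AffinityParseError("Ka records must carry the unit M^-1")
            expected = 1.0 / self.value
        else:
            if self.unit not in UNIT_FACTORS:
                raise AffinityParseError(f"unknown unit {self.unit!r}")
            expected = self.value * UNIT_FACTORS[self.unit]
        if abs(self.molar_value - expected) > 1e-12 * expected:
            raise AffinityParseError(
                f"molar_value {self.molar_value!r} inconsistent with {self.value!r} {self.unit}"
            )


def _normalize_unit(token: str) -> str:
    token = token.strip()
    if token in _KA_UNITS:
        return "M^-1"
    token = _UNIT_ALIASES.get(token, token)
    if token in UNIT_FACTORS:
        return token
    raise AffinityParseError(f"unknown unit {token!r}")


def _normalize_relation(token: str) -> str:
    token = _RELATION_ALIASES.get(token.strip(), token.strip())
    if token not in RELATIONS:
        raise AffinityParseError(f"unknown relation {token!r}")
    return token


def parse_affinity(
    text: str,
    measurement_type: str,
    relation: str = "=",
    pdb_id: str = "",
    ligand_id: str = "",
) -> AffinityRecord:
    """Parse a raw field like ``"3.0 nM"`` into a normalized record.

    ``measurement_type`` and ``relation`` come from their own columns in
    the delimited inputs.  For Ka the unit must be M^-1 and the molar value
    is the reciprocal (the equivalent Kd).
    """
    parts = text.split()
    if len(parts) != 2:
        raise AffinityParseError(f"expected 'value unit', got {text!r}")
    try:
        value = float(parts[0])
    except ValueError as exc:
        raise AffinityParseError(f"bad numeric value in {text!r}") from exc
    if not value > 0:
        raise AffinityParseError(f"affinity value must be positive, got {text!r}")
    unit = _normalize_unit(parts[1])
    if measurement_type == "Ka":
        molar = 1.0 / value
    else:
        molar = value * UNIT_FACTORS[unit]
    return AffinityRecord(
        pdb_id=pdb_id,
        ligand_id=ligand_id,
        measurement_type=measurement_type,
        relation=_normalize_relation(relation),
        value=value,
        unit=unit,
        molar_value=molar,
    )


def format_affinity(record: AffinityRecord) -> str:
    """Inverse of :func:`parse_affinity`'s value field: ``"3.0 nM"``.

    Uses the shortest round-tripping float representation, so
    re-parsing preserves ``molar_value`` exactly.
    """
    return f"{record.value!r} {record.unit}"


def select_preferred(records: Sequence[AffinityRecord]) -> Optional[AffinityRecord]:
    """Pick one record by the preference Kd (incl. Ka) > Ki > IC50.

    Within the winning type, exact ('=') relations beat inequalities and
    approximations, then the tightest (smallest molar) value wins.
    Returns None for empty input.
    """
    if not records:
        return None
    return min(
        records,
        key=lambda r: (
            _TYPE_RANK[r.measurement_type],
            0 if r.relation == "=" else 1,
            r.molar_value,
            r.pdb_id,
            r.ligand_id,
        ),
    )


def bin_value(molar_value: float) -> str:
    """Bin label for one molar value.

    Boundaries: [0, 1 nM), [1 nM, 1 uM), [1 uM, 1 mM], (1 mM, inf) —
    left-closed at 1 nM and 1 uM, with exactly 1 mM in the third bin.
    """
    if molar_value < 1e-9:
        return BIN_LABELS[0]
    if molar_value < 1e-6:
        return BIN_LABELS[1]
    if molar_value <= 1e-3:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def bin_distribution(records: Sequence[AffinityRecord], measurement_type: str) -> Dict[str, int]:
    """Counts of records per affinity bin for one measurement type.

    Requesting ``Kd`` also admits Ka records (stored on the Kd scale, as in
    the distribution table's "Kd (or Ka^-1)" row); any other type mixture
    is an error.  The counts always partition the input.
    """
    allowed = {measurement_type} | ({"Ka"} if measurement_type == "Kd" else set())
    counts = {label: 0 for label in BIN_LABELS}
    for record in records:
        if record.measurement_type not in allowed:
            raise ValueError(
                f"record of type {record.measurement_type!r} in a {measurement_type!r} distribution"
            )
        counts[bin_value(record.molar_value)] += 1
    return counts


@dataclass(frozen=True)
class DiscrepancyVerdict:
    """Exactly one category for a cross-database record pair."""

    category: str
    details: str = ""

    def __post_init__(self) -> None:
        if self.category not in DISCREPANCY_CATEGORIES:
            raise ValueError(f"unknown discrepancy category {self.category!r}")


def _values_agree(a: AffinityRecord, b: AffinityRecord, rtol: float = AGREEMENT_RTOL) -> bool:
    return abs(a.molar_value - b.molar_value) <= rtol * max(a.molar_value, b.molar_value)


def classify_discrepancy(a: AffinityRecord, b: AffinityRecord) -> DiscrepancyVerdict:
    """Assign one category to a pair of records for the same PDB entry.

    Precedence: unit-equivalent agreement (same type, relation and ligand,
    molar values within 0.5% relative), then measurement-type error, then
    inequality error, then wrong-pair error, else value error.
    """
    if a.pdb_id != b.pdb_id:
        raise ValueError(f"records reference different entries: {a.pdb_id!r} vs {b.pdb_id!r}")
    if (
        a.measurement_type == b.measurement_type
        and a.relation == b.relation
        and a.ligand_id == b.ligand_id
        and _values_agree(a, b)
    ):
        return DiscrepancyVerdict(
            "unit_equivalent_agreement",
            f"{format_affinity(a)} == {format_affinity(b)}",
        )
    if a.measurement_type != b.measurement_type:
        return DiscrepancyVerdict(
            "measurement_type_error", f"{a.measurement_type} vs {b.measurement_type}"
        )
    if a.relation != b.relation:
        return DiscrepancyVerdict("inequality_error", f"{a.relation!r} vs {b.relation!r}")
    if a.ligand_id != b.ligand_id:
        return DiscrepancyVerdict("wrong_pair_error", f"{a.ligand_id!r} vs {b.ligand_id!r}")
    return DiscrepancyVerdict("value_error", f"{format_affinity(a)} vs {format_affinity(b)}")


# ---------------------------------------------------------------------------
# Delimited-text interface
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["pdb_id", "ligand_id", "type", "relation", "value", "unit"]


def read_affinity_table(path) -> List[AffinityRecord]:
    """Read records from TSV with columns pdb_id, ligand_id, type, relation, value, unit."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise AffinityParseError(f"{path}: missing columns {missing}")
    return [
        parse_affinity(
            f"{row.value} {row.unit}",
            measurement_type=row.type,
            relation=row.relation,
            pdb_id=row.pdb_id,
            ligand_id=row.ligand_id,
        )
        for row in frame.itertuples(index=False)
    ]


def write_affinity_table(records: Iterable[AffinityRecord], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "pdb_id": r.pdb_id,
                "ligand_id": r.ligand_id,
                "type": r.measurement_type,
                "relation": r.relation,
                "value": repr(r.value),
                "unit": r.unit,
            }
            for r in records
        ],
        columns=_TABLE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def compare_affinity_tables(
    left: Sequence[AffinityRecord], right: Sequence[AffinityRecord]
) -> List[Tuple[AffinityRecord, AffinityRecord, DiscrepancyVerdict]]:
    """Classify every pair of records sharing a pdb_id across two tables.

    Records are paired positionally within each pdb_id group (the i-th left
    record with the i-th right record), which matches the one-row-per-entry
    layout of curated exports.
    """
    by_id: Dict[str, List[AffinityRecord]] = {}
    for record in right:
        by_id.setdefault(record.pdb_id, []).append(record)
    out = []
    seen: Dict[str, int] = {}
    for record in left:
        pool = by_id.get(record.pdb_id, [])
        index = seen.get(record.pdb_id, 0)
        if index >= len(pool):
            continue
        other = pool[index]
        seen[record.pdb_id] = index + 1
        out.append((record, other, classify_discrepancy(record, other)))
    return out
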