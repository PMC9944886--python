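"""The ligand-matching protocol: max over start families, max over conformers.

For one query pose against one database conformer, the final Tanimoto is
the maximum over the optimizer runs from every start pose (center-of-mass
start, 8 seeded random placements, 4 principal-axes starts).  Against a
conformer ensemble it is additionally the maximum over the (at most 64)
database conformers; conformers stay rigid throughout.  Ligand-level
values are symmetrized: max of (A pose vs B ensemble) and (B pose vs A
ensemble), where a ligand's pose is its first conformer (the experimental
pose in PDB-derived inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .gaussian_shape import build_shape
from .mol_io import Conformer, Ligand
from .superpose import (
    ConvergenceSettings,
    SuperpositionResult,
    com_align,
    generate_starts,
    optimize_overlap,
)

__all__ = ["ShapeMatch", "ProtocolSettings", "pair_tanimoto", "ensemble_tanimoto", "match_ligands"]

DEFAULT_MAX_CONFORMERS = 64


@dataclass
class ShapeMatch:
    """Best shape Tanimoto for a ligand pair, with provenance."""

    query_id: str
    db_id: str
    tanimoto: float
    best_conformer_index: int
    best_start_family: str
    direction: str = "query_vs_db"


@dataclass(frozen=True)
class ProtocolSettings:
    """Knobs of the matching protocol (defaults mirror the study conditions)."""

    n_random_starts: int = 8
    seed: int = 0
    max_conformers: int = DEFAULT_MAX_CONFORMERS
    include_hydrogens: bool = False
    radii: Optional[Mapping[str, float]] = None
    convergence: ConvergenceSettings = field(default_factory=ConvergenceSettings)


def _shape(conformer: Conformer, settings: ProtocolSettings):
    return build_shape(conformer, radii=settings.radii, include_hydrogens=settings.include_hydrogens)


def pair_tanimoto(
    query_pose: Conformer,
    db_conformer: Conformer,
    settings: Optional[ProtocolSettings] = None,
) -> SuperpositionResult:
    """Best superposition of one query pose onto one database conformer.

    Runs the local optimizer from the COM start, the seeded random starts
    and the 4 inertial starts; returns the run with the maximal Tanimoto,
    labeled with its start family.
    """
    s = settings or ProtocolSettings()
    query = _shape(query_pose, s)
    reference = _shape(db_conformer, s)

    runs = [("com", 0, com_align(query, reference))]
    for i, start in enumerate(
        generate_starts(query, reference, "random", n=s.n_random_starts, seed=s.seed)
    ):
        runs.append(("random", i, start))
    for i, start in enumerate(generate_starts(query, reference, "inertial")):
        runs.append(("inertial", i, start))

    best: Optional[SuperpositionResult] = None
    for family, index, start in runs:
        result = optimize_overlap(
            query, reference, start, settings=s.convergence, start_family=family, start_index=index
        )
        if best is None or result.tanimoto > best.tanimoto:
            best = result
    assert best is not None
    return best


def ensemble_tanimoto(
    query_pose: Conformer,
    db_ligand: Ligand,
    settings: Optional[ProtocolSettings] = None,
    query_id: str = "query",
    direction: str = "query_vs_db",
) -> ShapeMatch:
    """Max of :func:`pair_tanimoto` over the database ligand's conformers.

    The ensemble is truncated to ``max_conformers`` in input order; the
    returned match records the argmax conformer index and start family.
    """
    s = settings or ProtocolSettings()
    conformers = db_ligand.conformers[: s.max_conformers]
    if not conformers:
        raise ValueError(f"ligand {db_ligand.ligand_id!r} has an empty conformer ensemble")
    best_result: Optional[SuperpositionResult] = None
    best_index = -1
    for index, conformer in enumerate(conformers):
        result = pair_tanimoto(query_pose, conformer, s)
        if best_result is None or result.tanimoto > best_result.tanimoto:
            best_result, best_index = result, index
    assert best_result is not None
    return ShapeMatch(
        query_id=query_id,
        db_id=db_ligand.ligand_id,
        tanimoto=best_result.tanimoto,
        best_conformer_index=best_index,
        best_start_family=best_result.start_family,
        direction=direction,
    )


def match_ligands(
    ligand_a: Ligand,
    ligand_b: Ligand,
    settings: Optional[ProtocolSettings] = None,
) -> ShapeMatch:
    """Symmetrized ligand-pair match: max over both pose-vs-ensemble directions."""
    s = settings or ProtocolSettings()
    forward = ensemble_tanimoto(
        ligand_a.conformers[0], ligand_b, s, query_id=ligand_a.ligand_id, direction="a_vs_b"
    )
    backward = ensemble_tanimoto(
        ligand_b.conformers[0], ligand_a, s, query_id=ligand_b.ligand_id, direction="b_vs_a"
    )
    best = forward if forward.tanimoto >= backward.tanimoto else backward
    # canonical orientation: query/db follow the call order regardless of direction
    return ShapeMatch(
        query_id=ligand_a.ligand_id,
        db_id=ligand_b.ligand_id,
        tanimoto=best.tanimoto,
        best_conformer_index=best.best_conformer_index,
        best_start_family=best.best_start_family,
        direction=best.direction,
    )
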