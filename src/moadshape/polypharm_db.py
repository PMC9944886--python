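"""All-vs-all ensemble shape matching over a ligand set.

Every unordered ligand pair is scored once with the symmetrized ensemble
protocol; pairs are reported only when their Tanimoto strictly exceeds
the threshold (default 0.85, the database's reporting cutoff), sorted by
descending Tanimoto.  Pairs are independent work units, so the loop can
be parallelized as long as the sorted output stays identical.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Optional, Sequence

from .mol_io import Ligand
from .shape_protocol import ProtocolSettings, ShapeMatch, match_ligands

__all__ = ["DEFAULT_THRESHOLD", "all_vs_all_match"]

DEFAULT_THRESHOLD = 0.85


def all_vs_all_match(
    ligands: Sequence[Ligand],
    threshold: float = DEFAULT_THRESHOLD,
    settings: Optional[ProtocolSettings] = None,
) -> List[ShapeMatch]:
    """Score every unordered pair once; keep matches with Tanimoto > threshold."""
    if len(ligands) < 2:
        raise ValueError("all-vs-all matching needs at least two ligands")
    ids = [lig.ligand_id for lig in ligands]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ligand ids: {dupes}")
    matches: List[ShapeMatch] = []
    for a, b in combinations(ligands, 2):
        match = match_ligands(a, b, settings)
        if match.tanimoto > threshold:
            matches.append(match)
    matches.sort(key=lambda m: (-m.tanimoto, m.query_id, m.db_id))
    return matches
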