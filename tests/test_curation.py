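"""Structure filters, ligand validity, covalency, identity and families."""

from functools import lru_cache

import numpy as np
import pytest

from moadshape.affinity import parse_affinity
from moadshape.curation import (
    ComplexRecord,
    ValidityLabel,
    build_families,
    classify_ligand,
    detect_covalent,
    filter_complexes,
    pairwise_identity,
    select_leader,
)
from moadshape.fixtures import ComplexSpec, make_toy_complex
from moadshape.mol_io import Atom, Conformer, Ligand


def make_record(pdb_id="1ABC", resolution=2.0, r_work=0.18, r_free=0.21, rsr=0.15,
                rscc=0.95, ligand_label="valid", chains=(("A", "ACDEFGHIKL"),), affinity=None):
    return ComplexRecord(
        pdb_id=pdb_id, resolution=resolution, r_work=r_work, r_free=r_free,
        rsr=rsr, rscc=rscc, chains=list(chains),
        ligands=[("LG1", ValidityLabel(ligand_label))], affinity=affinity,
    )


class TestFilters:
    def test_resolution_boundary_inclusive(self):
        kept, discarded = filter_complexes(
            [make_record("GOOD", resolution=2.5), make_record("BAD", resolution=2.6)]
        )
        assert [r.pdb_id for r in kept] == ["GOOD"]
        assert discarded[0][0].pdb_id == "BAD" and "resolution" in discarded[0][1]

    def test_requires_valid_ligand_and_chain(self):
        no_ligand = make_record("NOLG", ligand_label="invalid")
        no_chain = make_record("NOCH", chains=())
        kept, discarded = filter_complexes([no_ligand, no_chain])
        assert kept == []
        reasons = {r.pdb_id: reason for r, reason in discarded}
        assert "ligand" in reasons["NOLG"] and "chain" in reasons["NOCH"]

    def test_hiq_rfree_rwork_gap_boundary(self):
        ok = make_record("OK05", r_work=0.18, r_free=0.23)       # gap exactly 0.05
        bad = make_record("BAD6", r_work=0.18, r_free=0.24)      # gap 0.06
        kept, discarded = filter_complexes([ok, bad], mode="hiq")
        assert [r.pdb_id for r in kept] == ["OK05"]
        assert "R_free - R_work" in discarded[0][1]

    def test_hiq_rscc_boundary_inclusive(self):
        kept, _ = filter_complexes([make_record(rscc=0.90)], mode="hiq")
        assert len(kept) == 1
        _, discarded = filter_complexes([make_record(rscc=0.89)], mode="hiq")
        assert "RSCC" in discarded[0][1]

    def test_hiq_rsr_boundary_inclusive(self):
        kept, _ = filter_complexes([make_record(rsr=0.20)], mode="hiq")
        assert len(kept) == 1
        _, discarded = filter_complexes([make_record(rsr=0.21)], mode="hiq")
        assert "RSR" in discarded[0][1]

    def test_missing_field_reported_and_discarded(self):
        record = make_record("MISS")
        record.rscc = None
        kept, discarded = filter_complexes([record], mode="hiq")
        assert kept == [] and "missing field" in discarded[0][1]

    def test_partition_property(self):
        records = [make_record(f"R{i:03d}", resolution=1.5 + 0.2 * i) for i in range(10)]
        kept, discarded = filter_complexes(records)
        assert len(kept) + len(discarded) == len(records)
        assert {r.pdb_id for r in kept}.isdisjoint({r.pdb_id for r, _ in discarded})


class TestValidity:
    @pytest.mark.parametrize(
        "code,label",
        [("SO4", "invalid"), ("GOL", "invalid"), ("NA", "invalid"),
         ("HEM", "part_of_protein"), ("MSE", "part_of_protein"), ("ATP", "valid")],
    )
    def test_list_driven_labels(self, code, label):
        assert classify_ligand(code).label == label

    def test_covalent_forces_protein_like_exclusion(self):
        verdict = classify_ligand("ATP", covalent=True)
        assert verdict.label == "part_of_protein"
        assert verdict.reason == "covalently bound"


class TestCovalency:
    def carbon_ligand(self, position):
        return Ligand("LG1", [Conformer([Atom("C", np.asarray(position, dtype=float))])])

    def test_contact_within_covalent_distance(self):
        # C-C covalent limit: 0.77 + 0.77 + 0.4 = 1.94 A > 1.4 A
        protein = [Atom("C", np.zeros(3))]
        assert detect_covalent(self.carbon_ligand([1.4, 0.0, 0.0]), protein) is True

    def test_remote_contact_is_not_covalent(self):
        protein = [Atom("C", np.zeros(3))]
        assert detect_covalent(self.carbon_ligand([4.0, 0.0, 0.0]), protein) is False

    def test_empty_protein_is_false(self):
        assert detect_covalent(self.carbon_ligand([0.0, 0.0, 0.0]), []) is False

    def test_planted_toy_complexes_recovered(self, tmp_path):
        from moadshape.mol_io import extract_het_ligands, read_protein_atoms

        for covalent in (False, True):
            spec = ComplexSpec(pdb_id="TOYC" if covalent else "TOYF", covalent=covalent)
            _, text = make_toy_complex(spec)
            path = tmp_path / f"{spec.pdb_id}.pdb"
            path.write_text(text)
            ligand = extract_het_ligands(path)[0]
            assert detect_covalent(ligand, read_protein_atoms(path)) is covalent


# ---------------------------------------------------------------------------
# Sequence identity vs an independent oracle
# ---------------------------------------------------------------------------

GAP_OPEN, GAP_EXTEND = -5.0, -1.0


def oracle_identities(a: str, b: str):
    """All identity fractions achievable by score-optimal end-gap-free
    alignments, via an independent backward memoized recursion."""
    n, m = len(a), len(b)

    def score(x, y):
        return 1.0 if x == y and x != "X" else 0.0

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == n or j == m:
            return 0.0  # free trailing overhang
        out = score(a[i], b[j]) + best(i + 1, j + 1, "M")
        out = max(out, (GAP_EXTEND if state == "X" else GAP_OPEN) + best(i + 1, j, "X"))
        out = max(out, (GAP_EXTEND if state == "Y" else GAP_OPEN) + best(i, j + 1, "Y"))
        return out

    starts = [(i, 0) for i in range(n + 1)] + [(0, j) for j in range(1, m + 1)]
    top = max(best(i, j, "M") for i, j in starts)

    identities = set()

    def walk(i, j, state, ident, cols):
        if i == n or j == m:
            if cols:
                identities.add(ident / cols)
            return
        here = best(i, j, state)
        s = score(a[i], b[j])
        if s + best(i + 1, j + 1, "M") == here:
            walk(i + 1, j + 1, "M", ident + (1 if s else 0), cols + 1)
        if (GAP_EXTEND if state == "X" else GAP_OPEN) + best(i + 1, j, "X") == here:
            walk(i + 1, j, "X", ident, cols + 1)
        if (GAP_EXTEND if state == "Y" else GAP_OPEN) + best(i, j + 1, "Y") == here:
            walk(i, j + 1, "Y", ident, cols + 1)

    for i, j in starts:
        if best(i, j, "M") == top:
            walk(i, j, "M", 0, 0)
    return top, identities


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0

    def test_totally_different_sequences(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_x_never_counts_as_match(self):
        assert pairwise_identity("AXA", "AXA") == pytest.approx(2.0 / 3.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    def test_symmetry(self):
        a, b = "ACDEFGHIKLMN", "ACDEFGAIKL"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACDEFGHIKL", "ACDEFGAIKL"),   # single substitution, 10-mers
            ("ACDEFGHIKL", "ACDEFHIKL"),    # single deletion
            ("ACDEFGHIKLMN", "DEFGHIKL"),   # containment, 12-mer vs 8-mer
            ("WYWYWY", "YWYWYW"),           # frame-shifted repeat
            ("ACDE", "ACDEFGHIKLMN"),       # prefix overhang
        ],
    )
    def test_matches_independent_dp_oracle(self, a, b):
        _, identities = oracle_identities(a, b)
        assert pairwise_identity(a, b) in identities

    @pytest.mark.parametrize("seed", range(4))
    def test_optimal_score_agrees_with_reference_aligner(self, seed):
        """The oracle's score model is itself checked against Biopython's
        global aligner with free end gaps."""
        from Bio.Align import PairwiseAligner

        rng = np.random.default_rng(seed)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(letters), size=10))
        b = "".join(rng.choice(list(letters), size=12))
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = GAP_OPEN
        aligner.extend_gap_score = GAP_EXTEND
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
        top, _ = oracle_identities(a, b)
        assert top == pytest.approx(aligner.score(a, b))


class TestFamilies:
    def seqs(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 2  # 40-mer
        near = base[:-2] + "AA"            # 95% identical
        mid = base[:20] + "W" * 20         # ~50%
        far = "W" * 40
        return base, near, mid, far

    def complexes(self):
        base, near, mid, far = self.seqs()
        return [
            make_record("1AAA", chains=[("A", base)],
                        affinity=parse_affinity("10 nM", "Kd", "=", "1AAA", "LG1")),
            make_record("1BBB", chains=[("A", near)],
                        affinity=parse_affinity("1 nM", "Kd", "=", "1BBB", "LG1")),
            make_record("1CCC", chains=[("A", mid)]),
            make_record("1DDD", chains=[("A", far)]),
        ]

    def test_single_linkage_closure(self):
        """Identities (A,B) and (B,C) above threshold link A-C transitively."""
        base = "ACDEFGHIKLMNPQRSTVWY" * 2
        a = make_record("1AAA", chains=[("A", base)])
        b = make_record("1BBB", chains=[("A", base[:-3] + "AAA")])   # ~92% to base
        c = make_record("1CCC", chains=[("A", base[:-6] + "AAAAAA")])  # ~92% to b, 85% to a
        assert pairwise_identity(base, b.longest_chain) >= 0.90
        assert pairwise_identity(b.longest_chain, c.longest_chain) >= 0.90
        assert pairwise_identity(base, c.longest_chain) < 0.90
        families = build_families([a, b, c], 0.90)
        assert len(families) == 1
        assert families[0].members == ["1AAA", "1BBB", "1CCC"]

    def test_all_dissimilar_gives_singletons(self):
        records = self.complexes()
        families = build_families([records[0], records[3]], 0.90)
        assert [f.members for f in families] == [["1AAA"], ["1DDD"]]

    def test_families_partition_the_set(self):
        records = self.complexes()
        for threshold in (0.90, 0.70, 0.50):
            families = build_families(records, threshold)
            members = [m for f in families for m in f.members]
            assert sorted(members) == sorted(r.pdb_id for r in records)

    def test_lower_threshold_coarsens(self):
        records = self.complexes()
        fine = {frozenset(f.members) for f in build_families(records, 0.90)}
        coarse = {frozenset(f.members) for f in build_families(records, 0.50)}
        for family in fine:
            assert any(family <= big for big in coarse)

    def test_leaders_only_at_ninety_percent(self):
        records = self.complexes()
        assert all(f.leader is not None for f in build_families(records, 0.90))
        assert all(f.leader is None for f in build_families(records, 0.70))


class TestLeaderSelection:
    def test_tightest_affinity_wins(self):
        a = make_record("1AAA", affinity=parse_affinity("10 nM", "Kd", "=", "1AAA", "LG1"))
        b = make_record("1BBB", affinity=parse_affinity("1 nM", "Kd", "=", "1BBB", "LG1"))
        families = build_families([a, b], 0.90)
        assert families[0].leader == "1BBB"

    def test_no_affinity_falls_back_to_resolution(self):
        a = make_record("1AAA", resolution=2.4)
        b = make_record("1BBB", resolution=1.6)
        families = build_families([a, b], 0.90)
        assert families[0].leader == "1BBB"

    def test_full_tie_breaks_lexicographically(self):
        a = make_record("1ZZZ")
        b = make_record("1AAA")
        families = build_families([a, b], 0.90)
        assert families[0].leader == "1AAA"

    def test_member_with_affinity_beats_better_resolution_without(self):
        with_aff = make_record("1AFF", resolution=2.4,
                               affinity=parse_affinity("1 uM", "Kd", "=", "1AFF", "LG1"))
        without = make_record("1RES", resolution=1.2)
        lookup = {r.pdb_id: r for r in (with_aff, without)}
        family = build_families([with_aff, without], 0.90)[0]
        assert select_leader(family, lookup) == "1AFF"
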