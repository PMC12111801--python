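"""Contacts, consensus numbering, alignment and fingerprint statistics."""

import itertools

import numpy as np
import pytest

from metafunnel import fingerprint as fp
from metafunnel.fingerprint import ResidueContact


def make_contact(lig, rec, num, name="LEU", cats=("any",)):
    return ResidueContact(lig, rec, num, name, frozenset(cats))


class TestCategorizeResidue:
    def test_examples(self):
        assert fp.categorize_residue("LEU") == {"hydrophobic"}
        assert fp.categorize_residue("ARG") == {"polar", "charged"}
        assert fp.categorize_residue("PHE") == {"hydrophobic", "aromatic"}

    def test_protonation_variants(self):
        assert "polar" in fp.categorize_residue("HIE")
        assert "charged" in fp.categorize_residue("HIP")
        assert fp.categorize_residue("CYX") == {"hydrophobic"}

    def test_unknown_errors(self):
        with pytest.raises(fp.UnknownResidueError):
            fp.categorize_residue("XYZ")


def toy_structure():
    """Minimal complex: LEU 10 / SER 11 receptor residues + LIG carbon."""
    import biotite.structure as struc

    atoms = []

    def atom(res_id, res_name, name, element, coord, hetero=False, chain="A"):
        a = struc.Atom(coord, chain_id=chain, res_id=res_id, res_name=res_name,
                       atom_name=name, element=element, hetero=hetero)
        atoms.append(a)

    atom(10, "LEU", "N", "N", [0.0, 0.0, 0.0])
    atom(10, "LEU", "CA", "C", [1.5, 0.0, 0.0])
    atom(10, "LEU", "C", "C", [2.2, 1.3, 0.0])
    atom(10, "LEU", "O", "O", [3.4, 1.4, 0.0])
    atom(10, "LEU", "CB", "C", [2.0, -1.0, 1.0])
    atom(11, "SER", "N", "N", [10.0, 0.0, 0.0])
    atom(11, "SER", "CA", "C", [11.5, 0.0, 0.0])
    atom(11, "SER", "C", "C", [12.0, 1.0, 0.0])
    atom(11, "SER", "O", "O", [13.2, 1.2, 0.0])
    atom(11, "SER", "OG", "O", [11.8, -1.4, 0.9])
    atom(99, "LIG", "C1", "C", [2.0, -1.0, 4.0], hetero=True, chain="L")
    atom(99, "LIG", "O1", "O", [11.8, -1.4, 4.0], hetero=True, chain="L")
    return struc.array(atoms)


class TestContactsFromComplex:
    def test_sidechain_hydrophobic_contact(self):
        s = toy_structure()
        contacts = fp.contacts_from_complex(s, "LIG", cutoff=4.0)
        leu = [c for c in contacts if c.residue_name == "LEU"]
        assert len(leu) == 1
        assert {"sidechain", "hydrophobic", "any"} <= set(leu[0].categories)

    def test_cutoff_excludes_distant(self):
        s = toy_structure()
        contacts = fp.contacts_from_complex(s, "LIG", cutoff=2.5)
        assert not any(c.residue_name == "LEU" for c in contacts)

    def test_boundary_distance_included(self):
        s = toy_structure()
        # LEU CB at (2,-1,1) vs ligand C1 at (2,-1,4): distance exactly 3.0
        contacts = fp.contacts_from_complex(s, "LIG", cutoff=3.0)
        assert any(c.residue_name == "LEU" for c in contacts)

    def test_hbond_flag_from_polar_pair(self):
        s = toy_structure()
        contacts = fp.contacts_from_complex(s, "LIG", cutoff=4.0)
        ser = [c for c in contacts if c.residue_name == "SER"]
        assert ser and "hbond_donor" in ser[0].categories

    def test_ligand_not_found(self):
        with pytest.raises(ValueError, match="not found"):
            fp.contacts_from_complex(toy_structure(), "NOPE")

    def test_rigid_motion_invariance(self):
        import biotite.structure as struc

        s = toy_structure()
        base = {(c.author_resnum, c.categories) for c in
                fp.contacts_from_complex(s, "LIG", cutoff=4.0)}
        rng = np.random.default_rng(0)
        # random rotation (QR of a random matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = s.copy()
        moved.coord = s.coord @ q.T + np.array([5.0, -3.0, 2.0])
        after = {(c.author_resnum, c.categories) for c in
                 fp.contacts_from_complex(moved, "LIG", cutoff=4.0)}
        assert base == after


def brute_force_global_score(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal global alignment score by exhaustive enumeration of all
    monotone alignments (including affine gap runs)."""
    best = float("-inf")

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, score + cost, "X")
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, score + cost, "Y")

    rec(0, 0, 0.0, "")
    return best


class TestPairwiseAlign:
    def test_identical_sequences(self):
        a, b, score = fp.pairwise_align("ACDEF", "ACDEF")
        assert a == b == "ACDEF" and score == 5.0

    def test_single_gap(self):
        a, b, score = fp.pairwise_align("ACDE", "ACE")
        assert score == 2.0
        assert b.count("-") == 1 and a == "ACDE"

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            fp.pairwise_align("AC1E", "ACE")

    def test_matches_bruteforce_on_short_sequences(self):
        rng = np.random.default_rng(5)
        alpha = "ACDE"
        for _ in range(30):
            la, lb = rng.integers(1, 7), rng.integers(1, 7)
            a = "".join(rng.choice(list(alpha), la))
            b = "".join(rng.choice(list(alpha), lb))
            _, _, score = fp.pairwise_align(a, b, gap_open=-2.0, gap_extend=-0.5)
            want = brute_force_global_score(a, b, 1.0, -1.0, -2.0, -0.5)
            assert score == pytest.approx(want), (a, b)

    def test_matches_biopython_optimal_score(self):
        Align = pytest.importorskip("Bio.Align")
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1.0, -1.0
        aligner.open_gap_score, aligner.extend_gap_score = -2.0, -0.5
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join(rng.choice(list("ACDEFGHIKL"), rng.integers(3, 12)))
            b = "".join(rng.choice(list("ACDEFGHIKL"), rng.integers(3, 12)))
            _, _, score = fp.pairwise_align(a, b, gap_open=-2.0, gap_extend=-0.5)
            assert score == pytest.approx(aligner.score(a, b)), (a, b)


class TestConsensusMap:
    def test_identity_for_ungapped(self):
        cmap = fp.consensus_map_from_alignment(
            {"A": "MKVL", "B": "MKVL"}, {"A": 1, "B": 1}
        )
        assert cmap.maps["A"] == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_leading_gap_shifts_columns(self):
        cmap = fp.consensus_map_from_alignment(
            {"A": "MKVL", "B": "-KVL"}, {"A": 1, "B": 1}
        )
        assert cmap.to_consensus("B", 1) == 2

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            fp.consensus_map_from_alignment({"A": "MKV", "B": "MKVL"}, {"A": 1, "B": 1})

    def test_roundtrip_recovers_author_numbering(self):
        rng = np.random.default_rng(12)
        seqs = {}
        offsets = {}
        for rec in ("R1", "R2", "R3"):
            chars = [
                "-" if rng.random() < 0.2 else "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
                for _ in range(40)
            ]
            seqs[rec] = "".join(chars)
            offsets[rec] = int(rng.integers(1, 300))
        cmap = fp.consensus_map_from_alignment(seqs, offsets)
        for rec, seq in seqs.items():
            inv = cmap.invert(rec)
            nongap = [i + 1 for i, ch in enumerate(seq) if ch != "-"]
            for idx, col in enumerate(nongap):
                assert inv[col] == offsets[rec] + idx
            # strictly increasing and injective
            nums = sorted(cmap.maps[rec])
            cols = [cmap.maps[rec][n] for n in nums]
            assert cols == sorted(cols) and len(set(cols)) == len(cols)

    def test_fixture_pairing(self):
        table = fp.load_residue_table("a")
        cmap = fp.consensus_map_from_table(table)
        assert cmap.to_consensus("PPARA", 276) == 85


class TestFingerprintMatrix:
    def _cmap(self):
        return fp.ConsensusMap({"R": {i: i for i in range(1, 100)}})

    def test_single_contact_frequency(self):
        fprint = fp.build_fingerprint(
            [make_contact("l1", "R", 5)], self._cmap(), ["l1"], "R"
        )
        assert fprint.frequency[5] == 1.0

    def test_universe_denominator_counts_contactless_ligands(self):
        contacts = [make_contact(f"l{i}", "R", 7) for i in range(8)]
        fprint = fp.build_fingerprint(
            contacts, self._cmap(), [f"l{i}" for i in range(10)], "R"
        )
        assert fprint.frequency[7] == pytest.approx(0.8)

    def test_unmappable_residue_errors(self):
        with pytest.raises(KeyError, match="999"):
            fp.build_fingerprint(
                [make_contact("l1", "R", 999)], self._cmap(), ["l1"], "R"
            )

    def test_tsv_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        contacts = [
            make_contact(f"l{i}", "R", int(col))
            for i in range(12)
            for col in rng.choice(np.arange(1, 30), size=5, replace=False)
        ]
        fprint = fp.build_fingerprint(
            contacts, self._cmap(), [f"l{i}" for i in range(12)], "R"
        )
        path = tmp_path / "fp.tsv"
        fprint.to_tsv(path)
        back = fp.ContactFingerprint.from_tsv(path, "R")
        assert back.matrix.equals(fprint.matrix)


class TestThresholdSets:
    def test_strict_boundary(self):
        import pandas as pd

        matrix = pd.DataFrame(
            {f"l{i}": [i < 6, i < 8] for i in range(8)}, index=[1, 2]
        )
        fprint = fp.ContactFingerprint("R", matrix)
        sets = fp.threshold_residue_sets(fprint)
        assert sets[0.75] == {2}  # 6/8 = 0.75 exactly is excluded
        assert sets[0.50] == {1, 2}
        assert sets[0.75] <= sets[0.50]

    def test_printed_residue_set_sizes(self):
        sets_a = fp.residue_sets_from_table(fp.load_residue_table("a"))
        assert len(sets_a["PPARA"]["gt75"]) == 8
        assert len(sets_a["PPARG"]["gt50"]) == 7
        assert len(sets_a["PPARA"]["gt50"]) == 13
        sets_b = fp.residue_sets_from_table(fp.load_residue_table("b"))
        assert len(sets_b["RXRG"]["gt75"]) == 7


class TestCoincidenceRate:
    def test_identity_and_asymmetry(self):
        assert fp.coincidence_rate({1, 2}, {1, 2}) == 100.0
        a, b = {1, 2, 3, 4}, {1, 2}
        assert fp.coincidence_rate(a, b) == 50.0
        assert fp.coincidence_rate(b, a) == 100.0

    def test_printed_isoform_rates(self):
        sets_a = fp.residue_sets_from_table(fp.load_residue_table("a"))
        assert fp.coincidence_rate(
            sets_a["PPARA"]["gt75"], sets_a["PPARB"]["gt75"]
        ) == pytest.approx(37.5)
        assert fp.coincidence_rate(
            sets_a["PPARA"]["gt75"], sets_a["PPARG"]["gt75"]
        ) == pytest.approx(12.5)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            fp.coincidence_rate(set(), {1})


class TestPharmacologySets:
    def test_antagonist_only_and_isoform_unique(self):
        contacts = {
            "R1": {"ago1": {1, 2}, "anta1": {2, 3}},
            "R2": {"ago1": {1}, "anta1": set()},
        }
        classes = {"ago1": "drug_agonist", "anta1": "drug_antagonist"}
        out = fp.classify_pharmacology_sets(contacts, classes)
        assert out["R1"]["antagonist_only"] == {3}
        assert out["R1"]["agonist_residues"] == {1, 2}
        # columns 2 and 3 are contacted in R1 only; column 1 is shared
        assert out["R1"]["isoform_unique"] == {2, 3}

    def test_shared_antagonist_columns_from_printed_tables(self):
        """The antagonist contacts PPARA and PPARB at the same consensus
        positions 87 and 91."""
        table = fp.load_residue_table("a")
        anta = table[table["role"] == "antagonist"]
        a = set(anta.loc[anta.receptor == "PPARA", "consensus_column"])
        b = set(anta.loc[anta.receptor == "PPARB", "consensus_column"])
        assert {87, 91} <= (a & b)

    def test_missing_classes_error(self):
        with pytest.raises(ValueError):
            fp.classify_pharmacology_sets({"R": {"l": {1}}}, {"l": "screen"})

    def test_planted_unique_residues_recovered(self):
        contacts = {
            "R1": {"ago": {1, 2, 10}},
            "R2": {"ago": {1, 2, 20}},
            "R3": {"ago": {1, 30}},
        }
        out = fp.classify_pharmacology_sets(
            contacts, {"ago": "drug_agonist", "x": "drug_antagonist"}
        )
        assert out["R1"]["isoform_unique"] == {10}
        assert out["R2"]["isoform_unique"] == {20}
        assert out["R3"]["isoform_unique"] == {30}
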