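import math
import random

import pytest

from cytofam.conservation_signatures import (MultipleAlignment, column_profiles,
                                             detect_wsxws, load_builtin_signatures,
                                             map_key_residues, parse_motif,
                                             progressive_align, scan_signature,
                                             trim_alignment)
from cytofam.formats_io import ProteinRecord

from oracles import dp_global_free_ends, regex_matches, trim_columns

SIGS, WSXWS = load_builtin_signatures()
SIG_BY_ID = {s.motif_id: s for s in SIGS}


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        aln = progressive_align([ProteinRecord("a", "MKVAWQH"),
                                 ProteinRecord("b", "MKVAWQH")])
        assert aln.rows == ("MKVAWQH", "MKVAWQH")

    def test_pairwise_score_matches_global_dp_oracle(self):
        a, b = "MKVA", "MKA"
        aln = progressive_align([ProteinRecord("a", a), ProteinRecord("b", b)])
        assert aln.ncols == 4  # one gap column
        # recompute the alignment's score (terminal gaps free) against the oracle
        from oracles import blosum
        cols = list(zip(*aln.rows))
        while cols and "-" in cols[0]:
            cols.pop(0)
        while cols and "-" in cols[-1]:
            cols.pop()
        score, in_gap = 0, False
        for x, y in cols:
            if x == "-" or y == "-":
                score -= 1 if in_gap else 12
                in_gap = True
            else:
                score += blosum(x, y)
                in_gap = False
        assert score == dp_global_free_ends(a, b)

    def test_single_sequence_passthrough(self):
        aln = progressive_align([ProteinRecord("a", "MKV")])
        assert aln.rows == ("MKV",)

    def test_column_count_at_least_longest_input(self):
        rng = random.Random(0)
        recs = [ProteinRecord(f"s{i}", "".join(
            rng.choice("ACDEFGHIKLMNPQRSTVWY")
            for _ in range(rng.randint(20, 40)))) for i in range(5)]
        aln = progressive_align(recs)
        assert aln.ncols >= max(len(r.seq) for r in recs)
        for i, rec in enumerate(recs):
            assert aln.ungapped(i) == rec.seq


def _random_alignment(rng, nrows, ncols, gap_p):
    rows = []
    for _ in range(nrows):
        rows.append("".join("-" if rng.random() < gap_p
                            else rng.choice("ACDEFGHIKLMNPQRSTVWY")
                            for _ in range(ncols)))
    return MultipleAlignment(tuple(f"r{i}" for i in range(nrows)), tuple(rows))


class TestTrimAlignment:
    def test_spec_worked_example(self):
        # 4 rows, column gap fractions 0, 0.25, 0.5 at gt 0.85
        aln = MultipleAlignment(("a", "b", "c", "d"),
                                ("MK-", "MKV", "M--", "MKV"))
        trimmed, kept = trim_alignment(aln, 0.85, 30.0)
        assert kept == [0] and trimmed.rows == ("M", "M", "M", "M")

    def test_gap_free_unchanged(self):
        aln = MultipleAlignment(("a", "b"), ("MKV", "MKA"))
        trimmed, kept = trim_alignment(aln)
        assert trimmed.rows == aln.rows and kept == [0, 1, 2]

    def test_all_gappy_floor_applies(self):
        aln = MultipleAlignment(("a", "b", "c", "d"),
                                ("A---------", "-C--------",
                                 "--D-------", "---E------"))
        trimmed, kept = trim_alignment(aln, 0.85, 30.0)
        assert len(kept) == math.ceil(0.3 * 10) == 3
        assert kept == [0, 1, 2]  # ties broken leftmost

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_column_filter_oracle_fuzz(self, seed):
        """100 fuzzed alignments per seed against the reference filter."""
        rng = random.Random(seed)
        for _ in range(100):
            aln = _random_alignment(rng, rng.randint(2, 8),
                                    rng.randint(1, 30), rng.random())
            gt = rng.choice([0.5, 0.7, 0.85, 1.0])
            cons = rng.choice([10.0, 30.0, 60.0])
            _, kept = trim_alignment(aln, gt, cons)
            assert kept == trim_columns(list(aln.rows), gt, cons)

    def test_ungapped_trimmed_row_is_subsequence(self):
        rng = random.Random(99)
        for _ in range(50):
            aln = _random_alignment(rng, 4, 25, 0.3)
            trimmed, _ = trim_alignment(aln, 0.85, 30.0)
            for i in range(4):
                sub, full = trimmed.ungapped(i), aln.ungapped(i)
                it = iter(full)
                assert all(ch in it for ch in sub)


class TestColumnProfiles:
    def test_invariant_column_max_information(self):
        aln = MultipleAlignment(tuple(f"r{i}" for i in range(10)), ("C",) * 10)
        (prof,) = column_profiles(aln)
        assert prof.information_bits == pytest.approx(math.log2(20))
        assert prof.consensus == "C"

    def test_uniform_column_zero_information(self):
        aln = MultipleAlignment(tuple(f"r{i}" for i in range(20)),
                                tuple("ACDEFGHIKLMNPQRSTVWY"))
        (prof,) = column_profiles(aln)
        assert prof.information_bits == pytest.approx(0.0, abs=1e-12)

    def test_hand_entropy(self):
        rows = tuple("Y" for _ in range(8)) + tuple("F" for _ in range(2))
        aln = MultipleAlignment(tuple(f"r{i}" for i in range(10)), rows)
        (prof,) = column_profiles(aln)
        h = -(0.8 * math.log2(0.8) + 0.2 * math.log2(0.2))
        assert prof.information_bits == pytest.approx(math.log2(20) - h)
        assert prof.gap_fraction == 0.0

    def test_frequencies_sum_to_one(self):
        aln = MultipleAlignment(("a", "b", "c"), ("M-K", "MKK", "M-R"))
        for prof in column_profiles(aln):
            assert sum(prof.frequencies) == pytest.approx(1.0)


class TestScanSignature:
    def test_worked_example(self):
        matches = scan_signature("MFAGIKAKPDPPW", SIG_BY_ID["F-I-KPDPP"])
        assert [(m.start, m.end) for m in matches] == [(2, 12)]
        assert matches[0].matched == "FAGIKAKPDPP"

    def test_zero_length_interval_rejected(self):
        # anchors must be separated by at least one residue
        assert scan_signature("FIKPDPP", SIG_BY_ID["F-I-KPDPP"]) == []

    def test_sequence_without_first_anchor(self):
        assert scan_signature("MAGIKAKPDPPW", SIG_BY_ID["F-I-KPDPP"]) == []

    def test_choice_anchor_matches_either(self):
        sig = SIG_BY_ID["W-P-W-P-F-L-K/F"]
        core = "WaPaWaPaFaLa"
        for last in "KF":
            assert scan_signature((core + last).upper(), sig)
        assert scan_signature((core + "M").upper(), sig) == []

    @pytest.mark.parametrize("motif_id", list(SIG_BY_ID))
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_regex_oracle_fuzz(self, motif_id, seed):
        """Fuzzed sequences: scanner ≡ lazy bounded-gap regex, all signatures."""
        rng = random.Random(seed * 97 + hash(motif_id) % 1000)
        sig = SIG_BY_ID[motif_id]
        anchors = ["/".join(a) for a in sig.anchors]
        # bias the alphabet toward anchor letters so matches actually occur
        alphabet = "ACDEFGHIKLMNPQRSTVWY" + "FIKPDWLVAS" * 3
        for _ in range(70):
            seq = "".join(rng.choice(alphabet) for _ in range(rng.randint(10, 120)))
            got = [(m.start, m.end) for m in scan_signature(seq, sig)]
            assert got == regex_matches(seq, anchors), seq

    def test_matched_substring_equals_slice(self):
        seq = "MFAGIKAKPDPPW"
        for m in scan_signature(seq, SIG_BY_ID["F-I-KPDPP"]):
            assert m.matched == seq[m.start - 1:m.end]


class TestWsxws:
    def test_single_occurrence(self):
        (m,) = detect_wsxws("AAWSGWSAA")
        assert (m.start, m.end, m.matched) == (3, 7, "WSGWS")

    def test_too_short_pattern_absent(self):
        assert detect_wsxws("WSWS") == []

    def test_two_separated_occurrences(self):
        ms = detect_wsxws("WSAWSMMMMMWSCWS")
        assert [(m.start, m.end) for m in ms] == [(1, 5), (11, 15)]

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_regex_oracle_fuzz(self, seed):
        import re
        rng = random.Random(seed)
        pat = re.compile("WS.WS")
        for _ in range(100):
            seq = "".join(rng.choice("WSAK") for _ in range(rng.randint(5, 60)))
            got = [(m.start, m.end) for m in detect_wsxws(seq)]
            assert got == [(m.start() + 1, m.end()) for m in pat.finditer(seq)]


class TestKeyResidues:
    def test_invariant_residue_fully_conserved(self):
        aln = MultipleAlignment(("ref", "s1", "s2"),
                                ("MKYV", "MRYV", "MAYA"))
        (rep,) = map_key_residues(aln, "ref", [("Y", 3)])
        assert rep.reference_ok and rep.conservation == 1.0

    def test_claimed_residue_mismatch_flagged(self):
        aln = MultipleAlignment(("ref", "s1"), ("MKFV", "MKFV"))
        (rep,) = map_key_residues(aln, "ref", [("Y", 3)])
        assert not rep.reference_ok  # reference has F where Y was claimed

    def test_gapped_reference_position_mapping(self):
        aln = MultipleAlignment(("ref", "s1"), ("M-KY", "MAKY"))
        (rep,) = map_key_residues(aln, "ref", [("Y", 3)])
        assert rep.column == 3 and rep.reference_ok

    def test_planted_heparin_binding_block(self):
        # the basic cluster RKKEKMK planted in every row: all 7 columns invariant
        rows = tuple("AA" + "RKKEKMK" + "CC" for _ in range(6))
        aln = MultipleAlignment(tuple(f"r{i}" for i in range(6)), rows)
        reports = map_key_residues(aln, "r0",
                                   [(c, i + 3) for i, c in enumerate("RKKEKMK")])
        assert all(r.reference_ok and r.conservation == 1.0 for r in reports)

    def test_position_beyond_reference_is_error(self):
        aln = MultipleAlignment(("ref",), ("MKV",))
        with pytest.raises(ValueError, match="beyond"):
            map_key_residues(aln, "ref", [("V", 9)])


class TestPlantedMotifRecovery:
    def test_exact_coordinates_at_rate_zero(self, bundle0):
        from cytofam.formats_io import read_fasta
        truth = bundle0.truth
        checked = 0
        for sid in bundle0.species_ids:
            recs = {r.id: r for r in read_fasta(bundle0.protein_paths[sid])}
            rows = truth[(truth.species_id == sid) & (truth.motifs != "")]
            for _, row in rows.dropna(subset=["motifs"]).iterrows():
                seq = recs[row.protein_id]
                for item in row.motifs.split(";"):
                    mid, span = item.rsplit(":", 1)
                    s, e = map(int, span.split("-"))
                    if mid == "WSXWS":
                        found = detect_wsxws(seq)
                    else:
                        found = scan_signature(seq, SIG_BY_ID[mid])
                    assert (s, e) in [(m.start, m.end) for m in found], \
                        (row.protein_id, mid)
                    checked += 1
        assert checked >= 50
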