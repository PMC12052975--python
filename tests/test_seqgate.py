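"""Full-size ABCG screening, alignment mapping, occurrence and logos."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gatekeeper as gk
from gatekeeper.seqgate import (AMINO_ACIDS, MSA, MotifPattern, SeqRecord,
                                align_global, columns_to_ref_positions,
                                consensus_motif, find_motif)


class TestFastaIO:
    def test_header_dialect_and_roundtrip(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1|Brassicaceae\nMKV\n>s2\nACDE*\n")
        recs = gk.read_fasta(p)
        assert recs[0] == SeqRecord("s1", "Brassicaceae", "MKV")
        assert recs[1].taxon == "unknown"
        assert recs[1].residues == "ACDE"  # terminator stripped
        out = tmp_path / "b.fasta"
        gk.write_fasta(recs, out)
        assert gk.read_fasta(out) == recs

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">s1\nMKV\n>s1\nMKW\n")
        with pytest.raises(ValueError, match="duplicate"):
            gk.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            gk.read_fasta(p)


class TestFindMotif:
    @pytest.mark.parametrize("seq, pattern, expected", [
        ("AALLAGPPKK", "LLXGPP", [3]),
        ("AALLGPPKK", "LLXGPP", []),
        ("VCTIHQPVCTIHQP", "VCTIHQP", [1, 8]),
    ])
    def test_examples(self, seq, pattern, expected):
        assert find_motif(seq, pattern) == expected

    def test_pattern_longer_than_sequence(self):
        assert find_motif("ML", "GLDARXAAXVMR") == []

    @given(st.text(alphabet="ACDG", min_size=1, max_size=30),
           st.text(alphabet="ACDGX", min_size=3, max_size=5))
    def test_against_sliding_window_oracle(self, seq, pattern):
        def brute(seq, pat):
            hits = []
            for i in range(len(seq) - len(pat) + 1):
                if all(p == "X" or p == s for p, s in zip(pat, seq[i:i + len(pat)])):
                    hits.append(i + 1)
            return hits

        assert find_motif(seq, MotifPattern(pattern)) == brute(seq, pattern)

    def test_pattern_validation(self):
        with pytest.raises(ValueError):
            MotifPattern("AB")  # too short
        with pytest.raises(ValueError):
            MotifPattern("AB1")


def _full_size_record(rid="ok1", taxon="Brassicaceae", length=1200, seed=0):
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list(AMINO_ACIDS), size=length)))
    pos = 10
    for motif in gk.FilterSpec().motifs:
        inst = [("A" if c == "X" else c) for c in motif.pattern]
        seq[pos:pos + len(inst)] = inst
        pos += 40
    return SeqRecord(rid, taxon, "".join(seq))


class TestFilterFullSize:
    def test_planted_positive_kept(self):
        kept, rejected = gk.filter_full_size([_full_size_record()])
        assert len(kept) == 1 and not rejected

    @pytest.mark.parametrize("length, ok", [(949, False), (950, True),
                                            (1800, True), (1801, False)])
    def test_length_bounds_inclusive(self, length, ok):
        r = _full_size_record(length=length)
        kept, rejected = gk.filter_full_size([r])
        assert bool(kept) is ok
        if not ok:
            assert rejected[0][1] == "length"

    def test_missing_motif_reason(self):
        r = _full_size_record()
        broken = SeqRecord(r.id, r.taxon, r.residues.replace("VCTIHQP", "VCTIHQA"))
        kept, rejected = gk.filter_full_size([broken])
        assert not kept
        assert rejected[0][1] == "motif VCTIHQP"

    def test_idempotent_and_partition(self):
        records = [_full_size_record(f"r{i}", seed=i, length=1000 + i * 37)
                   for i in range(5)]
        records.append(SeqRecord("short", "unknown", "MKV"))
        kept, rejected = gk.filter_full_size(records)
        assert len(kept) + len(rejected) == len(records)
        kept2, rejected2 = gk.filter_full_size(kept)
        assert kept2 == kept and not rejected2
        # order independence
        kept3, _ = gk.filter_full_size(records[::-1])
        assert sorted(r.id for r in kept3) == sorted(r.id for r in kept)


def brute_force_affine_score(a, b, mat, gap_open, gap_extend):
    """Enumerate every global alignment; affine gaps, first gap costs
    open + extend. Independent of the production aligner."""
    best = [-np.inf]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + mat[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open + gap_extend
            rec(i + 1, j, "U", score + cost)
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open + gap_extend
            rec(i, j + 1, "L", score + cost)

    rec(0, 0, "", 0.0)
    return best[0]


class TestAlignGlobal:
    def test_identical_pair_blosum62(self):
        a, b, score = align_global("FG", "FG")
        assert (a, b) == ("FG", "FG")
        assert score == 12.0  # F-F = 6 and G-G = 6 in BLOSUM62

    def test_empty_versus_two_residues(self):
        a, b, score = align_global("", "AA")
        assert (a, b) == ("--", "AA")
        assert score == -10.0 + 2 * -0.5  # one gap run of length 2

    def test_unknown_letter_named_in_error(self):
        with pytest.raises(ValueError, match="'1'"):
            align_global("A1", "AA")

    def test_small_pairs_match_enumeration_oracle(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        alpha = "ACDE"
        seqs = ["".join(s) for n in (1, 2) for s in itertools.product(alpha, repeat=n)]
        for a in seqs:
            for b in seqs:
                _, _, score = align_global(a, b)
                expected = brute_force_affine_score(a, b, mat, -10.0, -0.5)
                assert score == pytest.approx(expected), (a, b)

    def test_alignment_strings_reproduce_score(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        a, b, score = align_global("FGMIINM", "FGMNM")
        total = 0.0
        prev_a = prev_b = False
        for ca, cb in zip(a, b):
            if ca != "-" and cb != "-":
                total += mat[ca, cb]
                prev_a = prev_b = False
            elif cb == "-":
                total += -0.5 if prev_b else -10.5
                prev_b, prev_a = True, False
            else:
                total += -0.5 if prev_a else -10.5
                prev_a, prev_b = True, False
        assert total == pytest.approx(score)


class TestPositionMapping:
    def _msa(self, ref_row, other_rows=()):
        recs = [SeqRecord("REF", "unknown", ref_row)]
        recs += [SeqRecord(f"s{i}", "unknown", r) for i, r in enumerate(other_rows)]
        return MSA(records=recs, reference_id="REF")

    def test_single_gap_example(self):
        msa = self._msa("FG-MI")
        assert gk.ref_positions_to_columns(msa, [3]) == {3: 4}

    def test_ungapped_identity(self):
        msa = self._msa("FGMI")
        assert gk.ref_positions_to_columns(msa, [1, 2, 3, 4]) == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_position_beyond_reference_errors(self):
        with pytest.raises(ValueError):
            gk.ref_positions_to_columns(self._msa("FG-MI"), [5])

    @given(st.text(alphabet="FGMI", min_size=1, max_size=12),
           st.integers(0, 2**31 - 1))
    def test_roundtrip_on_random_gappings(self, seq, seed):
        rng = np.random.default_rng(seed)
        row = list(seq)
        for _ in range(rng.integers(0, 6)):
            row.insert(int(rng.integers(0, len(row) + 1)), "-")
        msa = self._msa("".join(row))
        positions = list(range(1, len(seq) + 1))
        cols = gk.ref_positions_to_columns(msa, positions)
        back = columns_to_ref_positions(msa, cols.values())
        assert {back[c]: c for c in back} == cols

    def test_reference_gap_column_rejected_in_inverse(self):
        msa = self._msa("F-G")
        with pytest.raises(ValueError):
            columns_to_ref_positions(msa, [2])


class TestExtractGateResidues:
    def test_named_residues_inside_printed_segments(self):
        ann = gk.DEFAULT_GATE_ANNOTATION
        expected = {585: "I", 589: "F", 592: "F", 698: "F",
                    1251: "Y", 1259: "I", 1260: "N", 1369: "N"}
        for pos, aa in expected.items():
            assert ann.segment_residue(pos) == aa

    def test_msa_columns_extraction(self):
        ref = SeqRecord("REF", "unknown", "FGMI")
        row = SeqRecord("q", "unknown", "FA-I")
        msa = MSA(records=[ref, row], reference_id="REF")
        got = gk.extract_gate_residues(row, via="msa-columns", msa=msa,
                                       positions=[2, 3, 4])
        assert got == {2: "A", 3: "-", 4: "I"}

    def test_pairwise_extraction_against_scaffold(self):
        scaffold = gk.make_reference_scaffold(seed=0)
        got = gk.extract_gate_residues(scaffold, via="pairwise",
                                       reference=scaffold)
        assert got == {703: "F", 704: "L", 1374: "F", 1375: "F"}


class TestOccurrenceAndLogo:
    def test_occurrence_fractions(self):
        extr = [("Brassicaceae", {704: aa}) for aa in "LLFV"]
        table = gk.occurrence_by_taxon(extr)
        assert table.fractions(704, "Brassicaceae") == {
            "L": 0.5, "F": 0.25, "V": 0.25}

    def test_single_record_degenerate(self):
        table = gk.occurrence_by_taxon([("X", {703: "F"})])
        assert table.fractions(703, "X") == {"F": 1.0}

    def test_pooling_is_count_weighted_mixture(self):
        a = [("A", {704: aa}) for aa in "LLF"]
        b = [("B", {704: aa}) for aa in "VF"]
        pooled = gk.occurrence_by_taxon([("P", m) for _, m in a + b])
        ta = gk.occurrence_by_taxon(a).counts_at(704, "A")
        tb = gk.occurrence_by_taxon(b).counts_at(704, "B")
        merged = {aa: ta.get(aa, 0) + tb.get(aa, 0) for aa in set(ta) | set(tb)}
        assert pooled.counts_at(704, "P") == merged

    def test_information_content_values(self):
        assert gk.information_content({"F": 100}) == pytest.approx(np.log2(20))
        uniform = {aa: 5 for aa in AMINO_ACIDS}
        assert gk.information_content(uniform) == pytest.approx(0.0, abs=1e-12)
        assert gk.information_content({"L": 5, "V": 5}) == pytest.approx(
            np.log2(20) - 1.0)

    def test_gaps_tracked_but_excluded_from_bits(self):
        assert gk.information_content({"F": 10, "-": 90}) == pytest.approx(np.log2(20))
        with pytest.raises(ValueError):
            gk.information_content({"-": 7})

    def test_small_sample_correction_reduces_bits(self):
        full = gk.information_content({"F": 5})
        corr = gk.information_content({"F": 5}, small_sample_correction=True)
        assert corr == pytest.approx(full - 19 / (2 * np.log(2) * 5))


class TestConsensusMotif:
    def test_single_and_pair_rules(self):
        assert consensus_motif([{"G": 0.95, "A": 0.05}]) == "G"
        spread = {aa: 0.35 / 18 for aa in "ACDEFGHIKMNQTVWYLR"}
        assert consensus_motif([{"S": 0.35, "P": 0.30, **spread}]) == "S/P"

    def test_gate_consensus_pattern(self):
        def spread():
            return {aa: 1.0 / 18 for aa in "ACDEFGHIKMNQTVWYLR"}

        profile = [
            {"G": 0.9, "A": 0.1},
            {"F": 0.9, "L": 0.1},
            spread(),
            spread(),
            {"S": 0.32, "P": 0.28, "A": 0.2, "G": 0.2},
            {"R": 0.32, "K": 0.28, "A": 0.2, "G": 0.2},
            spread(),
            spread(),
        ]
        assert consensus_motif(profile) == "G F x x S/P R/K x x"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            consensus_motif([{"G": 1.0}], t_single=0.0)
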