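"""Structure representation, parsing, distances and sample statistics."""

import numpy as np
import pytest

from ensembletree.structures import (
    RnaSequence,
    SecondaryStructure,
    StructureSample,
    basepair_distance,
    greyscale_diagram,
    pair_probabilities,
    parse_dotbracket,
    read_ct,
    read_fasta,
    read_sample_archive,
    signature_distance,
    signature_of,
    write_ct,
    write_dotbracket,
    write_sample_archive,
)


class TestRnaSequence:
    def test_normalizes_t_and_case(self):
        assert str(RnaSequence("acgt")) == "ACGU"

    def test_rejects_illegal_characters(self):
        with pytest.raises(ValueError, match="illegal"):
            RnaSequence("ACGX")

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            RnaSequence("")


class TestStructureValidation:
    def test_rejects_shared_base(self):
        with pytest.raises(ValueError, match="two pairs"):
            SecondaryStructure([(1, 8), (1, 9)], 10)

    def test_rejects_small_hairpin(self):
        with pytest.raises(ValueError, match="hairpin"):
            SecondaryStructure([(2, 5)], 8)

    def test_rejects_pseudoknot_by_default(self):
        with pytest.raises(ValueError, match="pseudoknot"):
            SecondaryStructure([(1, 8), (4, 12)], 12)

    def test_permissive_flag_stores_pseudoknot(self):
        s = SecondaryStructure([(1, 8), (4, 12)], 12, allow_pseudoknots=True)
        assert s.pseudoknotted

    def test_nested_pairs_accepted(self):
        s = SecondaryStructure([(1, 10), (2, 9), (3, 8)], 10)
        assert not s.pseudoknotted


class TestDotBracket:
    @pytest.mark.parametrize(
        "text,pairs",
        [("....", set()), ("((...))", {(1, 7), (2, 6)}), (".(....).", {(2, 7)})],
    )
    def test_parse_examples(self, text, pairs):
        assert parse_dotbracket(text).pairs == pairs

    @pytest.mark.parametrize("bad", ["(.)", "(..", "..)", "(.x.)"])
    def test_parse_errors(self, bad):
        with pytest.raises(ValueError):
            parse_dotbracket(bad)

    def test_error_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            parse_dotbracket("..)..")

    @pytest.mark.parametrize(
        "pairs,n,expect", [(set(), 4, "...."), ({(1, 7), (2, 6)}, 7, "((...))")]
    )
    def test_write_examples(self, pairs, n, expect):
        assert write_dotbracket(SecondaryStructure(pairs, n)) == expect

    def test_round_trip_identity(self, random_structures):
        for s in random_structures:
            assert parse_dotbracket(write_dotbracket(s)) == s


class TestSignatures:
    def test_empty_structure(self):
        assert signature_of(SecondaryStructure([], 5)).tolist() == [0] * 5

    def test_single_pair(self):
        assert signature_of(SecondaryStructure([(1, 8)], 8)).tolist() == [1, 0, 0, 0, 0, 0, 0, 1]

    def test_bit_count_is_twice_pair_count(self, random_structures):
        for s in random_structures:
            assert int(signature_of(s).sum()) == 2 * len(s.pairs)


class TestDistances:
    def test_identity(self, random_structures):
        s = random_structures[0]
        assert signature_distance(s, s) == 0
        assert basepair_distance(s, s) == 0

    def test_examples(self):
        a = SecondaryStructure([(1, 8)], 8)
        b = SecondaryStructure([], 8)
        c = SecondaryStructure([(2, 7)], 8)
        assert signature_distance(a, b) == 2
        assert basepair_distance(a, b) == 1
        assert basepair_distance(a, c) == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            signature_distance(SecondaryStructure([], 5), SecondaryStructure([], 6))
        with pytest.raises(ValueError, match="mismatch"):
            basepair_distance(SecondaryStructure([], 5), SecondaryStructure([], 6))

    def test_signature_distance_matches_positionwise_count(self, random_structures):
        # independent oracle: compare signatures position by position
        for s, t in zip(random_structures[:50], random_structures[50:]):
            expected = sum(
                int(a != b) for a, b in zip(signature_of(s), signature_of(t))
            )
            assert signature_distance(s, t) == expected

    def test_metric_properties_on_random_triples(self, random_structures):
        trip = list(zip(random_structures[0::3], random_structures[1::3], random_structures[2::3]))
        for s, t, u in trip:
            assert signature_distance(s, t) == signature_distance(t, s)
            assert (
                signature_distance(s, u)
                <= signature_distance(s, t) + signature_distance(t, u)
            )

    def test_signature_bounded_by_twice_basepair_distance(self, random_structures):
        for s, t in zip(random_structures[:50], random_structures[50:]):
            assert signature_distance(s, t) <= 2 * basepair_distance(s, t)


class TestStructureSample:
    def test_multiset_counting(self):
        a = SecondaryStructure([(1, 8)], 8)
        b = SecondaryStructure([], 8)
        samp = StructureSample([a, b, a, a])
        assert samp.size == 4
        assert samp.multiplicity(a) == 3
        assert np.isclose(samp.probabilities().sum(), 1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            StructureSample([])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="differing"):
            StructureSample([SecondaryStructure([], 5), SecondaryStructure([], 6)])

    def test_pair_probability_homogeneous(self):
        a = SecondaryStructure([(1, 8), (2, 7)], 8)
        probs = pair_probabilities(StructureSample([a] * 10))
        assert probs == {(1, 8): 1.0, (2, 7): 1.0}

    def test_pair_probability_half(self):
        a = SecondaryStructure([(1, 8)], 8)
        b = SecondaryStructure([], 8)
        probs = pair_probabilities(StructureSample([a] * 512 + [b] * 512))
        assert probs == {(1, 8): 0.5}

    def test_pair_probabilities_match_member_summation(self, random_samples):
        # brute-force oracle: sum indicator over every member of the multiset
        for samp in random_samples[:10]:
            probs = pair_probabilities(samp)
            for pair, p in probs.items():
                direct = sum(int(pair in s.pairs) for s in samp) / samp.size
                assert p == pytest.approx(direct, abs=1e-12)

    def test_pair_count_conservation(self, random_samples):
        for samp in random_samples[:10]:
            pairs, m = samp.pair_table()
            freq = samp.counts @ m.astype(np.int64)
            total_pairs = sum(int(c) * len(s.pairs) for s, c in zip(samp.structures, samp.counts))
            assert int(freq.sum()) == total_pairs


class TestGreyscaleDiagram:
    def test_certain_pair_is_black(self):
        a = SecondaryStructure([(1, 8)], 8)
        diag = greyscale_diagram(StructureSample([a] * 4))
        assert diag.arcs == [(1, 8, 0.0)]
        assert "rgb(0,0,0)" in diag.to_svg()

    def test_half_probability_grey(self):
        a = SecondaryStructure([(2, 7)], 8)
        b = SecondaryStructure([], 8)
        diag = greyscale_diagram(StructureSample([a, b]))
        assert diag.arcs == [(2, 7, 0.5)]

    def test_absent_pair_has_no_arc(self):
        diag = greyscale_diagram(StructureSample([SecondaryStructure([], 8)] * 3))
        assert diag.arcs == []


class TestFileFormats:
    def test_fasta_reader_normalizes(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nACGTACGT\n>b\nGGGCCC\n")
        records = read_fasta(p)
        assert [rid for rid, _ in records] == ["a", "b"]
        assert str(records[0][1]) == "ACGUACGU"

    def test_ct_round_trip(self, tmp_path):
        seq = RnaSequence("GGGAAAUCCC")
        s = SecondaryStructure([(1, 10), (2, 9), (3, 8)], 10)
        p = tmp_path / "s.ct"
        write_ct(p, seq, s)
        seq2, s2 = read_ct(p)
        assert seq2 == seq and s2 == s

    def test_archive_round_trip_and_determinism(self, tmp_path, random_samples):
        samp = random_samples[0]
        p1, p2 = tmp_path / "a1.txt", tmp_path / "a2.txt"
        write_sample_archive(p1, samp, engine="toy", seed=1)
        write_sample_archive(p2, samp, engine="toy", seed=1)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_sample_archive(p1)
        assert back.size == samp.size
        assert list(back.structures) == list(samp.structures)
        assert back.counts.tolist() == samp.counts.tolist()
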