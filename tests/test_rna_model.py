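import math

import pytest

from basinflood import rna_model as rm
from basinflood.landscape import RnaLandscape


class TestRnaSequence:
    def test_normalization_t_to_u_and_case(self):
        assert rm.RnaSequence("acgt").bases == "ACGU"

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GU", "12"])
    def test_rejects_non_rna(self, bad):
        with pytest.raises(rm.StructureError):
            rm.RnaSequence(bad)


class TestParseDotbracket:
    @pytest.mark.parametrize("text,pairs", [
        ("((...))", {(1, 7), (2, 6)}),
        (".........", set()),
        ("(...)", {(1, 5)}),
    ])
    def test_stack_matching(self, text, pairs):
        assert rm.parse_dotbracket(text).pairs == frozenset(pairs)

    @pytest.mark.parametrize("bad,pos", [("((.", 2), ("..)", 3), ("(.x)", 3)])
    def test_errors_name_position(self, bad, pos):
        with pytest.raises(rm.StructureError, match=f"position {pos}"):
            rm.parse_dotbracket(bad)

    def test_round_trip_over_full_landscape(self):
        for db in RnaLandscape("GGCGAAAGGCCAAGGC").enumerate_states():
            assert rm.parse_dotbracket(db).dot_bracket == db


class TestStructureInvariants:
    def test_crossing_pairs_rejected(self):
        with pytest.raises(rm.StructureError, match="crossing"):
            rm.SecondaryStructure(frozenset({(1, 6), (3, 9)}), 10)

    def test_shared_base_rejected(self):
        with pytest.raises(rm.StructureError, match="more than one pair"):
            rm.SecondaryStructure(frozenset({(1, 6), (6, 10)}), 10)


class TestValidateStructure:
    def test_valid_hairpin(self):
        seq = rm.RnaSequence("GGGAAACCC")
        rep = rm.validate_structure(seq, rm.parse_dotbracket("(((...)))"))
        assert rep.ok and not rep.violations

    def test_inadmissible_pair(self):
        seq = rm.RnaSequence("GGGAAACCC")
        s = rm.SecondaryStructure(frozenset({(4, 8)}), 9)  # A-C
        rep = rm.validate_structure(seq, s)
        assert not rep.ok
        assert any("inadmissible" in v for v in rep.violations)

    def test_short_hairpin_loop(self):
        rep = rm.validate_structure(rm.RnaSequence("GCGC"),
                                    rm.parse_dotbracket("(..)"))
        assert not rep.ok
        assert any("hairpin loop" in v for v in rep.violations)

    def test_length_mismatch(self):
        with pytest.raises(rm.StructureError, match="length"):
            rm.validate_structure(rm.RnaSequence("GCGC"),
                                  rm.parse_dotbracket("....."))


class TestNeighbors:
    def test_open_chain_gggaaaccc_has_nine(self):
        seq = rm.RnaSequence("GGGAAACCC")
        nbs = rm.neighbors(seq, rm.parse_dotbracket("." * 9))
        assert len(nbs) == 9
        assert all(len(s.pairs) == 1 for s in nbs)

    def test_full_hairpin_only_removals(self):
        seq = rm.RnaSequence("GGGAAACCC")
        nbs = rm.neighbors(seq, rm.parse_dotbracket("(((...)))"))
        assert sorted(n.dot_bracket for n in nbs) == [
            "((.....))", "(.(...).)", ".((...)).",
        ]

    def test_unpairable_sequence(self):
        assert rm.neighbors(rm.RnaSequence("AAAA"),
                            rm.parse_dotbracket("....")) == []

    @pytest.mark.parametrize("seq", ["GGGAAACCC", "ACGUACGUACGU"])
    def test_move_set_symmetric_and_bounded(self, seq):
        L = RnaLandscape(seq)
        delta = rm.delta_max_neighbors(rm.RnaSequence(seq))
        for x in L.enumerate_states():
            nbs = L.neighbors(x)
            assert len(nbs) == len(set(nbs)) <= delta
            for y in nbs:
                assert x in L.neighbors(y)


class TestDelta:
    @pytest.mark.parametrize("seq,expected", [
        ("GGGAAACCC", 9), ("AAAA", 0), ("GC", 0),
    ])
    def test_admissible_pair_count(self, seq, expected):
        assert rm.delta_max_neighbors(rm.RnaSequence(seq)) == expected

    def test_open_chain_attains_delta(self):
        seq = rm.RnaSequence("GGGAAACCC")
        n = len(rm.neighbors(seq, rm.parse_dotbracket("." * 9)))
        assert n == rm.delta_max_neighbors(seq)


class TestOrderKey:
    def test_energy_dominates(self):
        a = rm.structure_order_key(rm.parse_dotbracket("(...)"), 1.0)
        b = rm.structure_order_key(rm.parse_dotbracket("....."), 0.5)
        assert b < a

    def test_lexicographic_tie_break(self):
        a = rm.structure_order_key(rm.parse_dotbracket("((...))"), 0.0)
        b = rm.structure_order_key(rm.parse_dotbracket(".(...)."), 0.0)
        assert a < b

    def test_identical_inputs_equal(self):
        s = rm.parse_dotbracket("(...)")
        assert rm.structure_order_key(s, 0.3) == rm.structure_order_key(s, 0.3)


class TestSimplePairEnergy:
    def test_open_chain_zero(self):
        assert rm.simple_pair_energy(rm.RnaSequence("GGGAAACCC"),
                                     rm.parse_dotbracket("." * 9)) == 0.0

    def test_three_gc_pairs(self):
        assert rm.simple_pair_energy(rm.RnaSequence("GGGAAACCC"),
                                     rm.parse_dotbracket("(((...)))")) == -9.0

    def test_single_gu_pair(self):
        assert rm.simple_pair_energy(rm.RnaSequence("GAAAU"),
                                     rm.parse_dotbracket("(...)")) == -1.0

    def test_additive_over_single_pair_removal(self):
        """Removing one pair changes E by exactly that pair's table value."""
        L = RnaLandscape("GGGAAACCC")
        bases = "GGGAAACCC"
        for db in L.enumerate_states():
            pairs = rm.parse_dotbracket(db).pairs
            for i, j in pairs:
                removed = db[:i - 1] + "." + db[i:j - 1] + "." + db[j:]
                table = rm.SIMPLE_PAIR_TABLE[frozenset({bases[i - 1], bases[j - 1]})]
                assert math.isclose(L.energy(db) - L.energy(removed), table)


class TestViennaBackend:
    def test_open_chain_zero(self):
        assert rm.external_energy(rm.RnaSequence("GGGAAACCC"),
                                  rm.parse_dotbracket("." * 9)) == 0.0

    def test_deterministic(self):
        seq = rm.RnaSequence("GGGAAUUAUUGUUCCCUGAGAGCGGUAGUUCUC")
        s = rm.parse_dotbracket("((((......))))" + "." * 19)
        assert rm.external_energy(seq, s) == rm.external_energy(seq, s)

    def test_recorded_reference_value(self):
        """Hairpin free energy recorded once from ViennaRNA 2.7.2 (37C)."""
        e = rm.external_energy(rm.RnaSequence("GGGAAACCC"),
                               rm.parse_dotbracket("(((...)))"))
        assert e == pytest.approx(-1.2, abs=1e-9)

    def test_backend_provenance_recorded(self):
        be = rm.ViennaBackend()
        d = be.describe()
        assert d["units"] == "kcal/mol" and "viennarna_version" in d
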