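import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboseek.examples import (
    PREQ1_MUTANT_17,
    PREQ1_MUTANT_19,
    PREQ1_WILDTYPE,
    XPT_APTAMER,
)
from riboseek.io import (
    read_constraint,
    read_fasta,
    read_vienna,
    write_constraint,
    write_fasta,
    write_vienna,
)
from riboseek.structures import (
    MotifConstraint,
    RnaSequence,
    StructureParseError,
    base_pair_distance,
    hamming_distance,
    parse_dotbracket,
)
from riboseek.synthetic import random_nested_structure


class TestRnaSequence:
    def test_dna_and_lowercase_normalized(self):
        s = RnaSequence("x", "acgtACGT")
        assert s.residues == "ACGUACGU"
        assert s.to_dna() == "ACGTACGT"

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GU"])
    def test_illegal_input_rejected(self, bad):
        with pytest.raises(ValueError):
            RnaSequence("x", bad)


class TestParseDotbracket:
    @pytest.mark.parametrize(
        "text,pairs",
        [
            ("((...))", {(0, 6), (1, 5)}),
            (".......", set()),
            ("(...)", {(0, 4)}),
            ("", set()),
        ],
    )
    def test_pairs_by_stack_matching(self, text, pairs):
        s = parse_dotbracket(text)
        assert s.pairs == frozenset(pairs)
        assert s.dotbracket == text

    @pytest.mark.parametrize(
        "text,index",
        [("((...)", 0), (")(", 0), ("(.x.)", 2)],
    )
    def test_malformed_input_names_offending_index(self, text, index):
        with pytest.raises(StructureParseError) as err:
            parse_dotbracket(text)
        assert err.value.index == index

    def test_roundtrip_random_structures(self):
        rng = random.Random(0)
        for _ in range(50):
            s = random_nested_structure(rng.randint(5, 60), rng)
            assert parse_dotbracket(s.dotbracket).pairs == s.pairs


class TestBasePairDistance:
    def test_identity_and_derived_examples(self):
        a = parse_dotbracket("((...))")
        assert base_pair_distance(a, a) == 0
        assert base_pair_distance(a, parse_dotbracket(".(...).")) == 1
        assert base_pair_distance(a, parse_dotbracket(".......")) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            base_pair_distance(parse_dotbracket("..."), parse_dotbracket("...."))

    def test_metric_properties(self):
        rng = random.Random(1)
        structs = [random_nested_structure(30, rng) for _ in range(12)]
        for a in structs:
            for b in structs:
                d = base_pair_distance(a, b)
                assert d == base_pair_distance(b, a)
                assert (d == 0) == (a.pairs == b.pairs)
                for c in structs:
                    assert d <= base_pair_distance(a, c) + base_pair_distance(c, b)


class TestHammingDistance:
    def test_preq1_mutant_series(self):
        # the published mutant series: 17 mutations to escape, then exactly
        # two more forming one compensatory pair change
        assert hamming_distance(PREQ1_WILDTYPE, PREQ1_MUTANT_17) == 17
        assert hamming_distance(PREQ1_MUTANT_17, PREQ1_MUTANT_19) == 2
        assert hamming_distance(XPT_APTAMER, XPT_APTAMER) == 0

    def test_dna_rna_spellings_compare_equal(self):
        assert hamming_distance("ACGT", "ACGU") == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance("ACG", "ACGU")


class TestMotifConstraint:
    def test_validation_against_target(self):
        target = parse_dotbracket("..((...))..")
        c = MotifConstraint(region=(2, 9), required_substructure="((...))")
        c.validate_against(target)
        bad = MotifConstraint(region=(0, 7), required_substructure="((...))")
        with pytest.raises(ValueError):
            bad.validate_against(target)

    def test_region_and_positions_bounds(self):
        with pytest.raises(ValueError):
            MotifConstraint(region=(5, 2), required_substructure="")
        with pytest.raises(ValueError):
            MotifConstraint(fixed_positions={-1: "A"})
        c = MotifConstraint(fixed_positions={50: "G"})
        with pytest.raises(ValueError):
            c.validate_against(parse_dotbracket("." * 10), 10)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None)
def test_structure_pairs_never_cross(seed):
    """Nested-structure invariant: pairs from stack matching never cross."""
    rng = random.Random(seed)
    s = random_nested_structure(rng.randint(10, 50), rng)
    pairs = sorted(s.pairs)
    for i, j in pairs:
        for k, l in pairs:
            if i < k:
                assert k > j or l < j  # nested or disjoint


class TestFileFormats:
    def test_fasta_roundtrip(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        write_fasta([XPT_APTAMER, PREQ1_WILDTYPE], path)
        back = read_fasta(path)
        assert [s.id for s in back] == ["xpt", "queC"]
        assert back[0].residues == XPT_APTAMER.residues

    def test_vienna_roundtrip_ignores_energy_suffix(self, tmp_path):
        path = tmp_path / "fold.vienna"
        seq = RnaSequence("hp", "GGGAAACCC")
        structure = parse_dotbracket("(((...)))")
        write_vienna(seq, structure, path, dG=-9.0)
        seq2, structure2 = read_vienna(path)
        assert seq2.residues == seq.residues
        assert structure2.dotbracket == structure.dotbracket

    def test_vienna_length_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.vienna"
        path.write_text(">x\nACGU\n((...))\n")
        with pytest.raises(ValueError):
            read_vienna(path)

    def test_constraint_roundtrip_one_based(self, tmp_path):
        target = parse_dotbracket("..((...))..")
        c = MotifConstraint(
            region=(2, 9),
            required_substructure="((...))",
            fixed_positions={4: "G", 6: "A"},
        )
        path = tmp_path / "constraint.txt"
        write_constraint(c, path)
        back = read_constraint(path, target)
        assert back.region == c.region
        assert back.required_substructure == c.required_substructure
        assert back.fixed_positions == c.fixed_positions
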