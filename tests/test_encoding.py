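import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptaselect import (
    AptamerRecord,
    CompoundRecord,
    assemble_vector,
    encode_aptamer,
    filter_descriptors,
)
from aptaselect.encoding import (
    APTAMER_FEATURE_NAMES,
    read_category_map,
    read_descriptor_table,
    read_fasta,
    read_interactions,
    write_category_map,
)

from conftest import schema_with_descriptors

SEQ_ALPHABET = "acgut"


class TestEncodeAptamer:
    def test_single_symbol_sequence(self):
        vec = encode_aptamer(AptamerRecord("x", "aaaa"))
        assert np.allclose(vec[:4], [1, 0, 0, 0])
        assert vec[4] == 1.0  # aa
        assert np.allclose(vec[5:], 0)

    def test_t_and_u_are_interchangeable(self):
        assert np.array_equal(
            encode_aptamer(AptamerRecord("x", "acgt")),
            encode_aptamer(AptamerRecord("x", "acgu")),
        )

    def test_hand_counted_frequencies(self):
        # "acgu": 4 mononucleotides each once; 3 overlapping dinucleotides
        vec = encode_aptamer(AptamerRecord("x", "acgu"))
        assert np.allclose(vec[:4], 0.25)
        names = dict(zip(APTAMER_FEATURE_NAMES, vec))
        assert names["freq_ac"] == pytest.approx(1 / 3)
        assert names["freq_cg"] == pytest.approx(1 / 3)
        assert names["freq_gu"] == pytest.approx(1 / 3)
        assert sum(v for k, v in names.items() if len(k) == 7) == pytest.approx(1.0)

    def test_case_insensitive(self):
        assert np.array_equal(
            encode_aptamer(AptamerRecord("x", "AcGU")),
            encode_aptamer(AptamerRecord("x", "acgu")),
        )

    @settings(deadline=None)
    @given(st.text(alphabet=SEQ_ALPHABET, min_size=2, max_size=60))
    def test_blocks_each_sum_to_one(self, seq):
        vec = encode_aptamer(AptamerRecord("x", seq))
        assert vec[:4].sum() == pytest.approx(1.0)
        assert vec[4:].sum() == pytest.approx(1.0)
        assert vec.shape == (20,)

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match=r"'n' at position 2"):
            AptamerRecord("x", "acngu")

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="length 1"):
            encode_aptamer(AptamerRecord("x", "a"))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            AptamerRecord("x", "")


def _table(columns: dict[str, list[float]]) -> list[CompoundRecord]:
    n = len(next(iter(columns.values())))
    return [
        CompoundRecord(f"c{i}", {name: vals[i] for name, vals in columns.items()})
        for i in range(n)
    ]


class TestFilterDescriptors:
    def test_zero_variance_column_dropped(self):
        table = _table({"const": [3, 3, 3], "var": [1, 2, 3]})
        _, retained = filter_descriptors(table)
        assert retained == ["var"]

    def test_missing_value_column_dropped(self):
        table = _table({"holey": [1, math.nan, 3], "var": [1, 2, 3]})
        _, retained = filter_descriptors(table)
        assert retained == ["var"]

    def test_toy_table_retains_seven_of_ten(self):
        cols = {f"v{i}": [float(i + j * (i + 1)) for j in range(3)] for i in range(7)}
        cols["c1"] = [5.0, 5.0, 5.0]
        cols["c2"] = [-1.0, -1.0, -1.0]
        cols["m1"] = [1.0, math.nan, 3.0]
        _, retained = filter_descriptors(_table(cols))
        assert len(retained) == 7
        assert retained == [f"v{i}" for i in range(7)]  # order preserved

    def test_idempotent(self):
        table = _table({"const": [3, 3, 3], "a": [1, 2, 3], "b": [0, 5, 1]})
        once, names_once = filter_descriptors(table)
        twice, names_twice = filter_descriptors(once)
        assert names_once == names_twice
        assert [r.descriptors for r in once] == [r.descriptors for r in twice]

    def test_single_compound_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            filter_descriptors(_table({"a": [1.0], "b": [2.0]}))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_descriptors([])


class TestAssembleVector:
    @pytest.mark.parametrize("n_desc,expected", [(301, 321), (0, 20), (30, 50)])
    def test_vector_length_is_20_plus_descriptors(self, n_desc, expected, rng):
        schema = schema_with_descriptors(n_desc)
        assert len(schema) == expected
        compound = CompoundRecord(
            "c0", {name: float(v) for name, v in
                   zip(schema.compound_names, rng.normal(size=n_desc))}
        )
        vec = assemble_vector(AptamerRecord("a0", "acgu"), compound, schema)
        assert vec.shape == (expected,)

    def test_missing_descriptor_named_in_error(self):
        schema = schema_with_descriptors(2)
        compound = CompoundRecord("c0", {"d000": 1.0})
        with pytest.raises(KeyError, match="d001"):
            assemble_vector(AptamerRecord("a0", "acgu"), compound, schema)


class TestIO:
    def test_fasta_order_and_duplicates(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">s1\nacgu\n>s2\nggcc\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["s1", "s2"]
        p.write_text(">s1\nacgu\n>s1\nggcc\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_non_numeric_cell_is_missing(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("compound_id\tx\ty\nc1\t1.0\toops\nc2\t2.0\t3.0\n")
        recs = read_descriptor_table(p)
        assert math.isnan(recs[0].descriptors["y"])
        _, retained = filter_descriptors(recs)
        assert retained == ["x"]

    def test_category_map_roundtrip(self, tmp_path):
        mapping = {"x": "electrostatic", "y": "topological"}
        for name in ("m.yaml", "m.json"):
            p = tmp_path / name
            write_category_map(mapping, p)
            assert read_category_map(p) == mapping

    def test_interactions_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text(
            "compound_id\taptamer_id\tlabel\nc1\ta1\tpositive\nc1\ta1\tnegative\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_interactions(p)

    def test_study_roundtrip_identity(self, small_study, tmp_path):
        from aptaselect import write_study

        paths = write_study(small_study, tmp_path)
        aptamers = read_fasta(paths["fasta"])
        assert aptamers == list(small_study.aptamers)
        compounds = read_descriptor_table(paths["descriptors"])
        assert [c.id for c in compounds] == [c.id for c in small_study.compounds]
        for got, want in zip(compounds, small_study.compounds):
            for name, v in want.descriptors.items():
                assert got.descriptors[name] == pytest.approx(v, rel=1e-9)
        pairs = read_interactions(paths["interactions"])
        assert pairs == list(small_study.pairs)
        assert read_category_map(paths["categories"]) == small_study.category_map
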