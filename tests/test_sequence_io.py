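import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mybscan.sequence_io import (FORBIDDEN_NAME_CHARS, SequenceRecord, clean_names,
                                 detect_moltype, file_checksum, read_fasta,
                                 translate_cds, write_fasta)


def _write(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_multiline_bodies_are_concatenated_and_uppercased(self, tmp_path):
        recs = read_fasta(_write(tmp_path, ">a\nMK\nWL\n"))
        assert len(recs) == 1
        assert (recs[0].id, recs[0].residues) == ("a", "MKWL")

    def test_description_separated_from_id(self, tmp_path):
        recs = read_fasta(_write(tmp_path, ">a desc x\nmkw\n"))
        assert recs[0].id == "a"
        assert recs[0].description == "desc x"
        assert recs[0].residues == "MKW"

    def test_order_preserved(self, tmp_path):
        recs = read_fasta(_write(tmp_path, ">z\nMK\n>a\nWL\n>m\nKK\n"))
        assert [r.id for r in recs] == ["z", "a", "m"]

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="in.fasta"):
            read_fasta(_write(tmp_path, ""))

    def test_headerless_file_is_an_error(self, tmp_path):
        with pytest.raises(ValueError):
            read_fasta(_write(tmp_path, "MKWL\n"))

    def test_duplicate_ids_are_an_error_listing_them(self, tmp_path):
        with pytest.raises(ValueError, match="dup1"):
            read_fasta(_write(tmp_path, ">dup1\nMK\n>dup1\nWL\n"))


class TestCleanNames:
    @pytest.mark.parametrize("original,cleaned", [
        ("gene(1);x", "gene_1__x"),
        ("abc", "abc"),
        ("a b\tc", "a_b_c"),
        ("x[1]:y,z", "x_1__y_z"),
    ])
    def test_forbidden_characters_replaced(self, original, cleaned):
        recs, name_map = clean_names([SequenceRecord(original, "MK")])
        assert recs[0].id == cleaned
        assert name_map.forward[original] == cleaned

    def test_collisions_get_numeric_suffixes(self):
        recs, _ = clean_names([SequenceRecord("a b", "MK"), SequenceRecord("a;b", "WL")])
        assert [r.id for r in recs] == ["a_b", "a_b_2"]

    def test_mapping_is_invertible(self):
        originals = ["a b", "a;b", "a_b", "plain"]
        recs, name_map = clean_names([SequenceRecord(o, "MK") for o in originals])
        assert len({r.id for r in recs}) == len(originals)
        for o, rec in zip(originals, recs):
            assert name_map.original(rec.id) == o

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.text(alphabet=string.ascii_letters + " ();:,[]'\"\t_0123456789",
                            min_size=1).filter(lambda s: s.strip("_ \t")),
                    min_size=1, max_size=8))
    def test_idempotent_on_cleaned_output(self, names):
        records = [SequenceRecord(n, "MKW") for n in names]
        once, _ = clean_names(records)
        twice, _ = clean_names(once)
        assert [r.id for r in twice] == [r.id for r in once]
        assert not any(set(r.id) & FORBIDDEN_NAME_CHARS for r in once)


class TestTranslateCds:
    @pytest.mark.parametrize("cds,peptide", [
        ("ATGGCTTAA", "MA"),      # terminal stop removed
        ("ATGNNTGGA", "MXG"),     # ambiguous codon -> X
        ("ATGGC", "M"),           # trailing bases dropped
        ("ATGTAAGCT", "M*A"),     # internal stop kept
    ])
    def test_standard_code_frame_plus_one(self, cds, peptide):
        rec = SequenceRecord("c", cds, moltype="nucleotide")
        assert translate_cds(rec).residues == peptide

    def test_empty_peptide_returns_none(self):
        assert translate_cds(SequenceRecord("c", "TAA", moltype="nucleotide")) is None

    def test_peptide_input_rejected(self):
        with pytest.raises(ValueError):
            translate_cds(SequenceRecord("p", "MKWL", moltype="peptide"))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKMNPQRSTVWY", min_size=1, max_size=40))
    def test_reverse_translation_round_trip(self, peptide):
        # any codon choice must translate back to the same peptide
        import random
        from mybscan.simulate import reverse_translate
        cds = reverse_translate(random.Random(0), peptide)
        rec = SequenceRecord("x", cds, moltype="nucleotide")
        assert translate_cds(rec).residues == peptide


class TestRoundTripAndChecksum:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(0, 10 ** 6), st.text(alphabet="ACDEFGHIKLMNPQRSTVWY",
                                                   min_size=1, max_size=120)),
        min_size=1, max_size=6, unique_by=lambda t: t[0]))
    def test_write_read_round_trip(self, items):
        import tempfile
        from pathlib import Path
        records = [SequenceRecord(f"id{i}", seq) for i, seq in items]
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "rt.fasta"
            write_fasta(records, path)
            back = read_fasta(path, moltype="peptide")
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in records]

    def test_md5_reference_vectors(self, tmp_path):
        empty = tmp_path / "empty"
        empty.write_bytes(b"")
        assert file_checksum(empty) == "d41d8cd98f00b204e9800998ecf8427e"
        abc = tmp_path / "abc"
        abc.write_bytes(b"abc")
        assert file_checksum(abc) == "900150983cd24fb0d6963f7d28e17f72"
        assert file_checksum(abc) == file_checksum(abc)

    def test_unreadable_path_is_an_error(self, tmp_path):
        with pytest.raises(OSError):
            file_checksum(tmp_path / "missing")


class TestMoltypeDetection:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGTACGTAN", "nucleotide"),
        ("MKWVLAAGTW", "peptide"),
        ("ACGTACGTAC" * 9 + "MKWVLAAGTW", "nucleotide"),  # exactly 90% nucleotide
    ])
    def test_ninety_percent_rule(self, seq, expected):
        assert detect_moltype(seq) == expected
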