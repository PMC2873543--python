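"""PDB reading/writing, residue coding, missing-residue detection."""

import numpy as np
import pytest

from rnafrag import fixtures as fx
from rnafrag.structure_io import (
    StructureError,
    detect_missing_residues,
    one_letter_code,
    read_structure,
    write_fragment,
    write_structure,
)


@pytest.fixture()
def roundtrip(tmp_path):
    def _do(structure):
        path = tmp_path / f"{structure.entry_id}.pdb"
        write_structure(structure, path)
        return read_structure(path)
    return _do


class TestResidueCoding:
    @pytest.mark.parametrize(
        "resname,letter,parent",
        [
            ("A", "A", "A"), ("U", "U", "U"),
            ("1MA", "a", "A"), ("5MC", "c", "C"), ("PSU", "u", "U"),
            ("OMG", "g", "G"),
            ("DT", "u", "U"), ("DA", "a", "A"),  # DNA -> parent analog
            ("XXQ", "n", "unknown"),
        ],
    )
    def test_parent_nucleoside_mapping(self, resname, letter, parent):
        assert one_letter_code(resname) == (letter, parent)


class TestReadWrite:
    def test_duplex_roundtrip_counts(self, roundtrip):
        rd = roundtrip(fx.build_duplex("GCGCGCGC", "D8"))
        assert len(rd.models) == 1
        assert len(rd.models[0].strands) == 2
        assert sum(len(s) for s in rd.models[0].strands) == 16
        assert all(
            r.one_letter.isupper()
            for s in rd.models[0].strands for r in s.residues
        )

    def test_multi_model_identical_sequences(self, roundtrip):
        rd = roundtrip(fx.build_hairpin("GCG", "GAAA", "HP", method="NMR",
                                        resolution=None, n_models=3))
        assert len(rd.models) == 3
        seqs = {m.strands[0].sequence for m in rd.models}
        assert seqs == {"GCGGAAACGC"}

    def test_metadata_survives(self, roundtrip):
        import datetime
        rd = roundtrip(fx.build_duplex(
            "GCGC", "META", method="X-ray", resolution=2.13,
            deposition_date=datetime.date(2007, 3, 12)))
        assert rd.entry_id == "META"
        assert rd.method == "X-ray"
        assert rd.resolution == pytest.approx(2.13)
        assert rd.deposition_date == datetime.date(2007, 3, 12)

    def test_modified_residue_read_as_lowercase(self, roundtrip):
        rd = roundtrip(fx.build_hairpin("GCG", "GAAA", "HM",
                                        modified={5: "1MA"}))
        res = rd.models[0].strands[0].residues[4]
        assert res.name == "1MA"
        assert res.one_letter == "a"
        assert res.parent == "A"

    def test_coordinates_preserved_to_format_precision(self, roundtrip):
        st = fx.build_duplex("GCAU", "CP")
        rd = roundtrip(st)
        for s_orig, s_read in zip(st.models[0].strands, rd.models[0].strands):
            for r_orig, r_read in zip(s_orig.residues, s_read.residues):
                assert set(r_orig.atoms) == set(r_read.atoms)
                for name in r_orig.atoms:
                    assert np.allclose(
                        r_orig.atoms[name], r_read.atoms[name], atol=5e-4
                    )

    def test_written_text_reread_is_stable(self, tmp_path):
        st = fx.build_duplex("GCAU", "ST")
        p1 = tmp_path / "a.pdb"
        write_structure(st, p1)
        rd = read_structure(p1)
        text2 = write_structure(rd)
        assert p1.read_text() == text2

    def test_nonexistent_file_raises(self):
        with pytest.raises(StructureError):
            read_structure("/nonexistent/file.pdb")


class TestMissingResidues:
    def test_seqres_gap_detected(self, roundtrip):
        st = fx.inject_missing(fx.build_duplex("GCGAUCGCGC", "MS"),
                               [("A", 6), ("A", 7)])
        rd = roundtrip(st)
        missing = detect_missing_residues(rd)
        assert missing == {"A": [6, 7], "B": []}
        strand = rd.models[0].strands[0]
        assert len(strand) == 10
        assert not strand.residues[5].has_coordinates
        assert strand.residues[5].one_letter == "C"  # identity from SEQRES

    def test_complete_chain_has_no_missing(self, roundtrip):
        rd = roundtrip(fx.build_duplex("GCGC", "OK"))
        assert detect_missing_residues(rd) == {"A": [], "B": []}

    def test_numbering_gap_rule_without_seqres(self):
        # hand-written record: numbering 10,11,12,15,16 and no SEQRES
        lines = []
        serial = 1
        for num in (10, 11, 12, 15, 16):
            lines.append(
                f"ATOM  {serial:>5}  P     G A{num:>4}    "
                f"{float(num):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           P"
            )
            serial += 1
            lines.append(
                f"ATOM  {serial:>5}  C1'   G A{num:>4}    "
                f"{float(num):8.3f}{1.4:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
            serial += 1
            lines.append(
                f"ATOM  {serial:>5}  O4'   G A{num:>4}    "
                f"{float(num):8.3f}{2.1:8.3f}{1.0:8.3f}  1.00  0.00           O"
            )
            serial += 1
            lines.append(
                f"ATOM  {serial:>5}  N9    G A{num:>4}    "
                f"{float(num):8.3f}{0.7:8.3f}{1.0:8.3f}  1.00  0.00           N"
            )
            serial += 1
        text = "\n".join(lines) + "\nEND\n"
        import tempfile, os
        with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as f:
            f.write(text)
            path = f.name
        try:
            rd = read_structure(path)
            missing = detect_missing_residues(rd)
            assert missing == {"A": [4, 5]}
            strand = rd.models[0].strands[0]
            assert [r.number for r in strand.residues] == [10, 11, 12, 13, 14, 15, 16]
            assert strand.residues[3].parent == "unknown"
        finally:
            os.unlink(path)

    def test_detection_is_idempotent(self, roundtrip):
        st = fx.inject_missing(fx.build_duplex("GCGAUCGC", "ID"), [("A", 4)])
        rd = roundtrip(st)
        first = detect_missing_residues(rd)
        second = detect_missing_residues(rd)
        assert first == second
        assert len(rd.models[0].strands[0]) == 8


class TestWriteFragment:
    def test_author_numbering_and_atom_count(self):
        st = fx.build_hairpin("GCG", "GAAA", "WF")
        class Hit:
            model_number = 1
            segments = [("A", 2, 5)]
        text = write_fragment(st, Hit())
        atom_lines = [l for l in text.splitlines()
                      if l.startswith(("ATOM", "HETATM"))]
        expected = sum(
            len(r.atoms) for r in st.models[0].strands[0].residues[1:5]
        )
        assert len(atom_lines) == expected
        numbers = {int(l[22:26]) for l in atom_lines}
        assert numbers == {2, 3, 4, 5}

    def test_fragment_rereads_identically(self, tmp_path):
        st = fx.build_duplex("GCGAUC", "FR")
        class Hit:
            model_number = 1
            segments = [("A", 1, 6), ("B", 1, 6)]
        text = write_fragment(st, Hit())
        p = tmp_path / "frag.pdb"
        p.write_text(text)
        rd = read_structure(p)
        assert write_fragment(rd, Hit()) == text

    def test_missing_residue_in_fragment_is_error(self):
        st = fx.inject_missing(fx.build_duplex("GCGAUC", "FM"), [("A", 3)])
        detect_missing_residues(st)
        class Hit:
            model_number = 1
            segments = [("A", 1, 6)]
        with pytest.raises(StructureError):
            write_fragment(st, Hit())
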