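"""Shift-table data model and I/O round trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h3csp import (
    ShiftTable,
    export_talos_input,
    read_nmrstar,
    read_shift_tsv,
    write_nmrstar,
    write_shift_tsv,
)
from h3csp.shift_io import (
    NUCLEI,
    AmbiguityError,
    ShiftFormatError,
    read_intensity_tsv,
    write_intensity_tsv,
)


class TestShiftTableInvariants:
    def test_proline_amide_rejected(self):
        with pytest.raises(ShiftFormatError, match="proline"):
            ShiftTable("x", "AP", 1, {(2, "H"): 8.1})

    def test_nonfinite_rejected(self):
        with pytest.raises(ShiftFormatError, match="non-finite"):
            ShiftTable("x", "A", 1, {(1, "CA"): math.nan})

    def test_unknown_nucleus_rejected(self):
        with pytest.raises(ShiftFormatError, match="nucleus"):
            ShiftTable("x", "A", 1, {(1, "HB"): 1.2})

    def test_residue_type_lookup_respects_offset(self):
        t = ShiftTable("x", "TVA", 45, {(45, "CA"): 62.1})
        assert t.residue_type(45) == "T"
        assert t.residue_type(47) == "A"
        assert t.residue_type(44) is None

    def test_referencing_offset_shifts_one_nucleus(self, small_table):
        shifted = small_table.with_offsets({"CA": 0.5})
        assert shifted.get(45, "CA") == pytest.approx(small_table.get(45, "CA") + 0.5)
        assert shifted.get(45, "H") == small_table.get(45, "H")


class TestTsv:
    def test_single_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("residue_number\tresidue_type\tnucleus\tshift_ppm\n61\tL\tH\t9.5\n")
        t = read_shift_tsv(p)
        assert t.shifts == {(61, "H"): 9.5}
        assert t.residue_type(61) == "L"

    def test_duplicate_row_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n"
            "61\tL\tH\t9.5\n61\tL\tH\t9.6\n"
        )
        with pytest.raises(ShiftFormatError, match="duplicate"):
            read_shift_tsv(p)

    def test_conflicting_residue_type_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n"
            "50\tA\tCA\t52.0\n50\tG\tN\t108.0\n"
        )
        with pytest.raises(ShiftFormatError, match="conflicting"):
            read_shift_tsv(p)

    @pytest.mark.parametrize("bad", ["unknown nucleus\t50\tA\tQQ\t1.0", "non-numeric\t50\tA\tCA\txx"])
    def test_malformed_rows_rejected(self, tmp_path, bad):
        _, rn, aa, nuc, val = bad.split("\t")
        p = tmp_path / "t.tsv"
        p.write_text(
            "residue_number\tresidue_type\tnucleus\tshift_ppm\n"
            f"{rn}\t{aa}\t{nuc}\t{val}\n"
        )
        with pytest.raises(ShiftFormatError):
            read_shift_tsv(p)

    def test_co_alias_maps_to_c(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("residue_number\tresidue_type\tnucleus\tshift_ppm\n50\tA\tCO\t177.1\n")
        assert read_shift_tsv(p).get(50, "C") == 177.1

    def test_round_trip(self, small_table, tmp_path):
        p = tmp_path / "rt.tsv"
        write_shift_tsv(small_table, p)
        back = read_shift_tsv(p, condition_label=small_table.condition_label)
        assert back.shifts.keys() == small_table.shifts.keys()
        for k in small_table.shifts:
            assert back.shifts[k] == pytest.approx(small_table.shifts[k], abs=5e-4)


class TestNmrStar:
    def test_three_row_loop(self, tmp_path):
        p = tmp_path / "t.str"
        p.write_text(
            "data_test\nsave_shifts\n"
            "   _Assigned_chem_shift_list.Sf_category assigned_chemical_shifts\n"
            "   loop_\n"
            "      _Atom_chem_shift.ID\n"
            "      _Atom_chem_shift.Seq_ID\n"
            "      _Atom_chem_shift.Comp_ID\n"
            "      _Atom_chem_shift.Atom_ID\n"
            "      _Atom_chem_shift.Val\n"
            "      1 45 THR H  8.10\n"
            "      2 45 THR N  115.2\n"
            "      3 45 THR CA 62.1\n"
            "   stop_\nsave_\n"
        )
        t = read_nmrstar(p)
        assert len(t.shifts) == 3
        assert t.residue_type(45) == "T"
        assert t.get(45, "CA") == 62.1

    def test_conflicting_comp_id_rejected(self, tmp_path):
        p = tmp_path / "t.str"
        p.write_text(
            "data_test\nloop_\n"
            "_Atom_chem_shift.Seq_ID\n_Atom_chem_shift.Comp_ID\n"
            "_Atom_chem_shift.Atom_ID\n_Atom_chem_shift.Val\n"
            "50 ALA CA 52.0\n50 GLY N 108.0\nstop_\n"
        )
        with pytest.raises(ShiftFormatError, match="conflicting"):
            read_nmrstar(p)

    def test_missing_loop_is_format_error(self, tmp_path):
        p = tmp_path / "t.str"
        p.write_text("data_test\n_Entry.ID 1\n")
        with pytest.raises(ShiftFormatError, match="no assigned-chemical-shift loop"):
            read_nmrstar(p)

    def test_two_entities_need_selector(self, tmp_path):
        p = tmp_path / "t.str"
        p.write_text(
            "data_test\nloop_\n"
            "_Atom_chem_shift.Entity_ID\n_Atom_chem_shift.Seq_ID\n"
            "_Atom_chem_shift.Comp_ID\n_Atom_chem_shift.Atom_ID\n_Atom_chem_shift.Val\n"
            "1 45 THR CA 62.1\n2 45 ALA CA 52.5\nstop_\n"
        )
        with pytest.raises(AmbiguityError):
            read_nmrstar(p)
        t = read_nmrstar(p, entity_selector="2")
        assert t.residue_type(45) == "A"

    def test_unknown_atoms_ignored(self, tmp_path):
        p = tmp_path / "t.str"
        p.write_text(
            "data_test\nloop_\n"
            "_Atom_chem_shift.Seq_ID\n_Atom_chem_shift.Comp_ID\n"
            "_Atom_chem_shift.Atom_ID\n_Atom_chem_shift.Val\n"
            "45 THR CA 62.1\n45 THR HB 4.2\n45 THR CG2 21.5\nstop_\n"
        )
        t = read_nmrstar(p)
        assert set(t.shifts) == {(45, "CA")}
        assert t.get(45, "CA") == 62.1

    def test_empty_table_round_trips(self, tmp_path):
        empty = ShiftTable("empty", "", 1, {})
        p = tmp_path / "e.str"
        write_nmrstar(empty, p)
        assert read_nmrstar(p, condition_label="empty").shifts == {}

    def test_round_trip(self, small_table, tmp_path):
        p = tmp_path / "rt.str"
        write_nmrstar(small_table, p)
        back = read_nmrstar(p, condition_label=small_table.condition_label)
        assert back.shifts.keys() == small_table.shifts.keys()
        for k in small_table.shifts:
            assert back.shifts[k] == pytest.approx(small_table.shifts[k], abs=5e-4)
        assert back.residue_type(45) == "T"


@st.composite
def shift_tables(draw):
    n = draw(st.integers(min_value=0, max_value=15))
    residues = draw(
        st.lists(st.integers(min_value=1, max_value=200), min_size=n, max_size=n, unique=True)
    )
    aas = draw(
        st.lists(st.sampled_from("ACDEFGHIKLMNQRSTVWY"), min_size=n, max_size=n)
    )
    shifts = {}
    types = dict(zip(residues, aas))
    for rn in residues:
        for nuc in draw(st.sets(st.sampled_from(NUCLEI), min_size=1)):
            shifts[(rn, nuc)] = draw(
                st.floats(min_value=-10, max_value=200).map(lambda x: round(x, 3))
            )
    if types:
        off = min(types)
        seq = "".join(types.get(i, "X") for i in range(off, max(types) + 1))
    else:
        off, seq = 1, ""
    return ShiftTable("hyp", seq, off, shifts)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(table=shift_tables())
@pytest.mark.parametrize("dialect", ["tsv", "nmrstar"])
def test_round_trip_property(table, dialect, tmp_path_factory):
    """read(write(table)) preserves the shift set to >= 3 decimal places in
    both dialects."""
    tmp = tmp_path_factory.mktemp("rt")
    if dialect == "tsv":
        path = tmp / "t.tsv"
        write_shift_tsv(table, path)
        back = read_shift_tsv(path, condition_label="hyp")
    else:
        path = tmp / "t.str"
        write_nmrstar(table, path)
        back = read_nmrstar(path, condition_label="hyp")
    assert back.shifts.keys() == table.shifts.keys()
    for k, v in table.shifts.items():
        assert back.shifts[k] == pytest.approx(v, abs=5e-4)


class TestTalosExport:
    def test_row_count_equals_shift_count(self, small_table, tmp_path):
        n = export_talos_input(small_table, tmp_path / "talos.tab")
        assert n == len(small_table.shifts)

    def test_full_synthetic_table_row_count(self, h3_tables, tmp_path):
        table = h3_tables[0]
        n = export_talos_input(table, tmp_path / "talos.tab")
        text = (tmp_path / "talos.tab").read_text()
        data_rows = [
            ln for ln in text.splitlines()
            if ln and not ln.startswith(("DATA", "VARS", "FORMAT"))
        ]
        assert n == len(table.shifts) == len(data_rows)

    def test_proline_has_no_hn_row(self, tmp_path):
        t = ShiftTable("x", "AP", 1, {(1, "H"): 8.2, (2, "CA"): 63.3})
        export_talos_input(t, tmp_path / "talos.tab")
        rows = [ln for ln in (tmp_path / "talos.tab").read_text().splitlines() if " P " in ln]
        assert rows and all(" HN " not in r for r in rows)

    def test_header_carries_sequence(self, small_table, tmp_path):
        export_talos_input(small_table, tmp_path / "talos.tab")
        text = (tmp_path / "talos.tab").read_text()
        assert "DATA SEQUENCE TVALR" in text
        assert "DATA FIRST_RESID 45" in text


class TestIntensityTsv:
    def test_round_trip(self, tmp_path):
        from h3csp import IntensityTable

        t = IntensityTable("i", {45: 10.0, 46: 2.5})
        write_intensity_tsv(t, tmp_path / "i.tsv")
        back = read_intensity_tsv(tmp_path / "i.tsv", condition_label="i")
        assert back.intensities == t.intensities

    def test_nonpositive_rejected(self):
        from h3csp import IntensityTable

        with pytest.raises(ShiftFormatError):
            IntensityTable("i", {45: 0.0})
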