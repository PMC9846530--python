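import pytest

from h3csp import (
    CspProfile,
    CspRecord,
    DEFAULT_WEIGHTS,
    ShiftTable,
    default_h3_spec,
    generate_condition_set,
)


@pytest.fixture(scope="session")
def h3_tables():
    """Default three-condition synthetic set (60/30/15 bp emulation), seed 1."""
    return generate_condition_set(default_h3_spec(seed=1))


@pytest.fixture(scope="session")
def h3_spec():
    return default_h3_spec(seed=1)


@pytest.fixture
def small_table():
    """Five-residue table with full backbone shifts at residues 45-49."""
    seq = "TVALR"
    shifts = {}
    base = {"H": 8.1, "N": 115.2, "CA": 62.1, "CB": 69.5, "C": 174.8}
    for i in range(5):
        for nuc, v in base.items():
            shifts[(45 + i, nuc)] = v + 0.37 * i
    return ShiftTable("demo", seq, 45, shifts)


def profile_from_deltas(deltas, weights=DEFAULT_WEIGHTS, start=1):
    """Build a CspProfile whose complete records carry the given combined
    deltas (None entries become incomplete records)."""
    records = []
    for i, d in enumerate(deltas):
        records.append(
            CspRecord(
                residue_number=start + i,
                residue_type="A",
                d_hn=d,
                d_n=0.0 if d is not None else None,
                d_ca=0.0 if d is not None else None,
                delta_combined=d,
            )
        )
    return CspProfile(("a", "b"), weights, records)


SYNTHETIC_PDB = """\
HEADER    SYNTHETIC TEST STRUCTURE
ATOM      1  N   THR A  45      11.104  13.207   9.451  1.00 20.00           N
ATOM      2  CA  THR A  45      12.560  13.329   9.278  1.00 20.00           C
ATOM      3  C   THR A  45      13.034  14.688   9.785  1.00 20.00           C
ATOM      4  N   VAL A  46      14.248  14.774  10.320  1.00 20.00           N
ATOM      5  CA  VAL A  46      14.811  16.028  10.815  1.00 20.00           C
ATOM      6  C   VAL A  46      16.304  15.872  11.081  1.00 20.00           C
ATOM      7  N   ALA A  47      16.953  16.962  11.478  1.00 20.00           N
ATOM      8  CA  ALA A  47      18.380  16.942  11.774  1.00 20.00           C
ATOM      9  C   ALA A  47      19.167  16.504  10.545  1.00 20.00           C
ATOM     10  N   THR E  45      21.104  23.207  19.451  1.00 20.00           N
ATOM     11  CA  THR E  45      22.560  23.329  19.278  1.00 20.00           C
TER      12      ALA A  47
END
"""


@pytest.fixture
def synthetic_pdb(tmp_path):
    p = tmp_path / "synthetic.pdb"
    p.write_text(SYNTHETIC_PDB)
    return p
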