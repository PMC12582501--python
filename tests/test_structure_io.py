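"""Parsing PDB/mmCIF into the nucleotide-only model."""

import gzip

import numpy as np
import pytest

import polyads as pl
from polyads.structure_io import ParseError, read_structure, write_pdb

MINIMAL_G = """\
ATOM      1  N9    G A   1      -1.289   4.551   0.000  1.00  0.00           N
ATOM      2  C8    G A   1       0.023   4.962   0.000  1.00  0.00           C
ATOM      3  N7    G A   1       0.870   3.969   0.000  1.00  0.00           N
ATOM      4  C5    G A   1       0.071   2.833   0.000  1.00  0.00           C
ATOM      5  C6    G A   1       0.424   1.460   0.000  1.00  0.00           C
ATOM      6  O6    G A   1       1.554   0.955   0.000  1.00  0.00           O
ATOM      7  N1    G A   1      -0.700   0.641   0.000  1.00  0.00           N
ATOM      8  C2    G A   1      -1.999   1.087   0.000  1.00  0.00           C
ATOM      9  N2    G A   1      -2.949   0.139   0.000  1.00  0.00           N
ATOM     10  N3    G A   1      -2.342   2.364   0.000  1.00  0.00           N
ATOM     11  C4    G A   1      -1.265   3.177   0.000  1.00  0.00           C
END
"""


def test_minimal_single_guanine(tmp_path):
    p = tmp_path / "g.pdb"
    p.write_text(MINIMAL_G)
    st = read_structure(p)
    assert len(st) == 1
    assert st.chains() == ["A"]
    res = st.residues[0]
    assert res.parent_base == "G"
    assert res.key == "A/1"
    np.testing.assert_allclose(res.atom("O6").position, [1.554, 0.955, 0.0])


def test_gzip_transparency(tmp_path):
    plain = tmp_path / "g.pdb"
    plain.write_text(MINIMAL_G)
    packed = tmp_path / "g.pdb.bin"  # deliberately misleading extension
    packed.write_bytes(gzip.compress(MINIMAL_G.encode()))
    a = read_structure(plain)
    b = read_structure(packed)
    assert len(a) == len(b)
    for ra, rb in zip(a.residues, b.residues):
        assert ra.key == rb.key and ra.res_name == rb.res_name
        for aa, ab in zip(ra.atoms, rb.atoms):
            assert aa.name == ab.name
            np.testing.assert_array_equal(aa.position, ab.position)


def test_roundtrip_through_writer(tmp_path):
    pdb, _ = pl.make_polyad_fixture(pl.FixtureSpec())
    p = tmp_path / "t.pdb"
    p.write_text(pdb)
    st = read_structure(p)
    assert len(st) == 4
    p2 = tmp_path / "t2.pdb"
    p2.write_text(write_pdb(st))
    st2 = read_structure(p2)
    assert [r.key for r in st.residues] == [r.key for r in st2.residues]
    for ra, rb in zip(st.residues, st2.residues):
        assert [a.name for a in ra.atoms] == [a.name for a in rb.atoms]
        pa = np.array([a.position for a in ra.atoms])
        pb = np.array([a.position for a in rb.atoms])
        assert np.abs(pa - pb).max() <= 1e-3  # PDB coordinate precision


def test_mmcif_input(tmp_path):
    # write a tetrad fixture as mmCIF via gemmi and parse it back
    import gemmi
    pdb, _ = pl.make_polyad_fixture(pl.spec_for_order(5))
    st_g = gemmi.read_pdb_string(pdb)
    cif_path = tmp_path / "t.cif"
    st_g.setup_entities()
    cif_path.write_text(st_g.make_mmcif_document().as_string())
    st = read_structure(cif_path)
    assert len(st) == 5
    assert {r.parent_base for r in st.residues} == {"G", "A"}


def test_model_selection_and_errors(tmp_path):
    two_models = ("MODEL        1\n" + MINIMAL_G.replace("END\n", "ENDMDL\n")
                  + "MODEL        2\n"
                  + MINIMAL_G.replace("END\n", "ENDMDL\nEND\n"))
    p = tmp_path / "nmr.pdb"
    p.write_text(two_models)
    assert read_structure(p, model=2).model_num == 2
    with pytest.raises(ValueError, match="models 1..2"):
        read_structure(p, model=3)


def test_garbled_file_raises_parse_error(tmp_path):
    p = tmp_path / "junk.cif"
    p.write_text("data_x\nloop_\n_atom_site.oops\nnot closing\n'")
    with pytest.raises(ParseError):
        read_structure(p)


def test_ions_side_channel_and_ligand_exclusion(tmp_path):
    extra = (
        "HETATM   90  K     K B   1       0.000   0.000   1.700  1.00  0.00           K\n"
        "HETATM   91  C1  LIG C   1       0.000   9.000   0.000  1.00  0.00           C\n"
        "HETATM   92  O   HOH D   1       5.000   5.000   5.000  1.00  0.00           O\n"
    )
    p = tmp_path / "mix.pdb"
    p.write_text(MINIMAL_G.replace("END\n", extra + "END\n"))
    st = read_structure(p)
    assert len(st) == 1                      # ligand and water dropped
    assert [r.res_name for r in st.ions] == ["K"]


def test_modified_purine_maps_by_ring_atoms(tmp_path):
    # same guanine ring atoms under an unknown residue name
    text = MINIMAL_G.replace("  G A", "XGU A")
    p = tmp_path / "mod.pdb"
    p.write_text(text)
    st = read_structure(p)
    assert len(st) == 1
    assert st.residues[0].parent_base == "G"


def test_altloc_keeps_highest_occupancy(tmp_path):
    lines = []
    for alt, occ, x in (("A", 0.30, 1.000), ("B", 0.70, 2.000)):
        lines.append(
            f"ATOM      1  N9 {alt}  G A   1    {x:8.3f}   4.551   0.000"
            f"{occ:6.2f}  0.00           N")
    body = "\n".join(lines) + "\n"
    p = tmp_path / "alt.pdb"
    p.write_text(MINIMAL_G.replace(
        "ATOM      1  N9    G A   1      -1.289   4.551   0.000  1.00  0.00           N\n",
        body))
    st = read_structure(p)
    n9 = st.residues[0].atom("N9")
    assert n9 is not None
    assert abs(n9.position[0] - 2.0) < 1e-6
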