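"""Parsing, heme detection and site writing."""

import numpy as np
import pytest

from hemescan.fixtures import FixtureSpec, make_toy_heme_protein
from hemescan.structure_io import (
    Atom,
    NoPolymerError,
    StructureParseError,
    detect_heme_groups,
    read_structure,
    structure_to_pdb_string,
    write_site_pdb,
    write_structure_pdb,
)

from conftest import assert_structures_close


MINI_PDB = """\
ATOM      1  N   HIS A 144      11.000  10.000   9.000  1.00 20.00           N
ATOM      2  CA  HIS A 144      12.400  10.200   9.100  1.00 20.00           C
ATOM      3  CB  HIS A 144      13.100  11.300  10.000  1.00 20.00           C
ATOM      4  NE2 HIS A 144      14.500  11.100  10.400  1.00 20.00           N
ATOM      5  N   GLY A 145      12.000  13.000  12.000  1.00 30.00           N
ATOM      6  CA  GLY A 145      13.300  13.600  12.200  1.00 30.00           C
ATOM      7  C   GLY A 145      13.200  15.100  12.500  1.00 30.00           C
ATOM      8  N   TYR A 146      10.000  16.000  13.000  1.00 25.00           N
ATOM      9  CA  TYR A 146      10.900  16.900  13.700  1.00 25.00           C
ATOM     10  CB  TYR A 146      10.200  18.200  14.100  1.00 25.00           C
ATOM     11  OH  TYR A 146       9.100  20.200  15.300  1.00 25.00           O
END
"""


def test_round_trip_preserves_coordinates_and_identity(tmp_path, toy):
    s, _ = toy
    path = tmp_path / "toy.pdb"
    write_structure_pdb(s, path)
    again = read_structure(path)
    assert_structures_close(s, again, tol=1e-3 + 1e-9)
    # written at 3 decimals, so a second round trip is exact
    path2 = tmp_path / "toy2.pdb"
    write_structure_pdb(again, path2)
    assert_structures_close(again, read_structure(path2), tol=0.0)


def test_small_pdb_parses_with_author_numbering(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    s = read_structure(p)
    assert [r.name for r in s.residues] == ["HIS", "GLY", "TYR"]
    assert [r.seq_num for r in s.residues] == [144, 145, 146]
    np.testing.assert_allclose(
        s.residues[0].get_atom("NE2").coord, [14.5, 11.1, 10.4]
    )
    assert s.residues[1].atoms[0].bfactor == 30.0


def test_altloc_highest_occupancy_wins(tmp_path):
    text = (
        "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N\n"
        "ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.40 10.00           C\n"
        "ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.60 10.00           C\n"
        "ATOM      4  CB  SER A   1       1.500   1.400   0.000  1.00 10.00           C\n"
        "END\n"
    )
    p = tmp_path / "alt.pdb"
    p.write_text(text)
    s = read_structure(p)
    (res,) = s.residues
    assert len([a for a in res.atoms if a.name == "CA"]) == 1
    assert res.get_atom("CA").coord[0] == 2.0  # altloc B, occupancy 0.6
    assert res.get_atom("CA").altloc == ""


def test_altloc_occupancy_tie_prefers_letter_a(tmp_path):
    text = (
        "ATOM      1  CA ATHR A   1       1.000   0.000   0.000  0.50 10.00           C\n"
        "ATOM      2  CA BTHR A   1       2.000   0.000   0.000  0.50 10.00           C\n"
        "ATOM      3  N   THR A   1       0.000   1.000   0.000  1.00 10.00           N\n"
        "END\n"
    )
    p = tmp_path / "tie.pdb"
    p.write_text(text)
    s = read_structure(p)
    assert s.residues[0].get_atom("CA").coord[0] == 1.0


def test_first_model_only(tmp_path):
    text = (
        "MODEL        1\n"
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00 10.00           C\n"
        "ENDMDL\n"
        "END\n"
    )
    p = tmp_path / "nmr.pdb"
    p.write_text(text)
    s = read_structure(p)
    assert len(s.residues) == 1
    np.testing.assert_allclose(s.residues[0].get_atom("CA").coord, [1.0, 2.0, 3.0])


def test_hydrogens_and_waters_dropped(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
        "ATOM      2  HA  ALA A   1       1.500   2.500   3.000  1.00 10.00           H\n"
        "HETATM    3  O   HOH A 101       5.000   5.000   5.000  1.00 10.00           O\n"
        "END\n"
    )
    p = tmp_path / "hw.pdb"
    p.write_text(text)
    s = read_structure(p)
    assert len(s.residues) == 1
    assert [a.name for a in s.residues[0].atoms] == ["CA"]


def test_out_of_range_occupancy_clamped_with_warning(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.20 10.00           C\n"
        "END\n"
    )
    p = tmp_path / "occ.pdb"
    p.write_text(text)
    with pytest.warns(UserWarning, match="occupancy"):
        s = read_structure(p)
    assert s.residues[0].atoms[0].occupancy == 1.0


def test_parse_errors(tmp_path):
    missing = tmp_path / "nope.pdb"
    with pytest.raises(StructureParseError):
        read_structure(missing)
    empty = tmp_path / "empty.pdb"
    empty.write_text("")
    with pytest.raises(StructureParseError):
        read_structure(empty)
    heme_only = tmp_path / "hemeonly.pdb"
    heme_only.write_text(
        "HETATM    1 FE   HEM A 500       0.000   0.000   0.000  1.00 10.00          FE\nEND\n"
    )
    with pytest.raises(NoPolymerError):
        read_structure(heme_only)


def test_mmcif_reading_matches_pdb(tmp_path, toy):
    import gemmi

    s, _ = toy
    pdb_path = tmp_path / "toy.pdb"
    write_structure_pdb(s, pdb_path)
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "toy.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    s_cif = read_structure(cif_path, format_hint="mmcif")
    s_pdb = read_structure(pdb_path, format_hint="pdb")
    assert len(s_cif.residues) == len(s_pdb.residues)
    np.testing.assert_allclose(
        s_cif.protein_atom_coords(), s_pdb.protein_atom_coords(), atol=1e-3
    )


def test_detect_heme_groups(toy):
    s, gt = toy
    groups = detect_heme_groups(s)
    assert len(groups) == 1
    g = groups[0]
    assert g.code == "HEM"
    assert g.fe_atom.element == "FE"
    np.testing.assert_allclose(g.fe_coord, gt.fe_coord)


def test_detect_heme_requires_iron(toy):
    s, _ = toy
    s2 = s.copy()
    heme = next(r for r in s2.residues if r.is_hetero)
    # add a second heme-coded residue with the iron stripped
    import copy

    stripped = heme.copy()
    stripped.name = "HEC"
    stripped.seq_num = 502
    stripped.atoms = [a for a in stripped.atoms if a.name != "FE"]
    for a in stripped.atoms:
        a.coord = a.coord + np.array([40.0, 0.0, 0.0])
    s2.residues.append(stripped)
    with pytest.warns(UserWarning, match="without Fe"):
        groups = detect_heme_groups(s2)
    assert [g.code for g in groups] == ["HEM"]


def test_detect_heme_empty_and_order_invariance(toy):
    s, _ = toy
    protein_only = s.copy()
    protein_only.residues = [r for r in protein_only.residues if not r.is_hetero]
    assert detect_heme_groups(protein_only) == []

    shuffled = s.copy()
    for r in shuffled.residues:
        r.atoms = list(reversed(r.atoms))
    groups = detect_heme_groups(shuffled)
    assert len(groups) == 1
    assert groups[0].fe_atom.name == "FE"


def test_plddt_column_preserved(tmp_path):
    s, _ = make_toy_heme_protein(FixtureSpec(seed=5, plddt_profile=77.5))
    assert s.source_kind == "predicted_model"
    p = tmp_path / "af.pdb"
    write_structure_pdb(s, p)
    again = read_structure(p, source_kind="predicted_model")
    bfs = [a.bfactor for r in again.residues for a in r.atoms]
    assert all(0.0 <= b <= 100.0 for b in bfs)
    assert all(b == 77.5 for b in bfs)


def test_write_site_pdb_round_trip(tmp_path, toy):
    s, gt = toy
    heme_atoms = [
        Atom(name=nm, element=("FE" if nm == "FE" else nm[0]), coord=c)
        for nm, c in zip(gt.heme_names, gt.heme_coords)
    ]
    matched = [s.find_residue(rid) for rid in gt.site_rids]
    out = tmp_path / "site.pdb"
    write_site_pdb(s, heme_atoms, matched, out, scores={"score": 16})
    text = out.read_text()
    assert "MATCHED RESIDUE" in text
    again = read_structure(out)
    hemes = detect_heme_groups(again)
    # the query's own heme plus the placed one
    assert len(hemes) == 2
    fes = sorted(np.linalg.norm(h.fe_coord - gt.fe_coord) for h in hemes)
    assert fes[0] <= 1e-3  # self-match: placed Fe equals source Fe at PDB precision
    assert fes[1] <= 1e-3


def test_write_site_pdb_empty_match_list(tmp_path, toy):
    s, gt = toy
    heme_atoms = [
        Atom(name=nm, element=("FE" if nm == "FE" else "C"), coord=c)
        for nm, c in zip(gt.heme_names, gt.heme_coords)
    ]
    out = tmp_path / "site.pdb"
    write_site_pdb(s, heme_atoms, [], out)
    again = read_structure(out)
    assert len(detect_heme_groups(again)) == 2


def test_nonfinite_heme_rejected(tmp_path, toy):
    s, _ = toy
    bad = Atom(name="FE", element="FE", coord=[0, 0, 0])
    bad.coord = np.array([np.nan, 0.0, 0.0])
    with pytest.raises(ValueError):
        write_site_pdb(s, [bad], [], tmp_path / "x.pdb")
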