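"""Structure reading, normalization, and solvent-frame parsing."""

import io

import numpy as np
import pytest

from dhtopo.data import NONPOLAR_GROUP_COUNTS, nonpolar_carbon_names
from dhtopo.structure_model import (
    EmptyStructureError,
    ParseError,
    SolventFrame,
    classify_nonpolar_groups,
    place_amide_hydrogens,
    read_solvent_frames,
    read_structure,
    structure_to_pdb_string,
    write_xyz_frames,
)
from dhtopo.synthetic_data import make_helix

from conftest import normalize, random_rotation

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.984   2.830   0.100  1.00  0.00           C
ATOM      8  C   GLY A   2       5.480   2.700   0.200  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.600   0.300  1.00  0.00           O
ATOM     10  N   SER A   3       6.170   3.830   0.200  1.00  0.00           N
ATOM     11  CA  SER A   3       7.620   3.840   0.300  1.00  0.00           C
ATOM     12  C   SER A   3       8.200   5.240   0.300  1.00  0.00           C
ATOM     13  O   SER A   3       7.480   6.240   0.300  1.00  0.00           O
ATOM     14  CB  SER A   3       8.170   3.050   1.500  1.00  0.00           C
ATOM     15  OG  SER A   3       7.620   1.750   1.600  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


class TestReadStructure:
    def test_minimal_three_residues(self):
        s = read_structure(io.StringIO(MINIMAL_PDB))
        assert s.n_residues == 3
        assert [r.name for r in s.residues] == ["ALA", "GLY", "SER"]
        bb = s.backbone_index(s.residues[0])
        assert bb["N"].name == "N" and bb["CA"].name == "CA"
        assert bb["O"].element == "O"
        assert all(r.is_complete for r in s.residues)

    def test_altloc_highest_occupancy_retained(self):
        s = read_structure(io.StringIO(ALTLOC_PDB))
        ca = s.residues[0].get("CA")
        np.testing.assert_allclose(ca.position, [1.458, 0.0, 0.0])
        assert ca.altloc == ""
        # exactly one CA kept
        assert sum(1 for a in s.residues[0].atoms.values() if a.name == "CA") == 1

    def test_waters_routed_to_solvent(self):
        text = MINIMAL_PDB.replace(
            "END",
            "HETATM   16  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O\nEND",
        )
        s = read_structure(io.StringIO(text))
        assert s.n_residues == 3
        assert s.solvent is not None and s.solvent.n_waters == 1

    def test_empty_structure_raises(self):
        with pytest.raises((EmptyStructureError, ParseError)):
            read_structure(io.StringIO("HETATM    1  O   HOH A   1       0.0     0.0     0.0\nEND\n"))

    def test_roundtrip_preserves_classification(self, helix12):
        text = structure_to_pdb_string(helix12)
        again = normalize(read_structure(io.StringIO(text)))
        assert again.n_residues == helix12.n_residues
        key = lambda s: sorted(
            (a.chain_id, a.residue_index, a.name) for a in s.nonpolar_groups
        )
        assert key(again) == key(helix12)


class TestAmideHydrogens:
    def test_geometry_trans_peptide(self, helix12):
        for res in helix12.residues[1:]:
            h = res.get("H")
            assert h is not None
            n = res.atoms["N"].position
            assert np.linalg.norm(h.position - n) == pytest.approx(1.0, abs=1e-9)
            # H lies opposite the bisector: roughly anti to CA and C(prev)
            ca = res.atoms["CA"].position
            u = (h.position - n) / np.linalg.norm(h.position - n)
            v = (ca - n) / np.linalg.norm(ca - n)
            assert float(u @ v) < -0.3

    def test_n_terminus_has_no_h(self, helix12):
        assert helix12.residues[0].get("H") is None

    def test_proline_gets_no_h(self):
        s = make_helix(6)
        s.residues[3].name = "PRO"
        for atom in s.residues[3].atoms.values():
            atom.residue_name = "PRO"
        place_amide_hydrogens(s)
        assert s.residues[3].get("H") is None
        assert s.residues[4].get("H") is not None

    def test_idempotent_on_existing_hydrogens(self):
        s = place_amide_hydrogens(make_helix(6))
        before = {r.number: r.atoms["H"].position.copy() for r in s.residues if "H" in r.atoms}
        place_amide_hydrogens(s)
        for r in s.residues:
            if r.number in before:
                np.testing.assert_array_equal(r.atoms["H"].position, before[r.number])


class TestNonpolarClassification:
    # hand-derived: side-chain carbons with no covalent N/O/S neighbor
    HAND_TABLE = {
        "GLY": 0, "ALA": 1, "VAL": 3, "LEU": 4, "ILE": 4, "PRO": 2,
        "PHE": 7, "TRP": 7, "MET": 1, "SER": 0, "THR": 1, "CYS": 0,
        "TYR": 6, "ASN": 1, "GLN": 2, "ASP": 1, "GLU": 2, "LYS": 3,
        "ARG": 2, "HIS": 1,
    }

    @pytest.mark.parametrize("resname,count", sorted(HAND_TABLE.items()))
    def test_counts_match_hand_table(self, resname, count):
        assert NONPOLAR_GROUP_COUNTS[resname] == count

    def test_polyalanine_decamer_has_ten_groups(self):
        s = classify_nonpolar_groups(make_helix(10))
        assert len(s.nonpolar_groups) == 10
        assert all(a.name == "CB" for a in s.nonpolar_groups)

    def test_ser_cb_excluded_unless_relaxed(self):
        assert "CB" not in nonpolar_carbon_names("SER")
        assert "CB" in nonpolar_carbon_names("SER", include_heteroatom_bonded=True)

    def test_nonstandard_residue_contributes_nothing(self):
        s = make_helix(5)
        s.residues[2].name = "XYZ"
        classify_nonpolar_groups(s)
        assert all(a.residue_name != "XYZ" for a in s.nonpolar_groups)

    def test_rigid_body_invariance(self, helix12):
        rng = np.random.default_rng(7)
        rot = random_rotation(rng)
        moved = helix12.transformed(rot, np.array([5.0, -3.0, 11.0]))
        classify_nonpolar_groups(moved)
        assert len(moved.nonpolar_groups) == len(helix12.nonpolar_groups)


class TestSolventFrames:
    def test_xyz_roundtrip(self, tmp_path):
        o = np.array([[0.0, 0.0, 0.0], [2.8, 0.0, 0.0]])
        h = np.array(
            [[[1.0, 0.0, 0.0], [-0.3, 0.95, 0.0]], [[1.8, 0.0, 0.0], [3.1, 0.95, 0.0]]]
        )
        frame = SolventFrame(frame_index=0, oxygens=o, hydrogens=h)
        path = tmp_path / "w.xyz"
        write_xyz_frames([frame, frame], path)
        frames = read_solvent_frames(path)
        assert len(frames) == 2
        np.testing.assert_allclose(frames[0].oxygens, o, atol=1e-3)
        np.testing.assert_allclose(frames[0].hydrogens, h, atol=1e-3)

    def test_multimodel_pdb_frames(self, tmp_path):
        text = (
            "MODEL     1\n"
            "HETATM    1  O   HOH W   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ENDMDL\n"
            "MODEL     2\n"
            "HETATM    1  O   HOH W   1       1.000   0.000   0.000  1.00  0.00           O\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "frames.pdb"
        path.write_text(text)
        frames = read_solvent_frames(path)
        assert len(frames) == 2
        assert frames[1].oxygens[0, 0] == pytest.approx(1.0)

    def test_oh_distance_validated(self):
        with pytest.raises(Exception):
            SolventFrame(
                frame_index=0,
                oxygens=np.zeros((1, 3)),
                hydrogens=np.array([[[2.0, 0.0, 0.0], [0.0, 1.0, 0.0]]]),
            )

    def test_bad_xyz_line_names_location(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("# frame\nO 0 0 0\nQ 1 2 3\n")
        with pytest.raises(ParseError, match="line 3"):
            read_solvent_frames(path)
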