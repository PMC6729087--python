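import numpy as np
import pytest

from metadock.errors import (
    AmbiguityError,
    EmptyStructureError,
    PDBParseError,
    PDBQTParseError,
    SelectionError,
)
from metadock.structures_io import (
    Box,
    prepare_complex,
    read_pdb,
    read_pdbqt,
    read_pdbqt_poses,
    write_pdb,
    write_pdbqt,
    write_pose_set_pdbqt,
    _remove_nonpolar_hydrogens,
)
from metadock.torsion_tree import build_torsion_tree

from .conftest import chain_ligand, ring_ligand


SINGLE_ATOM = (
    "ATOM      1  C   UNK A   1       1.000   2.000   3.000  1.00  0.00"
    "           C\nEND\n"
)


class TestReadPDB:
    def test_single_atom_fields(self):
        structure = read_pdb(SINGLE_ATOM)
        (atom,) = structure.first_model.atoms
        assert atom.element == "C"
        assert atom.serial == 1
        assert np.allclose(atom.coords, [1.0, 2.0, 3.0])
        assert atom.is_heavy

    def test_multi_model_structure(self):
        text = (
            "MODEL        1\n" + SINGLE_ATOM.replace("END\n", "ENDMDL\n")
            + "MODEL        2\n"
            + SINGLE_ATOM.replace("1.000", "4.000").replace("END\n", "ENDMDL\n")
            + "END\n"
        )
        structure = read_pdb(text)
        assert len(structure.models) == 2
        assert np.allclose(structure.models[1].atoms[0].coords[0], 4.0)

    def test_round_trip_preserves_serials_and_coords(self, complex_pdb_text):
        first = read_pdb(complex_pdb_text)
        again = read_pdb(write_pdb(first))
        a1 = first.first_model.atoms
        a2 = again.first_model.atoms
        assert [a.serial for a in a1] == [a.serial for a in a2]
        assert np.allclose(
            [a.coords for a in a1], [a.coords for a in a2], atol=1e-3
        )

    def test_malformed_atom_line_raises(self):
        bad = SINGLE_ATOM.replace("   1.000", "   x.000")
        with pytest.raises(PDBParseError):
            read_pdb(bad)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyStructureError):
            read_pdb("REMARK nothing here\nEND\n")


class TestPrepareComplex:
    def test_waters_removed(self, complex_pdb_text):
        prepared = prepare_complex(read_pdb(complex_pdb_text), "LIG")
        names = {a.residue_name for a in prepared.receptor.atoms}
        names |= {a.residue_name for a in prepared.ligand.atoms}
        assert "HOH" not in names

    def test_first_ligand_instance_kept(self, complex_pdb_text):
        prepared = prepare_complex(read_pdb(complex_pdb_text), "LIG")
        # second copy is shifted +30 A in x; all kept atoms are near origin
        assert prepared.ligand.reference_coords[:, 0].max() < 10.0
        # and the other copy does not end up in the receptor either
        assert all(a.residue_name != "LIG" for a in prepared.receptor.atoms)

    def test_polar_hydrogen_rule(self, complex_pdb_text):
        prepared = prepare_complex(read_pdb(complex_pdb_text), "LIG")
        # 4 C + 1 O survive; of 4 H only the hydroxyl H remains
        elements = [a.element for a in prepared.ligand.atoms]
        assert elements.count("C") == 4
        assert elements.count("O") == 1
        assert elements.count("H") == 1
        assert len(prepared.ligand.atoms) == 6

    def test_lone_ion_removed(self, complex_pdb_text):
        prepared = prepare_complex(read_pdb(complex_pdb_text), "LIG")
        assert all(a.element != "NA" for a in prepared.receptor.atoms)

    def test_box_contains_ligand(self, complex_pdb_text):
        prepared = prepare_complex(read_pdb(complex_pdb_text), "LIG")
        assert prepared.box.contains(prepared.ligand.reference_coords)

    def test_missing_ligand_raises(self, complex_pdb_text):
        with pytest.raises(SelectionError):
            prepare_complex(read_pdb(complex_pdb_text), "XYZ")

    def test_ambiguous_selector_raises(self, complex_pdb_text):
        with pytest.raises(AmbiguityError):
            prepare_complex(
                read_pdb(complex_pdb_text),
                lambda r: r.name in {"LIG", "ALA"},
            )

    def test_hydrogen_stripping_idempotent(self, complex_pdb_text):
        prepared = prepare_complex(read_pdb(complex_pdb_text), "LIG")
        once = list(prepared.ligand.atoms)
        twice = _remove_nonpolar_hydrogens(once)
        assert twice == once


class TestPDBQT:
    def test_rigid_ligand_degenerate_tree(self):
        lig = ring_ligand(3)
        tree = build_torsion_tree(lig)
        text = write_pdbqt(lig, tree)
        assert "ROOT" in text and "ENDROOT" in text
        assert "BRANCH" not in text.replace("ENDBRANCH", "")
        assert "TORSDOF 0" in text

    def test_branch_count_matches_tree(self):
        lig = chain_ligand(5)  # 2 rotatable bonds
        tree = build_torsion_tree(lig)
        text = write_pdbqt(lig, tree)
        assert text.count("BRANCH") == 4  # 2 BRANCH + 2 ENDBRANCH
        assert "TORSDOF 2" in text

    def test_round_trip_coords_and_tree(self):
        lig = chain_ligand(6)
        tree = build_torsion_tree(lig)
        lig2, tree2 = read_pdbqt(write_pdbqt(lig, tree))
        assert lig2.n_atoms == lig.n_atoms
        assert np.abs(
            np.sort(lig2.reference_coords, axis=0)
            - np.sort(lig.reference_coords, axis=0)
        ).max() < 1e-3
        # the torsion tree must survive a write -> read -> write cycle
        assert len(tree2.branches) == len(tree.branches)
        text1 = write_pdbqt(lig, tree)
        text2 = write_pdbqt(lig2, tree2)
        branch_lines = lambda t: [l for l in t.splitlines() if "BRANCH" in l]
        assert branch_lines(text1) == branch_lines(text2)

    def test_multi_model_pose_set(self):
        lig = chain_ligand(4)
        tree = build_torsion_tree(lig)
        poses = [lig.reference_coords + i for i in range(3)]
        text = write_pose_set_pdbqt(lig, tree, poses, scores=[-1.0, -0.5, 0.0])
        coords, scores = read_pdbqt_poses(text)
        assert len(coords) == 3
        assert all(c.shape == (4, 3) for c in coords)
        assert scores[0] == pytest.approx(-1.0)

    def test_unclosed_branch_raises(self):
        lig = chain_ligand(5)
        tree = build_torsion_tree(lig)
        text = write_pdbqt(lig, tree)
        broken = "\n".join(
            l for l in text.splitlines() if not l.startswith("ENDBRANCH")
        )
        with pytest.raises(PDBQTParseError):
            read_pdbqt(broken)


class TestBox:
    def test_positive_extents_required(self):
        with pytest.raises(ValueError):
            Box((0.0, 0.0, 0.0), (1.0, -1.0, 1.0))

    def test_around_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [2.0, 4.0, 6.0]])
        box = Box.around_points(pts, 1.0)
        assert box.contains(pts)
        assert np.allclose(box.extents, [4.0, 6.0, 8.0])
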