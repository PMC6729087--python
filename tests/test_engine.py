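import os
import stat
import sys

import numpy as np
import pytest

from metadock.engine import (
    EngineConfig,
    PosePool,
    ScoreField,
    dock,
    dock_external,
    grid_search_best_position,
    randomize_conformation,
    score_pose,
)
from metadock.errors import EngineFailureError, PlacementError
from metadock.fragmenter import whole_ligand_fragment
from metadock.geometry import rotation_matrix
from metadock.structures_io import Box, Ligand, Receptor, write_pdbqt, write_pose_set_pdbqt
from metadock.torsion_tree import build_torsion_tree

from .conftest import chain_ligand, make_atom


def _one_atom_ligand(pos):
    a = make_atom(1, pos)
    return Ligand(atoms=[a], bonds=[], reference_coords=np.array([pos], float))


def _one_atom_receptor(pos):
    return Receptor(atoms=[make_atom(1, pos, resname="REC", chain="R")])


class TestScorePose:
    def test_contact_distance_gives_well_depth(self):
        lig = _one_atom_ligand([0.0, 0.0, 0.0])
        rec = _one_atom_receptor([3.8, 0.0, 0.0])
        assert score_pose(rec, lig.reference_coords, lig) == pytest.approx(-0.05)

    def test_clash_distance_value(self):
        lig = _one_atom_ligand([0.0, 0.0, 0.0])
        rec = _one_atom_receptor([3.3, 0.0, 0.0])
        expected = -0.05 * np.exp(-1.0) + 0.8 * 0.25
        assert score_pose(rec, lig.reference_coords, lig) == pytest.approx(
            expected, abs=1e-9
        )

    def test_outside_cutoff_is_zero(self):
        lig = _one_atom_ligand([0.0, 0.0, 0.0])
        rec = _one_atom_receptor([20.0, 0.0, 0.0])
        assert score_pose(rec, lig.reference_coords, lig) == 0.0

    def test_rigid_transform_invariance(self):
        lig = chain_ligand(5)
        rec = Receptor(
            atoms=[make_atom(i + 1, [3.8, 1.5 * i, 0.5], resname="REC")
                   for i in range(4)]
        )
        base = score_pose(rec, lig.reference_coords, lig)
        R = rotation_matrix([1.0, 2.0, 0.5], 37.0)
        t = np.array([5.0, -3.0, 2.0])
        rec2 = Receptor(
            atoms=[make_atom(a.serial, a.coords @ R.T + t, resname="REC")
                   for a in rec.atoms]
        )
        moved = score_pose(rec2, lig.reference_coords @ R.T + t, lig)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_numba_kernel_matches_numpy(self):
        rng = np.random.default_rng(3)
        lig = chain_ligand(6)
        rec = Receptor(
            atoms=[make_atom(i + 1, rng.uniform(-5, 5, 3), resname="REC")
                   for i in range(20)]
        )
        field = ScoreField(rec, lig)
        for _ in range(5):
            coords = lig.reference_coords + rng.normal(scale=2.0, size=(6, 3))
            assert field.score_fast(coords) == pytest.approx(
                field.score(coords), abs=1e-9
            )


class TestRandomize:
    def _setup(self):
        lig = chain_ligand(6)
        tree = build_torsion_tree(lig)
        frag = whole_ligand_fragment(lig, tree)
        box = Box((0.0, 0.0, 0.0), (14.0, 14.0, 14.0))
        return frag, box

    def test_atoms_inside_box(self):
        frag, box = self._setup()
        for seed in range(10):
            pose = randomize_conformation(frag, box, np.random.default_rng(seed))
            assert box.contains(pose.coords)

    def test_same_seed_bitwise_identical(self):
        frag, box = self._setup()
        p1 = randomize_conformation(frag, box, np.random.default_rng(42))
        p2 = randomize_conformation(frag, box, np.random.default_rng(42))
        assert np.array_equal(p1.coords, p2.coords)

    def test_different_seeds_give_different_torsions(self):
        frag, box = self._setup()
        hits = 0
        n = 200
        for s in range(n):
            a = randomize_conformation(frag, box, np.random.default_rng(2 * s))
            b = randomize_conformation(frag, box, np.random.default_rng(2 * s + 1))
            if np.abs(a.torsion_values - b.torsion_values).max() > 1.0:
                hits += 1
        assert hits / n >= 0.99

    def test_occupied_box_raises_placement_error(self):
        frag, _ = self._setup()
        # a box stuffed with receptor atoms so every placement clashes hard
        grid = np.stack(np.meshgrid(*[np.arange(-6, 7, 2.0)] * 3), -1).reshape(-1, 3)
        rec = Receptor(
            atoms=[make_atom(i + 1, g, resname="REC") for i, g in enumerate(grid)]
        )
        box = Box((0.0, 0.0, 0.0), (8.0, 8.0, 8.0))
        with pytest.raises(PlacementError):
            randomize_conformation(
                frag, box, np.random.default_rng(0), receptor=rec, max_tries=20
            )


class TestDock:
    def test_single_atom_lands_on_grid_optimum(self, shell_probe):
        receptor, ligand, box = shell_probe
        grid_pt, _ = grid_search_best_position(receptor, box, step=0.25)
        tree = build_torsion_tree(ligand)
        frag = whole_ligand_fragment(ligand, tree)
        pool = dock(receptor, frag, EngineConfig(box=box, exhaustiveness=4, seed=9))
        assert np.linalg.norm(pool.best_pose.coords[0] - grid_pt) < 0.5

    def test_pool_respects_num_modes_and_energy_range(self, shell_probe):
        receptor, ligand, box = shell_probe
        tree = build_torsion_tree(ligand)
        frag = whole_ligand_fragment(ligand, tree)
        cfg = EngineConfig(box=box, exhaustiveness=4, num_modes=3,
                           energy_range=0.5, seed=1)
        pool = dock(receptor, frag, cfg)
        assert len(pool.poses) <= 3
        assert all(p.score <= pool.best_score + 0.5 + 1e-12 for p in pool.poses)

    def test_fixed_seed_reproducible(self, shell_probe):
        receptor, ligand, box = shell_probe
        tree = build_torsion_tree(ligand)
        frag = whole_ligand_fragment(ligand, tree)
        cfg = EngineConfig(box=box, exhaustiveness=2, seed=7)
        p1 = dock(receptor, frag, cfg)
        p2 = dock(receptor, frag, cfg)
        assert len(p1) == len(p2)
        for a, b in zip(p1.poses, p2.poses):
            assert np.array_equal(a.coords, b.coords)
            assert a.score == b.score

    def test_poses_stay_near_box(self, small_planted):
        prep = small_planted.prepared()
        tree = build_torsion_tree(prep.ligand)
        frag = whole_ligand_fragment(prep.ligand, tree)
        pool = dock(prep.receptor, frag,
                    EngineConfig(box=prep.box, exhaustiveness=1, seed=3))
        radius = np.linalg.norm(
            prep.ligand.reference_coords
            - prep.ligand.reference_coords.mean(0), axis=1
        ).max()
        for p in pool.poses:
            assert prep.box.contains(p.coords, margin=radius)

    def test_more_exhaustiveness_not_worse_on_average(self, shell_probe):
        receptor, ligand, box = shell_probe
        tree = build_torsion_tree(ligand)
        frag = whole_ligand_fragment(ligand, tree)
        best = {e: [] for e in (2, 16)}
        for seed in range(30):
            for e in best:
                cfg = EngineConfig(box=box, exhaustiveness=e, seed=seed)
                best[e].append(dock(receptor, frag, cfg).best_score)
        assert np.mean(best[16]) <= np.mean(best[2]) + 1e-12


class TestDockExternal:
    def _pdbqt_pair(self):
        lig = chain_ligand(4)
        tree = build_torsion_tree(lig)
        lig_text = write_pdbqt(lig, tree)
        rec_text = "ATOM      1  C1  REC R   1       3.800   0.000   0.000" \
                   "  1.00  0.00     0.000 C \n"
        out_text = write_pose_set_pdbqt(
            lig, tree,
            [lig.reference_coords, lig.reference_coords + 1.0],
            scores=[-7.5, -6.0],
        )
        return rec_text, lig_text, out_text

    def test_absent_binary_raises(self):
        rec, lig, _ = self._pdbqt_pair()
        cfg = EngineConfig(box=Box((0, 0, 0), (10, 10, 10)))
        with pytest.raises(EngineFailureError):
            dock_external(rec, lig, cfg, "/no/such/binary")

    def test_fake_engine_round_trip(self, tmp_path):
        rec, lig, out = self._pdbqt_pair()
        fixture = tmp_path / "result.pdbqt"
        fixture.write_text(out)
        script = tmp_path / "fakevina"
        script.write_text(
            "#!" + sys.executable + "\n"
            "import shutil, sys\n"
            "args = dict(zip(sys.argv[1::2], sys.argv[2::2]))\n"
            "assert args['--exhaustiveness'] == '4'\n"
            "assert '--seed' in args and '--center_x' in args\n"
            f"shutil.copy({str(fixture)!r}, args['--out'])\n"
        )
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        cfg = EngineConfig(box=Box((0, 0, 0), (10, 10, 10)), exhaustiveness=4)
        pool = dock_external(rec, lig, cfg, str(script))
        assert len(pool.poses) == 2  # one per MODEL
        assert pool.best_score == pytest.approx(-7.5)
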