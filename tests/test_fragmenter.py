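import numpy as np
import pytest

from metadock.engine import Pose
from metadock.errors import ConfigError, RigidLigandError
from metadock.fragmenter import (
    FragmentState,
    expand_fragment,
    initial_fragment,
    make_schedule,
    select_for_expansion,
    whole_ligand_fragment,
)
from metadock.synthetic import make_branched_ligand
from metadock.torsion_tree import build_torsion_tree, measure_branch_dihedral

from .conftest import chain_ligand


class TestMakeSchedule:
    @pytest.mark.parametrize(
        "n,r,b,expected_counts,expected_k",
        [
            (15, 3, 3, (9, 12, 15), 9),
            (7, 1, 3, (7,), 7),
            (5, 3, 3, (2, 5), 2),  # r clamped to 2
            (10, 4, 2, (4, 6, 8, 10), 4),
        ],
    )
    def test_fragment_size_algebra(self, n, r, b, expected_counts, expected_k):
        sched = make_schedule(n, r, b)
        assert sched.explored_counts == expected_counts
        assert sched.active_count == expected_k
        assert sched.explored_counts[-1] == n

    def test_rigid_ligand_signals(self):
        with pytest.raises(RigidLigandError):
            make_schedule(0, 3, 3)

    def test_bad_config_raises(self):
        with pytest.raises(ConfigError):
            make_schedule(5, 0, 3)
        with pytest.raises(ConfigError):
            make_schedule(5, 3, 0)


class TestInitialFragment:
    def test_k_equals_n_gives_whole_ligand(self):
        lig = make_branched_ligand(5, 2)
        tree = build_torsion_tree(lig)
        frag = initial_fragment(lig, tree, make_schedule(5, 1, 3))
        assert frag.atoms == tuple(range(lig.n_atoms))
        assert set(frag.active) == set(range(5))

    def test_chain_small_fragment(self):
        lig = chain_ligand(6)  # N=3
        tree = build_torsion_tree(lig)
        frag = initial_fragment(lig, tree, make_schedule(3, 3, 1))
        assert len(frag.active) == 1
        assert len(frag.atoms) < lig.n_atoms

    @pytest.mark.parametrize("seed", range(5))
    def test_fragment_always_connected(self, seed):
        import networkx as nx

        lig = make_branched_ligand(6 + seed, seed)
        tree = build_torsion_tree(lig)
        sched = make_schedule(tree.n_dofs, 3, 2)
        frag = initial_fragment(lig, tree, sched)
        sub = lig.graph().subgraph(frag.atoms)
        assert nx.is_connected(sub)


def _reference_pose(frag: FragmentState) -> Pose:
    ref = frag.ligand.reference_coords[list(frag.atoms)]
    return Pose(coords=ref, score=0.0,
                torsion_values=np.zeros(len(frag.active)))


class TestExpandFragment:
    def test_reference_geometry_identity(self):
        lig = make_branched_ligand(6, 3)
        tree = build_torsion_tree(lig)
        sched = make_schedule(6, 3, 2)
        frag = initial_fragment(lig, tree, sched)
        grown = expand_fragment(frag, _reference_pose(frag), lig, tree, sched)
        ref = lig.reference_coords[list(grown.atoms)]
        assert np.abs(grown.coords - ref).max() < 1e-6

    def test_active_count_constant_and_explored_grows(self):
        lig = make_branched_ligand(8, 5)
        tree = build_torsion_tree(lig)
        sched = make_schedule(8, 3, 2)
        frag = initial_fragment(lig, tree, sched)
        k = sched.active_count
        assert len(frag.active) == k
        grown = expand_fragment(frag, _reference_pose(frag), lig, tree, sched)
        assert len(grown.explored) == len(frag.explored) + 2
        assert len(grown.active) == min(k, len(grown.explored))
        assert set(grown.active) & set(grown.explored[-2:]) == set(
            grown.explored[-2:]
        )

    def test_frozen_dihedrals_preserved(self):
        from metadock.engine import set_active_torsions

        lig = make_branched_ligand(7, 6)
        tree = build_torsion_tree(lig)
        sched = make_schedule(7, 3, 2)
        frag = initial_fragment(lig, tree, sched)
        rng = np.random.default_rng(4)
        coords = set_active_torsions(
            frag, frag.coords, rng.uniform(-180, 180, len(frag.active))
        )
        pose = Pose(coords=coords, score=0.0,
                    torsion_values=np.zeros(len(frag.active)))
        grown = expand_fragment(frag, pose, lig, tree, sched)
        for bi in grown.frozen:
            before = measure_branch_dihedral(
                lig, tree, bi, coords, index_map=frag.index_map
            )
            after = measure_branch_dihedral(
                lig, tree, bi, grown.coords, index_map=grown.index_map
            )
            diff = abs(before - after) % 360.0
            assert min(diff, 360.0 - diff) < 1e-6

    @pytest.mark.parametrize("n_dofs,seed", [(5, 1), (8, 2), (11, 3)])
    def test_full_schedule_reconstruction_identity(self, n_dofs, seed):
        lig = make_branched_ligand(n_dofs, seed)
        tree = build_torsion_tree(lig)
        sched = make_schedule(n_dofs, 3, 2)
        frag = initial_fragment(lig, tree, sched)
        sizes = [frag.n_atoms]
        while not frag.is_complete:
            frag = expand_fragment(frag, _reference_pose(frag), lig, tree, sched)
            sizes.append(frag.n_atoms)
        assert np.abs(frag.coords - lig.reference_coords).max() < 1e-6
        assert sizes == sorted(sizes) and len(set(sizes)) == len(sizes)


class _FakePool:
    def __init__(self, poses, fragment):
        self.poses = poses
        self.fragment = fragment


class TestSelectForExpansion:
    def _pool(self, coords_scores, lig):
        tree = build_torsion_tree(lig)
        frag = whole_ligand_fragment(lig, tree)
        poses = [
            Pose(coords=c, score=s, torsion_values=np.zeros(len(frag.active)))
            for c, s in coords_scores
        ]
        return _FakePool(poses, frag)

    def test_single_pose_returned(self):
        lig = chain_ligand(5)
        pool = self._pool([(lig.reference_coords, -5.0)], lig)
        assert len(select_for_expansion(pool, 5)) == 1

    def test_identical_poses_backfilled_by_score(self):
        lig = chain_ligand(5)
        c = lig.reference_coords
        pool = self._pool([(c, -5.0), (c, -4.0), (c, -3.0)], lig)
        kept = select_for_expansion(pool, 2, diversity_rmsd=1.0)
        assert [p.score for p in kept] == [-5.0, -4.0]

    def test_scores_non_decreasing(self):
        lig = chain_ligand(5)
        rng = np.random.default_rng(0)
        pool = self._pool(
            [(lig.reference_coords + rng.normal(size=(5, 3)),
              float(rng.normal())) for _ in range(20)],
            lig,
        )
        kept = select_for_expansion(pool, 8, diversity_rmsd=0.5)
        scores = [p.score for p in kept]
        assert scores == sorted(scores)
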