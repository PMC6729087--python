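import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from metadock.engine import Pose, PosePool
from metadock.errors import ConsistencyError, EmptyPoolError, MetadockError
from metadock.evaluation import (
    EvaluationRecord,
    benchmark_table,
    is_success,
    replicate_stats,
    rmsd_all_atom,
    top_rmsd,
    top_scoring,
)
from metadock.fragmenter import whole_ligand_fragment
from metadock.torsion_tree import build_torsion_tree

from .conftest import chain_ligand


def _pool(lig, coord_sets, scores):
    tree = build_torsion_tree(lig)
    frag = whole_ligand_fragment(lig, tree)
    poses = [
        Pose(coords=c, score=s, torsion_values=np.zeros(len(frag.active)))
        for c, s in zip(coord_sets, scores)
    ]
    return PosePool(poses=poses, fragment=frag)


class TestRMSD:
    def test_identical_is_zero(self):
        c = np.random.default_rng(0).normal(size=(7, 3))
        assert rmsd_all_atom(c, c) == 0.0

    def test_uniform_translation_is_its_norm(self):
        c = np.random.default_rng(1).normal(size=(9, 3))
        assert rmsd_all_atom(c, c + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_two_atom_hand_value(self):
        ref = np.zeros((2, 3))
        pose = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        assert rmsd_all_atom(ref, pose) == pytest.approx(np.sqrt(2.5))

    def test_hydrogens_excluded_via_mask(self):
        ref = np.zeros((3, 3))
        pose = np.array([[1.0, 0, 0], [1.0, 0, 0], [99.0, 0, 0]])
        mask = np.array([True, True, False])
        assert rmsd_all_atom(ref, pose, mask) == pytest.approx(1.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            rmsd_all_atom(np.zeros((3, 3)), np.zeros((4, 3)))

    coords = arrays(np.float64, (5, 3),
                    elements=st.floats(-50, 50, allow_nan=False))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=coords, b=coords, c=coords)
    def test_metric_properties(self, a, b, c):
        dab = rmsd_all_atom(a, b)
        assert dab >= 0.0
        assert dab == pytest.approx(rmsd_all_atom(b, a))
        assert rmsd_all_atom(a, a) == 0.0
        assert rmsd_all_atom(a, c) <= dab + rmsd_all_atom(b, c) + 1e-9


class TestTopRMSDAndScoring:
    def test_closest_pose_selected(self):
        lig = chain_ligand(4)
        ref = lig.reference_coords
        # two poses at the distances reported for a hard peptide redock
        pool = _pool(lig, [ref + 5.61 / np.sqrt(3), ref + 1.1 / np.sqrt(3)],
                     [-7.0, -6.0])
        _, r = top_rmsd(pool, lig)
        assert r == pytest.approx(1.1, abs=1e-9)

    def test_single_pose_pool(self):
        lig = chain_ligand(4)
        pool = _pool(lig, [lig.reference_coords + 2.0], [-1.0])
        pose, r = top_rmsd(pool, lig)
        assert pose is pool.poses[0]

    def test_agrees_with_brute_force_scan(self):
        lig = chain_ligand(5)
        rng = np.random.default_rng(7)
        coord_sets = [lig.reference_coords + rng.normal(scale=3.0, size=(5, 3))
                      for _ in range(300)]
        pool = _pool(lig, coord_sets, list(rng.normal(size=300)))
        _, r = top_rmsd(pool, lig)
        brute = min(
            rmsd_all_atom(lig.reference_coords, c, lig.heavy_mask)
            for c in coord_sets
        )
        assert r == pytest.approx(brute)

    def test_pooling_identity(self):
        lig = chain_ligand(5)
        rng = np.random.default_rng(8)
        sets = [lig.reference_coords + rng.normal(scale=2.0, size=(5, 3))
                for _ in range(40)]
        scores = list(rng.normal(size=40))
        a = _pool(lig, sets[:25], scores[:25])
        b = _pool(lig, sets[25:], scores[25:])
        merged = PosePool.merged([a, b])
        assert top_rmsd(merged, lig)[1] == pytest.approx(
            min(top_rmsd(a, lig)[1], top_rmsd(b, lig)[1])
        )

    def test_top_scoring_vs_top_rmsd_can_differ(self):
        lig = chain_ligand(4)
        ref = lig.reference_coords
        good_rmsd = ref + 1.0 / np.sqrt(3)
        bad_rmsd = ref + 4.0 / np.sqrt(3)
        pool = _pool(lig, [bad_rmsd, good_rmsd], [-9.0, -5.0])
        assert top_scoring(pool) is pool.poses[0]
        pose, _ = top_rmsd(pool, lig)
        assert pose is pool.poses[1]

    def test_score_tie_break_deterministic(self):
        lig = chain_ligand(4)
        ref = lig.reference_coords
        pool = _pool(lig, [ref + 1.0, ref + 2.0], [-5.0, -5.0])
        assert top_scoring(pool, lig) is pool.poses[0]
        assert top_scoring(pool, lig) is pool.poses[0]

    def test_empty_pool_raises(self):
        lig = chain_ligand(4)
        pool = _pool(lig, [], [])
        with pytest.raises(EmptyPoolError):
            top_rmsd(pool, lig)


class TestSuccessAndStats:
    @pytest.mark.parametrize(
        "rmsd,expected", [(1.1, True), (5.61, False), (2.0, False), (1.999, True)]
    )
    def test_strict_two_angstrom_threshold(self, rmsd, expected):
        assert is_success(rmsd) is expected

    def test_negative_rmsd_rejected(self):
        with pytest.raises(MetadockError):
            is_success(-0.1)

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3, 3, 3, 3, 3], (3.0, 0.0, 3.0)),
            ([1, 2, 3, 4, 5], (3.0, 1.5811, 1.0)),
            ([2.5], (2.5, 0.0, 2.5)),
        ],
    )
    def test_replicate_stats(self, values, expected):
        mean, sd, best = replicate_stats(values)
        assert mean == pytest.approx(expected[0])
        assert sd == pytest.approx(expected[1], abs=1e-4)
        assert best == pytest.approx(expected[2])

    def test_empty_raises(self):
        with pytest.raises(MetadockError):
            replicate_stats([])


class TestBenchmarkTable:
    def _records(self, values_by_complex):
        return [
            EvaluationRecord.from_values(cid, 5, 20, vals)
            for cid, vals in values_by_complex
        ]

    def test_rows_and_average(self):
        recs = self._records([("a", [1.0, 2.0]), ("b", [3.0, 5.0])])
        table, summary = benchmark_table({"proto": recs})
        assert len(table) == 3  # two complexes + average row
        avg = table.iloc[-1]
        assert avg["proto_mean"] == pytest.approx((1.5 + 4.0) / 2)

    def test_all_successful_zero_failure_rate(self):
        recs = self._records([("a", [1.0]), ("b", [0.5])])
        _, summary = benchmark_table({"p": recs})
        assert summary["p"]["failure_rate"] == 0.0

    def test_failure_rate_matches_direct_count(self):
        rng = np.random.default_rng(0)
        pairs = [(f"c{i}", list(rng.uniform(0.5, 4.0, size=5))) for i in range(30)]
        recs = self._records(pairs)
        _, summary = benchmark_table({"p": recs})
        direct = sum(1 for _, v in pairs if min(v) >= 2.0) / 30
        assert summary["p"]["failure_rate"] == pytest.approx(direct)

    def test_ragged_input_raises(self):
        a = self._records([("a", [1.0]), ("b", [2.0])])
        b = self._records([("a", [1.0])])
        with pytest.raises(ConsistencyError):
            benchmark_table({"p1": a, "p2": b})

    def test_success_rate_non_decreasing_in_replicates(self):
        rng = np.random.default_rng(1)
        values = list(rng.uniform(1.0, 4.0, size=8))
        flags = [
            EvaluationRecord.from_values("x", 3, 10, values[: n + 1]).success
            for n in range(8)
        ]
        assert flags == sorted(flags)
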