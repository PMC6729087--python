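"""Docking-engine contract plus the built-in seeded stochastic engine.

The built-in engine is deliberately simple and charge-free: a smooth
contact-based score (attractive Gaussian well at surface contact, quadratic
clash penalty) searched by repeated random placement followed by
derivative-free cyclic coordinate descent.  It is a test harness for the
meta-protocols, which are engine-agnostic: any Vina-compatible binary can
stand in through :func:`dock_external`.

Exhaustiveness has the usual meaning of "amount of independent sampling": a
docking call performs ``runs_per_exhaustiveness x exhaustiveness``
independent runs, each starting from a randomized conformation.
"""

from __future__ import annotations

import logging
import math
import os
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from ._kernels import min_contact_gap_kernel, refine_kernel, score_kernel
from .errors import (
    ConfigError,
    ConsistencyError,
    EmptyPoolError,
    EngineFailureError,
    PlacementError,
)
from .fragmenter import FragmentState, whole_ligand_fragment
from .geometry import random_rotation_matrix, rotate_about_axis
from .structures_io import Box, Ligand, Receptor, read_pdbqt, read_pdbqt_poses
from .torsion_tree import dihedral_reference_atoms, measure_branch_dihedral

logger = logging.getLogger(__name__)

__all__ = [
    "ELEMENT_RADII",
    "EngineConfig",
    "Pose",
    "PosePool",
    "ScoreField",
    "score_pose",
    "randomize_conformation",
    "dock",
    "dock_external",
    "grid_search_best_position",
]

#: per-element contact radii (A) used by the built-in score
ELEMENT_RADII = {"C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1}
DEFAULT_RADIUS = 1.8
CONTACT_CUTOFF = 8.0  # A; pairs beyond this contribute nothing
CLASH_GAP = -1.0  # A; random placements with a tighter receptor clash are rejected


def element_radius(element: str) -> float:
    return ELEMENT_RADII.get(element.upper(), DEFAULT_RADIUS)


@dataclass(frozen=True)
class EngineConfig:
    """Knobs of one docking call.

    ``exhaustiveness`` scales the number of independent runs (default 8);
    ``num_modes`` caps the returned binding modes (25); ``energy_range``
    drops poses scoring worse than best + range (10).  The remaining fields
    are internals of the built-in search.
    """

    box: Box
    exhaustiveness: int = 8
    num_modes: int = 25
    energy_range: float = 10.0
    seed: int = 0
    runs_per_exhaustiveness: int = 4
    cluster_rmsd: float = 1.0
    # refinement schedule: step halving from (2 A, 30 deg) to (0.01 A, 0.25 deg)
    step_translation: float = 2.0
    step_angle: float = 30.0
    min_step_translation: float = 0.01
    min_step_angle: float = 0.25
    convergence_tol: float = 1e-4
    max_cycles_per_level: int = 12
    # each run is a short basin-hopping chain: perturb + re-refine, with
    # Metropolis acceptance at ``hop_temperature`` (score units); the best
    # pose along the chain is returned
    mc_hops: int = 8
    hop_translation: float = 1.5
    hop_angle: float = 25.0
    hop_temperature: float = 0.05

    def __post_init__(self) -> None:
        if self.exhaustiveness < 1:
            raise ConfigError("exhaustiveness must be >= 1")
        if self.num_modes < 1:
            raise ConfigError("num_modes must be >= 1")
        if self.energy_range < 0:
            raise ConfigError("energy_range must be >= 0")

    @property
    def n_runs(self) -> int:
        return self.runs_per_exhaustiveness * self.exhaustiveness


@dataclass
class Pose:
    """One binding mode of the current fragment: coordinates plus score."""

    coords: np.ndarray
    score: float
    torsion_values: np.ndarray
    provenance: tuple = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.torsion_values = np.asarray(self.torsion_values, dtype=float)


@dataclass
class PosePool:
    """A scored set of poses of one fragment, sortable by score."""

    poses: list[Pose]
    fragment: FragmentState

    def __post_init__(self) -> None:
        for p in self.poses:
            if p.coords.shape != (self.fragment.n_atoms, 3):
                raise ConsistencyError("pose does not cover the fragment's atoms")

    def __len__(self) -> int:
        return len(self.poses)

    def sorted_by_score(self) -> list[Pose]:
        return sorted(self.poses, key=lambda p: p.score)

    @property
    def best_score(self) -> float:
        if not self.poses:
            raise EmptyPoolError("pool is empty")
        return min(p.score for p in self.poses)

    @property
    def best_pose(self) -> Pose:
        if not self.poses:
            raise EmptyPoolError("pool is empty")
        return min(enumerate(self.poses), key=lambda t: (t[1].score, t[0]))[1]

    @classmethod
    def merged(cls, pools: Sequence["PosePool"]) -> "PosePool":
        if not pools:
            raise EmptyPoolError("nothing to merge")
        n_atoms = pools[0].fragment.n_atoms
        atoms = pools[0].fragment.atoms
        for p in pools[1:]:
            if p.fragment.atoms != atoms or p.fragment.n_atoms != n_atoms:
                raise ConsistencyError("cannot merge pools over different atom sets")
        poses = [p for pool in pools for p in pool.poses]
        poses.sort(key=lambda p: p.score)
        return cls(poses=poses, fragment=pools[0].fragment)


class ScoreField:
    """Precomputed arrays for scoring one fragment against one receptor."""

    def __init__(
        self,
        receptor: Receptor,
        ligand: Ligand,
        atom_indices: Sequence[int] | None = None,
    ):
        if atom_indices is None:
            atom_indices = tuple(range(ligand.n_atoms))
        self.atom_indices = tuple(atom_indices)
        rec_heavy = receptor.heavy_mask
        self.rec = np.ascontiguousarray(receptor.coords[rec_heavy])
        rec_radii = np.array(
            [element_radius(e) for e, h in zip(receptor.elements, rec_heavy) if h]
        )
        self.heavy_idx = np.array(
            [i for i, a in enumerate(self.atom_indices) if ligand.atoms[a].is_heavy],
            dtype=np.int64,
        )
        lig_radii = np.array(
            [element_radius(ligand.atoms[self.atom_indices[i]].element)
             for i in self.heavy_idx]
        )
        self.sumr = np.ascontiguousarray(lig_radii[:, None] + rec_radii[None, :])
        self.cutoff = CONTACT_CUTOFF

        # intra-ligand nonbonded heavy pairs: graph distance >= 3 bonds
        g = ligand.graph()
        local_of = {a: i for i, a in enumerate(self.atom_indices)}
        near: set[tuple[int, int]] = set()
        for a in self.atom_indices:
            lengths = nx.single_source_shortest_path_length(g, a, cutoff=2)
            for w, _d in lengths.items():
                if w in local_of:
                    near.add((local_of[a], local_of[w]))
        int_i, int_j, int_sumr = [], [], []
        heavy_local = set(int(i) for i in self.heavy_idx)
        for i in range(len(self.atom_indices)):
            if i not in heavy_local:
                continue
            for j in range(i + 1, len(self.atom_indices)):
                if j not in heavy_local or (i, j) in near:
                    continue
                ri = element_radius(ligand.atoms[self.atom_indices[i]].element)
                rj = element_radius(ligand.atoms[self.atom_indices[j]].element)
                int_i.append(i)
                int_j.append(j)
                int_sumr.append(ri + rj)
        self.int_i = np.array(int_i, dtype=np.int64)
        self.int_j = np.array(int_j, dtype=np.int64)
        self.int_sumr = np.array(int_sumr, dtype=float)

    # reference NumPy implementation (the numba kernel mirrors this)
    def score(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float)
        lc = coords[self.heavy_idx]
        d = np.linalg.norm(lc[:, None, :] - self.rec[None, :, :], axis=-1)
        s = d - self.sumr
        within = d <= self.cutoff
        att = -0.05 * np.exp(-((s / 0.5) ** 2))
        rep = np.where(s < 0.0, 0.8 * s * s, 0.0)
        total = float(np.sum(np.where(within, att + rep, 0.0)))
        if len(self.int_i):
            dij = np.linalg.norm(coords[self.int_i] - coords[self.int_j], axis=1)
            si = dij - self.int_sumr
            total += float(np.sum(np.where(si < -0.5, 0.8 * si * si, 0.0)))
        return total

    def score_fast(self, coords: np.ndarray) -> float:
        return float(
            score_kernel(
                np.ascontiguousarray(coords), self.heavy_idx, self.rec, self.sumr,
                self.cutoff, self.int_i, self.int_j, self.int_sumr,
            )
        )

    def min_contact_gap(self, coords: np.ndarray) -> float:
        return float(
            min_contact_gap_kernel(
                np.ascontiguousarray(coords), self.heavy_idx, self.rec, self.sumr
            )
        )


def score_pose(
    receptor: Receptor,
    fragment_coords: np.ndarray,
    ligand: Ligand,
    atom_indices: Sequence[int] | None = None,
) -> float:
    """Deterministic closed-form contact score of a fragment placement.

    Lower is better.  For every receptor-ligand heavy-atom pair within 8 A,
    with surface gap s = d - (r_i + r_j): an attractive term
    -0.05 * exp(-(s/0.5)^2) plus a clash term 0.8 * s^2 for s < 0; plus
    0.8 * s^2 for intra-ligand nonbonded heavy pairs (graph distance >= 3)
    with s < -0.5.
    """
    return ScoreField(receptor, ligand, atom_indices).score(fragment_coords)


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------

def set_active_torsions(
    fragment: FragmentState, coords: np.ndarray, targets: Sequence[float]
) -> np.ndarray:
    """Return coords with the active torsions set to ``targets`` (degrees).

    Branches are processed root-outwards, so later rotations never disturb
    already-set dihedrals.
    """
    coords = np.array(coords, dtype=float)
    lig, tree = fragment.ligand, fragment.tree
    allowed = set(fragment.atoms)
    for target, bi in zip(targets, sorted(fragment.active)):
        quad = dihedral_reference_atoms(lig, tree, bi, allowed=allowed)
        imap = fragment.index_map
        from .geometry import dihedral as _dih

        cur = _dih(*(coords[imap[a]] for a in quad))
        delta = float(target) - cur
        idxs = fragment.active_distal_local(bi)
        if len(idxs) == 0:
            continue
        br = tree.branches[bi]
        origin = coords[imap[br.anchor]]
        axis = coords[imap[br.pivot]] - origin
        coords[idxs] = rotate_about_axis(coords[idxs], origin, axis, delta)
    return coords


def _randomized_coords(
    fragment: FragmentState,
    box: Box,
    rng: np.random.Generator,
    field: ScoreField | None,
    max_tries: int = 100,
) -> np.ndarray:
    for _try in range(max_tries):
        targets = rng.uniform(-180.0, 180.0, size=len(fragment.active))
        coords = set_active_torsions(fragment, fragment.coords, targets)
        cen = coords.mean(axis=0)
        R = random_rotation_matrix(rng)
        coords = (coords - cen) @ R.T + cen
        # place the centroid so every atom stays inside the box
        off = coords - coords.mean(axis=0)
        lo_c = box.lo - off.min(axis=0)
        hi_c = box.hi - off.max(axis=0)
        if np.any(lo_c > hi_c):
            center = np.asarray(box.center, dtype=float)
        else:
            center = rng.uniform(lo_c, hi_c)
        coords = coords + (center - coords.mean(axis=0))
        if field is None or field.min_contact_gap(coords) >= CLASH_GAP:
            return coords
    raise PlacementError(
        f"no clash-free placement found in {max_tries} tries "
        "(box too small or pocket occupied)"
    )


def randomize_conformation(
    fragment: FragmentState,
    box: Box,
    rng: np.random.Generator,
    receptor: Receptor | None = None,
    max_tries: int = 100,
) -> Pose:
    """Random pose of a fragment: active torsions uniform in [-180, 180),
    uniform rigid orientation, centroid uniform in the box (all atoms kept
    inside), rejection-resampled against hard receptor clashes.
    """
    field = (
        ScoreField(receptor, fragment.ligand, fragment.atoms)
        if receptor is not None
        else None
    )
    coords = _randomized_coords(fragment, box, rng, field, max_tries)
    score = field.score(coords) if field is not None else float("nan")
    torsions = _measure_active_torsions(fragment, coords)
    return Pose(coords=coords, score=score, torsion_values=torsions)


def _apply_torsion_deltas(
    fragment: FragmentState, coords: np.ndarray, deltas: Sequence[float]
) -> np.ndarray:
    """Rotate each active torsion by its delta (degrees), root-outwards."""
    coords = np.array(coords, dtype=float)
    imap = fragment.index_map
    for delta, bi in zip(deltas, sorted(fragment.active)):
        idxs = fragment.active_distal_local(bi)
        if len(idxs) == 0:
            continue
        br = fragment.tree.branches[bi]
        origin = coords[imap[br.anchor]]
        axis = coords[imap[br.pivot]] - origin
        coords[idxs] = rotate_about_axis(coords[idxs], origin, axis, float(delta))
    return coords


def _measure_active_torsions(fragment: FragmentState, coords: np.ndarray) -> np.ndarray:
    return np.array(
        [
            measure_branch_dihedral(
                fragment.ligand, fragment.tree, bi, coords,
                index_map=fragment.index_map,
            )
            for bi in sorted(fragment.active)
        ]
    )


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------

def _cluster_poses(
    results: list[tuple[float, int, np.ndarray]],
    heavy_mask: np.ndarray,
    threshold: float,
) -> list[tuple[float, int, np.ndarray]]:
    """Greedy score-ordered clustering; keeps the best representative of
    every cluster at ``threshold`` heavy-atom RMSD (no superposition)."""
    nh = max(1, int(heavy_mask.sum()))
    reps: list[tuple[float, int, np.ndarray]] = []
    rep_heavy: list[np.ndarray] = []
    for score, run_id, coords in sorted(results, key=lambda t: (t[0], t[1])):
        hc = coords[heavy_mask]
        if all(
            math.sqrt(float(np.sum((hc - rc) ** 2)) / nh) >= threshold
            for rc in rep_heavy
        ):
            reps.append((score, run_id, coords))
            rep_heavy.append(hc)
    return reps


def _active_bond_arrays(fragment: FragmentState):
    active_sorted = sorted(fragment.active)
    anchors = np.array(
        [fragment.local_index(fragment.tree.branches[bi].anchor) for bi in active_sorted],
        dtype=np.int64,
    )
    pivots = np.array(
        [fragment.local_index(fragment.tree.branches[bi].pivot) for bi in active_sorted],
        dtype=np.int64,
    )
    distal_lists = [fragment.active_distal_local(bi) for bi in active_sorted]
    distal_off = np.zeros(len(distal_lists) + 1, dtype=np.int64)
    for i, dl in enumerate(distal_lists):
        distal_off[i + 1] = distal_off[i] + len(dl)
    distal_flat = (
        np.concatenate(distal_lists).astype(np.int64)
        if distal_lists
        else np.zeros(0, dtype=np.int64)
    )
    return anchors, pivots, distal_flat, distal_off


def local_refine(
    receptor: Receptor,
    fragment: FragmentState,
    coords: np.ndarray,
    box: Box,
    step_translation: float = 2.0,
    step_angle: float = 30.0,
    min_step_translation: float = 0.01,
    min_step_angle: float = 0.25,
    convergence_tol: float = 1e-4,
    max_cycles_per_level: int = 12,
    field: ScoreField | None = None,
) -> tuple[np.ndarray, float]:
    """Deterministic local refinement of one fragment placement.

    Cyclic coordinate descent over rigid translation/rotation and the
    active torsions, with step halving; returns (coords, score).
    """
    if field is None:
        field = ScoreField(receptor, fragment.ligand, fragment.atoms)
    anchors, pivots, distal_flat, distal_off = _active_bond_arrays(fragment)
    coords = np.ascontiguousarray(np.array(coords, dtype=float))
    score = float(
        refine_kernel(
            coords, field.heavy_idx, field.rec, field.sumr, field.cutoff,
            field.int_i, field.int_j, field.int_sumr,
            anchors, pivots, distal_flat, distal_off,
            np.asarray(box.lo, dtype=float), np.asarray(box.hi, dtype=float),
            step_translation, step_angle,
            min_step_translation, min_step_angle,
            convergence_tol, max_cycles_per_level,
        )
    )
    return coords, score


def dock(
    receptor: Receptor,
    fragment: FragmentState,
    config: EngineConfig,
    instance_id: int = 0,
    initial_coords: np.ndarray | None = None,
) -> PosePool:
    """One engine call: independent randomize-and-refine runs, clustered.

    Performs ``runs_per_exhaustiveness * exhaustiveness`` runs, each a short
    basin-hopping chain from a randomized conformation; clusters the refined
    poses at ``cluster_rmsd`` and returns at most ``num_modes``
    representatives within ``energy_range`` of the best score, sorted by
    score.  Fully deterministic given ``config.seed``.

    ``initial_coords`` optionally seeds one extra run from a given placement
    instead of a randomized one; the incremental protocol uses this so a
    grown fragment continues from where its parent pose sat in the site.
    """
    field = ScoreField(receptor, fragment.ligand, fragment.atoms)
    box = config.box
    anchors, pivots, distal_flat, distal_off = _active_bond_arrays(fragment)
    box_lo = np.asarray(box.lo, dtype=float)
    box_hi = np.asarray(box.hi, dtype=float)

    def _refine(coords: np.ndarray, t0: float, a0: float) -> float:
        return float(
            refine_kernel(
                coords, field.heavy_idx, field.rec, field.sumr, field.cutoff,
                field.int_i, field.int_j, field.int_sumr,
                anchors, pivots, distal_flat, distal_off,
                box_lo, box_hi,
                t0, a0,
                config.min_step_translation, config.min_step_angle,
                config.convergence_tol, config.max_cycles_per_level,
            )
        )

    n_active = len(fragment.active)
    results: list[tuple[float, int, np.ndarray]] = []
    n_failed = 0
    run_plan: list[int] = list(range(config.n_runs))
    if initial_coords is not None:
        run_plan = [-1] + run_plan  # seeded local run first
    for run_id in run_plan:
        rng = np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence(
                    [int(config.seed) & 0x7FFFFFFF, run_id & 0xFFFFFFFF]
                )
            )
        )
        if run_id < 0:
            coords = np.array(initial_coords, dtype=float)
            if coords.shape != (fragment.n_atoms, 3):
                raise ConsistencyError("initial_coords do not cover the fragment")
        else:
            try:
                coords = _randomized_coords(fragment, box, rng, field)
            except PlacementError:
                n_failed += 1
                continue
        coords = np.ascontiguousarray(coords)
        score = _refine(coords, config.step_translation, config.step_angle)
        # basin hopping: perturb the refined pose and re-refine, with
        # Metropolis acceptance; gives each run a global reach beyond its
        # start basin while still returning the best pose seen
        cur, cur_score = coords, score
        for _hop in range(config.mc_hops):
            prop = cur.copy()
            prop += rng.normal(scale=config.hop_translation, size=3)[None, :]
            if prop.shape[0] > 1:
                cen = prop.mean(axis=0)
                axis = rng.normal(size=3)
                ang = rng.normal(scale=config.hop_angle)
                prop = rotate_about_axis(prop, cen, axis, ang)
            if n_active:
                deltas = rng.normal(scale=config.hop_angle, size=n_active)
                prop = _apply_torsion_deltas(fragment, prop, deltas)
            # keep the proposal's centroid inside the box
            cen = prop.mean(axis=0)
            prop += np.clip(cen, box_lo, box_hi) - cen
            prop = np.ascontiguousarray(prop)
            s = _refine(prop, config.step_translation / 2.0, config.step_angle / 2.0)
            accept = s < cur_score or (
                config.hop_temperature > 0
                and rng.random() < math.exp(-(s - cur_score) / config.hop_temperature)
            )
            if accept:
                cur, cur_score = prop, s
                if s < score - 1e-12:
                    score = s
                    coords = prop
        results.append((score, run_id, coords))

    if not results:
        raise EmptyPoolError(
            f"all {config.n_runs} runs failed placement ({n_failed} rejections)"
        )

    reps = _cluster_poses(results, fragment.heavy_mask, config.cluster_rmsd)
    best = reps[0][0]
    poses = [
        Pose(
            coords=coords,
            score=score,
            torsion_values=_measure_active_torsions(fragment, coords),
            provenance=(instance_id, run_id, int(config.seed)),
        )
        for score, run_id, coords in reps[: config.num_modes]
        if score <= best + config.energy_range
    ]
    return PosePool(poses=poses, fragment=fragment)


# ---------------------------------------------------------------------------
# external Vina-compatible engine
# ---------------------------------------------------------------------------

def dock_external(
    receptor_pdbqt: str,
    fragment_pdbqt: str,
    config: EngineConfig,
    binary_path: str,
) -> PosePool:
    """Run an external Vina-compatible binary on prepared PDBQT inputs.

    Inputs are written to a temporary directory (removed afterwards, so a
    failing call leaves no partial files); the binary is invoked with the
    usual receptor/ligand/box/exhaustiveness flags and its multi-MODEL PDBQT
    output is parsed into a :class:`PosePool`.
    """
    if not (os.path.isfile(binary_path) and os.access(binary_path, os.X_OK)):
        raise EngineFailureError(f"docking binary not executable: {binary_path}")
    cx, cy, cz = config.box.center
    sx, sy, sz = config.box.extents
    with tempfile.TemporaryDirectory(prefix="metadock_") as tmp:
        rec_path = os.path.join(tmp, "receptor.pdbqt")
        lig_path = os.path.join(tmp, "ligand.pdbqt")
        out_path = os.path.join(tmp, "out.pdbqt")
        with open(rec_path, "w") as fh:
            fh.write(receptor_pdbqt)
        with open(lig_path, "w") as fh:
            fh.write(fragment_pdbqt)
        cmd = [
            binary_path,
            "--receptor", rec_path,
            "--ligand", lig_path,
            "--out", out_path,
            "--center_x", str(cx), "--center_y", str(cy), "--center_z", str(cz),
            "--size_x", str(sx), "--size_y", str(sy), "--size_z", str(sz),
            "--exhaustiveness", str(config.exhaustiveness),
            "--num_modes", str(config.num_modes),
            "--energy_range", str(config.energy_range),
            "--seed", str(config.seed),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise EngineFailureError(
                f"external engine exited with {proc.returncode}", stderr=proc.stderr
            )
        try:
            with open(out_path) as fh:
                out_text = fh.read()
            pose_coords, scores = read_pdbqt_poses(out_text)
            ligand, tree = read_pdbqt(fragment_pdbqt)
        except Exception as exc:
            raise EngineFailureError(
                f"could not parse external engine output: {exc}", stderr=proc.stderr
            ) from exc
    fragment = whole_ligand_fragment(ligand, tree)
    poses = [
        Pose(
            coords=c,
            score=s if np.isfinite(s) else float(i),
            torsion_values=np.zeros(0),
            provenance=("external", i, int(config.seed)),
        )
        for i, (c, s) in enumerate(zip(pose_coords, scores))
    ]
    return PosePool(poses=poses, fragment=fragment)


# ---------------------------------------------------------------------------
# brute-force oracle used for engine validation
# ---------------------------------------------------------------------------

def grid_search_best_position(
    receptor: Receptor,
    box: Box,
    element: str = "C",
    step: float = 0.25,
) -> tuple[np.ndarray, float]:
    """Exhaustive grid scan of a single-atom probe over the box.

    Returns the best grid point and its score; serves as an independent
    optimum against which the stochastic search is checked.
    """
    lo, hi = box.lo, box.hi
    axes = [np.arange(lo[d], hi[d] + 1e-9, step) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rec_heavy = receptor.heavy_mask
    rec = receptor.coords[rec_heavy]
    rec_r = np.array(
        [element_radius(e) for e, h in zip(receptor.elements, rec_heavy) if h]
    )
    pr = element_radius(element)
    best_score = np.inf
    best_pt = pts[0]
    for chunk in np.array_split(pts, max(1, len(pts) // 20000)):
        d = np.linalg.norm(chunk[:, None, :] - rec[None, :, :], axis=-1)
        s = d - (pr + rec_r)[None, :]
        att = -0.05 * np.exp(-((s / 0.5) ** 2))
        rep = np.where(s < 0.0, 0.8 * s * s, 0.0)
        sc = np.sum(np.where(d <= CONTACT_CUTOFF, att + rep, 0.0), axis=1)
        i = int(np.argmin(sc))
        if sc[i] < best_score:
            best_score = float(sc[i])
            best_pt = chunk[i]
    return np.asarray(best_pt, dtype=float), best_score
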