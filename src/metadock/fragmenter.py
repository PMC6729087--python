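"""Incremental fragment schedule and fragment growth between docking rounds.

The incremental protocol docks larger and larger overlapping fragments of
the ligand instead of docking it whole.  Given N rotatable bonds, r rounds
and b new bonds per round, the fragment size (the constant number of
actively sampled bonds) is k = N - (r - 1) * b.  The first fragment is the
torsion-tree root plus the k branches closest to it; each later round grafts
b more branches onto selected poses, freezes the oldest torsions at their
docked values, and keeps exactly k bonds active (newest-first refill).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, ConsistencyError, RigidLigandError
from .geometry import kabsch
from .structures_io import Ligand
from .torsion_tree import TorsionTree

logger = logging.getLogger(__name__)

__all__ = [
    "Schedule",
    "FragmentState",
    "make_schedule",
    "initial_fragment",
    "whole_ligand_fragment",
    "expand_fragment",
    "select_for_expansion",
]


@dataclass(frozen=True)
class Schedule:
    """Round plan: cumulative explored-bond counts per docking round."""

    rounds: int
    new_bonds_per_round: int
    active_count: int  # k, the fragment size
    explored_counts: tuple[int, ...]

    @property
    def n_dofs(self) -> int:
        return self.explored_counts[-1]


def make_schedule(n_dofs: int, rounds: int, new_bonds: int) -> Schedule:
    """Derive the fragment size k = N - (r-1)*b and the per-round plan.

    If the requested round count would drive k below 1, r is reduced to the
    largest value keeping k >= 1 (logged).  A rigid ligand (N = 0) raises
    :class:`RigidLigandError`; callers should fall back to single-round
    rigid docking.
    """
    if n_dofs == 0:
        raise RigidLigandError("ligand has no rotatable bonds")
    if n_dofs < 0 or rounds < 1 or new_bonds < 1:
        raise ConfigError("n_dofs, rounds and new_bonds must be positive")
    max_rounds = 1 + (n_dofs - 1) // new_bonds
    r = min(rounds, max_rounds)
    if r < rounds:
        logger.info(
            "clamping rounds from %d to %d (N=%d, b=%d)", rounds, r, n_dofs, new_bonds
        )
    k = n_dofs - (r - 1) * new_bonds
    counts = tuple(k + i * new_bonds for i in range(r))
    assert counts[-1] == n_dofs
    return Schedule(
        rounds=r, new_bonds_per_round=new_bonds, active_count=k,
        explored_counts=counts,
    )


@dataclass
class FragmentState:
    """The subset of the ligand present at one docking round.

    ``atoms`` is the sorted tuple of ligand atom indices present;
    ``explored``/``active`` are branch indices into ``tree.branches``;
    ``coords`` holds the fragment's template geometry (rows follow
    ``atoms``): frozen torsions keep whatever values these coordinates
    encode, while active torsions are resampled by the engine.
    """

    ligand: Ligand
    tree: TorsionTree
    atoms: tuple[int, ...]
    explored: tuple[int, ...]
    active: tuple[int, ...]
    round_index: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ConsistencyError("fragment coords shape mismatch")
        self._local = {a: i for i, a in enumerate(self.atoms)}

    @property
    def frozen(self) -> tuple[int, ...]:
        act = set(self.active)
        return tuple(b for b in self.explored if b not in act)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def is_complete(self) -> bool:
        return len(self.explored) == self.tree.n_dofs

    def local_index(self, ligand_atom: int) -> int:
        return self._local[ligand_atom]

    @property
    def index_map(self) -> dict[int, int]:
        return self._local

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([self.ligand.atoms[a].is_heavy for a in self.atoms], bool)

    def active_distal_local(self, branch_index: int) -> np.ndarray:
        """Rows of ``coords`` moved when this branch's torsion rotates."""
        present = [
            self._local[a]
            for a in self.tree.branches[branch_index].distal
            if a in self._local and a != self.tree.branches[branch_index].pivot
        ]
        return np.array(sorted(present), dtype=np.int64)


def _fragment_atoms(tree: TorsionTree, explored: Sequence[int]) -> tuple[int, ...]:
    atoms = set(tree.root_atoms)
    for bi in explored:
        atoms |= tree.branches[bi].group
    return tuple(sorted(atoms))


def initial_fragment(
    ligand: Ligand, tree: TorsionTree, schedule: Schedule
) -> FragmentState:
    """Fragment 0: the root group plus the k branches closest to the root."""
    k = schedule.active_count
    explored = tuple(range(k))
    atoms = _fragment_atoms(tree, explored)
    coords = ligand.reference_coords[list(atoms)].copy()
    return FragmentState(
        ligand=ligand, tree=tree, atoms=atoms, explored=explored,
        active=explored, round_index=0, coords=coords,
    )


def whole_ligand_fragment(ligand: Ligand, tree: TorsionTree) -> FragmentState:
    """The degenerate fragment covering the entire ligand, all bonds active."""
    explored = tuple(range(tree.n_dofs))
    atoms = tuple(range(ligand.n_atoms))
    return FragmentState(
        ligand=ligand, tree=tree, atoms=atoms, explored=explored,
        active=explored, round_index=0,
        coords=ligand.reference_coords.copy(),
    )


def _anchor_triple(
    ligand: Ligand, tree: TorsionTree, placed: set[int], start: int
) -> tuple[int, int, int]:
    """Three placed, non-collinear (in reference geometry) atoms near ``start``.

    The triple defines the local frame used to transplant the reference
    internal geometry of a newly grafted rigid group into the current pose.
    Candidates are taken from ``start``'s own rigid group first: its
    internal geometry is torsion-invariant, so the frame transfer is exact.
    Only if the group is too small or collinear does the search widen
    breadth-first across explored bonds (then the transfer is approximate
    when intervening torsions differ from the reference).
    """
    own_group: frozenset[int] | None = None
    if start in tree.root_atoms:
        own_group = tree.root_atoms
    else:
        for b in tree.branches:
            if start in b.group:
                own_group = b.group
                break
    order = [start] + sorted((own_group or frozenset()) - {start})
    seen = set(order)
    g = ligand.graph()
    qi = 0
    while qi < len(order) and len(order) < 24:
        u = order[qi]
        qi += 1
        for w in sorted(g.neighbors(u)):
            if w in placed and w not in seen:
                seen.add(w)
                order.append(w)
    ref = ligand.reference_coords
    for i in range(1, len(order)):
        for j in range(i + 1, len(order)):
            v1 = ref[order[i]] - ref[start]
            v2 = ref[order[j]] - ref[start]
            if np.linalg.norm(np.cross(v1, v2)) > 1e-6:
                return (start, order[i], order[j])
    raise ConsistencyError("could not find non-collinear anchor atoms")


def expand_fragment(
    fragment: FragmentState,
    pose,
    ligand: Ligand,
    tree: TorsionTree,
    schedule: Schedule,
) -> FragmentState:
    """Grow a posed fragment by the next b branches of the torsion tree.

    New rigid groups are placed by rigidly mapping their reference geometry
    through the frame of three anchor atoms in the current pose, so frozen
    torsions keep their docked values and the grafted groups keep their
    reference internal geometry.  The active set becomes the b new bonds
    plus the most recently explored older bonds, up to k (newest-first).
    """
    pose_coords = np.asarray(pose.coords, dtype=float)
    if pose_coords.shape != (fragment.n_atoms, 3):
        raise ConsistencyError("pose does not cover the fragment's atoms")
    if fragment.round_index + 1 >= schedule.rounds and fragment.is_complete:
        raise ConfigError("fragment already covers the whole ligand")

    b = schedule.new_bonds_per_round
    n_old = len(fragment.explored)
    n_new = min(b, tree.n_dofs - n_old)
    if n_new < 1:
        raise ConfigError("no unexplored bonds remain")
    new_branches = tuple(range(n_old, n_old + n_new))

    # current coordinates per ligand atom index
    cur: dict[int, np.ndarray] = {
        a: pose_coords[i] for i, a in enumerate(fragment.atoms)
    }
    ref = ligand.reference_coords
    for bi in new_branches:
        br = tree.branches[bi]
        placed = set(cur)
        if br.anchor not in placed:
            raise ConsistencyError("branch anchor not placed; tree order broken")
        triple = _anchor_triple(ligand, tree, placed, br.anchor)
        P = ref[list(triple)]
        Q = np.array([cur[a] for a in triple])
        R, t = kabsch(P, Q)
        for a in sorted(br.group):
            cur[a] = ref[a] @ R.T + t

    explored = fragment.explored + new_branches
    atoms = _fragment_atoms(tree, explored)
    coords = np.array([cur[a] for a in atoms])

    k = schedule.active_count
    n_carry = max(0, min(k - n_new, n_old))
    active = tuple(fragment.explored[n_old - n_carry:]) + new_branches
    # when b exceeds k, only the newest k bonds stay active
    active = active[-min(k, len(explored)):]
    assert len(active) == min(k, len(explored))

    return FragmentState(
        ligand=ligand, tree=tree, atoms=atoms, explored=explored,
        active=active, round_index=fragment.round_index + 1, coords=coords,
    )


def select_for_expansion(pool, m: int, diversity_rmsd: float = 1.0) -> list:
    """Pick up to ``m`` poses for growth: best scores first, greedily kept
    only when at least ``diversity_rmsd`` (heavy-atom RMSD, no superposition)
    from every already-kept pose; backfilled by score when the diversity
    filter leaves fewer than ``m``.
    """
    if m < 1:
        raise ConfigError("m must be >= 1")
    poses = sorted(enumerate(pool.poses), key=lambda t: (t[1].score, t[0]))
    if not poses:
        raise ConfigError("pool is empty")
    heavy = pool.fragment.heavy_mask
    nh = max(1, int(heavy.sum()))

    kept: list = []
    kept_coords: list[np.ndarray] = []
    rest: list = []
    for _, pose in poses:
        if len(kept) >= m:
            break
        hc = pose.coords[heavy]
        diverse = all(
            math.sqrt(float(np.sum((hc - kc) ** 2)) / nh) >= diversity_rmsd
            for kc in kept_coords
        )
        if diverse:
            kept.append(pose)
            kept_coords.append(hc)
        else:
            rest.append(pose)
    for pose in rest:
        if len(kept) >= m:
            break
        kept.append(pose)
    kept.sort(key=lambda p: p.score)
    return kept
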