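"""Rotatable-bond detection and torsion-tree decomposition of a ligand.

A ligand's conformational degrees of freedom (DoFs) are its rotatable bonds.
The convention used here follows the AutoDockTools ligand-preparation
semantics: a bond is rotatable when it is a single bond, not part of any
ring, not terminal (both sides carry at least one heavy atom beyond the
bond), and not an amide C-N bond.  Removing the rotatable bonds partitions
the atoms into rigid groups; rooting that partition at an anchor group gives
the torsion tree that the PDBQT format serializes and the incremental
protocol grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import SelectionError, StructureError
from .geometry import dihedral
from .structures_io import Ligand

__all__ = [
    "Branch",
    "TorsionTree",
    "detect_rotatable_bonds",
    "build_torsion_tree",
    "count_dofs",
    "count_heavy_atoms",
    "measure_branch_dihedral",
]


@dataclass(frozen=True)
class Branch:
    """One rotatable bond of the tree: anchor (proximal) -> pivot (distal).

    ``group`` is the rigid group directly attached through the pivot;
    ``distal`` is everything beyond the bond (group plus all descendants).
    ``parent`` is the index of the parent branch, or -1 when anchored in the
    root group.
    """

    anchor: int
    pivot: int
    group: frozenset[int]
    distal: frozenset[int]
    parent: int

    @property
    def bond(self) -> tuple[int, int]:
        return (min(self.anchor, self.pivot), max(self.anchor, self.pivot))


@dataclass
class TorsionTree:
    root_atoms: frozenset[int]
    branches: list[Branch]

    @property
    def n_dofs(self) -> int:
        return len(self.branches)

    @property
    def rotatable_bonds(self) -> list[tuple[int, int]]:
        return [b.bond for b in self.branches]

    def children(self, branch_index: int) -> list[int]:
        return [i for i, b in enumerate(self.branches) if b.parent == branch_index]

    def group_of(self, branch_index: int) -> frozenset[int]:
        return self.branches[branch_index].group

    def all_atoms(self) -> frozenset[int]:
        atoms = set(self.root_atoms)
        for b in self.branches:
            atoms |= b.group
        return frozenset(atoms)

    def validate(self) -> None:
        atoms = set(self.root_atoms)
        for b in self.branches:
            if atoms & b.group:
                raise StructureError("rigid groups are not pairwise disjoint")
            atoms |= b.group


def _heavy_degree_excluding(g: nx.Graph, ligand: Ligand, u: int, excl: int) -> int:
    return sum(
        1 for w in g.neighbors(u) if w != excl and ligand.atoms[w].is_heavy
    )


def _is_amide_bond(g: nx.Graph, ligand: Ligand, u: int, v: int) -> bool:
    """C-N single bond where the carbon carries a terminal oxygen (carbonyl)."""
    eu, ev = ligand.atoms[u].element, ligand.atoms[v].element
    if {eu, ev} != {"C", "N"}:
        return False
    c = u if eu == "C" else v
    for w in g.neighbors(c):
        a = ligand.atoms[w]
        if a.element == "O" and _heavy_degree_excluding(g, ligand, w, c) == 0:
            return True
    return False


def detect_rotatable_bonds(ligand: Ligand) -> list[tuple[int, int]]:
    """Rotatable bonds under the single/acyclic/non-terminal/non-amide rule.

    Raises :class:`StructureError` if the bond graph is disconnected.
    """
    g = ligand.graph()
    if ligand.n_atoms > 1 and not nx.is_connected(g):
        raise StructureError("ligand bond graph is disconnected")
    acyclic = {tuple(sorted(e)) for e in nx.bridges(g)} if g.number_of_edges() else set()
    rotatable: list[tuple[int, int]] = []
    for u, v in sorted(acyclic):
        au, av = ligand.atoms[u], ligand.atoms[v]
        if not (au.is_heavy and av.is_heavy):
            continue  # bonds to hydrogen are terminal by definition
        if _heavy_degree_excluding(g, ligand, u, v) < 1:
            continue
        if _heavy_degree_excluding(g, ligand, v, u) < 1:
            continue
        if _is_amide_bond(g, ligand, u, v):
            continue
        rotatable.append((u, v))
    return rotatable


def _rigid_groups(ligand: Ligand, rotatable: Iterable[tuple[int, int]]) -> list[set[int]]:
    g = ligand.graph().copy()
    g.remove_edges_from(rotatable)
    return [set(c) for c in nx.connected_components(g)]


def build_torsion_tree(
    ligand: Ligand,
    rotatable_bonds: Sequence[tuple[int, int]] | None = None,
    root_choice: int | Iterable[int] | None = None,
) -> TorsionTree:
    """Decompose the ligand into a torsion tree rooted at a rigid group.

    ``root_choice`` may be an atom index (its rigid group becomes the root)
    or an explicit atom set that must equal a rigid group.  By default the
    root is the rigid group with the most heavy atoms, ties broken by the
    lowest minimum atom serial: a large rigid anchor keeps incremental
    fragments well seated.  Branches are ordered breadth-first from the root.
    """
    if rotatable_bonds is None:
        rotatable_bonds = detect_rotatable_bonds(ligand)
    bond_set = set(ligand.bonds)
    for b in rotatable_bonds:
        if (min(b), max(b)) not in bond_set:
            raise SelectionError(f"rotatable bond {b} is not a ligand bond")

    groups = _rigid_groups(ligand, rotatable_bonds)
    group_of: dict[int, int] = {}
    for gi, grp in enumerate(groups):
        for a in grp:
            group_of[a] = gi

    if root_choice is None:

        def key(gi: int) -> tuple[int, int]:
            grp = groups[gi]
            n_heavy = sum(1 for a in grp if ligand.atoms[a].is_heavy)
            min_serial = min(ligand.atoms[a].serial for a in grp)
            return (-n_heavy, min_serial)

        root_gi = min(range(len(groups)), key=key)
    elif isinstance(root_choice, int):
        root_gi = group_of[root_choice]
    else:
        wanted = set(root_choice)
        matches = [gi for gi, grp in enumerate(groups) if grp == wanted]
        if not matches:
            raise SelectionError("root_choice is not a rigid group of the ligand")
        root_gi = matches[0]

    # breadth-first traversal over rigid groups through rotatable bonds
    adjacency: dict[int, list[tuple[int, int, int]]] = {}
    for u, v in rotatable_bonds:
        gu, gv = group_of[u], group_of[v]
        adjacency.setdefault(gu, []).append((gv, u, v))
        adjacency.setdefault(gv, []).append((gu, v, u))

    branches: list[Branch] = []
    branch_of_group: dict[int, int] = {root_gi: -1}
    frontier = [root_gi]
    while frontier:
        next_frontier: list[int] = []
        for gi in frontier:
            for gj, anchor, pivot in sorted(adjacency.get(gi, [])):
                if gj in branch_of_group:
                    continue
                branches.append(
                    Branch(
                        anchor=anchor,
                        pivot=pivot,
                        group=frozenset(groups[gj]),
                        distal=frozenset(),
                        parent=branch_of_group[gi],
                    )
                )
                branch_of_group[gj] = len(branches) - 1
                next_frontier.append(gj)
        frontier = next_frontier

    if len(branch_of_group) != len(groups):
        raise StructureError("rotatable bonds do not span all rigid groups")

    distal = [set(b.group) for b in branches]
    for bi in range(len(branches) - 1, -1, -1):
        p = branches[bi].parent
        if p >= 0:
            distal[p] |= distal[bi]
    branches = [replace(b, distal=frozenset(distal[i])) for i, b in enumerate(branches)]

    tree = TorsionTree(root_atoms=frozenset(groups[root_gi]), branches=branches)
    tree.validate()
    return tree


def count_dofs(ligand: Ligand) -> int:
    """Number of rotatable bonds (docking degrees of freedom)."""
    return len(detect_rotatable_bonds(ligand))


def count_heavy_atoms(ligand: Ligand) -> int:
    return ligand.n_heavy


def dihedral_reference_atoms(
    ligand: Ligand, tree: TorsionTree, branch_index: int,
    allowed: set[int] | None = None,
) -> tuple[int, int, int, int]:
    """Deterministic (i, anchor, pivot, l) quadruple defining a branch dihedral.

    ``i`` is the lowest-index neighbor of the anchor on the proximal side;
    ``l`` the lowest-index neighbor of the pivot on the distal side.  Both
    always exist because rotatable bonds are non-terminal.  When ``allowed``
    is given (e.g. a fragment's atom set), candidates are restricted to it.
    """
    b = tree.branches[branch_index]
    g = ligand.graph()
    prox = [w for w in g.neighbors(b.anchor) if w != b.pivot and w not in b.distal]
    dist = [w for w in g.neighbors(b.pivot) if w != b.anchor]
    if allowed is not None:
        prox = [w for w in prox if w in allowed]
        dist = [w for w in dist if w in allowed]
    if not prox or not dist:
        raise StructureError(f"branch {branch_index} has no dihedral neighbors")
    # prefer a distal neighbor in the branch's own rigid group: it never moves
    # when a deeper torsion rotates, so dihedral readings stay independent
    in_group = [w for w in dist if w in b.group]
    l = min(in_group) if in_group else min(dist)
    return (min(prox), b.anchor, b.pivot, l)


def measure_branch_dihedral(
    ligand: Ligand, tree: TorsionTree, branch_index: int, coords: np.ndarray,
    index_map: dict[int, int] | None = None,
) -> float:
    """Dihedral (degrees) of a branch in the given coordinates.

    ``index_map`` maps ligand atom indices to rows of ``coords`` (identity
    when the coordinates cover the whole ligand in order).
    """
    allowed = set(index_map) if index_map is not None else None
    quad = dihedral_reference_atoms(ligand, tree, branch_index, allowed=allowed)
    if index_map is None:
        pts = [coords[a] for a in quad]
    else:
        pts = [coords[index_map[a]] for a in quad]
    return dihedral(*pts)
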