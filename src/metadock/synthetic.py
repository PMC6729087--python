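"""Synthetic receptor pockets and branched flexible ligands.

Every protocol and evaluation path can be exercised without downloads: the
generator builds abstract heavy-atom ligands (fused-triangle rigid groups
joined by rotatable bonds, 1.5 A bonds, tetrahedral-ish growth directions)
and molds a pocket of receptor pseudo-atoms around a planted reference
pose, optionally enclosed by a partially open shell that makes the site
buried rather than surface-exposed.  The planted pose sits at the contact
optimum of the built-in score by construction and is verified to be a
local minimum at generation time.

The fixtures are geometric constructs, not chemically valid molecules;
the engine score and all meta-algorithms operate on geometry plus the bond
graph only, so nothing more is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import ScoreField, element_radius, local_refine
from .fragmenter import whole_ligand_fragment
from .errors import ConfigError, GenerationError
from .geometry import random_rotation_matrix, rotate_about_axis, unit
from .structures_io import AtomRecord, Box, Ligand, PreparedComplex, Receptor
from .torsion_tree import build_torsion_tree, detect_rotatable_bonds

__all__ = [
    "PlantedComplex",
    "make_pocket_receptor",
    "make_branched_ligand",
    "plant_complex",
]

_BOND = 1.5  # A, standard bond length in generated ligands
_CONTACT = 3.8  # A, C-C surface-contact distance (r_C + r_C)


def _atom(serial: int, coords, element="C", name=None, resname="LIG",
          resid=1, chain="L") -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name or f"{element}{serial}",
        element=element,
        residue_name=resname,
        residue_id=resid,
        chain=chain,
        coords=np.asarray(coords, dtype=float),
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# pocket receptor
# ---------------------------------------------------------------------------

def make_pocket_receptor(
    seed: int,
    pocket_radius: float = 4.0,
    depth: float = 4.0,
    spacing: float = 2.2,
) -> Receptor:
    """Concave pocket of pseudo-atoms: a hemispherical cup opening along +z,
    topped by a channel of ``depth`` whose mouth narrows with height.

    ``depth = 0`` gives an open hemispherical pocket.  Deterministic given
    the seed (small radial jitter only, directed outward so the cavity
    stays clear: no atom lies within ``pocket_radius`` of the center).
    """
    if pocket_radius <= 0 or depth < 0:
        raise ConfigError("pocket_radius must be > 0 and depth >= 0")
    if depth > 0 and pocket_radius - 0.35 * depth <= 1.0:
        raise ConfigError("channel would pinch shut: reduce depth or widen pocket")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1

    n_cup = max(8, int(4.0 * math.pi * pocket_radius**2 / spacing**2))
    for d in _fibonacci_sphere(n_cup):
        if d[2] > 0.05:
            continue  # keep the mouth open upward
        r = pocket_radius + rng.uniform(0.0, 0.4)
        atoms.append(_atom(serial, r * d, resname="PKT", resid=serial, chain="R"))
        serial += 1

    if depth > 0:
        n_rings = max(1, int(round(depth / spacing)))
        for k in range(1, n_rings + 1):
            h = depth * k / n_rings
            ring_r = pocket_radius - 0.35 * h  # mouth narrows with height
            n_on_ring = max(6, int(2.0 * math.pi * ring_r / spacing))
            offset = rng.uniform(0.0, 2.0 * math.pi)
            for t in range(n_on_ring):
                ang = offset + 2.0 * math.pi * t / n_on_ring
                jit = rng.uniform(0.0, 0.3)
                pos = [
                    (ring_r + jit) * math.cos(ang),
                    (ring_r + jit) * math.sin(ang),
                    h,
                ]
                atoms.append(
                    _atom(serial, pos, resname="PKT", resid=serial, chain="R")
                )
                serial += 1

    return Receptor(atoms=atoms, id=f"pocket-{seed}")


# ---------------------------------------------------------------------------
# branched ligand
# ---------------------------------------------------------------------------

def make_branched_ligand(n_dofs: int, seed: int) -> Ligand:
    """Connected heavy-atom ligand with exactly ``n_dofs`` rotatable bonds.

    Rigid groups are 3-atom triangles (their internal bonds are cyclic and
    therefore never rotatable); every inter-group bond is single, acyclic
    and non-terminal, hence rotatable under the detection convention.  Atom
    count is 3 * (n_dofs + 1), monotone in ``n_dofs`` for a fixed seed.
    """
    if not (0 <= n_dofs <= 70):
        raise ConfigError("n_dofs must be in [0, 70]")
    rng = np.random.default_rng(seed)

    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    adj: dict[int, list[int]] = {}
    attach_count: dict[int, int] = {}

    # separation required from atoms at graph distance >= 3 so the internal
    # clash term of the contact score (s < -0.5 with C radii) never fires on
    # the reference conformation; 1-3 neighbors only need a loose floor
    _FAR_MIN = 2.0 * element_radius("C") - 0.5 + 0.15  # 3.45 A
    _NEAR_MIN = 2.2

    def _graph_distances(source: int) -> dict[int, int]:
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for w in adj.get(u, []):
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        return dist

    def _triangle_coords(v1: np.ndarray, e: np.ndarray) -> list[np.ndarray]:
        """Equilateral triangle with one vertex at v1, centroid along e."""
        e = unit(e)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, e)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        f = unit(np.cross(e, ref))
        f = rotate_about_axis(f[None, :], np.zeros(3), e, rng.uniform(0.0, 360.0))[0]
        g = v1 + (_BOND / math.sqrt(3.0)) * e
        half = _BOND / 2.0
        return [np.asarray(v1, float), g + half * f, g - half * f]

    def _commit_triangle(tri: list[np.ndarray]) -> list[int]:
        base = len(coords)
        coords.extend(tri)
        for i, j in [(base, base + 1), (base, base + 2), (base + 1, base + 2)]:
            bonds.append((i, j))
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        return [base, base + 1, base + 2]

    # core triangle in a random orientation at the origin
    R0 = random_rotation_matrix(rng)
    _commit_triangle(_triangle_coords(np.zeros(3), R0 @ np.array([0.0, 0.0, 1.0])))

    for _grow in range(n_dofs):
        placed = False
        for _attempt in range(500):
            # peptide-like topology: grow mostly as a chain (attach to the
            # newest rigid group), with occasional short side branches
            if len(coords) > 3 and rng.random() < 0.2:
                lo = max(0, len(coords) - 9)
            else:
                lo = len(coords) - 3
            q = int(rng.integers(lo, len(coords)))
            if attach_count.get(q, 0) >= 2:
                continue
            arr = np.array(coords)
            dist_q = _graph_distances(q)
            away = arr[q] - arr[adj[q]].mean(axis=0)
            try:
                away = unit(away)
            except ValueError:
                away = unit(rng.normal(size=3))
            d = unit(away + 0.7 * rng.normal(size=3))
            v1 = arr[q] + _BOND * d
            e = unit(d + 0.5 * rng.normal(size=3))
            tri = _triangle_coords(v1, e)
            # graph distance of a new atom to an old atom x:
            #   v1 -> 1 + dist(q, x); v2/v3 -> 2 + dist(q, x)
            ok = True
            for t, extra in zip(tri, (1, 2, 2)):
                dd = np.linalg.norm(arr - t, axis=1)
                for x in range(len(arr)):
                    gd = extra + dist_q.get(x, 99)
                    floor = 0.0 if gd <= 1 else (_NEAR_MIN if gd == 2 else _FAR_MIN)
                    if dd[x] < floor:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            new = _commit_triangle(tri)
            bonds.append((q, new[0]))
            adj[q].append(new[0])
            adj[new[0]].append(q)
            attach_count[q] = attach_count.get(q, 0) + 1
            placed = True
            break
        if not placed:
            raise GenerationError("could not grow the ligand without clashes")

    atoms = [_atom(i + 1, c) for i, c in enumerate(coords)]
    ligand = Ligand(
        atoms=atoms,
        bonds=bonds,
        reference_coords=np.array(coords),
        id=f"synthlig-{n_dofs}-{seed}",
    )
    detected = len(detect_rotatable_bonds(ligand))
    if detected != n_dofs:  # self-consistency gate
        raise GenerationError(
            f"generator produced {detected} rotatable bonds, wanted {n_dofs}"
        )
    return ligand


# ---------------------------------------------------------------------------
# planted complex
# ---------------------------------------------------------------------------

@dataclass
class PlantedComplex:
    """A synthetic complex whose reference pose is a planted score minimum."""

    receptor: Receptor
    ligand: Ligand
    box: Box
    pocket_depth: float
    n_dofs: int
    seed: int

    def prepared(self) -> PreparedComplex:
        return PreparedComplex(
            receptor=self.receptor, ligand=self.ligand, box=self.box
        )


def _depth_ranks(ligand: Ligand, tree) -> np.ndarray:
    """Per-atom burial rank in [0, 1]: 0 = root (anchor) group, 1 = the
    torsion-tree periphery."""
    ranks = np.zeros(ligand.n_atoms)
    nb = max(1, len(tree.branches))
    for bi, br in enumerate(tree.branches):
        for a in br.group:
            ranks[a] = (bi + 1) / nb
    return ranks


def _mold_receptor(
    ligand: Ligand,
    tree,
    rng: np.random.Generator,
    contacts_per_atom: int,
    open_cos: float,
) -> tuple[list[AtomRecord], np.ndarray]:
    """Mold contact atoms around the reference pose, anchor-weighted.

    Binding sites of the kind that defeat single-run docking are buried and
    anchor-driven, so the mold is graded: atoms near the torsion-tree root
    receive up to ``contacts_per_atom + 1`` contacts (a deep, specific
    anchor well), atoms near the periphery as few as one.  Contact
    directions avoid an approach corridor (directions u with
    dot(u, open_axis) > -open_cos are skipped) oriented from the anchor
    toward the periphery, so the groove is concave but enterable.
    Returns the atoms and the open axis.
    """
    lig = ligand.reference_coords
    atoms: list[AtomRecord] = []
    placed: list[np.ndarray] = []
    serial = 1

    ranks = _depth_ranks(ligand, tree)
    if ranks.max() > 0:
        buried = lig[ranks <= 0.34].mean(axis=0)
        outer = lig[ranks >= 0.66].mean(axis=0) if np.any(ranks >= 0.66) else lig.mean(axis=0)
        try:
            open_axis = unit(outer - buried)
        except ValueError:
            open_axis = unit(rng.normal(size=3))
    else:
        open_axis = unit(rng.normal(size=3))

    def try_place(pos: np.ndarray, min_rec_gap: float = 2.2) -> bool:
        nonlocal serial
        d_lig = np.linalg.norm(lig - pos, axis=1)
        if d_lig.min() < _CONTACT - 1e-9:
            return False
        if placed and np.min(
            np.linalg.norm(np.array(placed) - pos, axis=1)
        ) < min_rec_gap:
            return False
        atoms.append(_atom(serial, pos, resname="REC", resid=serial, chain="R"))
        placed.append(pos)
        serial += 1
        return True

    # contact atoms: each ligand heavy atom touches >= 1 receptor atom at
    # s = 0, with contact density graded by burial rank (anchor-region
    # atoms are cradled most richly)
    for i in range(len(lig)):
        want = max(1, int(round((contacts_per_atom + 1) - contacts_per_atom * ranks[i])))
        dir_cos = open_cos
        got = 0
        for _attempt in range(160):
            if got >= want:
                break
            u = unit(rng.normal(size=3))
            if np.dot(u, open_axis) > -dir_cos:
                continue  # keep the approach corridor open
            pos = lig[i] + _CONTACT * u
            # exact contact for atom i requires no tighter contact elsewhere
            d_others = np.delete(np.linalg.norm(lig - pos, axis=1), i)
            if len(d_others) and d_others.min() < _CONTACT:
                continue
            if try_place(pos):
                got += 1

    return atoms, open_axis


def _is_local_minimum(
    field: ScoreField,
    ligand: Ligand,
    tree,
    coords: np.ndarray,
    d_trans: float = 0.25,
    d_angle: float = 2.0,
) -> bool:
    base = field.score(coords)
    cen = coords.mean(axis=0)
    for ax in range(3):
        for sgn in (1.0, -1.0):
            pert = coords.copy()
            pert[:, ax] += sgn * d_trans
            if field.score(pert) < base - 1e-9:
                return False
            e = np.zeros(3)
            e[ax] = 1.0
            pert = rotate_about_axis(coords, cen, e, sgn * d_angle)
            if field.score(pert) < base - 1e-9:
                return False
    for br in tree.branches:
        distal = sorted(set(br.distal) - {br.pivot})
        if not distal:
            continue
        origin = coords[br.anchor]
        axis = coords[br.pivot] - origin
        for sgn in (1.0, -1.0):
            pert = coords.copy()
            pert[distal] = rotate_about_axis(
                coords[distal], origin, axis, sgn * d_angle
            )
            if field.score(pert) < base - 1e-9:
                return False
    return True


def plant_complex(
    n_dofs: int,
    seed: int,
    contacts_per_atom: int = 3,
    open_half_angle_deg: float = 70.0,
    box_padding: float = 5.0,
    max_tries: int = 20,
) -> PlantedComplex:
    """Generate a planted complex: ligand + molded groove + docking box.

    The receptor is molded around the ligand's reference conformation
    (every heavy atom near the s = 0 contact surface of at least one
    receptor atom), with contacts kept off a randomly oriented approach
    corridor of half-angle ``open_half_angle_deg`` so the groove is
    concave but enterable.  The planted pose is verified to be a local
    minimum of the contact score under +/- 0.25 A translations and
    +/- 2 deg rotations/torsions; on failure the complex is regenerated
    with a derived seed, up to ``max_tries``.
    """
    open_cos = math.cos(math.radians(open_half_angle_deg))
    for attempt in range(max_tries):
        sub_seed = (seed + 7919 * attempt) & 0x7FFFFFFF
        rng = np.random.default_rng(sub_seed)
        ligand = make_branched_ligand(n_dofs, sub_seed)
        tree = build_torsion_tree(ligand)
        rec_atoms, open_axis = _mold_receptor(
            ligand, tree, rng, contacts_per_atom, open_cos
        )
        if not rec_atoms:
            continue
        receptor = Receptor(atoms=rec_atoms, id=f"planted-{n_dofs}-{sub_seed}")
        # settle the molded pose into the exact contact-score minimum with a
        # fine-step refinement, so the planted reference is a true minimum
        fragment = whole_ligand_fragment(ligand, tree)
        wide_box = Box.around_points(ligand.reference_coords, box_padding + 2.0)
        relaxed, _ = local_refine(
            receptor, fragment, ligand.reference_coords, wide_box,
            step_translation=0.25, step_angle=2.0,
            min_step_translation=5e-4, min_step_angle=5e-3,
            convergence_tol=1e-10, max_cycles_per_level=60,
        )
        ligand.reference_coords = relaxed
        for a, c in zip(ligand.atoms, relaxed):
            a.coords = np.asarray(c, dtype=float)
        box = Box.around_points(relaxed, box_padding)
        field = ScoreField(receptor, ligand)
        if not _is_local_minimum(field, ligand, tree, relaxed):
            continue
        centroid = relaxed.mean(axis=0)
        depth = float(np.linalg.norm(relaxed - centroid, axis=1).max()) + _CONTACT
        return PlantedComplex(
            receptor=receptor,
            ligand=ligand,
            box=box,
            pocket_depth=depth,
            n_dofs=n_dofs,
            seed=seed,
        )
    raise GenerationError(
        f"no valid planted complex after {max_tries} attempts "
        f"(n_dofs={n_dofs}, seed={seed})"
    )
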