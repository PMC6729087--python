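"""Molecular structure containers and I/O (PDB, PDBQT torsion-tree dialect).

The containers are deliberately light: a rigid ``Receptor`` and a flexible
``Ligand`` made of :class:`AtomRecord` objects, plus a covalent bond graph on
the ligand.  PDB text is parsed with Biopython and converted into these
containers; the PDBQT dialect (ROOT/BRANCH/TORSDOF records carrying an
explicit torsion tree) is read and written directly, since the torsion tree
is the data structure the incremental protocol operates on.

Complex preparation follows the standard redocking recipe: drop waters, keep
the first model / first ligand instance, split ligand from receptor, strip
nonpolar hydrogens while keeping polar ones, and build a docking box around
the ligand's reference pose.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import (
    AmbiguityError,
    ConsistencyError,
    EmptyStructureError,
    PDBParseError,
    PDBQTParseError,
    SelectionError,
)

logger = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}

#: covalent radii (A) used only for distance-based bond perception
_COVALENT_RADII = {
    "H": 0.37, "C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02, "P": 1.06,
    "F": 0.71, "CL": 0.99, "BR": 1.14, "I": 1.33,
}
_DEFAULT_COVALENT_RADIUS = 0.85

#: elements accepted without complaint; anything else is kept but logged
KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I", "B", "SE",
    "FE", "ZN", "MG", "CA", "NA", "K", "MN", "CU", "NI", "CO",
}

POLAR_HEAVY = {"N", "O", "S"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: identity, position and partial charge."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    coords: np.ndarray
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        self.element = self.element.strip().upper()
        if self.element not in KNOWN_ELEMENTS:
            logger.debug("unusual element %r on atom %d", self.element, self.serial)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    name: str
    res_id: int
    chain: str
    atoms: list[AtomRecord]
    is_het: bool = False


@dataclass
class Model:
    serial: int
    residues: list[Residue]

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]


@dataclass
class Structure:
    """models -> chains -> residues -> atoms, as read from a PDB file."""

    id: str
    models: list[Model]

    @property
    def first_model(self) -> Model:
        return self.models[0]


@dataclass
class Receptor:
    """Rigid protein receptor; never transformed during docking."""

    atoms: list[AtomRecord]
    id: str = "receptor"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("receptor has no atoms")
        self._coords = np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass
class Ligand:
    """Flexible ligand: atoms, covalent bond graph, and a reference pose."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]]
    reference_coords: np.ndarray
    id: str = "ligand"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("ligand has no atoms")
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                "reference_coords shape does not match the atom count"
            )
        n = len(self.atoms)
        norm: list[tuple[int, int]] = []
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ConsistencyError(f"invalid bond ({i}, {j})")
            norm.append((min(i, j), max(i, j)))
        self.bonds = sorted(set(norm))
        self._graph: nx.Graph | None = None

    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(len(self.atoms)))
            g.add_edges_from(self.bonds)
            self._graph = g
        return self._graph

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def n_heavy(self) -> int:
        return int(self.heavy_mask.sum())

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass(frozen=True)
class Box:
    """Axis-aligned docking box: center and full extents, in Angstroms."""

    center: tuple[float, float, float]
    extents: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise ValueError("box extents must be strictly positive")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - 0.5 * np.asarray(self.extents)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + 0.5 * np.asarray(self.extents)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> bool:
        p = np.atleast_2d(points)
        return bool(
            np.all(p >= self.lo - margin) and np.all(p <= self.hi + margin)
        )

    @classmethod
    def around_points(cls, points: np.ndarray, padding: float) -> "Box":
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo = p.min(axis=0) - padding
        hi = p.max(axis=0) + padding
        return cls(tuple((lo + hi) / 2.0), tuple(hi - lo))


@dataclass
class PreparedComplex:
    """A prepared receptor/ligand pair with its docking box."""

    receptor: Receptor
    ligand: Ligand
    box: Box

    def __post_init__(self) -> None:
        if not self.box.contains(self.ligand.reference_coords):
            raise ConsistencyError("ligand reference pose lies outside the box")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB text into a :class:`Structure` (models/chains/residues/atoms).

    Raises :class:`PDBParseError` on malformed ATOM/HETATM records and
    :class:`EmptyStructureError` when no atoms are present.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(structure_id, io.StringIO(text))
    except PDBConstructionException as exc:  # message includes the line number
        raise PDBParseError(str(exc)) from exc

    models: list[Model] = []
    for bio_model in bio:
        residues: list[Residue] = []
        for bio_chain in bio_model:
            for bio_res in bio_chain:
                hetflag, resseq, _icode = bio_res.id
                atoms = []
                for bio_atom in bio_res:
                    elem = (bio_atom.element or "").strip()
                    if not elem:
                        elem = bio_atom.get_name().strip()[0]
                    atoms.append(
                        AtomRecord(
                            serial=int(bio_atom.serial_number),
                            name=bio_atom.get_name(),
                            element=elem,
                            residue_name=bio_res.get_resname().strip(),
                            residue_id=int(resseq),
                            chain=bio_chain.id,
                            coords=np.asarray(bio_atom.get_coord(), dtype=float),
                        )
                    )
                residues.append(
                    Residue(
                        name=bio_res.get_resname().strip(),
                        res_id=int(resseq),
                        chain=bio_chain.id,
                        atoms=atoms,
                        is_het=(hetflag.strip() != ""),
                    )
                )
        models.append(Model(serial=int(bio_model.id) + 1, residues=residues))

    if not models or not any(m.atoms for m in models):
        raise EmptyStructureError("no ATOM/HETATM records found")
    return Structure(id=structure_id, models=models)


def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _pdb_atom_line(atom: AtomRecord, het: bool, serial: int | None = None) -> str:
    rec = "HETATM" if het else "ATOM  "
    s = serial if serial is not None else atom.serial
    x, y, z = atom.coords
    return (
        f"{rec}{s:5d} {_format_atom_name(atom.name, atom.element)} "
        f"{atom.residue_name:>3s} {atom.chain[:1] or 'A'}{atom.residue_id:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to PDB text (fixed columns)."""
    lines: list[str] = []
    multi = len(structure.models) > 1
    for model in structure.models:
        if multi:
            lines.append(f"MODEL {model.serial:8d}")
        for res in model.residues:
            for atom in res.atoms:
                lines.append(_pdb_atom_line(atom, res.is_het))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def atoms_to_pdb(atoms: Sequence[AtomRecord], het: bool = False) -> str:
    """PDB text for a bare atom list (serials renumbered from 1)."""
    lines = [_pdb_atom_line(a, het, serial=i + 1) for i, a in enumerate(atoms)]
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# complex preparation
# ---------------------------------------------------------------------------

def infer_bonds(atoms: Sequence[AtomRecord], slack: float = 1.3) -> list[tuple[int, int]]:
    """Distance-based covalent bond perception (sum of covalent radii x slack)."""
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array(
        [_COVALENT_RADII.get(a.element, _DEFAULT_COVALENT_RADIUS) for a in atoms]
    )
    n = len(atoms)
    bonds: list[tuple[int, int]] = []
    if n < 2:
        return bonds
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cut = slack * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero((d < cut) & (d > 1e-6))
    for i, j in zip(ii, jj):
        if i < j:
            bonds.append((int(i), int(j)))
    return bonds


def _remove_nonpolar_hydrogens(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Drop hydrogens whose nearest heavy atom is carbon; keep polar H (N/O/S)."""
    heavy = [a for a in atoms if a.is_heavy]
    if not heavy:
        return [a for a in atoms if a.is_heavy]
    hcoords = np.array([a.coords for a in heavy])
    kept: list[AtomRecord] = []
    for a in atoms:
        if a.is_heavy:
            kept.append(a)
            continue
        d = np.linalg.norm(hcoords - a.coords, axis=1)
        partner = heavy[int(np.argmin(d))]
        if partner.element in POLAR_HEAVY:
            kept.append(a)
    return kept


def _is_lone_het_atom(res: Residue) -> bool:
    return res.is_het and len(res.atoms) == 1 and res.name not in WATER_RESNAMES


def _match_selector(
    res: Residue, selector: str | Callable[[Residue], bool]
) -> bool:
    if callable(selector):
        return bool(selector(res))
    return res.name == selector


def assign_gasteiger_charges(atoms: list[AtomRecord]) -> bool:
    """Try to set Gasteiger partial charges via RDKit; return True on success.

    Synthetic heavy-atom-only ligands are not chemically valid molecules, so
    failure is expected there: charges stay at 0.0 (the built-in engine score
    is charge-free, so this only matters on the external-engine path).
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import AllChem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        block = atoms_to_pdb(atoms, het=True)
        mol = Chem.MolFromPDBBlock(block, sanitize=True, removeHs=False)
        if mol is None or mol.GetNumAtoms() != len(atoms):
            return False
        AllChem.ComputeGasteigerCharges(mol)
        for atom, rd in zip(atoms, mol.GetAtoms()):
            q = float(rd.GetDoubleProp("_GasteigerCharge"))
            atom.partial_charge = q if np.isfinite(q) else 0.0
        return True
    except Exception:
        return False


def prepare_complex(
    structure: Structure,
    ligand_selector: str | Callable[[Residue], bool],
    box_padding: float = 5.0,
    charges: str = "gasteiger",
) -> PreparedComplex:
    """Apply the redocking preparation rules and split receptor from ligand.

    Waters are removed, only the first model and the first matching ligand
    instance are kept, lone single-atom het residues (stray ions) are
    dropped, nonpolar hydrogens are removed from both molecules while polar
    hydrogens are retained, and the docking box defaults to the ligand's
    bounding box padded by ``box_padding`` per side.
    """
    model = structure.first_model

    candidates = [
        r
        for r in model.residues
        if r.name not in WATER_RESNAMES and _match_selector(r, ligand_selector)
    ]
    if not candidates:
        raise SelectionError("no residue matches the ligand selector")
    species = {r.name for r in candidates}
    if len(species) > 1:
        raise AmbiguityError(
            f"selector matches more than one ligand species: {sorted(species)}"
        )
    ligand_res = candidates[0]  # first instance only

    receptor_atoms: list[AtomRecord] = []
    for res in model.residues:
        if res.name in WATER_RESNAMES:
            continue
        if res is ligand_res or _match_selector(res, ligand_selector):
            continue  # other copies of the ligand are discarded, not kept
        if _is_lone_het_atom(res):
            continue
        receptor_atoms.extend(_remove_nonpolar_hydrogens(list(res.atoms)))
    if not receptor_atoms:
        raise SelectionError("no receptor atoms remain after preparation")

    ligand_atoms = _remove_nonpolar_hydrogens(list(ligand_res.atoms))
    if charges == "gasteiger":
        if not assign_gasteiger_charges(ligand_atoms):
            warnings.warn(
                "could not compute Gasteiger charges; partial charges set to 0.0",
                stacklevel=2,
            )
    bonds = infer_bonds(ligand_atoms)
    ref = np.array([a.coords for a in ligand_atoms], dtype=float)
    ligand = Ligand(
        atoms=ligand_atoms,
        bonds=bonds,
        reference_coords=ref,
        id=f"{structure.id}:{ligand_res.name}",
    )
    receptor = Receptor(atoms=receptor_atoms, id=structure.id)
    box = Box.around_points(ref, box_padding)
    return PreparedComplex(receptor=receptor, ligand=ligand, box=box)


# ---------------------------------------------------------------------------
# PDBQT (torsion-tree dialect)
# ---------------------------------------------------------------------------

def _pdbqt_atom_line(atom: AtomRecord, serial: int, coords: np.ndarray) -> str:
    x, y, z = coords
    return (
        f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)} "
        f"{atom.residue_name:>3s} {atom.chain[:1] or 'A'}{atom.residue_id:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    "
        f"{atom.partial_charge:6.3f} {atom.element:<2s}"
    )


def write_pdbqt(
    ligand: Ligand,
    tree,
    pose_coords: np.ndarray | None = None,
    model_id: int | None = None,
) -> str:
    """Serialize a ligand and its torsion tree as PDBQT text.

    Atoms are emitted in torsion-tree order (root first, then branches in
    their stored order, nested), so BRANCH records can refer to serials.
    ``pose_coords`` overrides the reference coordinates (same atom order as
    ``ligand.atoms``).  TORSDOF equals the rotatable-bond count.
    """
    coords = (
        np.asarray(pose_coords, dtype=float)
        if pose_coords is not None
        else ligand.reference_coords
    )
    if coords.shape != (ligand.n_atoms, 3):
        raise ConsistencyError("pose_coords shape does not match the ligand")
    covered = set(tree.root_atoms)
    for b in tree.branches:
        covered |= set(b.group)
    if covered != set(range(ligand.n_atoms)):
        raise ConsistencyError("torsion tree does not cover the ligand's atoms")

    serial_of = {}
    next_serial = [1]
    lines: list[str] = []
    if model_id is not None:
        lines.append(f"MODEL {model_id:8d}")
    lines.append(f"REMARK  {ligand.id}")

    def emit_atoms(indices: Iterable[int]) -> None:
        for idx in sorted(indices):
            serial_of[idx] = next_serial[0]
            lines.append(
                _pdbqt_atom_line(ligand.atoms[idx], next_serial[0], coords[idx])
            )
            next_serial[0] += 1

    children: dict[int, list[int]] = {}
    for bi, b in enumerate(tree.branches):
        children.setdefault(b.parent, []).append(bi)

    lines.append("ROOT")
    emit_atoms(tree.root_atoms)
    lines.append("ENDROOT")

    def emit_branch(bi: int) -> None:
        b = tree.branches[bi]
        anchor_serial = serial_of[b.anchor]
        emit_atoms({b.pivot})
        pivot_serial = serial_of[b.pivot]
        # rewrite the BRANCH header now that the pivot's serial is known
        lines.insert(
            len(lines) - 1, f"BRANCH {anchor_serial:3d} {pivot_serial:3d}"
        )
        emit_atoms(set(b.group) - {b.pivot})
        for ci in children.get(bi, []):
            emit_branch(ci)
        lines.append(f"ENDBRANCH {anchor_serial:3d} {pivot_serial:3d}")

    for ci in children.get(-1, []):
        emit_branch(ci)

    lines.append(f"TORSDOF {len(tree.branches)}")
    if model_id is not None:
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


def write_pose_set_pdbqt(ligand: Ligand, tree, pose_coord_sets, scores=None) -> str:
    """Multi-MODEL PDBQT for a set of poses of the same ligand."""
    chunks = []
    for i, pc in enumerate(pose_coord_sets):
        text = write_pdbqt(ligand, tree, pose_coords=pc, model_id=i + 1)
        if scores is not None:
            head, rest = text.split("\n", 1)
            text = f"{head}\nREMARK VINA RESULT: {scores[i]:10.3f} 0.000 0.000\n{rest}"
        chunks.append(text)
    return "".join(chunks)


def _parse_pdbqt_atom(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or "LIG"
        chain = line[21].strip() or "A"
        resid = int(line[22:26]) if line[22:26].strip() else 1
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        charge = float(line[66:76]) if line[66:76].strip() else 0.0
        adtype = line[77:79].strip()
    except (ValueError, IndexError) as exc:
        raise PDBQTParseError(f"malformed atom record on line {lineno}") from exc
    element = adtype if adtype else (name[:1] or "C")
    if element.upper() in {"HD", "HS"}:
        element = "H"
    if element.upper() in {"A", "AC"}:  # AutoDock aromatic carbon type
        element = "C"
    return AtomRecord(
        serial=serial,
        name=name or element,
        element=element,
        residue_name=resname,
        residue_id=resid,
        chain=chain,
        coords=np.array([x, y, z]),
    )


def read_pdbqt(text: str):
    """Parse single-model PDBQT text into ``(Ligand, TorsionTree)``.

    The torsion tree is rebuilt from the ROOT/BRANCH nesting; covalent bonds
    are re-perceived from distances (the format does not store them), with
    the recorded rotatable bonds added explicitly.  For multi-MODEL files
    only the first model's topology is returned; use
    :func:`read_pdbqt_poses` for the coordinate sets.
    """
    from .torsion_tree import Branch, TorsionTree

    atoms: list[AtomRecord] = []
    index_of_serial: dict[int, int] = {}
    root_atoms: set[int] = set()
    # each stack frame: [anchor_serial, pivot_serial, group_indices]
    stack: list[list] = []
    raw_branches: list[tuple[int, int, set[int], int]] = []
    branch_stack: list[int] = []
    in_root = False
    seen_model = False
    torsdof: int | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line.split(None, 1)[0].upper() if line.strip() else ""
        if rec == "MODEL":
            if seen_model:
                break  # topology comes from the first model only
            seen_model = True
        elif rec == "ENDMDL":
            break
        elif rec == "ROOT":
            in_root = True
        elif rec == "ENDROOT":
            in_root = False
        elif rec == "BRANCH":
            parts = line.split()
            if len(parts) != 3:
                raise PDBQTParseError(f"malformed BRANCH on line {lineno}")
            anchor_serial, pivot_serial = int(parts[1]), int(parts[2])
            parent = branch_stack[-1] if branch_stack else -1
            raw_branches.append((anchor_serial, pivot_serial, set(), parent))
            branch_stack.append(len(raw_branches) - 1)
        elif rec == "ENDBRANCH":
            if not branch_stack:
                raise PDBQTParseError(f"ENDBRANCH without BRANCH on line {lineno}")
            branch_stack.pop()
        elif rec == "TORSDOF":
            torsdof = int(line.split()[1])
        elif rec in {"ATOM", "HETATM"}:
            atom = _parse_pdbqt_atom(line, lineno)
            idx = len(atoms)
            atoms.append(atom)
            index_of_serial[atom.serial] = idx
            if in_root:
                root_atoms.add(idx)
            elif branch_stack:
                raw_branches[branch_stack[-1]][2].add(idx)
        elif rec in {"REMARK", "END", "", "TER", "USER"}:
            continue
        else:
            logger.warning("ignoring unknown PDBQT record %r on line %s", rec, lineno)

    if branch_stack:
        raise PDBQTParseError(
            f"BRANCH opened but never closed (unmatched at end of input, "
            f"{len(branch_stack)} open)"
        )
    if not atoms:
        raise EmptyStructureError("no atoms in PDBQT input")

    branches: list[Branch] = []
    for anchor_serial, pivot_serial, group, parent in raw_branches:
        try:
            anchor = index_of_serial[anchor_serial]
            pivot = index_of_serial[pivot_serial]
        except KeyError as exc:
            raise PDBQTParseError(
                f"BRANCH refers to unknown atom serial {exc.args[0]}"
            ) from exc
        branches.append(
            Branch(
                anchor=anchor,
                pivot=pivot,
                group=frozenset(group),
                distal=frozenset(),  # filled below
                parent=parent,
            )
        )
    # distal sets: a branch's group plus all descendant groups
    distal = [set(b.group) for b in branches]
    for bi in range(len(branches) - 1, -1, -1):
        p = branches[bi].parent
        if p >= 0:
            distal[p] |= distal[bi]
    branches = [replace(b, distal=frozenset(distal[i])) for i, b in enumerate(branches)]

    coords = np.array([a.coords for a in atoms], dtype=float)
    bonds = set(infer_bonds(atoms))
    for b in branches:
        bonds.add((min(b.anchor, b.pivot), max(b.anchor, b.pivot)))
    ligand = Ligand(
        atoms=atoms, bonds=sorted(bonds), reference_coords=coords, id="pdbqt"
    )
    tree = TorsionTree(root_atoms=frozenset(root_atoms), branches=branches)
    if torsdof is not None and torsdof != len(branches):
        logger.warning(
            "TORSDOF %d disagrees with %d BRANCH records", torsdof, len(branches)
        )
    return ligand, tree


def read_pdbqt_poses(text: str) -> tuple[list[np.ndarray], list[float]]:
    """Coordinates (and scores, when present) of every MODEL in PDBQT text.

    A file without MODEL records yields a single pose.  Scores are taken from
    ``REMARK VINA RESULT`` lines and default to nan.
    """
    poses: list[np.ndarray] = []
    scores: list[float] = []
    current: list[list[float]] | None = None
    current_score = float("nan")
    saw_model = False

    def flush() -> None:
        nonlocal current, current_score
        if current:
            poses.append(np.array(current, dtype=float))
            scores.append(current_score)
        current = None
        current_score = float("nan")

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line.split(None, 1)[0].upper() if line.strip() else ""
        if rec == "MODEL":
            saw_model = True
            flush()
            current = []
        elif rec == "ENDMDL":
            flush()
        elif rec in {"ATOM", "HETATM"}:
            if current is None:
                current = []
            atom = _parse_pdbqt_atom(line, lineno)
            current.append(list(atom.coords))
        elif line.upper().startswith("REMARK VINA RESULT"):
            try:
                current_score = float(line.split(":")[1].split()[0])
            except (IndexError, ValueError):
                pass
    flush()
    if not poses:
        raise EmptyStructureError("no atoms in PDBQT input")
    if saw_model:
        counts = {p.shape[0] for p in poses}
        if len(counts) > 1:
            raise PDBQTParseError("MODELs have differing atom counts")
    return poses, scores
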