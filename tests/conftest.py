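import numpy as np
import pytest

from metadock.structures_io import AtomRecord, Box, Ligand, Receptor


def make_atom(serial, coords, element="C", name=None, resname="LIG", resid=1,
              chain="L"):
    return AtomRecord(
        serial=serial,
        name=name or f"{element}{serial}",
        element=element,
        residue_name=resname,
        residue_id=resid,
        chain=chain,
        coords=np.asarray(coords, dtype=float),
    )


def chain_ligand(n_heavy: int, spacing: float = 1.5) -> Ligand:
    """A zig-zag all-carbon chain: n_heavy-3 rotatable bonds when n_heavy>3."""
    coords = []
    for i in range(n_heavy):
        coords.append([i * spacing * 0.87, (i % 2) * spacing * 0.5, 0.0])
    atoms = [make_atom(i + 1, c) for i, c in enumerate(coords)]
    bonds = [(i, i + 1) for i in range(n_heavy - 1)]
    return Ligand(atoms=atoms, bonds=bonds, reference_coords=np.array(coords),
                  id=f"chain-{n_heavy}")


def ring_ligand(n: int = 6, radius: float = 1.5) -> Ligand:
    ang = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                              np.zeros(n)])
    atoms = [make_atom(i + 1, c) for i, c in enumerate(coords)]
    bonds = [(i, (i + 1) % n) for i in range(n)]
    return Ligand(atoms=atoms, bonds=bonds, reference_coords=coords, id="ring")


@pytest.fixture(scope="session")
def small_planted():
    """One small planted complex shared by slow protocol tests."""
    from metadock.synthetic import plant_complex

    return plant_complex(4, seed=11)


@pytest.fixture
def shell_probe():
    from metadock.benchmarks import single_atom_shell_complex

    return single_atom_shell_complex(seed=5)


def pdb_fixture_text() -> str:
    """A hand-written complex: 6-atom protein, 3 waters, an ion, and two
    copies of a LIG residue carrying polar and nonpolar hydrogens."""
    lines = []

    def atom(serial, name, resname, chain, resid, x, y, z, element, het=False):
        rec = "HETATM" if het else "ATOM  "
        nm = f" {name:<3s}" if len(element) == 1 and len(name) < 4 else f"{name:<4s}"
        lines.append(
            f"{rec}{serial:5d} {nm} {resname:>3s} {chain}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
        )

    s = 1
    # short "protein"
    for i in range(6):
        atom(s, "CA", "ALA", "A", i + 1, 10.0 + 1.5 * i, 0.0, 0.0, "C"); s += 1
    # waters
    for i in range(3):
        atom(s, "O", "HOH", "W", 100 + i, 20.0, 5.0 + i, 0.0, "O", het=True); s += 1
    # stray ion (lone het atom)
    atom(s, "NA", "NA", "I", 200, 25.0, 0.0, 0.0, "NA", het=True); s += 1
    # ligand copy 1: 4 C, 1 O with polar H, 3 nonpolar H on carbons
    lig = [
        ("C1", "C", 0.0, 0.0, 0.0), ("C2", "C", 1.5, 0.0, 0.0),
        ("C3", "C", 2.25, 1.3, 0.0), ("C4", "C", 3.75, 1.3, 0.0),
        ("O1", "O", 4.5, 2.5, 0.0),
        ("H1", "H", -0.6, 0.9, 0.0), ("H2", "H", 1.9, -0.95, 0.3),
        ("H3", "H", 4.2, 0.4, 0.2), ("HO1", "H", 5.45, 2.4, 0.0),
    ]
    for name, el, x, y, z in lig:
        atom(s, name, "LIG", "L", 301, x, y, z, el, het=True); s += 1
    # ligand copy 2 (same species, shifted): only the first must survive
    for name, el, x, y, z in lig:
        atom(s, name, "LIG", "L", 302, x + 30.0, y, z, el, het=True); s += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def complex_pdb_text():
    return pdb_fixture_text()
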