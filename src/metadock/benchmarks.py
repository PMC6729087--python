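"""Benchmark harnesses over synthetic planted complexes.

These drive the budget-matched protocol comparison (single vs pooled multi
vs incremental at an equal engine-call budget), the brute-force oracle
check of the built-in engine, and the nested-seed pooling monotonicity
audit.  They are used both by the test suite and by the reproduction
script, with problem sizes chosen for desk-scale runtimes.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .engine import EngineConfig, PosePool, dock, grid_search_best_position
from .evaluation import is_success, top_rmsd
from .fragmenter import whole_ligand_fragment
from .protocols import ProtocolConfig, run_incremental, run_multi, run_single
from .structures_io import Box, Ligand, Receptor
from .synthetic import _atom, _fibonacci_sphere, plant_complex
from .torsion_tree import build_torsion_tree

logger = logging.getLogger(__name__)

__all__ = [
    "single_atom_shell_complex",
    "engine_oracle_deviations",
    "compare_protocols_on_planted",
    "pooling_success_by_instances",
]


def single_atom_shell_complex(
    seed: int, n_shell: int = 48, shell_radius: float = 3.8, box_half: float = 3.0
):
    """A single-atom probe ligand inside a spherical shell of receptor atoms.

    Every shell atom's contact surface (s = 0) passes through the shell
    center, so the center is the unique optimum of the contact score: a
    clean target for comparing the stochastic search against a grid scan.
    """
    rng = np.random.default_rng(seed)
    center = rng.uniform(-1.0, 1.0, size=3)
    dirs = _fibonacci_sphere(n_shell)
    rec_atoms = [
        _atom(i + 1, center + shell_radius * d, resname="SHL", resid=i + 1, chain="R")
        for i, d in enumerate(dirs)
    ]
    receptor = Receptor(atoms=rec_atoms, id=f"shell-{seed}")
    lig_atom = _atom(1, center + rng.uniform(-0.5, 0.5, size=3))
    ligand = Ligand(
        atoms=[lig_atom], bonds=[],
        reference_coords=np.array([center]), id=f"probe-{seed}",
    )
    box = Box(tuple(center), (2 * box_half,) * 3)
    return receptor, ligand, box


def engine_oracle_deviations(
    n_seeds: int = 10, base_seed: int = 0, exhaustiveness: int = 8
) -> list[float]:
    """Distance (A) between the engine's best pose and the brute-force
    0.25 A grid optimum of the single-atom shell fixture, per seed."""
    devs: list[float] = []
    for s in range(n_seeds):
        seed = (base_seed + s) & 0x7FFFFFFF
        receptor, ligand, box = single_atom_shell_complex(seed)
        grid_pt, _ = grid_search_best_position(receptor, box, step=0.25)
        tree = build_torsion_tree(ligand)
        fragment = whole_ligand_fragment(ligand, tree)
        cfg = EngineConfig(box=box, exhaustiveness=exhaustiveness, seed=seed)
        pool = dock(receptor, fragment, cfg)
        best = pool.best_pose
        devs.append(float(np.linalg.norm(best.coords[0] - grid_pt)))
    return devs


def compare_protocols_on_planted(
    n_complexes: int = 4,
    dof_low: int = 6,
    dof_high: int = 10,
    n_seeds: int = 5,
    threads: int = 24,
    rounds: int = 3,
    new_bonds: int = 2,
    exhaustiveness: int = 1,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Budget-matched comparison of the three protocols on planted pockets.

    Every protocol spends the same number of independent engine runs:
    the incremental protocol performs ``threads`` calls per round at the
    given exhaustiveness; the multi protocol runs ``threads * rounds``
    instances at the same exhaustiveness; the single protocol runs one call
    with its exhaustiveness scaled up to match.  Returns one row per
    (complex, master seed, protocol) with the top-RMSD to the planted pose.
    """
    dof_cycle = list(range(dof_low, dof_high + 1))
    rows = []
    for ci in range(n_complexes):
        n_dofs = dof_cycle[ci % len(dof_cycle)]
        complex_seed = (base_seed + 104729 + 13 * ci) & 0x7FFFFFFF
        planted = plant_complex(n_dofs, complex_seed)
        prepared = planted.prepared()
        engine = EngineConfig(box=prepared.box, exhaustiveness=exhaustiveness)
        budget_calls = threads * rounds
        configs = {
            "single": ProtocolConfig(
                kind="single",
                engine=replace(engine, exhaustiveness=exhaustiveness * budget_calls),
            ),
            "multi": ProtocolConfig(
                kind="multi", engine=engine, instances=budget_calls
            ),
            "incremental": ProtocolConfig(
                kind="incremental", engine=engine, threads=threads,
                rounds=rounds, new_bonds=new_bonds,
            ),
        }
        runners = {
            "single": run_single, "multi": run_multi, "incremental": run_incremental,
        }
        for si in range(n_seeds):
            master = (base_seed + 31 * ci + 1009 * si) & 0x7FFFFFFF
            for name, cfg in configs.items():
                cfg_seeded = replace(cfg, master_seed=master)
                pool = runners[name](prepared, cfg_seeded)
                _, rmsd = top_rmsd(pool, planted.ligand)
                rows.append(
                    {
                        "complex": planted.ligand.id,
                        "n_dofs": n_dofs,
                        "master_seed": master,
                        "protocol": name,
                        "top_rmsd": rmsd,
                        "success": is_success(rmsd),
                    }
                )
    return pd.DataFrame(rows)


def pooling_success_by_instances(
    n_dofs: int = 4,
    complex_seed: int = 0,
    max_instances: int = 8,
    exhaustiveness: int = 2,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Best pooled top-RMSD for nested instance prefixes 1..max_instances.

    Instance pools are computed once with seeds master+0..max-1; the pooled
    result for n instances merges the first n pools, so the best RMSD is a
    running minimum and the success flag is non-decreasing in n.
    """
    planted = plant_complex(n_dofs, complex_seed)
    prepared = planted.prepared()
    tree = build_torsion_tree(planted.ligand)
    fragment = whole_ligand_fragment(planted.ligand, tree)
    pools = []
    for i in range(max_instances):
        cfg = EngineConfig(
            box=prepared.box, exhaustiveness=exhaustiveness, seed=master_seed + i
        )
        pools.append(dock(prepared.receptor, fragment, cfg, instance_id=i))
    rows = []
    for n in range(1, max_instances + 1):
        merged = PosePool.merged(pools[:n])
        _, rmsd = top_rmsd(merged, planted.ligand)
        rows.append(
            {"instances": n, "top_rmsd": rmsd, "success": is_success(rmsd)}
        )
    return pd.DataFrame(rows)
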