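"""The three compared docking protocols.

* ``single`` — one engine call on the whole ligand (exhaustiveness does all
  the work of sampling).
* ``multi`` — n independent engine calls with distinct seeds, pools merged
  ("run several short instances in parallel and group their results").
* ``incremental`` — parallelized incremental meta-docking: dock a small
  fragment with k active bonds, select diverse well-scoring poses, grow
  them by b bonds per round (older torsions frozen at their docked values),
  and re-dock, until the whole ligand is reconstructed in the site.

Results are a pure function of (complex, config, master_seed): instances
are executed sequentially with per-instance seeds, which is contractually
identical to a concurrent execution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal

from .engine import EngineConfig, PosePool, dock
from .errors import (
    ConfigError,
    EmptyPoolError,
    MetadockError,
    ProtocolError,
    RigidLigandError,
)
from .fragmenter import (
    expand_fragment,
    initial_fragment,
    make_schedule,
    select_for_expansion,
    whole_ligand_fragment,
)
from .structures_io import PreparedComplex
from .torsion_tree import build_torsion_tree

logger = logging.getLogger(__name__)

__all__ = ["ProtocolConfig", "run_single", "run_multi", "run_incremental", "run"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of one protocol run.

    ``threads`` is the number of docking tasks per incremental round;
    ``instances`` the number of pooled engine calls in the multi protocol.
    ``expansion_size`` (poses grown per round) defaults to ``threads``.
    The default incremental protocol uses 3 rounds, 3 new bonds per round,
    24 threads, with engine exhaustiveness 4.
    """

    kind: Literal["single", "multi", "incremental"]
    engine: EngineConfig
    instances: int = 12
    threads: int = 24
    rounds: int = 3
    new_bonds: int = 3
    expansion_size: int | None = None
    diversity_rmsd: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.instances < 1 or self.threads < 1:
            raise ConfigError("instances and threads must be >= 1")
        if self.rounds < 1 or self.new_bonds < 1:
            raise ConfigError("rounds and new_bonds must be >= 1")

    @classmethod
    def default_incremental(
        cls, engine: EngineConfig, master_seed: int = 0
    ) -> "ProtocolConfig":
        return cls(
            kind="incremental",
            engine=replace(engine, exhaustiveness=4),
            threads=24,
            rounds=3,
            new_bonds=3,
            master_seed=master_seed,
        )

    def engine_call_count(self, n_dofs: int | None = None) -> int:
        """Budget accounting: one thread = one engine call per round."""
        if self.kind == "single":
            return 1
        if self.kind == "multi":
            return self.instances
        rounds = self.rounds
        if n_dofs is not None and n_dofs > 0:
            rounds = make_schedule(n_dofs, self.rounds, self.new_bonds).rounds
        return rounds * self.threads


def _lineage_seed(master: int, round_index: int, lineage: int, call: int) -> int:
    """Stable per-call seed stream for expansion lineages."""
    h = (
        (master & 0x7FFFFFFF)
        ^ (round_index * 0x9E3779B1)
        ^ (lineage * 0x85EBCA77)
        ^ (call * 0xC2B2AE3D)
    )
    return h & 0x7FFFFFFF


def run_single(complex: PreparedComplex, config: ProtocolConfig) -> PosePool:
    """One engine call on the whole ligand (conformation randomized inside)."""
    tree = build_torsion_tree(complex.ligand)
    fragment = whole_ligand_fragment(complex.ligand, tree)
    engine_cfg = replace(config.engine, box=complex.box, seed=config.master_seed)
    pool = dock(complex.receptor, fragment, engine_cfg, instance_id=0)
    logger.info(
        "single call=0 seed=%d runs=%d best=%.4f",
        engine_cfg.seed, engine_cfg.n_runs, pool.best_score,
    )
    return pool


def run_multi(complex: PreparedComplex, config: ProtocolConfig) -> PosePool:
    """n independent engine calls with seeds master+0..n-1, pools merged."""
    tree = build_torsion_tree(complex.ligand)
    fragment = whole_ligand_fragment(complex.ligand, tree)
    pools: list[PosePool] = []
    for i in range(config.instances):
        engine_cfg = replace(
            config.engine, box=complex.box, seed=config.master_seed + i
        )
        try:
            pool = dock(complex.receptor, fragment, engine_cfg, instance_id=i)
        except MetadockError as exc:
            logger.warning("multi instance %d failed: %s", i, exc)
            continue
        logger.info(
            "multi call=%d seed=%d runs=%d best=%.4f",
            i, engine_cfg.seed, engine_cfg.n_runs, pool.best_score,
        )
        pools.append(pool)
    if not pools:
        raise EmptyPoolError("every multi instance failed")
    return PosePool.merged(pools)


def run_incremental(complex: PreparedComplex, config: ProtocolConfig) -> PosePool:
    """Parallelized incremental meta-docking; returns full-ligand poses only."""
    ligand = complex.ligand
    tree = build_torsion_tree(ligand)
    try:
        schedule = make_schedule(tree.n_dofs, config.rounds, config.new_bonds)
    except RigidLigandError:
        logger.info("rigid ligand: falling back to single-run docking")
        return run_single(complex, config)

    m = config.expansion_size or config.threads
    fragment = initial_fragment(ligand, tree, schedule)

    pools: list[PosePool] = []
    for i in range(config.threads):
        engine_cfg = replace(
            config.engine, box=complex.box, seed=config.master_seed + i
        )
        try:
            pool = dock(complex.receptor, fragment, engine_cfg, instance_id=i)
        except MetadockError as exc:
            logger.warning("round 1 task %d failed: %s", i, exc)
            continue
        logger.info(
            "incremental round=1 lineage=%d seed=%d best=%.4f",
            i, engine_cfg.seed, pool.best_score,
        )
        pools.append(pool)
    if not pools:
        raise ProtocolError("round 1 produced no poses")
    pool = PosePool.merged(pools)

    for round_index in range(1, schedule.rounds):
        try:
            selected = select_for_expansion(pool, m, config.diversity_rmsd)
        except ConfigError as exc:
            raise ProtocolError(f"empty selection at round {round_index + 1}") from exc
        calls_per_lineage = math.ceil(config.threads / len(selected))
        round_pools: list[PosePool] = []
        for lineage, pose in enumerate(selected):
            grown = expand_fragment(pool.fragment, pose, ligand, tree, schedule)
            for c in range(calls_per_lineage):
                seed = _lineage_seed(config.master_seed, round_index, lineage, c)
                engine_cfg = replace(config.engine, box=complex.box, seed=seed)
                try:
                    sub = dock(
                        complex.receptor, grown, engine_cfg, instance_id=lineage,
                        initial_coords=grown.coords,
                    )
                except MetadockError as exc:
                    logger.warning(
                        "round %d lineage %d call %d failed: %s",
                        round_index + 1, lineage, c, exc,
                    )
                    continue
                logger.info(
                    "incremental round=%d lineage=%d seed=%d best=%.4f",
                    round_index + 1, lineage, seed, sub.best_score,
                )
                round_pools.append(sub)
        if not round_pools:
            raise ProtocolError(f"round {round_index + 1} produced no poses")
        pool = PosePool.merged(round_pools)

    assert pool.fragment.n_atoms == ligand.n_atoms
    return pool


def run(complex: PreparedComplex, config: ProtocolConfig) -> PosePool:
    """Dispatch on ``config.kind``."""
    if config.kind == "single":
        return run_single(complex, config)
    if config.kind == "multi":
        return run_multi(complex, config)
    if config.kind == "incremental":
        return run_incremental(complex, config)
    raise ConfigError(f"unknown protocol kind {config.kind!r}")
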