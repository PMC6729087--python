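"""Redocking evaluation: all-atom RMSD, top-RMSD pose, 2 A success.

The RMSD is the strictest one used in redocking work: all heavy atoms of
the ligand, fixed 1:1 correspondence, and no superposition (the receptor is
rigid and fixed in space, so position and orientation errors count).  The
*top-RMSD* conformation — the produced pose closest to the crystal
reference regardless of score — measures sampling power; the *top-scoring*
conformation measures scoring power.  A pose reproduces the reference when
its all-atom RMSD is strictly below 2 A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, EmptyPoolError, MetadockError
from .structures_io import Ligand

SUCCESS_RMSD = 2.0  # A, strict ("< 2")

__all__ = [
    "SUCCESS_RMSD",
    "EvaluationRecord",
    "rmsd_all_atom",
    "top_rmsd",
    "top_scoring",
    "is_success",
    "replicate_stats",
    "benchmark_table",
]


def rmsd_all_atom(
    reference_coords: np.ndarray,
    pose_coords: np.ndarray,
    heavy_mask: np.ndarray | None = None,
) -> float:
    """Heavy-atom RMSD with fixed correspondence and no superposition.

    ``heavy_mask`` selects the heavy atoms; by default all rows are used
    (callers pass the ligand's mask when hydrogens are present).  Set it to
    a backbone selection for the more lenient backbone-only variant.
    """
    ref = np.asarray(reference_coords, dtype=float)
    pos = np.asarray(pose_coords, dtype=float)
    if ref.shape != pos.shape:
        raise ConsistencyError(
            f"atom-count mismatch: reference {ref.shape} vs pose {pos.shape}"
        )
    if heavy_mask is not None:
        mask = np.asarray(heavy_mask, dtype=bool)
        ref = ref[mask]
        pos = pos[mask]
    if len(ref) == 0:
        raise ConsistencyError("no atoms selected for RMSD")
    return float(math.sqrt(np.mean(np.sum((ref - pos) ** 2, axis=1))))


def _reference_arrays(reference) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(reference, Ligand):
        return reference.reference_coords, reference.heavy_mask
    return np.asarray(reference, dtype=float), None


def top_rmsd(pool, reference) -> tuple[object, float]:
    """The pose of the pool closest to the reference, and its RMSD.

    ``reference`` is a :class:`Ligand` (its reference pose and heavy mask
    are used) or a bare coordinate array.  Ties break by better score, then
    lower pose index.
    """
    if not pool.poses:
        raise EmptyPoolError("pool is empty")
    ref, mask = _reference_arrays(reference)
    best = None
    best_key = None
    for i, pose in enumerate(pool.poses):
        r = rmsd_all_atom(ref, pose.coords, mask)
        key = (r, pose.score, i)
        if best_key is None or key < best_key:
            best_key = key
            best = pose
    return best, float(best_key[0])


def top_scoring(pool, reference=None):
    """The best-scored pose; ties break by lower reference RMSD (when a
    reference is given), then pose index."""
    if not pool.poses:
        raise EmptyPoolError("pool is empty")
    ref_mask = _reference_arrays(reference) if reference is not None else None

    def key(t):
        i, pose = t
        if ref_mask is not None:
            return (pose.score, rmsd_all_atom(ref_mask[0], pose.coords, ref_mask[1]), i)
        return (pose.score, 0.0, i)

    return min(enumerate(pool.poses), key=key)[1]


def is_success(rmsd: float) -> bool:
    """True iff the redocking RMSD is strictly below the 2 A threshold."""
    if rmsd < 0:
        raise MetadockError("RMSD cannot be negative")
    return rmsd < SUCCESS_RMSD


def replicate_stats(values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, sample sd with n-1, min) over replicate RMSDs; sd=0 for n=1."""
    if len(values) == 0:
        raise MetadockError("at least one replicate value is required")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd, float(arr.min())


@dataclass
class EvaluationRecord:
    """Per-complex redocking outcome over replicates."""

    complex_id: str
    n_dofs: int
    n_heavy: int
    per_replicate_top_rmsd: list[float]
    mean: float
    sd: float
    best: float
    success: bool

    @classmethod
    def from_values(
        cls, complex_id: str, n_dofs: int, n_heavy: int, values: Sequence[float]
    ) -> "EvaluationRecord":
        mean, sd, best = replicate_stats(values)
        return cls(
            complex_id=complex_id,
            n_dofs=n_dofs,
            n_heavy=n_heavy,
            per_replicate_top_rmsd=list(values),
            mean=mean,
            sd=sd,
            best=best,
            success=is_success(best),
        )


def benchmark_table(
    records: Mapping[str, Sequence[EvaluationRecord]],
) -> tuple[pd.DataFrame, dict]:
    """Benchmark rows (one per complex, mean +/- sd per protocol) + summary.

    ``records`` maps protocol name -> per-complex records; every protocol
    must cover the same complexes in the same order.  The summary holds the
    per-protocol mean of means, mean of sds, and failure rate (fraction of
    complexes whose best replicate RMSD is >= 2 A).
    """
    if not records:
        raise ConsistencyError("no records given")
    protocols = list(records)
    ids = [r.complex_id for r in records[protocols[0]]]
    for proto in protocols:
        if [r.complex_id for r in records[proto]] != ids:
            raise ConsistencyError(
                f"protocol {proto!r} does not cover the same complexes"
            )

    first = records[protocols[0]]
    rows = []
    for i, cid in enumerate(ids):
        row = {
            "complex_id": cid,
            "dofs": first[i].n_dofs,
            "atoms": first[i].n_heavy,
        }
        for proto in protocols:
            rec = records[proto][i]
            row[f"{proto}_mean"] = rec.mean
            row[f"{proto}_sd"] = rec.sd
        rows.append(row)
    table = pd.DataFrame(rows)

    avg = {"complex_id": "average", "dofs": np.nan, "atoms": np.nan}
    summary: dict = {}
    for proto in protocols:
        recs = records[proto]
        mean_of_means = float(np.mean([r.mean for r in recs]))
        mean_of_sds = float(np.mean([r.sd for r in recs]))
        failure_rate = float(np.mean([not r.success for r in recs]))
        avg[f"{proto}_mean"] = mean_of_means
        avg[f"{proto}_sd"] = mean_of_sds
        summary[proto] = {
            "mean_rmsd": mean_of_means,
            "mean_sd": mean_of_sds,
            "failure_rate": failure_rate,
        }
    table = pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
    return table, summary
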