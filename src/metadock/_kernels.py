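"""Numba kernels for the built-in engine's scoring and local refinement.

These mirror the reference NumPy implementation in :mod:`metadock.engine`
(`ScoreField.score`); equality of the two paths is covered by tests.  The
kernels exist purely for speed: the stochastic search evaluates the score
tens of thousands of times per docking call.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def score_kernel(
    coords, heavy_idx, rec, sumr, cutoff, int_i, int_j, int_sumr
):
    """Contact score: smooth attractive well at surface contact plus a
    quadratic clash penalty, over receptor-ligand heavy-atom pairs within
    the cutoff, and an intra-ligand clash term for nonbonded pairs."""
    total = 0.0
    nh = heavy_idx.shape[0]
    nr = rec.shape[0]
    c2 = cutoff * cutoff
    for a in range(nh):
        i = heavy_idx[a]
        x = coords[i, 0]
        y = coords[i, 1]
        z = coords[i, 2]
        for r in range(nr):
            dx = x - rec[r, 0]
            dy = y - rec[r, 1]
            dz = z - rec[r, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= c2:
                s = math.sqrt(d2) - sumr[a, r]
                total += -0.05 * math.exp(-(s / 0.5) ** 2)
                if s < 0.0:
                    total += 0.8 * s * s
    for p in range(int_i.shape[0]):
        i = int_i[p]
        j = int_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        s = math.sqrt(dx * dx + dy * dy + dz * dz) - int_sumr[p]
        if s < -0.5:
            total += 0.8 * s * s
    return total


@njit(cache=True)
def min_contact_gap_kernel(coords, heavy_idx, rec, sumr):
    """Smallest surface gap s = d - (r_i + r_j) over all heavy pairs."""
    best = 1e30
    for a in range(heavy_idx.shape[0]):
        i = heavy_idx[a]
        for r in range(rec.shape[0]):
            dx = coords[i, 0] - rec[r, 0]
            dy = coords[i, 1] - rec[r, 1]
            dz = coords[i, 2] - rec[r, 2]
            s = math.sqrt(dx * dx + dy * dy + dz * dz) - sumr[a, r]
            if s < best:
                best = s
    return best


@njit(cache=True)
def _rotate_subset(coords, idxs, ox, oy, oz, ux, uy, uz, angle_rad):
    c = math.cos(angle_rad)
    s = math.sin(angle_rad)
    for t in range(idxs.shape[0]):
        i = idxs[t]
        px = coords[i, 0] - ox
        py = coords[i, 1] - oy
        pz = coords[i, 2] - oz
        dot = ux * px + uy * py + uz * pz
        cx = uy * pz - uz * py
        cy = uz * px - ux * pz
        cz = ux * py - uy * px
        coords[i, 0] = ox + px * c + cx * s + ux * dot * (1.0 - c)
        coords[i, 1] = oy + py * c + cy * s + uy * dot * (1.0 - c)
        coords[i, 2] = oz + pz * c + cz * s + uz * dot * (1.0 - c)


@njit(cache=True)
def refine_kernel(
    coords, heavy_idx, rec, sumr, cutoff, int_i, int_j, int_sumr,
    bond_anchor, bond_pivot, distal_flat, distal_off,
    box_lo, box_hi,
    t0, a0, t_min, a_min, tol, max_cycles,
):
    """Derivative-free cyclic coordinate descent over rigid translation,
    rigid rotation and active torsions, with step halving.

    Modifies ``coords`` in place; returns the final score.  Translations
    that would push the fragment centroid outside the box are rejected.
    """
    n = coords.shape[0]
    nb = bond_anchor.shape[0]
    best = score_kernel(coords, heavy_idx, rec, sumr, cutoff, int_i, int_j, int_sumr)
    backup = np.empty_like(coords)
    t = t0
    a = a0
    while t >= t_min or a >= a_min:
        for _cycle in range(max_cycles):
            cycle_start = best
            # rigid translations along each axis
            for ax in range(3):
                for sgn in (1.0, -1.0):
                    d = sgn * t
                    m = 0.0
                    for i in range(n):
                        m += coords[i, ax]
                    m = m / n + d
                    if m < box_lo[ax] or m > box_hi[ax]:
                        continue
                    for i in range(n):
                        coords[i, ax] += d
                    sc = score_kernel(
                        coords, heavy_idx, rec, sumr, cutoff, int_i, int_j, int_sumr
                    )
                    if sc < best - 1e-12:
                        best = sc
                        break
                    for i in range(n):
                        coords[i, ax] -= d
            # rigid rotations about the centroid
            if n > 1:
                for ax in range(3):
                    ux = 1.0 if ax == 0 else 0.0
                    uy = 1.0 if ax == 1 else 0.0
                    uz = 1.0 if ax == 2 else 0.0
                    for sgn in (1.0, -1.0):
                        backup[:, :] = coords
                        cx = 0.0
                        cy = 0.0
                        cz = 0.0
                        for i in range(n):
                            cx += coords[i, 0]
                            cy += coords[i, 1]
                            cz += coords[i, 2]
                        cx /= n
                        cy /= n
                        cz /= n
                        all_idx = np.arange(n)
                        _rotate_subset(
                            coords, all_idx, cx, cy, cz, ux, uy, uz,
                            math.radians(sgn * a),
                        )
                        sc = score_kernel(
                            coords, heavy_idx, rec, sumr, cutoff,
                            int_i, int_j, int_sumr,
                        )
                        if sc < best - 1e-12:
                            best = sc
                            break
                        coords[:, :] = backup
            # active torsions
            for b in range(nb):
                anc = bond_anchor[b]
                piv = bond_pivot[b]
                ax_x = coords[piv, 0] - coords[anc, 0]
                ax_y = coords[piv, 1] - coords[anc, 1]
                ax_z = coords[piv, 2] - coords[anc, 2]
                norm = math.sqrt(ax_x * ax_x + ax_y * ax_y + ax_z * ax_z)
                if norm < 1e-9:
                    continue
                ax_x /= norm
                ax_y /= norm
                ax_z /= norm
                idxs = distal_flat[distal_off[b]:distal_off[b + 1]]
                if idxs.shape[0] == 0:
                    continue
                for sgn in (1.0, -1.0):
                    backup[:, :] = coords
                    _rotate_subset(
                        coords, idxs,
                        coords[anc, 0], coords[anc, 1], coords[anc, 2],
                        ax_x, ax_y, ax_z, math.radians(sgn * a),
                    )
                    sc = score_kernel(
                        coords, heavy_idx, rec, sumr, cutoff, int_i, int_j, int_sumr
                    )
                    if sc < best - 1e-12:
                        best = sc
                        break
                    coords[:, :] = backup
            if cycle_start - best < tol:
                break
        t *= 0.5
        a *= 0.5
    return best
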