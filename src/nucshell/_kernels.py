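"""Numba kernels: neighbor list construction and force evaluation.

The neighbor list stores pairs within the per-type-pair cutoff plus a skin and
is rebuilt when any bead has moved more than half the skin.  Pair energies use
the table form U(r) = A*(s^12 - s^6) - C (s = sigma_pair / r), zero beyond the
pair cutoff; bonds are finite-extensible springs centered on their per-bond
rest length.  Everything is serial and deterministic.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def build_neighbor_pairs(pos, types, rlist2, pairs_out):
    """All-pairs scan into pairs_out; returns pair count (-1 if overflow)."""
    n = pos.shape[0]
    cap = pairs_out.shape[0]
    count = 0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ti = types[i]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2[ti, types[j]]:
                if count >= cap:
                    return -1
                pairs_out[count, 0] = i
                pairs_out[count, 1] = j
                count += 1
    return count


@njit(cache=True)
def build_neighbor_pairs_cells(pos, types, rlist2, cell_size, pairs_out):
    """Cell-list neighbor build (same output contract as build_neighbor_pairs)."""
    n = pos.shape[0]
    cap = pairs_out.shape[0]
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = pos[:, d].min()
        hi[d] = pos[:, d].max()
    nc = np.empty(3, dtype=np.int64)
    for d in range(3):
        nc[d] = max(1, int((hi[d] - lo[d]) / cell_size) + 1)
    ncell = nc[0] * nc[1] * nc[2]
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = min(int((pos[i, 0] - lo[0]) / cell_size), nc[0] - 1)
        cy = min(int((pos[i, 1] - lo[1]) / cell_size), nc[1] - 1)
        cz = min(int((pos[i, 2] - lo[2]) / cell_size), nc[2] - 1)
        c = (cx * nc[1] + cy) * nc[2] + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    count = 0
    for cx in range(nc[0]):
        for cy in range(nc[1]):
            for cz in range(nc[2]):
                c = (cx * nc[1] + cy) * nc[2] + cz
                for dx in range(-1, 2):
                    ax = cx + dx
                    if ax < 0 or ax >= nc[0]:
                        continue
                    for dy in range(-1, 2):
                        ay = cy + dy
                        if ay < 0 or ay >= nc[1]:
                            continue
                        for dz in range(-1, 2):
                            az = cz + dz
                            if az < 0 or az >= nc[2]:
                                continue
                            c2 = (ax * nc[1] + ay) * nc[2] + az
                            if c2 < c:
                                continue
                            same = c2 == c
                            for a in range(counts[c], counts[c + 1]):
                                i = order[a]
                                b0 = a + 1 if same else counts[c2]
                                for b in range(b0, counts[c2 + 1]):
                                    j = order[b]
                                    ddx = pos[i, 0] - pos[j, 0]
                                    ddy = pos[i, 1] - pos[j, 1]
                                    ddz = pos[i, 2] - pos[j, 2]
                                    r2 = ddx * ddx + ddy * ddy + ddz * ddz
                                    if r2 < rlist2[types[i], types[j]]:
                                        if count >= cap:
                                            return -1
                                        if i < j:
                                            pairs_out[count, 0] = i
                                            pairs_out[count, 1] = j
                                        else:
                                            pairs_out[count, 0] = j
                                            pairs_out[count, 1] = i
                                        count += 1
    return count


@njit(cache=True)
def compute_forces(pos, types, pairs, n_pairs,
                   A, C, rc2, sig2,
                   bond_i, bond_j, bond_r0, bond_k, bond_dmax,
                   forces):
    """Pair + bond forces into ``forces``; returns (potential_energy, bad_bond).

    bad_bond is -1 when all bonds are within their finite-extensibility range,
    otherwise the index of the first overstretched bond (forces invalid then).
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pe = 0.0
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        ti = types[i]
        tj = types[j]
        if r2 < rc2[ti, tj]:
            if r2 < 1e-18:  # coincident beads: singular geometry
                return np.nan, p
            s2 = sig2[ti, tj] / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            a = A[ti, tj]
            pe += a * (s12 - s6) - C[ti, tj]
            fr = a * (12.0 * s12 - 6.0 * s6) / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        delta = bond_dmax[b] - bond_r0[b]
        y = (r - bond_r0[b]) / delta
        if y >= 1.0 or y <= -1.0:
            return pe, b
        one_m_y2 = 1.0 - y * y
        pe += -0.5 * bond_k[b] * delta * delta * np.log(one_m_y2)
        # radial force -dU/dr, projected on the separation vector
        fr = -bond_k[b] * delta * y / one_m_y2 / max(r, 1e-12)
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return pe, -1


@njit(cache=True)
def max_displacement_sq(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return m
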