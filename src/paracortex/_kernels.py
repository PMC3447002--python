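"""Compiled per-step movement kernels.

These numba kernels implement exactly the semantics of the reference
NumPy/Python operations (`motility.base_jump_probabilities` sampling with
crowding, `lattice.resolve_double_occupancy`) over the whole population in
a single pass; cells are visited in a caller-supplied shuffled order and
all randomness comes from caller-supplied uniform draws, so runs are
reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def move_kernel(
    perm,
    pos,
    heading,
    alpha,
    vx,
    vy,
    vz,
    state,
    occ,
    cum_base,
    off_flat,
    jlen,
    ux,
    uy,
    uz,
    p_reorient,
    r_branch,
    r_pick,
    r_head,
):
    """One movement step for all cells, in the order given by ``perm``.

    With probability alpha[i] the draw comes from the chemotaxis-only
    cos²/length distribution toward (vx, vy, vz)[i]; otherwise from the
    base-walk cumulative table row of the cell's heading state. A draw
    into a full or outside site is a failed move: the cell stays and the
    heading is unchanged (equivalent to transferring blocked probability
    mass to the no-jump slot). Executed jumps reset the heading with
    probability ``p_reorient``.
    """
    for k in range(perm.size):
        i = perm[k]
        j = 0
        a = alpha[i]
        if a > 0.0 and r_branch[i] < a:
            tot = 0.0
            w = np.empty(26)
            for m in range(26):
                c = ux[m] * vx[i] + uy[m] * vy[i] + uz[m] * vz[i]
                if c > 0.0:
                    w[m] = c * c / jlen[m]
                else:
                    w[m] = 0.0
                tot += w[m]
            if tot <= 0.0:
                continue
            target = r_pick[i] * tot
            acc = 0.0
            for m in range(26):
                acc += w[m]
                if w[m] > 0.0 and acc >= target:
                    j = m + 1
                    break
            if j == 0:
                continue
        else:
            row = cum_base[heading[i]]
            r = r_pick[i]
            j = 26
            for m in range(27):
                if r < row[m]:
                    j = m
                    break
        if j == 0:
            continue
        d = pos[i] + off_flat[j - 1]
        if state[d] == 1 and occ[d] < 2:
            occ[pos[i]] -= 1
            occ[d] += 1
            pos[i] = d
            if r_head[i] < p_reorient:
                heading[i] = j


@njit(cache=True)
def resolve_kernel(
    perm,
    pos,
    heading,
    alpha,
    vx,
    vy,
    vz,
    state,
    occ,
    base_probs,
    off_flat,
    jlen,
    ux,
    uy,
    uz,
    p_reorient,
    r_pick,
    r_head,
):
    """Forced move attempt for every cell on a doubly occupied site.

    The cell's combined jump distribution (no-jump excluded) is
    renormalized over admissible destinations and sampled; if no
    destination is admissible the cell stays and is counted. Cells whose
    partner already vacated the shared site are skipped. Returns the
    number of stuck cells.
    """
    stuck = 0
    for k in range(perm.size):
        i = perm[k]
        p = pos[i]
        if occ[p] < 2:
            continue
        a = alpha[i]
        ctot = 0.0
        wc = np.zeros(26)
        if a > 0.0:
            for m in range(26):
                c = ux[m] * vx[i] + uy[m] * vy[i] + uz[m] * vz[i]
                if c > 0.0:
                    wc[m] = c * c / jlen[m]
                    ctot += wc[m]
        w = np.zeros(26)
        tot = 0.0
        for m in range(26):
            d = p + off_flat[m]
            if state[d] == 1 and occ[d] < 2:
                val = (1.0 - a) * base_probs[heading[i], m + 1]
                if ctot > 0.0:
                    val += a * wc[m] / ctot
                w[m] = val
                tot += val
        if tot <= 0.0:
            stuck += 1
            continue
        target = r_pick[i] * tot
        acc = 0.0
        j = -1
        for m in range(26):
            acc += w[m]
            if w[m] > 0.0 and acc >= target:
                j = m
                break
        if j < 0:
            for m in range(25, -1, -1):
                if w[m] > 0.0:
                    j = m
                    break
        occ[p] -= 1
        d = p + off_flat[j]
        occ[d] += 1
        pos[i] = d
        if r_head[i] < p_reorient:
            heading[i] = j + 1
    return stuck
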