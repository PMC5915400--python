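"""Numba-compiled inner loops for the lattice model.

All randomness is pre-drawn from a single seeded numpy Generator by the
callers in :mod:`matesim.lattice` and passed in as flat arrays, so runs are
bit-reproducible from ``(params, seed)`` and independent of numba's own RNG.

Lattice arrays are flat (length ``side**2``), C-order row major.  Cell codes
live in :mod:`matesim.lattice`; they are duplicated here as plain ints because
numba specialises on literals.
"""

import numba
import numpy as np

EMPTY = 0
P = 1
M = 2

NO_STRATEGY = 0
SWITCHER = 1
NONSWITCHER = 2

PHASE_NA = 0
WILL_SWITCH = 1
WONT_SWITCH = 2

PEDIGREE = 0
BERNOULLI = 1


@numba.njit(cache=True)
def growth_round_kernel(
    mating_type,
    strategy,
    phase,
    clone_id,
    intraclonal,
    side,
    torus,
    growth_chance,
    switching_cost,
    intraclonal_cost,
    order,
    u_div,
    u_tgt,
    u_mig,
    u_phase,
    pedigree_mode,
):
    """One asexual round: cells in ``order`` each attempt a single division.

    Random-sequential update: occupancy changes take effect immediately, so a
    site emptied-into earlier in the round blocks later cells.  Returns the
    number of divisions performed.
    """
    n_div = 0
    nbr = np.empty(8, np.int64)
    for i in range(order.shape[0]):
        idx = order[i]
        row = idx // side
        col = idx % side
        # empty Moore neighbours
        k = 0
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = row + dr
                cc = col + dc
                if torus:
                    rr = rr % side
                    cc = cc % side
                elif rr < 0 or rr >= side or cc < 0 or cc >= side:
                    continue
                j = rr * side + cc
                if mating_type[j] == EMPTY:
                    nbr[k] = j
                    k += 1
        if k == 0:
            continue
        p = growth_chance
        if strategy[idx] == SWITCHER:
            p *= 1.0 - switching_cost
        if intraclonal[idx]:
            p *= intraclonal_cost
        if u_div[i] >= p:
            continue
        tgt = nbr[int(u_tgt[i] * k)]

        mt0 = mating_type[idx]
        opposite = M if mt0 == P else P
        if strategy[idx] == NONSWITCHER:
            # non-switcher lineages conserve mating type
            type_a = mt0
            type_b = mt0
            phase_a = PHASE_NA
            phase_b = PHASE_NA
        else:
            if phase[idx] == WILL_SWITCH:
                # one product switches (and is not yet re-competent), the
                # other keeps the type and stays competent
                type_a = opposite
                type_b = mt0
                if pedigree_mode == PEDIGREE:
                    phase_a = WONT_SWITCH
                    phase_b = WILL_SWITCH
                else:
                    # two independent bits from one uniform
                    phase_a = WILL_SWITCH if u_phase[i] < 0.5 else WONT_SWITCH
                    phase_b = WILL_SWITCH if (u_phase[i] * 2.0) % 1.0 < 0.5 else WONT_SWITCH
            else:
                # non-competent switcher: no switch, one product gains
                # competence
                type_a = mt0
                type_b = mt0
                if pedigree_mode == PEDIGREE:
                    phase_a = WILL_SWITCH
                    phase_b = WONT_SWITCH
                else:
                    phase_a = WILL_SWITCH if u_phase[i] < 0.5 else WONT_SWITCH
                    phase_b = WILL_SWITCH if (u_phase[i] * 2.0) % 1.0 < 0.5 else WONT_SWITCH
        # fair coin: which product migrates to the empty site
        if u_mig[i] < 0.5:
            site_a, site_b = idx, tgt
        else:
            site_a, site_b = tgt, idx
        mating_type[site_a] = type_a
        phase[site_a] = phase_a
        mating_type[site_b] = type_b
        phase[site_b] = phase_b
        strategy[tgt] = strategy[idx]
        clone_id[tgt] = clone_id[idx]
        intraclonal[tgt] = intraclonal[idx]
        n_div += 1
    return n_div


@numba.njit(cache=True)
def mating_moore_kernel(mating_type, mated, side, torus, order, u_pick, out_a, out_b):
    """Greedy neighbourhood mating pass.

    Cells are visited in ``order``; an unmated cell pairs with a uniformly
    chosen unmated opposite-type Moore neighbour if one exists.  A single pass
    yields a maximal matching: a cell left unmated at its visit can never gain
    an eligible partner later (partners only ever get consumed).
    """
    nz = 0
    nbr = np.empty(8, np.int64)
    for i in range(order.shape[0]):
        idx = order[i]
        if mated[idx] or mating_type[idx] == EMPTY:
            continue
        want = M if mating_type[idx] == P else P
        row = idx // side
        col = idx % side
        k = 0
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = row + dr
                cc = col + dc
                if torus:
                    rr = rr % side
                    cc = cc % side
                elif rr < 0 or rr >= side or cc < 0 or cc >= side:
                    continue
                j = rr * side + cc
                if mating_type[j] == want and not mated[j]:
                    nbr[k] = j
                    k += 1
        if k == 0:
            continue
        j = nbr[int(u_pick[i] * k)]
        mated[idx] = True
        mated[j] = True
        out_a[nz] = idx
        out_b[nz] = j
        nz += 1
    return nz


@numba.njit(cache=True)
def mating_global_kernel(mating_type, mated, order, u_pick, out_a, out_b):
    """Greedy mass-action mating: partner uniform among all unmated opposites.

    Maintains swap-removal pools of unmated P and M cells so each pairing is
    O(1); total zygotes equal min(#P, #M) among participating cells.
    """
    n = mating_type.shape[0]
    pool_p = np.empty(n, np.int64)
    pool_m = np.empty(n, np.int64)
    pos = np.empty(n, np.int64)
    np_ = 0
    nm = 0
    for idx in range(n):
        if mating_type[idx] == P and not mated[idx]:
            pool_p[np_] = idx
            pos[idx] = np_
            np_ += 1
        elif mating_type[idx] == M and not mated[idx]:
            pool_m[nm] = idx
            pos[idx] = nm
            nm += 1
    nz = 0
    for i in range(order.shape[0]):
        idx = order[i]
        if mated[idx] or mating_type[idx] == EMPTY:
            continue
        if mating_type[idx] == P:
            if nm == 0:
                continue
            j = pool_m[int(u_pick[i] * nm)]
            # remove j from M pool, idx from P pool
            q = pos[j]
            pool_m[q] = pool_m[nm - 1]
            pos[pool_m[q]] = q
            nm -= 1
            q = pos[idx]
            pool_p[q] = pool_p[np_ - 1]
            pos[pool_p[q]] = q
            np_ -= 1
        else:
            if np_ == 0:
                continue
            j = pool_p[int(u_pick[i] * np_)]
            q = pos[j]
            pool_p[q] = pool_p[np_ - 1]
            pos[pool_p[q]] = q
            np_ -= 1
            q = pos[idx]
            pool_m[q] = pool_m[nm - 1]
            pos[pool_m[q]] = q
            nm -= 1
        mated[idx] = True
        mated[j] = True
        out_a[nz] = idx
        out_b[nz] = j
        nz += 1
    return nz
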