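"""Compiled inner loop of the cytoneme simulator.

Samples the same process as the reference operations in
:mod:`adhesim.cytoneme_sim`, with one shortcut: the per-pair established
contact count over the ``m = min(x_i, x_j)`` aligned levels is drawn as
``c ~ Binomial(m, p)``, and the single individually needed entry — the top
aligned level, i.e. the tip of the shorter cytoneme (both tips when equal) —
is drawn from its exact conditional law given ``c`` (Bernoulli ``c/m``).
This is distributionally identical to assigning every level independently.
"""

import numpy as np
from numba import njit

__all__ = ["run"]


@njit(cache=True)
def _find_pairs(pos, occ, radius, m_sites, pi, pj):
    """Neighbouring unordered pairs via occupancy lookup; returns count."""
    n = pos.shape[0]
    np_ = 0
    for i in range(n):
        for d in range(1, radius + 1):
            j = occ[(pos[i] + d) % m_sites]
            if j >= 0:
                # record each unordered pair once
                a, b = (i, j) if i < j else (j, i)
                pi[np_] = a
                pj[np_] = b
                np_ += 1
    return np_


@njit(cache=True)
def _pair_contacts_involving(i, pos, occ, lens, radius, m_sites, p_contact):
    """Fresh total contact count over all pairs involving cytoneme i."""
    total = 0
    for d in range(-radius, radius + 1):
        if d == 0:
            continue
        j = occ[(pos[i] + d) % m_sites]
        if j >= 0 and j != i:
            if d < 0 and (pos[i] + d) % m_sites == (pos[i] + abs(d)) % m_sites:
                continue  # tiny lattice: same site reached both ways
            m = min(lens[i], lens[j])
            if m > 0:
                total += np.random.binomial(m, p_contact)
    return total


@njit(cache=True)
def run(
    pos0,
    len0,
    m_sites,
    radius,
    p_elong0,
    p_shrink0,
    alpha,
    e_ii,
    p_contact,
    k_bt,
    total_steps,
    burn_in,
    snap_interval,
    snap_count,
    seed,
):
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    lens = len0.copy()
    occ = -np.ones(m_sites, dtype=np.int64)
    for i in range(n):
        occ[pos[i]] = i

    max_pairs = n * radius + 1
    pi = np.empty(max_pairs, dtype=np.int64)
    pj = np.empty(max_pairs, dtype=np.int64)
    pc = np.empty(max_pairs, dtype=np.int64)
    ptop = np.empty(max_pairs, dtype=np.uint8)
    tip = np.empty(n, dtype=np.int64)
    cyt_count = np.empty(n, dtype=np.int64)

    snap_len = np.zeros((snap_count, n), dtype=np.int64)
    snap_pos = np.zeros((snap_count, n), dtype=np.int64)
    snap_cnt = np.zeros((snap_count, n), dtype=np.int64)
    snap_pair_n = np.zeros(snap_count, dtype=np.int64)
    snap_pi = np.zeros((snap_count, max_pairs), dtype=np.int64)
    snap_pj = np.zeros((snap_count, max_pairs), dtype=np.int64)
    snap_pc = np.zeros((snap_count, max_pairs), dtype=np.int64)
    s_idx = 0

    for stp in range(1, total_steps + 1):
        # 1. fresh contact assignment for every neighbouring pair
        n_pairs = _find_pairs(pos, occ, radius, m_sites, pi, pj)
        for i in range(n):
            tip[i] = 0
            cyt_count[i] = 0
        for q in range(n_pairs):
            a = pi[q]
            b = pj[q]
            m = min(lens[a], lens[b])
            if m > 0:
                c = np.random.binomial(m, p_contact)
                top = 0
                if c > 0 and np.random.random() < c / m:
                    top = 1
                pc[q] = c
                ptop[q] = top
                cyt_count[a] += c
                cyt_count[b] += c
                # the top aligned level is the tip of the shorter cytoneme
                if lens[a] <= lens[b]:
                    tip[a] += top
                if lens[b] <= lens[a]:
                    tip[b] += top
            else:
                pc[q] = 0
                ptop[q] = 0

        # 2. synchronous growth/shrink using pre-update tip contacts
        for i in range(n):
            x = lens[i]
            pe = p_elong0 * np.exp(-alpha * x)
            ps = p_shrink0 * np.exp(-tip[i] * e_ii)
            r = np.random.random()
            if x > 0 and r <= ps / (pe + ps):
                lens[i] = x - 1
            else:
                lens[i] = x + 1

        # 3. one Metropolis translocation attempt (+-1 site, exclusion)
        i = np.random.randint(0, n)
        d = 1 if np.random.random() < 0.5 else -1
        target = (pos[i] + d) % m_sites
        if occ[target] < 0:
            before = 0
            for q in range(n_pairs):
                if pi[q] == i or pj[q] == i:
                    before += pc[q]
            old = pos[i]
            occ[old] = -1
            pos[i] = target
            occ[target] = i
            after = _pair_contacts_involving(i, pos, occ, lens, radius, m_sites, p_contact)
            d_e = -e_ii * (after - before)
            accept = True
            if d_e > 0:
                accept = np.random.random() <= np.exp(-d_e / k_bt)
            if not accept:
                occ[target] = -1
                pos[i] = old
                occ[old] = i
            else:
                # refresh the step's assignment for the mover so snapshots
                # taken at this step reflect the accepted configuration;
                # pairs not involving the mover keep their drawn counts
                old_n = n_pairs
                opi = pi[:old_n].copy()
                opj = pj[:old_n].copy()
                opc = pc[:old_n].copy()
                n_pairs = _find_pairs(pos, occ, radius, m_sites, pi, pj)
                for q in range(n_pairs):
                    a = pi[q]
                    b = pj[q]
                    m = min(lens[a], lens[b])
                    if m <= 0:
                        pc[q] = 0
                    elif a == i or b == i:
                        pc[q] = np.random.binomial(m, p_contact)
                    else:
                        pc[q] = 0
                        for w in range(old_n):
                            if opi[w] == a and opj[w] == b:
                                pc[q] = opc[w]
                                break
                for ii in range(n):
                    cyt_count[ii] = 0
                for q in range(n_pairs):
                    cyt_count[pi[q]] += pc[q]
                    cyt_count[pj[q]] += pc[q]

        if stp >= burn_in and s_idx < snap_count and (stp - burn_in) % snap_interval == 0:
            for ii in range(n):
                snap_len[s_idx, ii] = lens[ii]
                snap_pos[s_idx, ii] = pos[ii]
                snap_cnt[s_idx, ii] = cyt_count[ii]
            snap_pair_n[s_idx] = n_pairs
            for q in range(n_pairs):
                snap_pi[s_idx, q] = pi[q]
                snap_pj[s_idx, q] = pj[q]
                snap_pc[s_idx, q] = pc[q]
            s_idx += 1

    return snap_len, snap_pos, snap_cnt, snap_pair_n, snap_pi, snap_pj, snap_pc
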