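"""Compiled periodic Voronoi geometry and Metropolis Monte Carlo loop.

Each Voronoi cell is computed independently by half-plane clipping: starting
from a large square around the generator, the polygon is clipped by the
perpendicular bisector with every nearby generator (periodic images
included).  The result is validated with the standard sufficiency criterion:
if every generator within distance ``G`` has been clipped and the farthest
polygon vertex lies within ``G/2`` of the generator, the cell is exact; the
gathering radius grows adaptively until the criterion holds.

This locality is what the Monte Carlo loop exploits: a point displacement
can only change the polygons of cells whose generator lies within twice
their own circumradius of the old or new position, so only those energies
are recomputed per move.
"""

import numpy as np
from numba import njit

__all__ = ["tessellate_arrays", "run_mc", "ENV_LABEL", "MAXV", "MAXN"]

ENV_LABEL = 3
MAXV = 96  # polygon vertex capacity
MAXN = 64  # neighbour capacity per cell
MAXC = 4096  # candidate capacity


@njit(cache=True, inline="always")
def _wrap(x, box):
    x = x % box
    if x < 0:
        x += box
    return x


@njit(cache=True)
def _clip_halfplane(px, py, own, nv, cx, cy, qx, qy, qid, tx, ty, town):
    """Clip polygon by the bisector of (c, q), keeping the side of c.

    Edge i runs from vertex i to i+1 and carries the index of the generator
    whose bisector it lies on (-1 for the seed square).  Returns the new
    vertex count.
    """
    mx = 0.5 * (cx + qx)
    my = 0.5 * (cy + qy)
    nx_ = qx - cx
    ny_ = qy - cy
    k = 0
    for i in range(nv):
        j = i + 1
        if j == nv:
            j = 0
        ga = (px[i] - mx) * nx_ + (py[i] - my) * ny_
        gb = (px[j] - mx) * nx_ + (py[j] - my) * ny_
        if ga <= 0.0:
            tx[k] = px[i]
            ty[k] = py[i]
            town[k] = own[i]
            k += 1
            if gb > 0.0:
                t = ga / (ga - gb)
                tx[k] = px[i] + t * (px[j] - px[i])
                ty[k] = py[i] + t * (py[j] - py[i])
                town[k] = qid
                k += 1
        elif gb <= 0.0:
            t = ga / (ga - gb)
            tx[k] = px[i] + t * (px[j] - px[i])
            ty[k] = py[i] + t * (py[j] - py[i])
            town[k] = own[i]
            k += 1
    for i in range(k):
        px[i] = tx[i]
        py[i] = ty[i]
        own[i] = town[i]
    return k


@njit(cache=True)
def _gather_bins(cx, cy, self_idx, pts, box, head, nxt, nb, bs, ring, cqx, cqy, cid):
    """Candidates from bins within `ring`; minimal-image coordinates.

    Guarantees completeness out to distance ``ring * bs``; valid only when
    the minimal image is the sole relevant one (box much larger than the
    gathering radius), which the caller enforces.
    """
    n_c = 0
    bx = int(cx / bs)
    by = int(cy / bs)
    if bx >= nb:
        bx = nb - 1
    if by >= nb:
        by = nb - 1
    span = 2 * ring + 1
    if span >= nb:
        # every bin once
        for b in range(nb * nb):
            q = head[b]
            while q >= 0:
                if q != self_idx:
                    dx = pts[q, 0] - cx
                    dx -= box * np.rint(dx / box)
                    dy = pts[q, 1] - cy
                    dy -= box * np.rint(dy / box)
                    cqx[n_c] = cx + dx
                    cqy[n_c] = cy + dy
                    cid[n_c] = q
                    n_c += 1
                q = nxt[q]
    else:
        for ox in range(-ring, ring + 1):
            gx = (bx + ox) % nb
            for oy in range(-ring, ring + 1):
                gy = (by + oy) % nb
                q = head[gx * nb + gy]
                while q >= 0:
                    if q != self_idx:
                        dx = pts[q, 0] - cx
                        dx -= box * np.rint(dx / box)
                        dy = pts[q, 1] - cy
                        dy -= box * np.rint(dy / box)
                        cqx[n_c] = cx + dx
                        cqy[n_c] = cy + dy
                        cid[n_c] = q
                        n_c += 1
                    q = nxt[q]
    return n_c


@njit(cache=True)
def _gather_images(cx, cy, self_idx, pts, box, shells, cqx, cqy, cid):
    """All generators with all periodic images within +-`shells` boxes.

    Complete (no validity assumption); used for small systems where cells can
    span a sizeable fraction of the box.
    """
    m = pts.shape[0]
    n_c = 0
    for q in range(m):
        for sx in range(-shells, shells + 1):
            for sy in range(-shells, shells + 1):
                if q == self_idx and sx == 0 and sy == 0:
                    continue
                cqx[n_c] = pts[q, 0] + sx * box
                cqy[n_c] = pts[q, 1] + sy * box
                cid[n_c] = q
                n_c += 1
    return n_c


@njit(cache=True)
def _cell_poly(
    self_idx, cx, cy, pts, box, small_mode, head, nxt, nb, bs, ring0,
    px, py, own, tx, ty, town, cqx, cqy, cid,
):
    """Exact Voronoi polygon of one generator.

    Returns ``(nv, rmax)``; polygon vertices/edge owners are left in
    ``px/py/own[:nv]``.  Adaptively enlarges the gathering radius until the
    farthest vertex is within half of it.
    """
    if small_mode:
        n_c = _gather_images(cx, cy, self_idx, pts, box, 4, cqx, cqy, cid)
        g = 4.0 * box
        px[0] = cx - g
        py[0] = cy - g
        px[1] = cx + g
        py[1] = cy - g
        px[2] = cx + g
        py[2] = cy + g
        px[3] = cx - g
        py[3] = cy + g
        own[0] = -1
        own[1] = -1
        own[2] = -1
        own[3] = -1
        nv = 4
        for t in range(n_c):
            nv = _clip_halfplane(px, py, own, nv, cx, cy, cqx[t], cqy[t], cid[t], tx, ty, town)
        rmax2 = 0.0
        for i in range(nv):
            d2 = (px[i] - cx) ** 2 + (py[i] - cy) ** 2
            if d2 > rmax2:
                rmax2 = d2
        return nv, np.sqrt(rmax2)

    ring = ring0
    while True:
        g = ring * bs
        if 2.0 * g >= box:
            # gathering radius no longer small vs the box: complete fallback
            n_c = _gather_images(cx, cy, self_idx, pts, box, 2, cqx, cqy, cid)
            g = 1e30
        else:
            n_c = _gather_bins(cx, cy, self_idx, pts, box, head, nxt, nb, bs, ring, cqx, cqy, cid)
        half = g if g < 1e29 else 2.0 * box
        px[0] = cx - half
        py[0] = cy - half
        px[1] = cx + half
        py[1] = cy - half
        px[2] = cx + half
        py[2] = cy + half
        px[3] = cx - half
        py[3] = cy + half
        own[0] = -1
        own[1] = -1
        own[2] = -1
        own[3] = -1
        nv = 4
        for t in range(n_c):
            nv = _clip_halfplane(px, py, own, nv, cx, cy, cqx[t], cqy[t], cid[t], tx, ty, town)
        rmax2 = 0.0
        for i in range(nv):
            d2 = (px[i] - cx) ** 2 + (py[i] - cy) ** 2
            if d2 > rmax2:
                rmax2 = d2
        rmax = np.sqrt(rmax2)
        if 2.0 * rmax <= g:
            return nv, rmax
        ring += 2


@njit(cache=True)
def _poly_energy(nv, px, py, own, self_idx, cx, cy, my_label, labels, gamma, a0, ac, bc, edge_eps):
    """Mechanical energy of one cell from its polygon.

    ``a*(A-A0)^2 + b*P^2 - 0.5 * sum gamma[q_i, q_j] * l_ij``; the gamma
    matrix carries zeros for any pair involving the environment label, and
    edges shorter than ``edge_eps`` are treated as numerical slivers.
    Edges against the cell's own periodic images (possible only in tiny
    boxes) are not adhesive contacts.
    """
    area2 = 0.0
    perim = 0.0
    adh = 0.0
    for i in range(nv):
        j = i + 1
        if j == nv:
            j = 0
        ax = px[i] - cx
        ay = py[i] - cy
        bx = px[j] - cx
        by = py[j] - cy
        area2 += ax * by - ay * bx
        el = np.sqrt((bx - ax) ** 2 + (by - ay) ** 2)
        perim += el
        o = own[i]
        if o >= 0 and o != self_idx and el >= edge_eps:
            adh += gamma[my_label, labels[o]] * el
    area = 0.5 * np.abs(area2)
    return ac * (area - a0) ** 2 + bc * perim * perim - 0.5 * adh


@njit(cache=True)
def tessellate_arrays(pts, box, small_mode, bs_target):
    """Full periodic Voronoi tessellation of all generators.

    Returns per-cell areas, perimeters, circumradii, and shared-edge data
    aggregated per neighbouring generator (lengths summed over periodic
    images): ``(areas, perims, rmax, n_neigh, neigh_idx, neigh_len)``.
    """
    m = pts.shape[0]
    nb = max(1, int(box / bs_target))
    bs = box / nb
    head = -np.ones(nb * nb, dtype=np.int64)
    nxt = -np.ones(m, dtype=np.int64)
    for q in range(m):
        bx = min(int(pts[q, 0] / bs), nb - 1)
        by = min(int(pts[q, 1] / bs), nb - 1)
        b = bx * nb + by
        nxt[q] = head[b]
        head[b] = q

    px = np.empty(MAXV)
    py = np.empty(MAXV)
    own = np.empty(MAXV, dtype=np.int64)
    tx = np.empty(MAXV)
    ty = np.empty(MAXV)
    town = np.empty(MAXV, dtype=np.int64)
    cqx = np.empty(MAXC)
    cqy = np.empty(MAXC)
    cid = np.empty(MAXC, dtype=np.int64)

    areas = np.zeros(m)
    perims = np.zeros(m)
    rmaxs = np.zeros(m)
    n_neigh = np.zeros(m, dtype=np.int64)
    neigh_idx = -np.ones((m, MAXN), dtype=np.int64)
    neigh_len = np.zeros((m, MAXN))

    for c in range(m):
        cx = pts[c, 0]
        cy = pts[c, 1]
        nv, rmax = _cell_poly(
            c, cx, cy, pts, box, small_mode, head, nxt, nb, bs, 2,
            px, py, own, tx, ty, town, cqx, cqy, cid,
        )
        area2 = 0.0
        perim = 0.0
        for i in range(nv):
            j = i + 1
            if j == nv:
                j = 0
            ax = px[i] - cx
            ay = py[i] - cy
            bx_ = px[j] - cx
            by_ = py[j] - cy
            area2 += ax * by_ - ay * bx_
            el = np.sqrt((bx_ - ax) ** 2 + (by_ - ay) ** 2)
            perim += el
            o = own[i]
            if o >= 0 and o != c and el > 0.0:
                found = -1
                for w in range(n_neigh[c]):
                    if neigh_idx[c, w] == o:
                        found = w
                        break
                if found < 0:
                    found = n_neigh[c]
                    neigh_idx[c, found] = o
                    n_neigh[c] += 1
                neigh_len[c, found] += el
        areas[c] = 0.5 * np.abs(area2)
        perims[c] = perim
        rmaxs[c] = rmax
    return areas, perims, rmaxs, n_neigh, neigh_idx, neigh_len


@njit(cache=True)
def _gather_affected(
    x1, y1, x2, y2, pts, labels, box, head, nxt, nb, bs, rmax, rmax_bound,
    small_mode, aff, stamp, stampv,
):
    """Mechanical cells whose polygon can change when a generator moves
    between (x1, y1) and (x2, y2): generator within twice its own
    circumradius of either position."""
    m = pts.shape[0]
    na = 0
    if small_mode:
        for c in range(m):
            if labels[c] == ENV_LABEL:
                continue
            keep = False
            for k in range(2):
                ox = x1 if k == 0 else x2
                oy = y1 if k == 0 else y2
                dx = pts[c, 0] - ox
                dx -= box * np.rint(dx / box)
                dy = pts[c, 1] - oy
                dy -= box * np.rint(dy / box)
                if dx * dx + dy * dy <= (2.0 * rmax[c] + 1e-9) ** 2:
                    keep = True
            if keep:
                aff[na] = c
                stamp[c] = stampv
                na += 1
        return na
    ring_aff = int(2.0 * rmax_bound / bs) + 1
    if 2 * ring_aff + 1 > nb:
        ring_aff = nb // 2  # stamp dedupe keeps revisits harmless
    for k in range(2):
        ox = x1 if k == 0 else x2
        oy = y1 if k == 0 else y2
        bx = min(int(ox / bs), nb - 1)
        by = min(int(oy / bs), nb - 1)
        for oxb in range(-ring_aff, ring_aff + 1):
            gx = (bx + oxb) % nb
            for oyb in range(-ring_aff, ring_aff + 1):
                gy = (by + oyb) % nb
                q = head[gx * nb + gy]
                while q >= 0:
                    if labels[q] != ENV_LABEL and stamp[q] != stampv:
                        dx = pts[q, 0] - ox
                        dx -= box * np.rint(dx / box)
                        dy = pts[q, 1] - oy
                        dy -= box * np.rint(dy / box)
                        if dx * dx + dy * dy <= (2.0 * rmax[q] + 1e-9) ** 2:
                            aff[na] = q
                            stamp[q] = stampv
                            na += 1
                    q = nxt[q]
    return na


@njit(cache=True)
def run_mc(
    pts0,
    labels0,
    box,
    gamma,
    a0,
    ac,
    bc,
    kbt,
    edge_eps,
    total_steps,
    burn_in,
    snap_interval,
    snap_count,
    max_disp0,
    rate_lo,
    rate_hi,
    adapt_interval,
    recompute_interval,
    seed,
    kbt_start,
    anneal_steps,
    relocate_frac,
    swap_frac,
):
    """Metropolis Monte Carlo over generator points with local energy updates.

    The temperature is annealed geometrically from ``kbt_start`` down to
    ``kbt`` over the first ``anneal_steps`` steps (pass ``anneal_steps = 0``
    or ``kbt_start = kbt`` for a fixed-temperature run).  A fraction
    ``relocate_frac`` of proposals relocates the chosen point uniformly in
    the box instead of within the displacement disk, and a fraction
    ``swap_frac`` exchanges the type labels of two cellular generators
    (Kawasaki exchange: geometry untouched, only adhesion terms change).
    All proposals are symmetric, so the stationary law at fixed temperature
    is Boltzmann.  Only displacement proposals enter the step-size
    adaptation window.

    Returns ``(snapshots, energy_trace, final_max_disp, accepted, attempted)``
    where ``snapshots`` has shape (snap_count, m, 2) and the trace records the
    incrementally tracked total energy at each snapshot.
    """
    np.random.seed(seed)
    m = pts0.shape[0]
    pts = pts0.copy()
    labels = labels0.copy()
    n_cellpts = 0
    for q in range(m):
        if labels[q] != ENV_LABEL:
            n_cellpts += 1
    cell_ids = np.empty(n_cellpts, dtype=np.int64)
    w = 0
    for q in range(m):
        if labels[q] != ENV_LABEL:
            cell_ids[w] = q
            w += 1
    small_mode = box < 8.0 or m < 30

    nb = max(1, int(box / 1.0))
    bs = box / nb
    head = -np.ones(nb * nb, dtype=np.int64)
    nxt = -np.ones(m, dtype=np.int64)
    prv = -np.ones(m, dtype=np.int64)
    binof = np.empty(m, dtype=np.int64)

    for q in range(m):
        bx = min(int(pts[q, 0] / bs), nb - 1)
        by = min(int(pts[q, 1] / bs), nb - 1)
        b = bx * nb + by
        nxt[q] = head[b]
        if head[b] >= 0:
            prv[head[b]] = q
        prv[q] = -1
        head[b] = q
        binof[q] = b

    px = np.empty(MAXV)
    py = np.empty(MAXV)
    own = np.empty(MAXV, dtype=np.int64)
    tx = np.empty(MAXV)
    ty = np.empty(MAXV)
    town = np.empty(MAXV, dtype=np.int64)
    cqx = np.empty(MAXC)
    cqy = np.empty(MAXC)
    cid = np.empty(MAXC, dtype=np.int64)

    e = np.zeros(m)
    rmax = np.zeros(m)
    e_new = np.zeros(m)
    rmax_new = np.zeros(m)
    aff = np.empty(m, dtype=np.int64)
    stamp = np.zeros(m, dtype=np.int64)
    stampv = 0

    def_ring = 2

    # initial energies and circumradii of all mechanical (non-environment) cells
    u_total = 0.0
    rmax_bound = 0.0
    for c in range(m):
        if labels[c] == ENV_LABEL:
            continue
        nv, rm = _cell_poly(
            c, pts[c, 0], pts[c, 1], pts, box, small_mode, head, nxt, nb, bs, def_ring,
            px, py, own, tx, ty, town, cqx, cqy, cid,
        )
        e[c] = _poly_energy(
            nv, px, py, own, c, pts[c, 0], pts[c, 1], labels[c], labels, gamma,
            a0, ac, bc, edge_eps,
        )
        rmax[c] = rm
        u_total += e[c]
        if rm > rmax_bound:
            rmax_bound = rm

    snaps = np.zeros((snap_count, m, 2))
    snap_labels = np.zeros((snap_count, m), dtype=np.int64)
    trace = np.zeros(snap_count)
    s_idx = 0
    max_disp = max_disp0
    acc_window = 0
    disp_att = 0
    acc_total = 0
    att_total = 0

    if anneal_steps > 0 and kbt_start > kbt:
        cool = (kbt / kbt_start) ** (1.0 / anneal_steps)
    else:
        cool = 1.0
    kbt_now = kbt_start if anneal_steps > 0 else kbt

    for stp in range(1, total_steps + 1):
        if stp <= anneal_steps:
            kbt_now *= cool
        else:
            kbt_now = kbt
        att_total += 1
        if swap_frac > 0.0 and n_cellpts >= 2 and np.random.random() < swap_frac:
            # Kawasaki exchange of two generator labels (cell-cell orders the
            # arrangement; cell-environment migrates vacancies and cells)
            a = np.random.randint(0, m)
            b = np.random.randint(0, m)
            if a != b and labels[a] != labels[b]:
                stampv += 1
                na = _gather_affected(
                    pts[a, 0], pts[a, 1], pts[b, 0], pts[b, 1], pts, labels, box,
                    head, nxt, nb, bs, rmax, rmax_bound, small_mode, aff, stamp, stampv,
                )
                # the endpoints change mechanical status; force-include them
                if stamp[a] != stampv:
                    aff[na] = a
                    stamp[a] = stampv
                    na += 1
                if stamp[b] != stampv:
                    aff[na] = b
                    stamp[b] = stampv
                    na += 1
                u_before = 0.0
                for t in range(na):
                    u_before += e[aff[t]]
                la = labels[a]
                labels[a] = labels[b]
                labels[b] = la
                u_after = 0.0
                for t in range(na):
                    c = aff[t]
                    if labels[c] == ENV_LABEL:
                        e_new[c] = 0.0
                        rmax_new[c] = rmax[c]
                        continue
                    nv, rm = _cell_poly(
                        c, pts[c, 0], pts[c, 1], pts, box, small_mode, head, nxt,
                        nb, bs, def_ring, px, py, own, tx, ty, town, cqx, cqy, cid,
                    )
                    en = _poly_energy(
                        nv, px, py, own, c, pts[c, 0], pts[c, 1], labels[c], labels,
                        gamma, a0, ac, bc, edge_eps,
                    )
                    e_new[c] = en
                    rmax_new[c] = rm
                    u_after += en
                d_u = u_after - u_before
                if d_u <= 0.0 or np.random.random() <= np.exp(-d_u / kbt_now):
                    for t in range(na):
                        c = aff[t]
                        e[c] = e_new[c]
                        rmax[c] = rmax_new[c]
                        if labels[c] != ENV_LABEL and rmax[c] > rmax_bound:
                            rmax_bound = rmax[c]
                    u_total += d_u
                    acc_total += 1
                else:
                    lb = labels[a]
                    labels[a] = labels[b]
                    labels[b] = lb
        else:
            idx = np.random.randint(0, m)
            oldx = pts[idx, 0]
            oldy = pts[idx, 1]
            if relocate_frac > 0.0 and np.random.random() < relocate_frac:
                newx = np.random.random() * box
                newy = np.random.random() * box
            else:
                rr = max_disp * np.sqrt(np.random.random())
                th = 2.0 * np.pi * np.random.random()
                newx = _wrap(oldx + rr * np.cos(th), box)
                newy = _wrap(oldy + rr * np.sin(th), box)
            disp_att += 1

            stampv += 1
            na = _gather_affected(
                oldx, oldy, newx, newy, pts, labels, box, head, nxt, nb, bs,
                rmax, rmax_bound, small_mode, aff, stamp, stampv,
            )

            u_before = 0.0
            for t in range(na):
                u_before += e[aff[t]]

            # tentative move: update position and bin membership
            b_old = binof[idx]
            bx = min(int(newx / bs), nb - 1)
            by = min(int(newy / bs), nb - 1)
            b_new = bx * nb + by
            pts[idx, 0] = newx
            pts[idx, 1] = newy
            if b_new != b_old:
                # unlink
                if prv[idx] >= 0:
                    nxt[prv[idx]] = nxt[idx]
                else:
                    head[b_old] = nxt[idx]
                if nxt[idx] >= 0:
                    prv[nxt[idx]] = prv[idx]
                # link
                nxt[idx] = head[b_new]
                prv[idx] = -1
                if head[b_new] >= 0:
                    prv[head[b_new]] = idx
                head[b_new] = idx
                binof[idx] = b_new

            u_after = 0.0
            for t in range(na):
                c = aff[t]
                nv, rm = _cell_poly(
                    c, pts[c, 0], pts[c, 1], pts, box, small_mode, head, nxt, nb, bs,
                    def_ring, px, py, own, tx, ty, town, cqx, cqy, cid,
                )
                en = _poly_energy(
                    nv, px, py, own, c, pts[c, 0], pts[c, 1], labels[c], labels, gamma,
                    a0, ac, bc, edge_eps,
                )
                e_new[c] = en
                rmax_new[c] = rm
                u_after += en

            d_u = u_after - u_before
            accept = d_u <= 0.0 or np.random.random() <= np.exp(-d_u / kbt_now)
            if accept:
                for t in range(na):
                    c = aff[t]
                    e[c] = e_new[c]
                    rmax[c] = rmax_new[c]
                    if rmax[c] > rmax_bound:
                        rmax_bound = rmax[c]
                u_total += d_u
                acc_window += 1
                acc_total += 1
            else:
                # restore position and bin membership
                pts[idx, 0] = oldx
                pts[idx, 1] = oldy
                b_cur = binof[idx]
                if b_cur != b_old:
                    if prv[idx] >= 0:
                        nxt[prv[idx]] = nxt[idx]
                    else:
                        head[b_cur] = nxt[idx]
                    if nxt[idx] >= 0:
                        prv[nxt[idx]] = prv[idx]
                    nxt[idx] = head[b_old]
                    prv[idx] = -1
                    if head[b_old] >= 0:
                        prv[head[b_old]] = idx
                    head[b_old] = idx
                    binof[idx] = b_old

        if disp_att >= adapt_interval:
            rate = acc_window / disp_att
            if rate > rate_hi:
                max_disp *= 1.1
            elif rate < rate_lo:
                max_disp *= 0.9
            if max_disp < 1e-4:
                max_disp = 1e-4
            if max_disp > box / 4.0:
                max_disp = box / 4.0
            acc_window = 0
            disp_att = 0
            # tighten the circumradius bound (it only grows between refreshes)
            rb = 0.0
            for c in range(m):
                if labels[c] != ENV_LABEL and rmax[c] > rb:
                    rb = rmax[c]
            rmax_bound = rb

        if stp % recompute_interval == 0:
            # drift guard: recompute tracked energies from scratch
            u_total = 0.0
            for c in range(m):
                if labels[c] == ENV_LABEL:
                    continue
                nv, rm = _cell_poly(
                    c, pts[c, 0], pts[c, 1], pts, box, small_mode, head, nxt, nb, bs,
                    def_ring, px, py, own, tx, ty, town, cqx, cqy, cid,
                )
                e[c] = _poly_energy(
                    nv, px, py, own, c, pts[c, 0], pts[c, 1], labels[c], labels, gamma,
                    a0, ac, bc, edge_eps,
                )
                rmax[c] = rm
                u_total += e[c]

        if stp >= burn_in and s_idx < snap_count and (stp - burn_in) % snap_interval == 0:
            for q in range(m):
                snaps[s_idx, q, 0] = pts[q, 0]
                snaps[s_idx, q, 1] = pts[q, 1]
                snap_labels[s_idx, q] = labels[q]
            trace[s_idx] = u_total
            s_idx += 1

    return snaps, snap_labels, trace, max_disp, acc_total, att_total
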