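"""Numba event-loop kernels for the cylindrical-lattice germ-line simulator.

All state lives in flat arrays so the event loop compiles to machine code.
Cells are identified by integers assigned in birth order (never reused), so
event-time ties resolve to the earlier-born cell by construction of the
argmin scan.  The kernels share the displacement cascade `_place`, which
implements the movement rules:

1. an empty slot in the division row is filled by shifting cells along the
   circular short axis toward the nearest empty slot;
2. otherwise an empty slot in the next (more proximal) row receives the
   daughter, rearranging that row the same way;
3. otherwise the daughter is pushed forward or sideways with probability 1/2
   each (forward only, for single-slot rows), and the displaced cell iterates
   under the same rules until an empty slot fills or a cell exits past the
   last row into the meiotic queue.

Cells pushed to a different row have their pending division time rescaled by
the ratio of cycle lengths between the new and old rows.
"""

import numpy as np
from numba import njit

INF = 1.0e18

# phase codes used in pulse-chase snapshots
PH_G1, PH_S, PH_G2, PH_M, PH_ARREST = 0, 1, 2, 3, 4


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's RNG (used when calling the placement helper directly)."""
    np.random.seed(seed)


@njit(cache=True)
def _cycle_len(cp_rows, anchors, lengths, min_len, row, clock):
    """Bilinear cycle length at 0-based ``row`` and developmental ``clock``."""
    na = anchors.shape[0]
    nr = cp_rows.shape[0]
    # clock segment (clamped)
    if na == 1 or clock <= anchors[0]:
        ia, wa = 0, 0.0
    elif clock >= anchors[na - 1]:
        ia, wa = na - 2, 1.0
    else:
        ia = 0
        for k in range(na - 1):
            if clock < anchors[k + 1]:
                ia = k
                break
        wa = (clock - anchors[ia]) / (anchors[ia + 1] - anchors[ia])
    # row segment (clamped)
    if nr == 1 or row <= cp_rows[0]:
        jr, wr = 0, 0.0
    elif row >= cp_rows[nr - 1]:
        jr, wr = nr - 2, 1.0
    else:
        jr = 0
        for k in range(nr - 1):
            if row < cp_rows[k + 1]:
                jr = k
                break
        wr = (row - cp_rows[jr]) / (cp_rows[jr + 1] - cp_rows[jr])
    if na == 1:
        v0 = lengths[0, jr]
        v1 = lengths[0, jr + 1] if nr > 1 else v0
    else:
        v0 = lengths[ia, jr] * (1.0 - wa) + lengths[ia + 1, jr] * wa
        if nr > 1:
            v1 = lengths[ia, jr + 1] * (1.0 - wa) + lengths[ia + 1, jr + 1] * wa
        else:
            v1 = v0
    v = v0 * (1.0 - wr) + v1 * wr
    if v < min_len:
        v = min_len
    return v


@njit(cache=True)
def _min_cycle_len(cp_rows, anchors, lengths, min_len, nrows, clock):
    """Minimum cycle length over the MZ at ``clock``; piecewise-linear in the
    row, so extrema occur at control points or lattice edges."""
    m = _cycle_len(cp_rows, anchors, lengths, min_len, 0.0, clock)
    v = _cycle_len(cp_rows, anchors, lengths, min_len, nrows - 1.0, clock)
    if v < m:
        m = v
    for j in range(cp_rows.shape[0]):
        r = cp_rows[j]
        if 0.0 <= r <= nrows - 1.0:
            v = _cycle_len(cp_rows, anchors, lengths, min_len, r, clock)
            if v < m:
                m = v
    return m


@njit(cache=True)
def _interp_caps(geo_anchors, geo_table, clock, rr):
    """Row capacity at ``clock``: linear between anchors, clamped, rounded."""
    ng = geo_anchors.shape[0]
    if ng == 1 or clock <= geo_anchors[0]:
        v = geo_table[0, rr]
    elif clock >= geo_anchors[ng - 1]:
        v = geo_table[ng - 1, rr]
    else:
        ia = 0
        for k in range(ng - 1):
            if clock < geo_anchors[k + 1]:
                ia = k
                break
        wa = (clock - geo_anchors[ia]) / (geo_anchors[ia + 1] - geo_anchors[ia])
        v = geo_table[ia, rr] * (1.0 - wa) + geo_table[ia + 1, rr] * wa
    nv = int(np.rint(v))
    return nv if nv >= 1 else 1


@njit(cache=True)
def _insert_in_row(lat, occ, caps, r, s, cell, row, slot):
    """Place ``cell`` in row ``r`` (which has a free slot) as close to slot
    ``s`` as possible, shifting intervening cells toward the nearest empty
    slot.  Equidistant empty slots are tie-broken by one RNG draw."""
    w = caps[r]
    if lat[r, s] < 0:
        lat[r, s] = cell
        row[cell] = r
        slot[cell] = s
        occ[r] += 1
        return
    dirn = 0
    dist = -1
    for d in range(1, w):
        right = lat[r, (s + d) % w] < 0
        left = lat[r, (s - d) % w] < 0
        if right and left:
            dirn = 1 if np.random.random() < 0.5 else -1
            dist = d
            break
        if right:
            dirn, dist = 1, d
            break
        if left:
            dirn, dist = -1, d
            break
    # shift cells at offsets dist-1 .. 1 outward by one slot
    for k in range(dist - 1, 0, -1):
        src = (s + dirn * k) % w
        dst = (s + dirn * (k + 1)) % w
        c = lat[r, src]
        lat[r, dst] = c
        slot[c] = dst
    tgt = (s + dirn) % w
    lat[r, tgt] = cell
    row[cell] = r
    slot[cell] = tgt
    occ[r] += 1


@njit(cache=True)
def _place(lat, occ, caps, nrows, cell, r0, s0, row, slot,
           force_forward, moved, moved_old):
    """Run the displacement cascade for ``cell`` conceptually at (r0, s0).

    Returns (n_row_moves, exited_cell): ``moved[:n]`` lists cells that
    settled in a different row than they came from (for division-time
    rescaling; a cell entering fresh, with no origin row, is excluded),
    ``exited_cell`` is the id of the cell pushed past the last row, or -1.
    Returns (-1, -1) if the cascade exceeds the sanity bound (broken
    occupancy invariant).
    """
    total = 0
    for r in range(nrows):
        total += caps[r]
    limit = 10 * total + 100

    cur = cell
    orow = -1  # fresh cell: no origin row
    r = r0
    s = s0
    first = True
    nm = 0
    steps = 0
    while True:
        steps += 1
        if steps > limit:
            return -1, -1
        w = caps[r]
        if occ[r] < w and not (first and force_forward):
            _insert_in_row(lat, occ, caps, r, s, cur, row, slot)
            if orow >= 0 and orow != r:
                moved[nm] = cur
                moved_old[nm] = orow
                nm += 1
            return nm, -1
        if r + 1 < nrows:
            s2 = s % caps[r + 1]
            if occ[r + 1] < caps[r + 1]:
                _insert_in_row(lat, occ, caps, r + 1, s2, cur, row, slot)
                if orow >= 0 and orow != r + 1:
                    moved[nm] = cur
                    moved_old[nm] = orow
                    nm += 1
                return nm, -1
            # both rows full: forward or sideways with equal probability
            forward = True
            if w > 1 and not (first and force_forward):
                forward = np.random.random() < 0.5
            if forward:
                nxt = lat[r + 1, s2]
                lat[r + 1, s2] = cur
                row[cur] = r + 1
                slot[cur] = s2
                if orow >= 0 and orow != r + 1:
                    moved[nm] = cur
                    moved_old[nm] = orow
                    nm += 1
                cur = nxt
                orow = r + 1
                r = r + 1
                s = s2
            else:
                dirn = 1 if np.random.random() < 0.5 else -1
                sb = (s + dirn) % w
                nxt = lat[r, sb]
                lat[r, sb] = cur
                row[cur] = r
                slot[cur] = sb
                if orow >= 0 and orow != r:
                    moved[nm] = cur
                    moved_old[nm] = orow
                    nm += 1
                cur = nxt
                orow = r
                s = sb
            first = False
        else:
            # last row is full
            forward = True
            if w > 1 and not (first and force_forward):
                forward = np.random.random() < 0.5
            if forward:
                return nm, cur  # cur exits into the meiotic queue
            dirn = 1 if np.random.random() < 0.5 else -1
            sb = (s + dirn) % w
            nxt = lat[r, sb]
            lat[r, sb] = cur
            row[cur] = r
            slot[cur] = sb
            if orow >= 0 and orow != r:
                moved[nm] = cur
                moved_old[nm] = orow
                nm += 1
            cur = nxt
            orow = r
            s = sb
            first = False



@njit(cache=True)
def _fill_row_lengths(cp_rows, anchors, lengths, min_len, nrows, clock, out):
    """Exact per-row cycle lengths at ``clock`` (linear in the row between
    control points, clamped at the ends); returns the minimum over the MZ."""
    nr = cp_rows.shape[0]
    na = anchors.shape[0]
    # clock interpolation weights
    if na == 1 or clock <= anchors[0]:
        ia, wa = 0, 0.0
    elif clock >= anchors[na - 1]:
        ia, wa = na - 2, 1.0
    else:
        ia = 0
        for k in range(na - 1):
            if clock < anchors[k + 1]:
                ia = k
                break
        wa = (clock - anchors[ia]) / (anchors[ia + 1] - anchors[ia])
    mn = INF
    # control-point values at this clock
    for r in range(nrows):
        rr = float(r)
        if nr == 1 or rr <= cp_rows[0]:
            jr, wr = 0, 0.0
        elif rr >= cp_rows[nr - 1]:
            jr, wr = nr - 2, 1.0
        else:
            jr = 0
            for k in range(nr - 1):
                if rr < cp_rows[k + 1]:
                    jr = k
                    break
            wr = (rr - cp_rows[jr]) / (cp_rows[jr + 1] - cp_rows[jr])
        if na == 1:
            v0 = lengths[0, jr]
            v1 = lengths[0, jr + 1] if nr > 1 else v0
        else:
            v0 = lengths[ia, jr] * (1.0 - wa) + lengths[ia + 1, jr] * wa
            if nr > 1:
                v1 = lengths[ia, jr + 1] * (1.0 - wa) + lengths[ia + 1, jr + 1] * wa
            else:
                v1 = v0
        v = v0 * (1.0 - wr) + v1 * wr
        if v < min_len:
            v = min_len
        out[r] = v
        if v < mn:
            mn = v
    return mn


@njit(cache=True)
def _rescale_moved_tab(nm, moved, moved_old, row, tdiv, tau, t, row_len):
    """Scale pending division times of row-changed cells by the ratio of
    cycle lengths between the new and old rows (current-clock table)."""
    for k in range(nm):
        c = moved[k]
        if tdiv[c] >= INF:
            continue  # arrested cells keep their state
        ratio = row_len[row[c]] / row_len[moved_old[k]]
        tdiv[c] = t + (tdiv[c] - t) * ratio
        tau[c] = tau[c] * ratio


@njit(cache=True)
def _rescale_moved(nm, moved, moved_old, row, tdiv, tau, t,
                   cp_rows, anchors, lengths, min_len, clock):
    """Scale pending division times of row-changed cells by the ratio of
    cycle lengths between the new and old rows (at the current clock)."""
    for k in range(nm):
        c = moved[k]
        if tdiv[c] >= INF:
            continue  # arrested cells keep their state
        old_l = _cycle_len(cp_rows, anchors, lengths, min_len, float(moved_old[k]), clock)
        new_l = _cycle_len(cp_rows, anchors, lengths, min_len, float(row[c]), clock)
        ratio = new_l / old_l
        remaining = tdiv[c] - t
        tdiv[c] = t + remaining * ratio
        tau[c] = tau[c] * ratio


@njit(cache=True)
def run_ma_kernel(seed,
                  nrows, caps, geo_anchors, geo_table, geo_static,
                  cp_rows, anchors, lengths, min_len,
                  jitter, variant,
                  premeiosis, pmz_start, frac_cum, exp_m_index,
                  n_exit_target, n_pop_target, max_divisions,
                  row, slot, depth, tdiv, tau, tg2, g2done,
                  active, lat, occ, moved, moved_old, row_len,
                  exit_cell, exit_depth, exit_time, exit_clock, div_times):
    """Mutation-accumulation run: seed one progenitor distally, run the
    division event loop until ``n_exit_target`` cells have left the MZ (or
    the MZ population reaches ``n_pop_target``, or ``max_divisions``).

    variant: 0 standard (+1 to each daughter), 1 immortal strand (row-1
    parent keeps its template strands: the staying daughter at the parent
    slot inherits +0 and the new daughter +2; once the first row is full one
    daughter is indeed always pushed out of it), 2 rate-scaled (+1/gamma to
    both, gamma = cell cycle length of the parent / minimum cycle length
    over the MZ).

    Returns (n_exits, n_divisions, n_cells_total); n_exits == -1 flags a
    broken displacement invariant.
    """
    np.random.seed(seed)
    lat[:, :] = -1
    occ[:] = 0
    for rr in range(nrows):
        caps[rr] = _interp_caps(geo_anchors, geo_table, 0.0, rr)
    min_mz = _fill_row_lengths(cp_rows, anchors, lengths, min_len, nrows, 0.0, row_len)

    # seed the progenitor at the distal end
    row[0] = 0
    slot[0] = 0
    depth[0] = 0.0
    lat[0, 0] = 0
    occ[0] = 1
    l0 = row_len[0]
    tdiv[0] = l0 * (1.0 + jitter * (np.random.random() - 0.5))
    tau[0] = l0
    tg2[0] = INF
    g2done[0] = 1
    active[0] = 0
    n_active = 1
    n_cells = 1
    n_exits = 0
    ndiv = 0
    t = 0.0
    pop = 1

    while n_exits < n_exit_target and pop < n_pop_target and ndiv < max_divisions:
        # next event: smallest pending time; ids increase with birth order so
        # the scan's first minimum is the earlier-born cell
        best = active[0]
        bt = tdiv[best]
        if premeiosis == 1 and tg2[best] < bt:
            bt = tg2[best]
        for k in range(1, n_active):
            c = active[k]
            ct = tdiv[c]
            if premeiosis == 1 and tg2[c] < ct:
                ct = tg2[c]
            if ct < bt:
                bt = ct
                best = c
        if bt >= INF:
            break  # everything arrested; no further events
        t = bt
        c = best

        if premeiosis == 1 and tg2[c] <= tdiv[c] and g2done[c] == 0:
            # G2 entry in the proximal MZ: arrest if the simulated local
            # mitotic index already exceeds the experimental one
            g2done[c] = 1
            tg2[c] = INF
            r = row[c]
            if r >= pmz_start:
                w = caps[r]
                nm_row = 0
                ncell_row = 0
                for ss in range(w):
                    cc = lat[r, ss]
                    if cc >= 0:
                        ncell_row += 1
                        if tdiv[cc] < INF:
                            frac_m = 1.0 - frac_cum[r, 2]
                            # in M when within the M-phase span of division
                            if tdiv[cc] - t <= frac_m * tau[cc]:
                                nm_row += 1
                if ncell_row > 0 and nm_row / ncell_row > exp_m_index[r]:
                    tdiv[c] = INF  # arrested pre-meiotic cell keeps its slot
            continue

        # division event
        ndiv += 1
        clock = float(ndiv)
        div_times[ndiv - 1] = t
        min_mz = _fill_row_lengths(cp_rows, anchors, lengths, min_len, nrows,
                                   clock, row_len)

        if geo_static == 0:
            # re-interpolate geometry; handle shrinking rows proximal-first
            changed = False
            for rr in range(nrows):
                if _interp_caps(geo_anchors, geo_table, clock, rr) != caps[rr]:
                    changed = True
                    break
            if changed:
                for rr in range(nrows - 1, -1, -1):
                    nv = _interp_caps(geo_anchors, geo_table, clock, rr)
                    oldc = caps[rr]
                    if nv >= oldc:
                        caps[rr] = nv
                        continue
                    caps[rr] = nv
                    for ss in range(nv, oldc):
                        ev = lat[rr, ss]
                        lat[rr, ss] = -1
                        if ev < 0:
                            continue
                        occ[rr] -= 1
                        s_start = nv - 1 if slot[ev] >= nv else slot[ev]
                        old_row_ev = rr
                        nm, exited = _place(lat, occ, caps, nrows, ev, rr, s_start,
                                            row, slot, False, moved, moved_old)
                        if nm < 0:
                            return -1, ndiv, n_cells
                        _rescale_moved_tab(nm, moved, moved_old, row, tdiv, tau,
                                           t, row_len)
                        if exited != ev and exited < 0 and row[ev] != old_row_ev:
                            # the evicted cell entered `_place` as "fresh";
                            # rescale it here if it changed rows
                            if tdiv[ev] < INF:
                                ratio = row_len[row[ev]] / row_len[old_row_ev]
                                tdiv[ev] = t + (tdiv[ev] - t) * ratio
                                tau[ev] = tau[ev] * ratio
                        if exited >= 0:
                            n_exits += 1
                            exit_cell[n_exits - 1] = exited
                            exit_depth[n_exits - 1] = depth[exited]
                            exit_time[n_exits - 1] = t
                            exit_clock[n_exits - 1] = clock
                            tdiv[exited] = INF
                            tg2[exited] = INF
                            row[exited] = -1
                            pop -= 1
                            for k in range(n_active):
                                if active[k] == exited:
                                    active[k] = active[n_active - 1]
                                    n_active -= 1
                                    break

        r = row[c]
        s = slot[c]
        par_len = row_len[r]

        d = n_cells
        n_cells += 1
        pop += 1

        # pedigree-depth bookkeeping: the parent id stands for the staying
        # daughter, the fresh id for the pushed daughter
        if variant == 0:
            depth[d] = depth[c] + 1.0
            depth[c] = depth[c] + 1.0
        elif variant == 1:
            if r == 0:
                depth[d] = depth[c] + 2.0
                # staying daughter (the parent id) not incremented
            else:
                depth[d] = depth[c] + 1.0
                depth[c] = depth[c] + 1.0
        else:
            inc = min_mz / par_len  # = 1/gamma
            depth[d] = depth[c] + inc
            depth[c] = depth[c] + inc

        nm, exited = _place(lat, occ, caps, nrows, d, r, s, row, slot, False,
                            moved, moved_old)
        if nm < 0:
            return -1, ndiv, n_cells  # displacement-chain invariant broken
        _rescale_moved_tab(nm, moved, moved_old, row, tdiv, tau, t, row_len)
        if exited >= 0:
            n_exits += 1
            exit_cell[n_exits - 1] = exited
            exit_depth[n_exits - 1] = depth[exited]
            exit_time[n_exits - 1] = t
            exit_clock[n_exits - 1] = clock
            tdiv[exited] = INF
            tg2[exited] = INF
            row[exited] = -1
            pop -= 1
            if exited != d:
                for k in range(n_active):
                    if active[k] == exited:
                        active[k] = active[n_active - 1]
                        n_active -= 1
                        break

        # fresh division times, sampled independently for both daughters at
        # their final rows: uniform, mean = local cycle length, width 1 % of it
        for cc in (c, d):
            if cc == d and exited == d:
                continue
            lr = row_len[row[cc]]
            tdiv[cc] = t + lr * (1.0 + jitter * (np.random.random() - 0.5))
            tau[cc] = lr
            if premeiosis == 1:
                g2done[cc] = 0
                tg2[cc] = tdiv[cc] - (1.0 - frac_cum[row[cc], 1]) * tau[cc]
            else:
                tg2[cc] = INF
        if exited != d:
            active[n_active] = d
            n_active += 1

    return n_exits, ndiv, n_cells


@njit(cache=True)
def run_ma(seed,
           nrows, caps, geo_anchors, geo_table, geo_static,
           cp_rows, anchors, lengths, min_len,
           jitter, variant,
           premeiosis, pmz_start, frac_cum, exp_m_index,
           n_exit_target, n_pop_target, max_divisions,
           row, slot, depth, tdiv, tau, tg2, g2done,
           active, lat, occ, moved, moved_old, row_len,
           exit_cell, exit_depth, exit_time, exit_clock, div_times,
           pop_depth):
    """Wrapper around the mutation-accumulation loop that also copies out the
    final MZ population's pedigree depths into ``pop_depth``."""
    res = run_ma_kernel(seed, nrows, caps, geo_anchors, geo_table, geo_static,
                        cp_rows, anchors, lengths, min_len,
                        jitter, variant,
                        premeiosis, pmz_start, frac_cum, exp_m_index,
                        n_exit_target, n_pop_target, max_divisions,
                        row, slot, depth, tdiv, tau, tg2, g2done,
                        active, lat, occ, moved, moved_old, row_len,
                        exit_cell, exit_depth, exit_time, exit_clock, div_times)
    n_exits, ndiv, n_cells = res
    npop = 0
    if n_exits >= 0:
        for c in range(n_cells):
            if row[c] >= 0:  # still occupies the lattice (cycling or arrested)
                pop_depth[npop] = depth[c]
                npop += 1
    return n_exits, ndiv, n_cells, npop


@njit(cache=True)
def _age_frac(tdiv_c, tau_c, t):
    """Fraction of the cycle elapsed, from the pending division time."""
    x = 1.0 - (tdiv_c - t) / tau_c
    if x < 0.0:
        x = 0.0
    if x > 1.0:
        x = 1.0
    return x


@njit(cache=True)
def run_pc_kernel(seed,
                  nrows, caps,
                  cp_rows, anchors, lengths, min_len,
                  jitter, frac_cum,
                  premeiosis, pmz_start, exp_m_index,
                  pre_run, chase_times,
                  row, slot, tdiv, tau, tg2, g2done, edu, arrested,
                  active, lat, occ, moved, moved_old, row_len,
                  out_count, out_row, out_phase, out_dna, out_edu):
    """Pulse-chase run: pre-fill the MZ with an asynchronous population
    (exponential age density f with f(0) = 2 f(1)), pre-run ``pre_run`` hours,
    mark S-phase cells EdU-positive at time 0, then snapshot every cell's
    (row, phase, DNA content, EdU flag) at each chase time.

    ``frac_cum`` is (nrows, 3): cumulative (G1, G1+S, G1+S+G2) phase
    boundaries per row.  DNA content ramps linearly 2C -> 4C across S phase.
    Returns the number of cells created, or -1 on a broken invariant.
    """
    np.random.seed(seed)
    lat[:, :] = -1
    occ[:] = 0
    _fill_row_lengths(cp_rows, anchors, lengths, min_len, nrows, 0.0, row_len)
    t0 = -pre_run
    n_cells = 0
    n_active = 0
    for rr in range(nrows):
        lr = row_len[rr]
        for ss in range(caps[rr]):
            c = n_cells
            n_cells += 1
            row[c] = rr
            slot[c] = ss
            lat[rr, ss] = c
            occ[rr] += 1
            # inverse CDF of F(x) = 2 - 2^(1-x)
            u = np.random.random()
            x0 = 1.0 - np.log2(2.0 - u)
            tau[c] = lr
            tdiv[c] = t0 + (1.0 - x0) * lr
            edu[c] = 0
            arrested[c] = 0
            if x0 >= frac_cum[rr, 1]:
                g2done[c] = 1
                tg2[c] = INF
            else:
                g2done[c] = 0
                tg2[c] = tdiv[c] - (1.0 - frac_cum[rr, 1]) * lr
            active[n_active] = c
            n_active += 1

    n_chase = chase_times.shape[0]
    i_chase = 0
    pulsed = False
    t = t0
    while i_chase < n_chase:
        # next division / G2-entry event
        best = -1
        bt = INF
        for k in range(n_active):
            c = active[k]
            ct = tdiv[c]
            if premeiosis == 1 and tg2[c] < ct:
                ct = tg2[c]
            if ct < bt:
                bt = ct
                best = c
        # the EdU pulse and any due snapshots come first
        while True:
            next_mark = 0.0 if not pulsed else INF
            next_snap = chase_times[i_chase] if i_chase < n_chase else INF
            boundary = next_mark if next_mark < next_snap else next_snap
            if boundary > bt or boundary >= INF:
                break
            if not pulsed and next_mark <= next_snap:
                for k in range(n_active):
                    c = active[k]
                    if arrested[c] == 1:
                        continue
                    x = _age_frac(tdiv[c], tau[c], 0.0)
                    rr = row[c]
                    if frac_cum[rr, 0] <= x < frac_cum[rr, 1]:
                        edu[c] = 1
                pulsed = True
            else:
                ts = chase_times[i_chase]
                cnt = 0
                for k in range(n_active):
                    c = active[k]
                    rr = row[c]
                    out_row[i_chase, cnt] = rr
                    out_edu[i_chase, cnt] = edu[c]
                    if arrested[c] == 1:
                        out_phase[i_chase, cnt] = PH_ARREST
                        out_dna[i_chase, cnt] = 4.0
                    else:
                        x = _age_frac(tdiv[c], tau[c], ts)
                        b1 = frac_cum[rr, 0]
                        b2 = frac_cum[rr, 1]
                        b3 = frac_cum[rr, 2]
                        if x < b1:
                            out_phase[i_chase, cnt] = PH_G1
                            out_dna[i_chase, cnt] = 2.0
                        elif x < b2:
                            out_phase[i_chase, cnt] = PH_S
                            out_dna[i_chase, cnt] = 2.0 + 2.0 * (x - b1) / (b2 - b1)
                        elif x < b3:
                            out_phase[i_chase, cnt] = PH_G2
                            out_dna[i_chase, cnt] = 4.0
                        else:
                            out_phase[i_chase, cnt] = PH_M
                            out_dna[i_chase, cnt] = 4.0
                    cnt += 1
                out_count[i_chase] = cnt
                i_chase += 1
            if i_chase >= n_chase:
                return n_cells
        if best < 0:
            return n_cells  # nothing left to cycle; remaining snaps done above

        t = bt
        c = best
        if premeiosis == 1 and tg2[c] <= tdiv[c] and g2done[c] == 0:
            g2done[c] = 1
            tg2[c] = INF
            r = row[c]
            if r >= pmz_start:
                w = caps[r]
                nm_row = 0
                ncell_row = 0
                for ss in range(w):
                    cc = lat[r, ss]
                    if cc >= 0:
                        ncell_row += 1
                        if arrested[cc] == 0:
                            frac_m = 1.0 - frac_cum[r, 2]
                            if tdiv[cc] - t <= frac_m * tau[cc]:
                                nm_row += 1
                if ncell_row > 0 and nm_row / ncell_row > exp_m_index[r]:
                    tdiv[c] = INF
                    arrested[c] = 1
            continue

        # division; the clock is frozen (cycle parameters constant over a
        # pulse-chase experiment, which spans at most ~8 h)
        r = row[c]
        s = slot[c]
        d = n_cells
        n_cells += 1
        edu[d] = edu[c]
        arrested[d] = 0
        nm, exited = _place(lat, occ, caps, nrows, d, r, s, row, slot, False,
                            moved, moved_old)
        if nm < 0:
            return -1
        _rescale_moved_tab(nm, moved, moved_old, row, tdiv, tau, t, row_len)
        if exited >= 0:
            tdiv[exited] = INF
            tg2[exited] = INF
            if exited != d:
                for k in range(n_active):
                    if active[k] == exited:
                        active[k] = active[n_active - 1]
                        n_active -= 1
                        break
        for cc in (c, d):
            if cc == d and exited == d:
                continue
            lr = row_len[row[cc]]
            tdiv[cc] = t + lr * (1.0 + jitter * (np.random.random() - 0.5))
            tau[cc] = lr
            g2done[cc] = 0
            tg2[cc] = tdiv[cc] - (1.0 - frac_cum[row[cc], 1]) * tau[cc]
        if exited != d:
            active[n_active] = d
            n_active += 1
    return n_cells
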