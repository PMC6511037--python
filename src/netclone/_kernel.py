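"""JIT-compiled Monte Carlo engine for the static fully connected case.

Same dynamics as the pure-Python loop in :mod:`netclone.mmc` (move kinds,
probabilities, Metropolis rule, OBOC termination, attempt accounting), but
operating on flat arrays with numba.  Restricted to gamma = 2 with integer
epsilon on the full N(N-1) tabula rasa, where synapse ids are arithmetic:
``sid(a, b) = a*(N-1) + (b if b < a else b - 1)``.

The two engines draw from different random streams (numba's own
Mersenne-Twister state vs ``random.Random``), so individual runs differ
move-for-move while sharing the identical model; results are cross-checked
in the test suite, and every kernel run is integrity-checked by rebuilding
the final state in Python and recomputing H exactly.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


STATUS_OK = 0
STATUS_OVERFLOW = 1  # a synapse exceeded per-synapse pair capacity
_CAP = 64


@njit(cache=True)
def _acc(dtot_cells, dtot_vals, ncells, cellx, ddx):
    for z in range(ncells):
        if dtot_cells[z] == cellx:
            dtot_vals[z] += ddx
            return ncells
    dtot_cells[ncells] = cellx
    dtot_vals[ncells] = ddx
    return ncells + 1


@njit(cache=True)
def _occ_remove(cell, s, side, occ_len, occ_list, occ_pos, nm1):
    pos = occ_pos[s, side]
    last = occ_list[cell, occ_len[cell] - 1]
    occ_list[cell, pos] = last
    lside = 0 if last // nm1 == cell else 1
    occ_pos[last, lside] = pos
    occ_len[cell] -= 1
    occ_pos[s, side] = -1


@njit(cache=True)
def _occ_add(cell, s, side, occ_len, occ_list, occ_pos):
    occ_pos[s, side] = occ_len[cell]
    occ_list[cell, occ_len[cell]] = s
    occ_len[cell] += 1


@njit(cache=True)
def _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, cell, beta, d):
    old = counts[cell, beta]
    new = old + d
    counts[cell, beta] = new
    totals[cell] += d
    if old == 0 and new > 0:
        cell_ntypes[cell] += 1
        if cell_ntypes[cell] == 2:
            purity[0] += 1
        type_ncells[beta] += 1
        if type_ncells[beta] == 2:
            purity[1] += 1
    elif old > 0 and new == 0:
        cell_ntypes[cell] -= 1
        if cell_ntypes[cell] == 1:
            purity[0] -= 1
        type_ncells[beta] -= 1
        if type_ncells[beta] == 1:
            purity[1] -= 1


@njit(cache=True)
def _move_synapse(
    p, dest, orient, pair_syn, pair_orient, pair_pos,
    syn_count, syn_list, occ_len, occ_list, occ_pos, nm1,
):
    src = pair_syn[p]
    if src != dest:
        pos = pair_pos[p]
        lastp = syn_list[src, syn_count[src] - 1]
        syn_list[src, pos] = lastp
        pair_pos[lastp] = pos
        syn_count[src] -= 1
        if syn_count[src] == 0:
            a = src // nm1
            r = src % nm1
            b = r + 1 if r >= a else r
            _occ_remove(a, src, 0, occ_len, occ_list, occ_pos, nm1)
            _occ_remove(b, src, 1, occ_len, occ_list, occ_pos, nm1)
        if syn_count[dest] >= _CAP:
            return False
        if syn_count[dest] == 0:
            a = dest // nm1
            r = dest % nm1
            b = r + 1 if r >= a else r
            _occ_add(a, dest, 0, occ_len, occ_list, occ_pos)
            _occ_add(b, dest, 1, occ_len, occ_list, occ_pos)
        syn_list[dest, syn_count[dest]] = p
        pair_pos[p] = syn_count[dest]
        syn_count[dest] += 1
        pair_syn[p] = dest
    pair_orient[p] = orient
    return True


@njit(cache=True)
def run_static_kernel(
    n, pair_pre, pair_post, pj, ps, pf, eps, temperature, max_attempts, seed
):
    """Random initialization plus the full Metropolis loop; returns
    (status, attempts, converged, h_init, h_final, n_strict,
     att_jump, att_swap, att_flip, acc_jump, acc_swap, acc_flip,
     pair_syn, pair_orient)."""
    np.random.seed(seed)
    nm1 = n - 1
    nsyn = n * nm1
    n_pairs = pair_pre.shape[0]

    pair_syn = np.empty(n_pairs, np.int64)
    pair_orient = np.empty(n_pairs, np.int64)
    for p in range(n_pairs):
        pair_syn[p] = np.random.randint(nsyn)
        pair_orient[p] = np.random.randint(2)

    syn_count = np.zeros(nsyn, np.int64)
    syn_list = np.zeros((nsyn, _CAP), np.int64)
    pair_pos = np.zeros(n_pairs, np.int64)
    for p in range(n_pairs):
        s = pair_syn[p]
        if syn_count[s] >= _CAP:
            return (
                STATUS_OVERFLOW, 0, False, 0, 0, 0,
                0, 0, 0, 0, 0, 0, pair_syn, pair_orient,
            )
        syn_list[s, syn_count[s]] = p
        pair_pos[p] = syn_count[s]
        syn_count[s] += 1

    occ_len = np.zeros(n, np.int64)
    occ_list = np.zeros((n, 2 * nm1), np.int64)
    occ_pos = np.full((nsyn, 2), -1, np.int64)
    for s in range(nsyn):
        if syn_count[s] > 0:
            a = s // nm1
            r = s % nm1
            b = r + 1 if r >= a else r
            _occ_add(a, s, 0, occ_len, occ_list, occ_pos)
            _occ_add(b, s, 1, occ_len, occ_list, occ_pos)

    counts = np.zeros((n, n), np.int64)
    totals = np.zeros(n, np.int64)
    for p in range(n_pairs):
        s = pair_syn[p]
        a = s // nm1
        r = s % nm1
        b = r + 1 if r >= a else r
        if pair_orient[p] == 1:
            fa, fb = b, a
        else:
            fa, fb = a, b
        counts[fa, pair_pre[p]] += 1
        counts[fb, pair_post[p]] += 1

    cell_ntypes = np.zeros(n, np.int64)
    type_ncells = np.zeros(n, np.int64)
    purity = np.zeros(2, np.int64)  # [impure cells, spread types]
    h = np.int64(0)
    for cell in range(n):
        t = np.int64(0)
        k = 0
        for beta in range(n):
            v = counts[cell, beta]
            if v > 0:
                t += v
                k += 1
                type_ncells[beta] += 1
                h -= (1 + eps) * v * v
        totals[cell] = t
        cell_ntypes[cell] = k
        h += eps * t * t
    for cell in range(n):
        if cell_ntypes[cell] > 1:
            purity[0] += 1
    for beta in range(n):
        if type_ncells[beta] > 1:
            purity[1] += 1
    h_init = h

    e1 = 1 + eps
    e1x2 = 2 * e1
    c2 = pj + ps
    c3 = c2 + pf
    dh_cap = 745.0 * temperature
    two_nm1 = 2 * nm1

    att_jump = att_swap = att_flip = 0
    acc_jump = acc_swap = acc_flip = 0
    n_strict = 0
    attempts = 0
    converged = purity[0] == 0 and purity[1] == 0
    dtot_cells = np.empty(8, np.int64)
    dtot_vals = np.empty(8, np.int64)

    while attempts < max_attempts and not converged:
        attempts += 1
        kind = 0
        while True:
            u = np.random.random()
            if u < pj:
                break
            if u < c2:
                kind = 1
                break
            if u < c3:
                kind = 2
                break

        if kind == 1:
            c = np.random.randint(n)
            nocc = occ_len[c]
            if nocc >= 2:
                i = np.random.randint(nocc)
                j = np.random.randint(nocc - 1)
                if j >= i:
                    j += 1
                s1 = occ_list[c, i]
                s2 = occ_list[c, j]
                p1 = syn_list[s1, np.random.randint(syn_count[s1])]
                p2 = syn_list[s2, np.random.randint(syn_count[s2])]
                o1 = np.random.randint(2)
                o2 = np.random.randint(2)
                att_swap += 1
                aa = s1 // nm1
                rr = s1 % nm1
                bb = rr + 1 if rr >= aa else rr
                cc = s2 // nm1
                rr = s2 % nm1
                dd = rr + 1 if rr >= cc else rr
                if pair_orient[p1] == 1:
                    fa1, fb1 = bb, aa
                else:
                    fa1, fb1 = aa, bb
                if o1 == 1:
                    a21, b21 = dd, cc
                else:
                    a21, b21 = cc, dd
                if pair_orient[p2] == 1:
                    fa2, fb2 = dd, cc
                else:
                    fa2, fb2 = cc, dd
                if o2 == 1:
                    a22, b22 = bb, aa
                else:
                    a22, b22 = aa, bb
                mu1, nu1 = pair_pre[p1], pair_post[p1]
                mu2, nu2 = pair_pre[p2], pair_post[p2]
                m1 = fa1 != a21
                m2 = fb1 != b21
                m3 = fa2 != a22
                m4 = fb2 != b22
                dh = np.int64(0)
                ncells = 0
                if mu1 != mu2 and mu1 != nu2 and nu1 != mu2 and nu1 != nu2:
                    if m1:
                        dh -= e1x2 * (counts[a21, mu1] - counts[fa1, mu1] + 1)
                    if m2:
                        dh -= e1x2 * (counts[b21, nu1] - counts[fb1, nu1] + 1)
                    if m3:
                        dh -= e1x2 * (counts[a22, mu2] - counts[fa2, mu2] + 1)
                    if m4:
                        dh -= e1x2 * (counts[b22, nu2] - counts[fb2, nu2] + 1)
                    # totals deltas, accumulated over the distinct cells
                    if m1:
                        ncells = _acc(dtot_cells, dtot_vals, ncells, fa1, -1)
                        ncells = _acc(dtot_cells, dtot_vals, ncells, a21, 1)
                    if m2:
                        ncells = _acc(dtot_cells, dtot_vals, ncells, fb1, -1)
                        ncells = _acc(dtot_cells, dtot_vals, ncells, b21, 1)
                    if m3:
                        ncells = _acc(dtot_cells, dtot_vals, ncells, fa2, -1)
                        ncells = _acc(dtot_cells, dtot_vals, ncells, a22, 1)
                    if m4:
                        ncells = _acc(dtot_cells, dtot_vals, ncells, fb2, -1)
                        ncells = _acc(dtot_cells, dtot_vals, ncells, b22, 1)
                    for z in range(ncells):
                        ddx = dtot_vals[z]
                        if ddx != 0:
                            tv = totals[dtot_cells[z]]
                            dh += eps * (2 * tv * ddx + ddx * ddx)
                else:
                    # shared type between the pairs: sequential mutate-compute,
                    # then revert; exact for aggregated changes
                    dh = np.int64(0)
                    if m1:
                        cv = counts[fa1, mu1]
                        counts[fa1, mu1] = cv - 1
                        dh -= e1 * (-2 * cv + 1)
                        tv = totals[fa1]
                        totals[fa1] = tv - 1
                        dh += eps * (-2 * tv + 1)
                        cv = counts[a21, mu1]
                        counts[a21, mu1] = cv + 1
                        dh -= e1 * (2 * cv + 1)
                        tv = totals[a21]
                        totals[a21] = tv + 1
                        dh += eps * (2 * tv + 1)
                    if m2:
                        cv = counts[fb1, nu1]
                        counts[fb1, nu1] = cv - 1
                        dh -= e1 * (-2 * cv + 1)
                        tv = totals[fb1]
                        totals[fb1] = tv - 1
                        dh += eps * (-2 * tv + 1)
                        cv = counts[b21, nu1]
                        counts[b21, nu1] = cv + 1
                        dh -= e1 * (2 * cv + 1)
                        tv = totals[b21]
                        totals[b21] = tv + 1
                        dh += eps * (2 * tv + 1)
                    if m3:
                        cv = counts[fa2, mu2]
                        counts[fa2, mu2] = cv - 1
                        dh -= e1 * (-2 * cv + 1)
                        tv = totals[fa2]
                        totals[fa2] = tv - 1
                        dh += eps * (-2 * tv + 1)
                        cv = counts[a22, mu2]
                        counts[a22, mu2] = cv + 1
                        dh -= e1 * (2 * cv + 1)
                        tv = totals[a22]
                        totals[a22] = tv + 1
                        dh += eps * (2 * tv + 1)
                    if m4:
                        cv = counts[fb2, nu2]
                        counts[fb2, nu2] = cv - 1
                        dh -= e1 * (-2 * cv + 1)
                        tv = totals[fb2]
                        totals[fb2] = tv - 1
                        dh += eps * (-2 * tv + 1)
                        cv = counts[b22, nu2]
                        counts[b22, nu2] = cv + 1
                        dh -= e1 * (2 * cv + 1)
                        tv = totals[b22]
                        totals[b22] = tv + 1
                        dh += eps * (2 * tv + 1)
                    # revert: counts/totals are re-applied on acceptance below
                    if m1:
                        counts[fa1, mu1] += 1
                        counts[a21, mu1] -= 1
                        totals[fa1] += 1
                        totals[a21] -= 1
                    if m2:
                        counts[fb1, nu1] += 1
                        counts[b21, nu1] -= 1
                        totals[fb1] += 1
                        totals[b21] -= 1
                    if m3:
                        counts[fa2, mu2] += 1
                        counts[a22, mu2] -= 1
                        totals[fa2] += 1
                        totals[a22] -= 1
                    if m4:
                        counts[fb2, nu2] += 1
                        counts[b22, nu2] -= 1
                        totals[fb2] += 1
                        totals[b22] -= 1

                accept = dh <= 0
                if not accept:
                    if dh < dh_cap:
                        accept = np.random.random() < np.exp(-dh / temperature)
                    else:
                        accept = np.random.random() < 0.0
                if accept:
                    if m1:
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, fa1, mu1, -1)
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, a21, mu1, 1)
                    if m2:
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, fb1, nu1, -1)
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, b21, nu1, 1)
                    if m3:
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, fa2, mu2, -1)
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, a22, mu2, 1)
                    if m4:
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, fb2, nu2, -1)
                        _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, b22, nu2, 1)
                    ok = _move_synapse(p1, s2, o1, pair_syn, pair_orient, pair_pos,
                                       syn_count, syn_list, occ_len, occ_list, occ_pos, nm1)
                    ok2 = _move_synapse(p2, s1, o2, pair_syn, pair_orient, pair_pos,
                                        syn_count, syn_list, occ_len, occ_list, occ_pos, nm1)
                    if not (ok and ok2):
                        return (
                            STATUS_OVERFLOW, attempts, False, h_init, h, n_strict,
                            att_jump, att_swap, att_flip, acc_jump, acc_swap, acc_flip,
                            pair_syn, pair_orient,
                        )
                    h += dh
                    acc_swap += 1
                    if dh < 0:
                        n_strict += 1
                    if purity[0] == 0 and purity[1] == 0:
                        converged = True
                continue
            kind = 0  # no two occupied synapses at this cell: jump instead

        if kind == 2:
            p = np.random.randint(n_pairs)
            att_flip += 1
            d = pair_syn[p]
            a = d // nm1
            r = d % nm1
            b = r + 1 if r >= a else r
            if pair_orient[p] == 0:
                fa, fb, new_o = a, b, 1
            else:
                fa, fb, new_o = b, a, 0
            a2, b2 = fb, fa
        else:
            p = np.random.randint(n_pairs)
            s = pair_syn[p]
            a = s // nm1
            r = s % nm1
            b = r + 1 if r >= a else r
            if pair_orient[p] == 0:
                fa, fb = a, b
            else:
                fa, fb = b, a
            c = fa if np.random.randint(2) == 0 else fb
            while True:
                k = np.random.randint(two_nm1)
                if k < nm1:
                    d = c * nm1 + k
                else:
                    k2 = k - nm1
                    x = k2 + 1 if k2 >= c else k2
                    d = x * nm1 + (c - 1 if c > x else c)
                if d != s:
                    break
            new_o = np.random.randint(2)
            att_jump += 1
            a2 = d // nm1
            r = d % nm1
            b2 = r + 1 if r >= a2 else r
            if new_o == 1:
                a2, b2 = b2, a2

        mu, nu = pair_pre[p], pair_post[p]
        moved_a = fa != a2
        moved_b = fb != b2
        dh = np.int64(0)
        if moved_a:
            dh -= e1x2 * (counts[a2, mu] - counts[fa, mu] + 1)
        if moved_b:
            dh -= e1x2 * (counts[b2, nu] - counts[fb, nu] + 1)
        if moved_a or moved_b:
            ncells = 0
            if moved_a:
                dtot_cells[0] = fa
                dtot_vals[0] = -1
                dtot_cells[1] = a2
                dtot_vals[1] = 1
                ncells = 2
            if moved_b:
                ncells = _acc(dtot_cells, dtot_vals, ncells, fb, -1)
                ncells = _acc(dtot_cells, dtot_vals, ncells, b2, 1)
            for z in range(ncells):
                ddx = dtot_vals[z]
                if ddx != 0:
                    tv = totals[dtot_cells[z]]
                    dh += eps * (2 * tv * ddx + ddx * ddx)

        accept = dh <= 0
        if not accept:
            if dh < dh_cap:
                accept = np.random.random() < np.exp(-dh / temperature)
            else:
                accept = np.random.random() < 0.0
        if accept:
            if moved_a:
                _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, fa, mu, -1)
                _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, a2, mu, 1)
            if moved_b:
                _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, fb, nu, -1)
                _apply_endpoint(counts, totals, cell_ntypes, type_ncells, purity, b2, nu, 1)
            ok = _move_synapse(p, d, new_o, pair_syn, pair_orient, pair_pos,
                               syn_count, syn_list, occ_len, occ_list, occ_pos, nm1)
            if not ok:
                return (
                    STATUS_OVERFLOW, attempts, False, h_init, h, n_strict,
                    att_jump, att_swap, att_flip, acc_jump, acc_swap, acc_flip,
                    pair_syn, pair_orient,
                )
            h += dh
            if kind == 2:
                acc_flip += 1
            else:
                acc_jump += 1
            if dh < 0:
                n_strict += 1
            if purity[0] == 0 and purity[1] == 0:
                converged = True

    return (
        STATUS_OK, attempts, converged, h_init, h, n_strict,
        att_jump, att_swap, att_flip, acc_jump, acc_swap, acc_flip,
        pair_syn, pair_orient,
    )
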