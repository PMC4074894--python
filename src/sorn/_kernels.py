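"""Numba kernels for the inner simulation loop.

The excitatory-to-excitatory weight matrix is stored densely (``w``, with 0
meaning "no synapse"; every existing synapse has a strictly positive weight)
together with explicit adjacency lists:

``row_cols[i, :row_len[i]]``
    presynaptic partners of neuron ``i`` (the support of row ``i``), kept
    sorted in ascending column order,
``col_rows[j, :col_len[j]]``
    postsynaptic partners of neuron ``j`` (order irrelevant).

Keeping the row lists sorted pins down the floating-point summation order of
every accumulation (recurrent drive, row sums for synaptic scaling) to
"ascending index, sequential".  A straight-line reference implementation that
loops over a dense matrix in index order therefore reproduces the kernels
bit for bit, which the test suite exploits.

The per-step work is split in two phases so that the caller can interleave
the structural-plasticity random draw (which must see the connectivity left
behind by STDP eliminations) between them:

phase A : activity update -> history shift -> STDP -> inhibitory STDP
phase B : structural insertion -> synaptic scaling -> intrinsic plasticity
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_phase_a", "step_phase_b", "triad_census_dense"]


#: De Bruijn multiply-and-lookup for O(1) trailing-zero count on 64-bit
#: words; the table is generated from the sequence so it cannot drift.
_DEBRUIJN = np.uint64(0x03F79D71B4CB0A89)
_DEBRUIJN_TABLE = np.zeros(64, dtype=np.int64)
with np.errstate(over="ignore"):  # uint64 wraparound is the point
    for _i in range(64):
        _DEBRUIJN_TABLE[int((np.uint64(1 << _i) * _DEBRUIJN)
                            >> np.uint64(58))] = _i
del _i


@njit(cache=True)
def triad_census_dense(adj, canon):
    """Counts of weakly-connected 3-node induced subgraphs per canonical
    code.

    ``adj`` is the dense boolean adjacency matrix; ``canon`` maps each
    6-bit directed-triple code (bit order: (0,1), (0,2), (1,0), (1,2),
    (2,0), (2,1) for the sorted triple) to its canonical class code.
    Only connected triples are visited: for each pair a < b, candidate
    third nodes c > b come from bitsets of undirected neighborhoods —
    c must touch both of a, b when (a, b) is not linked, and at least one
    of them otherwise.
    """
    n = adj.shape[0]
    counts = np.zeros(64, dtype=np.int64)
    nw = (n + 63) // 64
    und = np.zeros((n, nw), dtype=np.uint64)
    one = np.uint64(1)
    for i in range(n):
        for j in range(n):
            if i != j and (adj[i, j] or adj[j, i]):
                und[i, j >> 6] |= one << np.uint64(j & 63)

    for a in range(n):
        for b in range(a + 1, n):
            ab = adj[a, b]
            ba = adj[b, a]
            linked = ab or ba
            base = 0
            if ab:
                base |= 1
            if ba:
                base |= 4
            start = (b + 1) >> 6
            shift = (b + 1) & 63
            for wd in range(start, nw):
                if linked:
                    m = und[a, wd] | und[b, wd]
                else:
                    m = und[a, wd] & und[b, wd]
                if wd == start and shift != 0:
                    m &= ~((one << np.uint64(shift)) - one)
                while m:
                    lsb = m & (np.uint64(0) - m)
                    c = (wd << 6) + _DEBRUIJN_TABLE[
                        (lsb * _DEBRUIJN) >> np.uint64(58)]
                    m ^= lsb
                    code = base
                    if adj[a, c]:
                        code |= 2
                    if adj[b, c]:
                        code |= 8
                    if adj[c, a]:
                        code |= 16
                    if adj[c, b]:
                        code |= 32
                    counts[canon[code]] += 1
    return counts


@njit(cache=True)
def step_phase_a(w, row_cols, row_len, col_rows, col_len,
                 w_ei, ei_mask, w_ie,
                 t_e, t_i,
                 x_curr, x_prev, y_curr, y_prev,
                 noise_e, noise_i,
                 eta_stdp, eta_inhib, istdp_gain,
                 do_activity, do_shift, do_stdp, do_istdp):
    """Activity update, history shift, STDP and inhibitory STDP.

    ``istdp_gain`` is the precomputed factor ``1 + 1/mu_istdp``.  Returns
    ``(x_new, y_new, n_active_e, n_removed)``: the freshly computed activity
    vectors, the number of excitatory spikes among them, and the number of
    synapses eliminated by STDP.
    """
    n_e = x_curr.shape[0]
    n_i = y_curr.shape[0]
    n_active = 0
    n_removed = 0
    x_new = np.zeros(n_e, dtype=np.uint8)
    y_new = np.zeros(n_i, dtype=np.uint8)

    if do_activity:
        # active-unit index lists (ascending, so summation order is the
        # documented ascending-index sequential order)
        act_x = np.empty(n_e, dtype=np.int64)
        n_ax = 0
        for j in range(n_e):
            if x_curr[j]:
                act_x[n_ax] = j
                n_ax += 1
        act_y = np.empty(n_i, dtype=np.int64)
        n_ay = 0
        for k in range(n_i):
            if y_curr[k]:
                act_y[n_ay] = k
                n_ay += 1

        # recurrent excitatory drive, accumulated in ascending presynaptic
        # index order (outer loop over active j)
        drive = np.zeros(n_e, dtype=np.float64)
        for m in range(n_ax):
            j = act_x[m]
            for k in range(col_len[j]):
                i = col_rows[j, k]
                drive[i] += w[i, j]
        for i in range(n_e):
            tot = drive[i]
            for m in range(n_ay):
                tot -= w_ei[i, act_y[m]]
            tot = tot - t_e[i] + noise_e[i]
            if tot > 0.0:
                x_new[i] = 1
                n_active += 1
        for i in range(n_i):
            tot = 0.0
            for m in range(n_ax):
                tot += w_ie[i, act_x[m]]
            tot = tot - t_i[i] + noise_i[i]
            if tot > 0.0:
                y_new[i] = 1

        if do_shift:
            for j in range(n_e):
                x_prev[j] = x_curr[j]
                x_curr[j] = x_new[j]
            for k in range(n_i):
                y_prev[k] = y_curr[k]
                y_curr[k] = y_new[k]

    if do_stdp:
        for i in range(n_e):
            xi_t = x_curr[i]
            xi_p = x_prev[i]
            if xi_t == 0 and xi_p == 0:
                continue
            k = 0
            while k < row_len[i]:
                j = row_cols[i, k]
                coeff = np.int64(xi_t) * np.int64(x_prev[j]) \
                    - np.int64(xi_p) * np.int64(x_curr[j])
                if coeff != 0:
                    v = w[i, j] + eta_stdp * coeff
                    if v <= 0.0:
                        # eliminate: remove from the sorted row list ...
                        w[i, j] = 0.0
                        for m in range(k, row_len[i] - 1):
                            row_cols[i, m] = row_cols[i, m + 1]
                        row_len[i] -= 1
                        # ... and from the (unsorted) column list
                        for m in range(col_len[j]):
                            if col_rows[j, m] == i:
                                col_rows[j, m] = col_rows[j, col_len[j] - 1]
                                col_len[j] -= 1
                                break
                        n_removed += 1
                        continue  # same k now holds the next entry
                    w[i, j] = v
                k += 1

    if do_istdp:
        for k in range(n_i):
            if y_prev[k]:
                for i in range(n_e):
                    if ei_mask[i, k]:
                        dw = -eta_inhib * (1.0 - x_curr[i] * istdp_gain)
                        v = w_ei[i, k] + dw
                        if v < 0.0:
                            v = 0.0
                        w_ei[i, k] = v

    return x_new, y_new, n_active, n_removed


@njit(cache=True)
def step_phase_b(w, row_cols, row_len, col_rows, col_len,
                 t_e, h_ip, x_curr,
                 add_i, add_j, w_init,
                 eta_ip, do_scaling, do_ip):
    """Structural insertion, multiplicative synaptic scaling, intrinsic
    plasticity.  ``add_i < 0`` means no structural insertion this step.
    The caller guarantees spare adjacency-list capacity before insertion.
    """
    n_e = x_curr.shape[0]

    if add_i >= 0:
        # sorted insert into the row list
        pos = row_len[add_i]
        for m in range(row_len[add_i]):
            if row_cols[add_i, m] > add_j:
                pos = m
                break
        for m in range(row_len[add_i], pos, -1):
            row_cols[add_i, m] = row_cols[add_i, m - 1]
        row_cols[add_i, pos] = add_j
        row_len[add_i] += 1
        col_rows[add_j, col_len[add_j]] = add_i
        col_len[add_j] += 1
        w[add_i, add_j] = w_init

    if do_scaling:
        for i in range(n_e):
            ln = row_len[i]
            if ln > 0:
                s = 0.0
                for k in range(ln):
                    s += w[i, row_cols[i, k]]
                for k in range(ln):
                    j = row_cols[i, k]
                    w[i, j] = w[i, j] / s

    if do_ip:
        for i in range(n_e):
            t_e[i] = t_e[i] + eta_ip * (x_curr[i] - h_ip[i])
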