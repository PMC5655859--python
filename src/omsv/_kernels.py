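"""Numba kernels for label-map dynamic programming alignment.

The DP state is over label pairs (query i matched to target j); transitions
look back at most ``max_skip`` skipped labels on each side.  The score of a
transition is

    match_bonus - (dq - dt)^2 / (2 * (sd0^2 + scale * dt))
    - miss_penalty * (skipped target labels)
    - false_penalty * (skipped query labels)

with free end gaps on both sides (any cell may start or end the chain).
Ties are broken deterministically: more matched pairs first, then smaller
total absolute residual, then the smaller predecessor cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e18
_EPS = 1e-9


@njit(cache=True)
def dp_tables(q, t, match_bonus, miss_pen, false_pen, sd0sq, vscale, max_skip,
              resolution, max_pen, jump_cost):
    """Full DP with backpointers; returns tables plus the best end cell."""
    nq = q.size
    nt = t.size
    dtab, iv, mtab = prep_target(t, sd0sq, vscale, max_skip, resolution)
    S = np.empty((nq, nt), np.float64)
    NP = np.empty((nq, nt), np.int32)
    AR = np.empty((nq, nt), np.float64)
    BI = np.empty((nq, nt), np.int32)
    BJ = np.empty((nq, nt), np.int32)
    best = NEG_INF
    bi = -1
    bj = -1
    bn_end = 0
    ba_end = 0.0
    for i in range(nq):
        for j in range(nt):
            bs = match_bonus
            bn = 1
            ba = 0.0
            pbi = -1
            pbj = -1
            for di in range(1, max_skip + 2):
                ii = i - di
                if ii < 0:
                    break
                dq = q[i] - q[ii]
                fpen = false_pen * (di - 1)
                for dj in range(1, max_skip + 2):
                    jj = j - dj
                    if jj < 0:
                        break
                    dt = dtab[j, dj - 1]
                    if dt < 0.0:
                        break
                    r = dq - dt
                    pen = r * r * iv[j, dj - 1]
                    if pen > max_pen:
                        if jump_cost <= 0.0:
                            continue
                        pen = jump_cost
                    s = (S[ii, jj] + match_bonus - pen
                         - miss_pen * mtab[j, dj - 1] - fpen)
                    cn = NP[ii, jj] + 1
                    ca = AR[ii, jj] + abs(r)
                    better = False
                    if s > bs + _EPS:
                        better = True
                    elif s > bs - _EPS:
                        if cn > bn:
                            better = True
                        elif cn == bn and ca < ba - _EPS:
                            better = True
                    if better:
                        bs = s
                        bn = cn
                        ba = ca
                        pbi = ii
                        pbj = jj
            S[i, j] = bs
            NP[i, j] = bn
            AR[i, j] = ba
            BI[i, j] = pbi
            BJ[i, j] = pbj
            eb = False
            if bs > best + _EPS:
                eb = True
            elif bs > best - _EPS:
                if bn > bn_end:
                    eb = True
                elif bn == bn_end and ba < ba_end - _EPS:
                    eb = True
            if eb:
                best = bs
                bi = i
                bj = j
                bn_end = bn
                ba_end = ba
    return S, NP, AR, BI, BJ, best, bi, bj


@njit(cache=True)
def prep_target(t, sd0sq, vscale, max_skip, resolution):
    """Per-(j, dj) target interval lengths, 1/(2 var) factors, and
    effective miss counts.

    A skipped target label lying within the optical resolution of either
    flanking matched label is almost certainly fused into the query's
    observed label, so it does not count as a miss.
    """
    nt = t.size
    dtab = np.empty((nt, max_skip + 1), np.float64)
    iv = np.empty((nt, max_skip + 1), np.float64)
    mtab = np.zeros((nt, max_skip + 1), np.float64)
    for j in range(nt):
        for dj in range(1, max_skip + 2):
            jj = j - dj
            if jj < 0:
                dtab[j, dj - 1] = -1.0
                iv[j, dj - 1] = 0.0
            else:
                dt = t[j] - t[jj]
                var = sd0sq + vscale * dt
                if var < 1.0:
                    var = 1.0
                dtab[j, dj - 1] = dt
                iv[j, dj - 1] = 0.5 / var
                nm = 0
                for k in range(jj + 1, j):
                    if (t[k] - t[jj] > resolution
                            and t[j] - t[k] > resolution):
                        nm += 1
                mtab[j, dj - 1] = nm
    return dtab, iv, mtab


@njit(cache=True)
def dp_score_pre(q, nt, dtab, iv, mtab, match_bonus, miss_pen, false_pen,
                 max_skip, max_pen, S, NP, SI, SJ):
    """Score-only DP with precomputed target tables and caller scratch.

    Scratch arrays must be at least (nq, nt).  Returns
    (score, n_pairs, start_i, start_j, end_i, end_j).
    """
    nq = q.size
    best = NEG_INF
    bi = 0
    bj = 0
    bn_end = 0
    for i in range(nq):
        qi = q[i]
        for j in range(nt):
            bs = match_bonus
            bn = 1
            si = i
            sj = j
            for di in range(1, max_skip + 2):
                ii = i - di
                if ii < 0:
                    break
                dq = qi - q[ii]
                base = match_bonus - false_pen * (di - 1)
                for dj in range(1, max_skip + 2):
                    dt = dtab[j, dj - 1]
                    if dt < 0.0:
                        break
                    r = dq - dt
                    pen = r * r * iv[j, dj - 1]
                    if pen > max_pen:
                        continue
                    jj = j - dj
                    s = (S[ii, jj] + base - pen
                         - miss_pen * mtab[j, dj - 1])
                    if s > bs + _EPS or (s > bs - _EPS and NP[ii, jj] + 1 > bn):
                        bs = s
                        bn = NP[ii, jj] + 1
                        si = SI[ii, jj]
                        sj = SJ[ii, jj]
            S[i, j] = bs
            NP[i, j] = bn
            SI[i, j] = si
            SJ[i, j] = sj
            if bs > best + _EPS or (bs > best - _EPS and bn > bn_end):
                best = bs
                bi = i
                bj = j
                bn_end = bn
    return best, bn_end, SI[bi, bj], SJ[bi, bj], bi, bj


@njit(cache=True)
def dp_score_ends(q, t, match_bonus, miss_pen, false_pen, sd0sq, vscale,
                  max_skip, resolution, max_pen):
    """Score-only DP: (score, n_pairs, start_i, start_j, end_i, end_j)."""
    nq = q.size
    nt = t.size
    dtab, iv, mtab = prep_target(t, sd0sq, vscale, max_skip, resolution)
    S = np.empty((nq, nt), np.float64)
    NP = np.empty((nq, nt), np.int32)
    SI = np.empty((nq, nt), np.int32)
    SJ = np.empty((nq, nt), np.int32)
    return dp_score_pre(q, nt, dtab, iv, mtab, match_bonus, miss_pen,
                        false_pen, max_skip, max_pen, S, NP, SI, SJ)


@njit(cache=True)
def all_pairs_scores(flat, mirror_flat, offs, match_bonus, miss_pen,
                     false_pen, sd0sq, vscale, max_skip, resolution,
                     max_pen, min_labels, centers, halfspans, use_hints):
    """All-vs-all screening of molecule pairs (both orientations).

    ``flat`` concatenates every molecule's label array; molecule k occupies
    ``flat[offs[k]:offs[k+1]]``.  ``mirror_flat`` holds the mirrored label
    arrays at the same offsets.  Returns per-pair arrays (i, j, score,
    orientation, n_pairs, and the matched endpoint label indices on query
    and target); query is the lower-index molecule.
    """
    n = offs.size - 1
    npairs_total = n * (n - 1) // 2
    out_i = np.empty(npairs_total, np.int32)
    out_j = np.empty(npairs_total, np.int32)
    out_score = np.full(npairs_total, NEG_INF)
    out_orient = np.zeros(npairs_total, np.int8)
    out_np = np.zeros(npairs_total, np.int32)
    out_qs = np.zeros(npairs_total, np.int32)
    out_qe = np.zeros(npairs_total, np.int32)
    out_ts = np.zeros(npairs_total, np.int32)
    out_te = np.zeros(npairs_total, np.int32)
    # precompute per-molecule target tables and shared scratch
    nmax = 0
    for k in range(n):
        sz = offs[k + 1] - offs[k]
        if sz > nmax:
            nmax = sz
    dtabs = np.empty((n, nmax, max_skip + 1), np.float64)
    ivtabs = np.empty((n, nmax, max_skip + 1), np.float64)
    mtabs = np.empty((n, nmax, max_skip + 1), np.float64)
    for k in range(n):
        t = flat[offs[k]:offs[k + 1]]
        if t.size:
            dtab, iv, mtab = prep_target(t, sd0sq, vscale, max_skip,
                                         resolution)
            dtabs[k, :t.size, :] = dtab
            ivtabs[k, :t.size, :] = iv
            mtabs[k, :t.size, :] = mtab
    S = np.empty((nmax, nmax), np.float64)
    NP = np.empty((nmax, nmax), np.int32)
    SI = np.empty((nmax, nmax), np.int32)
    SJ = np.empty((nmax, nmax), np.int32)
    idx = 0
    for i in range(n):
        qf = flat[offs[i]:offs[i + 1]]
        qm = mirror_flat[offs[i]:offs[i + 1]]
        nqi = qf.size
        for j in range(i + 1, n):
            out_i[idx] = i
            out_j[idx] = j
            t = flat[offs[j]:offs[j + 1]]
            if nqi < min_labels or t.size < min_labels:
                idx += 1
                continue
            if use_hints and centers[i] >= 0.0 and centers[j] >= 0.0:
                # bounding boxes: molecules too far apart to overlap
                # cannot produce a qualifying edge
                if abs(centers[i] - centers[j]) > (halfspans[i]
                                                   + halfspans[j]
                                                   + 100_000.0):
                    idx += 1
                    continue
            dtab = dtabs[j]
            iv = ivtabs[j]
            mtab = mtabs[j]
            s1, n1, si1, sj1, ei1, ej1 = dp_score_pre(
                qf, t.size, dtab, iv, mtab, match_bonus, miss_pen,
                false_pen, max_skip, max_pen, S, NP, SI, SJ)
            s2, n2, si2, sj2, ei2, ej2 = dp_score_pre(
                qm, t.size, dtab, iv, mtab, match_bonus, miss_pen,
                false_pen, max_skip, max_pen, S, NP, SI, SJ)
            if s1 >= s2:
                out_score[idx] = s1
                out_orient[idx] = 1
                out_np[idx] = n1
                out_qs[idx] = si1
                out_qe[idx] = ei1
                out_ts[idx] = sj1
                out_te[idx] = ej1
            else:
                out_score[idx] = s2
                out_orient[idx] = -1
                out_np[idx] = n2
                # mirrored query index k maps to original nq-1-k
                out_qs[idx] = nqi - 1 - si2
                out_qe[idx] = nqi - 1 - ei2
                out_ts[idx] = sj2
                out_te[idx] = ej2
            idx += 1
    return (out_i, out_j, out_score, out_orient, out_np, out_qs, out_qe,
            out_ts, out_te)


@njit(cache=True)
def molecules_vs_target(flat, mirror_flat, offs, t, match_bonus, miss_pen,
                        false_pen, sd0sq, vscale, max_skip, resolution,
                        max_pen, min_labels):
    """Score every molecule against one target map (both orientations).

    Score-only screening used for best-map assignment; the winning map's
    alignment is recomputed with a full traceback afterwards.  Returns
    (score, orientation, n_pairs) per molecule.
    """
    n = offs.size - 1
    nt = t.size
    dtab, iv, mtab = prep_target(t, sd0sq, vscale, max_skip, resolution)
    nmax = 0
    for k in range(n):
        sz = offs[k + 1] - offs[k]
        if sz > nmax:
            nmax = sz
    S = np.empty((nmax, nt), np.float64)
    NP = np.empty((nmax, nt), np.int32)
    SI = np.empty((nmax, nt), np.int32)
    SJ = np.empty((nmax, nt), np.int32)
    out_score = np.full(n, NEG_INF)
    out_orient = np.zeros(n, np.int8)
    out_np = np.zeros(n, np.int32)
    for k in range(n):
        q = flat[offs[k]:offs[k + 1]]
        if q.size < min_labels:
            continue
        qm = mirror_flat[offs[k]:offs[k + 1]]
        s1, n1, _, _, _, _ = dp_score_pre(
            q, nt, dtab, iv, mtab, match_bonus, miss_pen, false_pen,
            max_skip, max_pen, S, NP, SI, SJ)
        s2, n2, _, _, _, _ = dp_score_pre(
            qm, nt, dtab, iv, mtab, match_bonus, miss_pen, false_pen,
            max_skip, max_pen, S, NP, SI, SJ)
        if s1 >= s2:
            out_score[k] = s1
            out_orient[k] = 1
            out_np[k] = n1
        else:
            out_score[k] = s2
            out_orient[k] = -1
            out_np[k] = n2
    return out_score, out_orient, out_np


@njit(cache=True)
def molecules_vs_target_ends(flat, mirror_flat, offs, t, match_bonus,
                             miss_pen, false_pen, sd0sq, vscale, max_skip,
                             resolution, max_pen, min_labels):
    """Like ``molecules_vs_target`` but also returns the matched target
    index range (for approximate placement)."""
    n = offs.size - 1
    nt = t.size
    dtab, iv, mtab = prep_target(t, sd0sq, vscale, max_skip, resolution)
    nmax = 0
    for k in range(n):
        sz = offs[k + 1] - offs[k]
        if sz > nmax:
            nmax = sz
    S = np.empty((nmax, nt), np.float64)
    NP = np.empty((nmax, nt), np.int32)
    SI = np.empty((nmax, nt), np.int32)
    SJ = np.empty((nmax, nt), np.int32)
    out_score = np.full(n, NEG_INF)
    out_orient = np.zeros(n, np.int8)
    out_np = np.zeros(n, np.int32)
    out_ts = np.full(n, -1, np.int32)
    out_te = np.full(n, -1, np.int32)
    for k in range(n):
        q = flat[offs[k]:offs[k + 1]]
        if q.size < min_labels:
            continue
        qm = mirror_flat[offs[k]:offs[k + 1]]
        s1, n1, si1, sj1, ei1, ej1 = dp_score_pre(
            q, nt, dtab, iv, mtab, match_bonus, miss_pen, false_pen,
            max_skip, max_pen, S, NP, SI, SJ)
        s2, n2, si2, sj2, ei2, ej2 = dp_score_pre(
            qm, nt, dtab, iv, mtab, match_bonus, miss_pen, false_pen,
            max_skip, max_pen, S, NP, SI, SJ)
        if s1 >= s2:
            out_score[k] = s1
            out_orient[k] = 1
            out_np[k] = n1
            out_ts[k] = sj1
            out_te[k] = ej1
        else:
            out_score[k] = s2
            out_orient[k] = -1
            out_np[k] = n2
            out_ts[k] = sj2
            out_te[k] = ej2
    return out_score, out_orient, out_np, out_ts, out_te
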