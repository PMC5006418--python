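"""Numba-compiled inner loops: seed extension, banded affine alignment,
profile-HMM dynamic programming and covariance-model CYK.

Sequence encoding used everywhere: A=0, C=1, G=2, T=3, N=4, wall=5.
``N`` scores as a mismatch and never seeds a word match; the wall code marks
contig separators in concatenated genome arrays and behaves as an
impassable mismatch.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def ungapped_extend_batch(q, g, qpos, gpos, W, r, qpen, xdrop,
                          out_score, out_lext, out_rext):
    """X-drop ungapped extension of exact word seeds, batched over seeds.

    For each seed (query offset ``qpos[s]``, genome offset ``gpos[s]``) the
    seed word scores ``W*r``; extension proceeds outward on the diagonal,
    keeping the best prefix and stopping when the running score drops more
    than ``xdrop`` below it.
    """
    nq = q.shape[0]
    ng = g.shape[0]
    for s in range(qpos.shape[0]):
        # left
        i = qpos[s] - 1
        j = gpos[s] - 1
        sc = 0
        best = 0
        bestoff = 0
        off = 1
        while i >= 0 and j >= 0:
            a = q[i]
            b = g[j]
            if a == 5 or b == 5:
                break
            if a == b and a < 4:
                sc += r
            else:
                sc += qpen
            if sc > best:
                best = sc
                bestoff = off
            if sc < best - xdrop:
                break
            i -= 1
            j -= 1
            off += 1
        lbest = best
        lext = bestoff
        # right
        i = qpos[s] + W
        j = gpos[s] + W
        sc = 0
        best = 0
        bestoff = 0
        off = 1
        while i < nq and j < ng:
            a = q[i]
            b = g[j]
            if a == 5 or b == 5:
                break
            if a == b and a < 4:
                sc += r
            else:
                sc += qpen
            if sc > best:
                best = sc
                bestoff = off
            if sc < best - xdrop:
                break
            i += 1
            j += 1
            off += 1
        out_score[s] = W * r + lbest + best
        out_lext[s] = lext
        out_rext[s] = bestoff


@njit(cache=True)
def gotoh_extend(qs, gs, r, qpen, go, ge, band, xdrop):
    """Banded affine-gap extension with free end, anchored at (0, 0).

    Aligns prefixes of ``qs`` against prefixes of ``gs`` (Gotoh recurrences),
    restricted to |i-j| <= band, with X-drop termination.  Returns
    ``(best_score, qlen, glen, matches, columns)`` for the best-scoring
    prefix pair, where matches/columns describe the traceback alignment.
    """
    n = qs.shape[0]
    m = gs.shape[0]
    width = 2 * band + 1
    H = np.full((n + 1, width), NEG)
    E = np.full((n + 1, width), NEG)  # gap in query (consume genome)
    F = np.full((n + 1, width), NEG)  # gap in genome (consume query)
    H[0, band] = 0.0
    best = 0.0
    besti = 0
    bestj = 0
    for j in range(1, min(m, band) + 1):
        E[0, band + j] = -(go + ge * j)
        H[0, band + j] = E[0, band + j]
    stopped = False
    for i in range(1, n + 1):
        jlo = i - band
        if jlo < 0:
            jlo = 0
        jhi = i + band
        if jhi > m:
            jhi = m
        if jlo > m:
            break
        rowmax = NEG
        for j in range(jlo, jhi + 1):
            k = j - i + band
            if j == 0:
                F[i, k] = -(go + ge * i)
                H[i, k] = F[i, k]
                if H[i, k] > rowmax:
                    rowmax = H[i, k]
                continue
            # E: from (i, j-1) -> k-1 same row
            e = NEG
            if k - 1 >= 0:
                if E[i, k - 1] > NEG / 2:
                    e = E[i, k - 1] - ge
                h = H[i, k - 1]
                if h > NEG / 2 and h - go - ge > e:
                    e = h - go - ge
            E[i, k] = e
            # F: from (i-1, j) -> k+1 previous row
            f = NEG
            if k + 1 < width:
                if F[i - 1, k + 1] > NEG / 2:
                    f = F[i - 1, k + 1] - ge
                h = H[i - 1, k + 1]
                if h > NEG / 2 and h - go - ge > f:
                    f = h - go - ge
            F[i, k] = f
            # match/mismatch from (i-1, j-1) -> same k
            a = qs[i - 1]
            b = gs[j - 1]
            if a == 5 or b == 5:
                s = NEG
            elif a == b and a < 4:
                s = r
            else:
                s = float(qpen)
            d = NEG
            if H[i - 1, k] > NEG / 2 and s > NEG / 2:
                d = H[i - 1, k] + s
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, k] = h
            if h > rowmax:
                rowmax = h
            if h > best:
                best = h
                besti = i
                bestj = j
        if rowmax < best - xdrop:
            stopped = True
            break
    # traceback from (besti, bestj) in state H
    matches = 0
    cols = 0
    i = besti
    j = bestj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        k = j - i + band
        if state == 0:
            hv = H[i, k]
            # which predecessor?
            if j > 0 and i > 0:
                a = qs[i - 1]
                b = gs[j - 1]
                if a == 5 or b == 5:
                    s = NEG
                elif a == b and a < 4:
                    s = r
                else:
                    s = float(qpen)
                if H[i - 1, k] > NEG / 2 and abs(H[i - 1, k] + s - hv) < 1e-6:
                    cols += 1
                    if a == b and a < 4:
                        matches += 1
                    i -= 1
                    j -= 1
                    continue
            if E[i, k] > NEG / 2 and abs(E[i, k] - hv) < 1e-6:
                state = 1
                continue
            if F[i, k] > NEG / 2 and abs(F[i, k] - hv) < 1e-6:
                state = 2
                continue
            break  # start cell
        elif state == 1:
            ev = E[i, k]
            cols += 1
            if k - 1 >= 0 and E[i, k - 1] > NEG / 2 and abs(E[i, k - 1] - ge - ev) < 1e-6:
                j -= 1
                continue
            j -= 1
            state = 0
            continue
        else:
            fv = F[i, k]
            cols += 1
            if k + 1 < width and F[i - 1, k + 1] > NEG / 2 and abs(F[i - 1, k + 1] - ge - fv) < 1e-6:
                i -= 1
                continue
            i -= 1
            state = 0
            continue
    return best, besti, bestj, matches, cols


# ---------------------------------------------------------------------------
# profile HMM kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def phmm_viterbi(x, lo_m, t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd,
                 log_entry, log_exit):
    """Local Viterbi log-odds (nats) of sequence ``x`` against the profile.

    ``lo_m[k, c]`` is the match-state log-odds emission (5 columns, N=worst
    case); transitions are natural-log probabilities indexed by source node.
    Entry into any match state costs ``log_entry``; exit from node k costs
    ``log_exit[k]``.
    """
    L = x.shape[0]
    M = lo_m.shape[0]
    VM = np.full((L + 1, M + 1), NEG)
    VI = np.full((L + 1, M + 1), NEG)
    VD = np.full((L + 1, M + 1), NEG)
    best = NEG
    for t in range(1, L + 1):
        c = x[t - 1]
        for k in range(1, M + 1):
            v = log_entry  # fresh local start B -> M_k
            if k > 1:
                a = VM[t - 1, k - 1] + t_mm[k - 1]
                if a > v:
                    v = a
                a = VI[t - 1, k - 1] + t_im[k - 1]
                if a > v:
                    v = a
                a = VD[t - 1, k - 1] + t_dm[k - 1]
                if a > v:
                    v = a
            VM[t, k] = v + lo_m[k - 1, c]
            if k < M:
                a = VM[t - 1, k] + t_mi[k]
                b = VI[t - 1, k] + t_ii[k]
                VI[t, k] = a if a > b else b
            a = VM[t, k - 1] + t_md[k - 1] if k > 1 else NEG
            b = VD[t, k - 1] + t_dd[k - 1] if k > 1 else NEG
            VD[t, k] = a if a > b else b
            e = VM[t, k] + log_exit[k - 1]
            if e > best:
                best = e
    return best


@njit(cache=True)
def phmm_forward(x, lo_m, t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd,
                 log_entry, log_exit):
    """Local forward log-odds (nats): logsumexp over all local alignments."""
    L = x.shape[0]
    M = lo_m.shape[0]
    FM = np.full((L + 1, M + 1), NEG)
    FI = np.full((L + 1, M + 1), NEG)
    FD = np.full((L + 1, M + 1), NEG)
    total = NEG
    for t in range(1, L + 1):
        c = x[t - 1]
        for k in range(1, M + 1):
            v = log_entry
            if k > 1:
                for a in (FM[t - 1, k - 1] + t_mm[k - 1],
                          FI[t - 1, k - 1] + t_im[k - 1],
                          FD[t - 1, k - 1] + t_dm[k - 1]):
                    if a > NEG / 2:
                        if v < a:
                            v, a = a, v
                        v = v + math.log1p(math.exp(a - v))
            FM[t, k] = v + lo_m[k - 1, c]
            if k < M:
                a = FM[t - 1, k] + t_mi[k]
                b = FI[t - 1, k] + t_ii[k]
                if a < b:
                    a, b = b, a
                FI[t, k] = a + math.log1p(math.exp(b - a)) if b > NEG / 2 else a
            if k > 1:
                a = FM[t, k - 1] + t_md[k - 1]
                b = FD[t, k - 1] + t_dd[k - 1]
                if a < b:
                    a, b = b, a
                FD[t, k] = a + math.log1p(math.exp(b - a)) if b > NEG / 2 else a
            e = FM[t, k] + log_exit[k - 1]
            if e > NEG / 2:
                if total < e:
                    total, e = e, total
                total = total + math.log1p(math.exp(e - total))
    return total


@njit(cache=True)
def phmm_posterior(x, lo_m, t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd,
                   log_entry, log_exit):
    """Per-position posterior probability of being emitted by the model.

    Returns (posterior[L], forward_nats).  Paths are weighted as in
    :func:`phmm_forward`; residues outside an alignment are emitted by the
    null model and contribute log-odds 0, so the denominator is
    1 + sum over alignments.
    """
    L = x.shape[0]
    M = lo_m.shape[0]
    FM = np.full((L + 1, M + 1), NEG)
    FI = np.full((L + 1, M + 1), NEG)
    FD = np.full((L + 1, M + 1), NEG)
    for t in range(1, L + 1):
        c = x[t - 1]
        for k in range(1, M + 1):
            v = log_entry
            if k > 1:
                for a in (FM[t - 1, k - 1] + t_mm[k - 1],
                          FI[t - 1, k - 1] + t_im[k - 1],
                          FD[t - 1, k - 1] + t_dm[k - 1]):
                    if a > NEG / 2:
                        if v < a:
                            v, a = a, v
                        v = v + math.log1p(math.exp(a - v))
            FM[t, k] = v + lo_m[k - 1, c]
            if k < M:
                a = FM[t - 1, k] + t_mi[k]
                b = FI[t - 1, k] + t_ii[k]
                if a < b:
                    a, b = b, a
                FI[t, k] = a + math.log1p(math.exp(b - a)) if b > NEG / 2 else a
            if k > 1:
                a = FM[t, k - 1] + t_md[k - 1]
                b = FD[t, k - 1] + t_dd[k - 1]
                if a < b:
                    a, b = b, a
                FD[t, k] = a + math.log1p(math.exp(b - a)) if b > NEG / 2 else a
    # backward: BM[t,k] = logsum of path weights from M_k at position t to exit
    BM = np.full((L + 1, M + 1), NEG)
    BI = np.full((L + 1, M + 1), NEG)
    BD = np.full((L + 1, M + 1), NEG)
    for t in range(L, 0, -1):
        for k in range(M, 0, -1):
            v = log_exit[k - 1]
            if k < M:
                if t < L:
                    a = t_mm[k] + lo_m[k, x[t]] + BM[t + 1, k + 1]
                    if a > NEG / 2:
                        if v < a:
                            v, a = a, v
                        v = v + math.log1p(math.exp(a - v))
                    a = t_mi[k] + BI[t + 1, k]
                    if a > NEG / 2:
                        if v < a:
                            v, a = a, v
                        v = v + math.log1p(math.exp(a - v))
                a = t_md[k] + BD[t, k + 1]
                if a > NEG / 2:
                    if v < a:
                        v, a = a, v
                    v = v + math.log1p(math.exp(a - v))
            BM[t, k] = v
            if k < M:
                b = NEG
                if t < L:
                    a = t_im[k] + lo_m[k, x[t]] + BM[t + 1, k + 1]
                    b2 = t_ii[k] + BI[t + 1, k]
                    b = a
                    if b2 > b:
                        b, b2 = b2, b
                    if b2 > NEG / 2:
                        b = b + math.log1p(math.exp(b2 - b))
                BI[t, k] = b
                d = NEG
                if t < L:
                    d = t_dm[k] + lo_m[k, x[t]] + BM[t + 1, k + 1]
                d2 = t_dd[k] + BD[t, k + 1] if k + 1 <= M else NEG
                if d2 > d:
                    d, d2 = d2, d
                if d2 > NEG / 2:
                    d = d + math.log1p(math.exp(d2 - d))
                BD[t, k] = d
    total = NEG
    for t in range(1, L + 1):
        for k in range(1, M + 1):
            e = FM[t, k] + log_exit[k - 1]
            if e > NEG / 2:
                if total < e:
                    total, e = e, total
                total = total + math.log1p(math.exp(e - total))
    post = np.zeros(L)
    denom = math.log1p(math.exp(total)) if total > NEG / 2 else 0.0
    for t in range(1, L + 1):
        num = NEG
        # FM includes the emission at t; BM continues after it, so each
        # path through (t, M_k) or (t, I_k) is weighted exactly once.
        for k in range(1, M + 1):
            for val in (FM[t, k] + BM[t, k], FI[t, k] + BI[t, k]):
                if val > NEG / 2:
                    if num < val:
                        num, val = val, num
                    num = num + math.log1p(math.exp(val - num))
        post[t - 1] = math.exp(num - denom) if num > NEG / 2 else 0.0
    return post, total


# ---------------------------------------------------------------------------
# covariance model CYK
# ---------------------------------------------------------------------------

@njit(cache=True)
def cm_cyk(x, stype, tr_ptr, tr_n, tr_to, tr_lp, eL, eR, eP, bleft, bright):
    """Max log-odds (nats) CYK over all spans; fills the full alpha table.

    ``stype``: 0=S 1=ML 2=MR 3=MP 4=D 5=IL 6=IR 7=B 8=E.  Transitions go
    from lower to higher state index except insert self-loops, so states are
    swept in descending order within each span length.
    Returns (alpha, best_score, best_i, best_j).
    """
    L = x.shape[0]
    S = stype.shape[0]
    alpha = np.full((S, L + 1, L + 1), NEG, dtype=np.float32)
    for d in range(0, L + 1):
        for i in range(0, L - d + 1):
            j = i + d
            for s in range(S - 1, -1, -1):
                st = stype[s]
                if st == 8:  # END
                    if d == 0:
                        alpha[s, i, j] = 0.0
                    continue
                if st == 7:  # BIF
                    best = NEG
                    bl = bleft[s]
                    br = bright[s]
                    for k in range(i, j + 1):
                        a = alpha[bl, i, k]
                        b = alpha[br, k, j]
                        if a > NEG / 2 and b > NEG / 2 and a + b > best:
                            best = a + b
                    alpha[s, i, j] = best
                    continue
                if st == 0 or st == 4:  # S or D: non-emitting
                    best = NEG
                    for ti in range(tr_ptr[s], tr_ptr[s] + tr_n[s]):
                        to = tr_to[ti]
                        a = alpha[to, i, j]
                        if a > NEG / 2 and a + tr_lp[ti] > best:
                            best = a + tr_lp[ti]
                    alpha[s, i, j] = best
                    continue
                if st == 1 or st == 5:  # ML / IL: emit left
                    if d < 1:
                        continue
                    em = eL[s, x[i]]
                    best = NEG
                    for ti in range(tr_ptr[s], tr_ptr[s] + tr_n[s]):
                        to = tr_to[ti]
                        a = alpha[to, i + 1, j]
                        if a > NEG / 2 and a + tr_lp[ti] > best:
                            best = a + tr_lp[ti]
                    if best > NEG / 2:
                        alpha[s, i, j] = best + em
                    continue
                if st == 2 or st == 6:  # MR / IR: emit right
                    if d < 1:
                        continue
                    em = eR[s, x[j - 1]]
                    best = NEG
                    for ti in range(tr_ptr[s], tr_ptr[s] + tr_n[s]):
                        to = tr_to[ti]
                        a = alpha[to, i, j - 1]
                        if a > NEG / 2 and a + tr_lp[ti] > best:
                            best = a + tr_lp[ti]
                    if best > NEG / 2:
                        alpha[s, i, j] = best + em
                    continue
                # MP: emit pair
                if d < 2:
                    continue
                a4 = x[i]
                b4 = x[j - 1]
                em = eP[s, 5 * a4 + b4]
                best = NEG
                for ti in range(tr_ptr[s], tr_ptr[s] + tr_n[s]):
                    to = tr_to[ti]
                    a = alpha[to, i + 1, j - 1]
                    if a > NEG / 2 and a + tr_lp[ti] > best:
                        best = a + tr_lp[ti]
                if best > NEG / 2:
                    alpha[s, i, j] = best + em
    best = NEG
    bi = 0
    bj = 0
    for i in range(L + 1):
        for j in range(i, L + 1):
            if alpha[0, i, j] > best:
                best = alpha[0, i, j]
                bi = i
                bj = j
    return alpha, best, bi, bj
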