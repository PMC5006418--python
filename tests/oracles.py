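"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity the package computes with an optimized
algorithm, using a deliberately naive implementation: full unbanded
Smith-Waterman with affine gaps, explicit path/parse enumeration for the
profile-HMM forward score and the CYK parse score, and exhaustive
assignment enumeration for Dollo losses.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ncranno.search import encode

NEG = -1.0e30


# ---------------------------------------------------------------------------
# full affine-gap local alignment (Gotoh), unbanded, no X-drop
# ---------------------------------------------------------------------------

def smith_waterman_affine(a: str, b: str, r: int, q: int, go: int, ge: int):
    """Optimal local alignment score and one optimal alignment path.

    Gap of length k costs ``go + k * ge``.  Returns ``(score, pairs)`` where
    pairs is the list of aligned index tuples ``(i, j)`` for match/mismatch
    columns of one optimum (gap columns omitted).
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            F[i, j] = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            s = r if a[i - 1] == b[j - 1] else q
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    # traceback of one optimum
    pairs = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            s = r if a[i - 1] == b[j - 1] else q
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) < 1e-9:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif abs(H[i, j] - E[i, j]) < 1e-9:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if abs(E[i, j] - (E[i, j - 1] - ge)) < 1e-9:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            if abs(F[i, j] - (F[i - 1, j] - ge)) < 1e-9:
                i -= 1
            else:
                i -= 1
                state = "H"
    pairs.reverse()
    return best, pairs


def optimum_contains_word(a: str, b: str, pairs, W: int) -> bool:
    """True if the alignment contains W consecutive identical match columns."""
    run = 0
    prev = None
    for i, j in pairs:
        contiguous = prev is not None and i == prev[0] + 1 and j == prev[1] + 1
        if a[i] == b[j]:
            run = run + 1 if contiguous and run > 0 else 1
        else:
            run = 0
        if run >= W:
            return True
        prev = (i, j)
    return False


# ---------------------------------------------------------------------------
# profile-HMM forward score by explicit path recursion
# ---------------------------------------------------------------------------

def phmm_forward_oracle(phmm, seq: str) -> float:
    """Sum of path weights over all local alignments, in bits."""
    (lo, tmm, tmi, tmd, tim, tii, tdm, tdd,
     log_entry, log_exit) = phmm._log_arrays()
    x = encode(seq)
    L, M = len(x), phmm.M
    em = np.exp(lo)

    def p(arr, k):
        v = arr[k]
        return math.exp(v) if v > NEG / 2 else 0.0

    exitp = np.exp(log_exit)

    def after_match(k, t):  # in M_k having emitted x[t-1]; 1-based t
        w = exitp[k - 1]
        if k < M:
            if t < L:
                w += p(tmm, k) * em[k, x[t]] * after_match(k + 1, t + 1)
                w += p(tmi, k) * after_insert(k, t + 1)
            w += p(tmd, k) * after_delete(k + 1, t)
        return w

    def after_insert(k, t):  # in I_k having emitted x[t-1] at odds 1
        w = 0.0
        if t < L:
            w += p(tim, k) * em[k, x[t]] * after_match(k + 1, t + 1)
            w += p(tii, k) * after_insert(k, t + 1)
        return w

    def after_delete(k, t):  # in D_k, nothing emitted at t yet
        w = 0.0
        if k < M:
            if t < L:
                w += p(tdm, k) * em[k, x[t]] * after_match(k + 1, t + 1)
            w += p(tdd, k) * after_delete(k + 1, t)
        return w

    entry = math.exp(log_entry)
    total = 0.0
    for t in range(1, L + 1):
        for k in range(1, M + 1):
            total += entry * em[k - 1, x[t - 1]] * after_match(k, t)
    return math.log2(total) if total > 0 else float("-inf")


# ---------------------------------------------------------------------------
# CYK parse score by explicit parse-tree recursion (no tables)
# ---------------------------------------------------------------------------

def cyk_oracle(cm, seq: str) -> float:
    """Max log-odds (bits) over all parse trees, by naive recursion."""
    x = encode(seq)

    def best(s, i, j):
        st = int(cm.stype[s])
        if st == 8:  # END
            return 0.0 if i == j else -math.inf
        if st == 7:  # BIF
            bl, br = int(cm.bleft[s]), int(cm.bright[s])
            return max((best(bl, i, k) + best(br, k, j)
                        for k in range(i, j + 1)), default=-math.inf)
        if st in (0, 4):  # S / D, non-emitting
            return _over_transitions(s, i, j, 0.0)
        if st in (1, 5):  # ML / IL
            if j - i < 1:
                return -math.inf
            return _over_transitions(s, i + 1, j, float(cm.eL[s, x[i]]))
        if st in (2, 6):  # MR / IR
            if j - i < 1:
                return -math.inf
            return _over_transitions(s, i, j - 1, float(cm.eR[s, x[j - 1]]))
        if j - i < 2:  # MP
            return -math.inf
        return _over_transitions(s, i + 1, j - 1,
                                 float(cm.eP[s, 5 * x[i] + x[j - 1]]))

    def _over_transitions(s, i, j, em):
        out = -math.inf
        for ti in range(int(cm.tr_ptr[s]), int(cm.tr_ptr[s] + cm.tr_n[s])):
            v = best(int(cm.tr_to[ti]), i, j) + float(cm.tr_lp[ti]) + em
            if v > out:
                out = v
        return out

    L = len(x)
    top = max(best(0, i, j)
              for i in range(L + 1) for j in range(i, L + 1))
    return top / math.log(2.0)


# ---------------------------------------------------------------------------
# Dollo minimum losses by exhaustive single-gain assignment enumeration
# ---------------------------------------------------------------------------

def dollo_min_losses(tree, leaf_states: dict) -> int | None:
    """Minimum loss count over all assignments with exactly one gain.

    ``tree`` is an :class:`ncranno.dollo.Tree`; ``leaf_states`` maps leaf
    label to 0/1.  A gain is an edge whose parent is absent and child
    present; a present root also counts as the single gain.  Returns None
    if the family is absent everywhere (no gain needed).
    """
    if not any(leaf_states.values()):
        return None
    internal = [n for n in tree.preorder if tree.children[n]]
    best = None
    for bits in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, bits))
        state.update(leaf_states)
        gains = losses = 0
        if state[tree.root] == 1:
            gains += 1
        for n in tree.preorder:
            parent = tree.parent[n]
            if parent is None:
                continue
            if state[parent] == 0 and state[n] == 1:
                gains += 1
            elif state[parent] == 1 and state[n] == 0:
                losses += 1
        if gains == 1 and (best is None or losses < best):
            best = losses
    return best
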