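"""Miniature covariance models: an SCFG over a seed alignment's consensus
structure, scored by CYK, calibrated on shuffled-sequence nulls, with the
three-criterion acceptance rule, overlap resolution and final curation.

The model is global in the model and local in the sequence: the best-scoring
subsequence parsed by the complete grammar is reported, and flanking
sequence is explained by the null model.  Guide-tree nodes are derived from
the consensus structure (MATP for paired match columns, MATL/MATR for
unpaired ones, BIF for multiloops); paired nodes emit 16-way joint
distributions, which is what gives the model its secondary-structure
signal.  Infernal's local ends, truncated-hit modes and banded search are
deliberately out of scope: the decision logic (gathering threshold,
E-value, model coverage, 300 nt curation re-score) is the point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._stats import fit_gumbel_censored
from .search import encode
from .seqio import GenomicInterval, SeedAlignment, reverse_complement

__all__ = [
    "CovarianceModel",
    "CmHit",
    "AnnotatedLocus",
    "build_cm",
    "cyk",
    "calibrate_cm",
    "search_cm",
    "resolve_overlaps",
    "curate_final",
]

LN2 = math.log(2.0)
_GAPS = {"-", "."}
_IDX = {b: i for i, b in enumerate("ACGT")}

# state type codes shared with the kernel
S_S, S_ML, S_MR, S_MP, S_D, S_IL, S_IR, S_B, S_E = range(9)
_MATCH_WEIGHT = {S_ML: 1, S_MR: 1, S_MP: 2}


@dataclass
class CovarianceModel:
    family_id: str
    rna_class: str
    clen: int
    consensus: str
    structure: str                   # over match columns, '(', ')', '.'
    background: np.ndarray           # (4,)
    # flattened state machine for the CYK kernel
    stype: np.ndarray
    tr_ptr: np.ndarray
    tr_n: np.ndarray
    tr_to: np.ndarray
    tr_lp: np.ndarray
    eL: np.ndarray
    eR: np.ndarray
    eP: np.ndarray
    bleft: np.ndarray
    bright: np.ndarray
    node_kinds: list[str] = field(default_factory=list)
    GA: float | None = None
    gumbel: tuple[float, float] | None = None  # (mu, lambda_evd) in bits
    max_window_factor: int = 4

    @property
    def calibrated(self) -> bool:
        return self.gumbel is not None and self.GA is not None

    @property
    def max_window(self) -> int:
        return self.max_window_factor * self.clen

    def evalue(self, bitscore: float, n_search: float) -> float:
        if self.gumbel is None:
            raise ValueError("model is not calibrated")
        mu, lam = self.gumbel
        return float(n_search * math.exp(-lam * (bitscore - mu)))


@dataclass(frozen=True)
class CmHit:
    interval: GenomicInterval
    bitscore: float
    evalue: float
    model_coverage: float
    family_id: str
    rna_class: str = "misc_RNA"
    status: str = "raw"
    evidence: frozenset = frozenset()


@dataclass(frozen=True)
class AnnotatedLocus:
    """A curated ncRNA locus ready for GFF3/TSV emission."""

    family_id: str
    rna_class: str
    interval: GenomicInterval
    bitscore: float
    evalue: float
    evidence: frozenset = frozenset()
    curated: bool = True
    clipped: bool = False


def build_cm(seed: SeedAlignment, taxon_filter: set | None = None,
             background=None, p_ins: float = 0.02,
             p_ins_self: float = 0.5) -> CovarianceModel:
    """Build a covariance model from a seed alignment.

    ``taxon_filter`` drops rows whose names are not in the given set before
    counting (used to build clade-specific model variants); the guide-tree
    topology comes from the consensus structure alone, so filtering changes
    emissions but never topology.  Match columns are those with <50 % gaps;
    emissions get +1 pseudocounts.  Structure pairs with exactly one column
    dropped from the match set are an error.
    """
    rows = dict(seed.rows)
    if taxon_filter is not None:
        rows = {k: v for k, v in rows.items() if k in taxon_filter}
        if not rows:
            raise ValueError("taxon filter removed every row")
    mat = list(rows.values())
    nrow = len(mat)
    ncol = len(seed.ss_cons)
    match_cols = [c for c in range(ncol)
                  if sum(r[c] in _GAPS for r in mat) / nrow < 0.5]
    if not match_cols:
        raise ValueError("alignment has zero match columns")
    in_match = set(match_cols)
    rank = {c: k for k, c in enumerate(match_cols)}
    pairs_full = seed.pair_table()
    struct = []
    pair: dict[int, int] = {}
    for c in match_cols:
        p = pairs_full.get(c)
        if p is None:
            struct.append(".")
        elif p not in in_match:
            raise ValueError(
                f"SS_cons pair ({c},{p}) spans a dropped (insert) column"
            )
        else:
            struct.append("(" if p > c else ")")
            pair[rank[c]] = rank[p]
    structure = "".join(struct)
    clen = len(match_cols)

    if background is None:
        counts = np.ones(4)
        for r in mat:
            for ch in r:
                if ch in _IDX:
                    counts[_IDX[ch]] += 1
        background = counts / counts.sum()
    bg = np.asarray(background, float)

    # per-column residue counts (+1) and joint pair counts (+1)
    col_res = np.ones((clen, 4))
    for r in mat:
        for c in match_cols:
            ch = r[c]
            if ch in _IDX:
                col_res[rank[c], _IDX[ch]] += 1

    builder = _StateBuilder(structure, pair, col_res, mat, match_cols, rank,
                            bg, p_ins, p_ins_self)
    builder.run()
    consensus = "".join("ACGT"[int(np.argmax(col_res[k]))]
                        for k in range(clen))
    return CovarianceModel(
        family_id=seed.family_id, rna_class=seed.rna_class,
        clen=clen, consensus=consensus, structure=structure,
        background=bg, node_kinds=builder.node_kinds, **builder.arrays(),
    )


class _StateBuilder:
    """Recursive guide-tree walk emitting the flattened state machine."""

    def __init__(self, structure, pair, col_res, mat, match_cols, rank,
                 bg, p_ins, p_ins_self):
        self.structure = structure
        self.pair = pair
        self.col_res = col_res
        self.mat = mat
        self.match_cols = match_cols
        self.rank = rank
        self.bg = bg
        self.p_ins = p_ins
        self.p_self = p_ins_self
        self.stype: list[int] = []
        self.emit: list[tuple] = []       # per state: (kind, payload)
        self.trans: list[list] = []       # per state: [(to, prob), ...]
        self.bif: list[tuple] = []        # per state: (left, right) or None
        self.node_kinds: list[str] = []

    def _add(self, st, emit=None):
        self.stype.append(st)
        self.emit.append(emit)
        self.trans.append([])
        self.bif.append(None)
        return len(self.stype) - 1

    def run(self):
        root = self._add(S_S)
        self.node_kinds.append("ROOT")
        entries = self._segment(0, len(self.structure))
        self._link([root], [], entries)

    def _usage_counts(self, kind, k1, k2=None):
        """Split-state usage counts (+1 Laplace) for a node, from the rows."""
        c1 = self.match_cols[k1]
        if kind == "MATL" or kind == "MATR":
            npresent = sum(1 for r in self.mat if r[c1] in _IDX)
            return [npresent + 1, len(self.mat) - npresent + 1]  # M, D
        c2 = self.match_cols[k2]
        mp = ml = mr = d = 0
        for r in self.mat:
            a, b = r[c1] in _IDX, r[c2] in _IDX
            if a and b:
                mp += 1
            elif a:
                ml += 1
            elif b:
                mr += 1
            else:
                d += 1
        return [mp + 1, ml + 1, mr + 1, d + 1]

    def _segment(self, i, j):
        """Emit states for match-ordinal interval [i, j); returns the entry
        split states [(idx, weight), ...] of its first node."""
        if i >= j:
            e = self._add(S_E)
            self.node_kinds.append("END")
            return [(e, 1.0)]
        s = self.structure
        if s[i] == ".":
            w = self._usage_counts("MATL", i)
            ml = self._add(S_ML, ("L", i))
            d = self._add(S_D)
            il = self._add(S_IL, ("bg",))
            self.node_kinds.append("MATL")
            nxt = self._segment(i + 1, j)
            self._link([ml, d], [il], nxt)
            return [(ml, w[0]), (d, w[1])]
        if s[j - 1] == ".":
            w = self._usage_counts("MATR", j - 1)
            mr = self._add(S_MR, ("R", j - 1))
            d = self._add(S_D)
            ir = self._add(S_IR, ("bg",))
            self.node_kinds.append("MATR")
            nxt = self._segment(i, j - 1)
            self._link([mr, d], [ir], nxt)
            return [(mr, w[0]), (d, w[1])]
        if self.pair.get(i) == j - 1:
            w = self._usage_counts("MATP", i, j - 1)
            mp = self._add(S_MP, ("P", i, j - 1))
            ml = self._add(S_ML, ("L", i))
            mr = self._add(S_MR, ("R", j - 1))
            d = self._add(S_D)
            il = self._add(S_IL, ("bg",))
            ir = self._add(S_IR, ("bg",))
            self.node_kinds.append("MATP")
            nxt = self._segment(i + 1, j - 1)
            self._link([mp, ml, mr, d], [il, ir], nxt)
            return [(mp, w[0]), (ml, w[1]), (mr, w[2]), (d, w[3])]
        # bifurcation: i pairs k with k < j-1
        k = self.pair[i]
        b = self._add(S_B)
        self.node_kinds.append("BIF")
        sl = self._add(S_S)
        self.node_kinds.append("BEGL")
        left = self._segment(i, k + 1)
        self._link([sl], [], left)
        sr = self._add(S_S)
        self.node_kinds.append("BEGR")
        right = self._segment(k + 1, j)
        self._link([sr], [], right)
        self.bif[b] = (sl, sr)
        return [(b, 1.0)]

    def _link(self, splits, inserts, nxt):
        tot = sum(w for _, w in nxt)
        norm = [(idx, w / tot) for idx, w in nxt]
        n_ins = len(inserts)
        for s in splits:
            main = 1.0 - self.p_ins * n_ins
            self.trans[s] = [(ins, self.p_ins) for ins in inserts]
            self.trans[s] += [(idx, main * w) for idx, w in norm]
        for pos, ins in enumerate(inserts):
            later = inserts[pos + 1:]
            main = 1.0 - self.p_self - self.p_ins * len(later)
            self.trans[ins] = [(ins, self.p_self)]
            self.trans[ins] += [(l, self.p_ins) for l in later]
            self.trans[ins] += [(idx, main * w) for idx, w in norm]

    def arrays(self):
        S = len(self.stype)
        stype = np.asarray(self.stype, dtype=np.int64)
        tr_ptr = np.zeros(S, dtype=np.int64)
        tr_n = np.zeros(S, dtype=np.int64)
        to_flat: list[int] = []
        lp_flat: list[float] = []
        for s in range(S):
            tr_ptr[s] = len(to_flat)
            tr_n[s] = len(self.trans[s])
            for to, p in self.trans[s]:
                to_flat.append(to)
                lp_flat.append(math.log(p))
        eL = np.full((S, 5), _kernels.NEG)
        eR = np.full((S, 5), _kernels.NEG)
        eP = np.full((S, 25), _kernels.NEG)
        logbg = np.log(self.bg)
        for s in range(S):
            em = self.emit[s]
            if em is None:
                continue
            if em[0] == "bg":
                tgt = eL if self.stype[s] == S_IL else eR
                tgt[s, :4] = 0.0
                tgt[s, 4] = 0.0
            elif em[0] == "L" or em[0] == "R":
                k = em[1]
                p = self.col_res[k] / self.col_res[k].sum()
                lo = np.log(p) - logbg
                tgt = eL if em[0] == "L" else eR
                tgt[s, :4] = lo
                tgt[s, 4] = lo.min()
            else:  # pair
                k1, k2 = em[1], em[2]
                joint = np.ones((4, 4))
                c1 = self.match_cols[k1]
                c2 = self.match_cols[k2]
                for r in self.mat:
                    if r[c1] in _IDX and r[c2] in _IDX:
                        joint[_IDX[r[c1]], _IDX[r[c2]]] += 1
                joint /= joint.sum()
                lo = np.log(joint) - logbg[:, None] - logbg[None, :]
                full = np.full((5, 5), lo.min())
                full[:4, :4] = lo
                eP[s] = full.ravel()
        bleft = np.full(S, -1, dtype=np.int64)
        bright = np.full(S, -1, dtype=np.int64)
        for s, lr in enumerate(self.bif):
            if lr is not None:
                bleft[s], bright[s] = lr
        return dict(
            stype=stype, tr_ptr=tr_ptr, tr_n=tr_n,
            tr_to=np.asarray(to_flat, dtype=np.int64),
            tr_lp=np.asarray(lp_flat, dtype=np.float64),
            eL=eL, eR=eR, eP=eP, bleft=bleft, bright=bright,
        )


def _cyk_details(cm: CovarianceModel, seq: str):
    """CYK over one sequence: (bits, matched_positions, (span_start, span_end))."""
    x = encode(seq)
    alpha, best, bi, bj = _kernels.cm_cyk(
        x, cm.stype, cm.tr_ptr, cm.tr_n, cm.tr_to, cm.tr_lp,
        cm.eL, cm.eR, cm.eP, cm.bleft, cm.bright,
    )
    if best < _kernels.NEG / 2:
        return float("-inf"), 0, (0, 0)
    matched = _traceback_matched(cm, alpha, x, bi, bj)
    return best / LN2, matched, (bi, bj)


def _traceback_matched(cm, alpha, x, i0, j0):
    """Walk the optimal parse recomputing argmax decisions; count consensus
    columns aligned to residues (MP counts two)."""
    stack = [(0, i0, j0)]
    matched = 0
    while stack:
        s, i, j = stack.pop()
        st = int(cm.stype[s])
        if st == S_E:
            continue
        if st == S_B:
            target = alpha[s, i, j]
            bl, br = int(cm.bleft[s]), int(cm.bright[s])
            for k in range(i, j + 1):
                if abs(alpha[bl, i, k] + alpha[br, k, j] - target) < 1e-4:
                    stack.append((bl, i, k))
                    stack.append((br, k, j))
                    break
            continue
        if st in (S_ML, S_IL):
            em = cm.eL[s, x[i]]
            ni, nj = i + 1, j
        elif st in (S_MR, S_IR):
            em = cm.eR[s, x[j - 1]]
            ni, nj = i, j - 1
        elif st == S_MP:
            em = cm.eP[s, 5 * x[i] + x[j - 1]]
            ni, nj = i + 1, j - 1
        else:  # S or D
            em = 0.0
            ni, nj = i, j
        if st in _MATCH_WEIGHT:
            matched += _MATCH_WEIGHT[st]
        target = alpha[s, i, j] - em
        found = False
        for ti in range(int(cm.tr_ptr[s]), int(cm.tr_ptr[s] + cm.tr_n[s])):
            to = int(cm.tr_to[ti])
            a = alpha[to, ni, nj]
            if a > _kernels.NEG / 2 and abs(a + cm.tr_lp[ti] - target) < 1e-4:
                stack.append((to, ni, nj))
                found = True
                break
        if not found and cm.tr_n[s] > 0:
            # numerical slack: fall back to the best-scoring successor
            best_to, best_v = -1, _kernels.NEG
            for ti in range(int(cm.tr_ptr[s]), int(cm.tr_ptr[s] + cm.tr_n[s])):
                to = int(cm.tr_to[ti])
                v = alpha[to, ni, nj] + cm.tr_lp[ti]
                if v > best_v:
                    best_to, best_v = to, v
            if best_to >= 0:
                stack.append((best_to, ni, nj))
    return matched


def cyk(cm: CovarianceModel, seq: str):
    """Score a sequence: returns ``(bitscore, matched_positions)``.

    The bitscore is the maximum log-odds (bits) over all subsequences
    parsed globally by the model; ``matched_positions`` counts consensus
    columns aligned to residues, for model-coverage computation.  Sequences
    longer than ``max_window_factor * clen`` are refused — use
    :func:`search_cm`, which windows internally.
    """
    if len(seq) > cm.max_window:
        raise ValueError(
            f"sequence length {len(seq)} exceeds the CYK window cap "
            f"{cm.max_window}; use windowed search (search_cm)"
        )
    bits, matched, _span = _cyk_details(cm, seq)
    return bits, matched


def _score_windowed(cm: CovarianceModel, seq: str):
    """Best CYK result over 4*clen windows with 50 % overlap.

    Returns (bits, matched, (start, end)) in ``seq`` coordinates.
    """
    w = cm.max_window
    if len(seq) <= w:
        bits, matched, span = _cyk_details(cm, seq)
        return bits, matched, span
    step = max(1, w // 2)
    best = (float("-inf"), 0, (0, 0))
    pos = 0
    while True:
        end = min(len(seq), pos + w)
        bits, matched, span = _cyk_details(cm, seq[pos:end])
        if bits > best[0]:
            best = (bits, matched, (pos + span[0], pos + span[1]))
        if end >= len(seq):
            break
        pos += step
    return best


def calibrate_cm(cm: CovarianceModel, n: int = 1000, seed: int = 0,
                 ga: float | None = None) -> CovarianceModel:
    """Calibrate E-value statistics on mononucleotide-shuffled consensus
    sequences and set the gathering threshold.

    Fits a Gumbel by maximum likelihood to ``n`` null CYK bitscores;
    ``E(S) = n_search * exp(-lambda_evd * (S - mu))``.  GA defaults to the
    maximum null score plus 2 bits; an externally supplied ``ga`` (or one
    already set on the model) is left untouched.
    """
    if n < 100:
        raise ValueError("calibration requires n >= 100 shuffles")
    rng = np.random.default_rng(seed)
    letters = np.array(list(cm.consensus))
    scores = np.empty(n)
    for i in range(n):
        s = "".join(rng.permutation(letters))
        scores[i], _, _ = _cyk_details(cm, s)
    mu, beta = fit_gumbel_censored(scores)
    cm.gumbel = (float(mu), 1.0 / float(beta))
    if ga is not None:
        cm.GA = float(ga)
    elif cm.GA is None:
        cm.GA = float(scores.max() + 2.0)
    cm._null_scores = scores
    return cm


def search_cm(cm: CovarianceModel, regions, genome_length: int | None = None,
              e_max: float = 0.01, min_coverage: float = 0.70,
              evidence: frozenset = frozenset()) -> list[CmHit]:
    """Score candidate regions with the calibrated model on both strands.

    A hit is ``accepted`` iff bitscore >= GA (inclusive at the gathering
    threshold), E-value < ``e_max`` (strict) and model coverage >= 70 %.
    The search-space size for E-values is ``2 * genome_length / clen`` when
    the genome length is known, else per-region.
    """
    if not cm.calibrated:
        raise ValueError("model must be calibrated before search")
    hits = []
    for region in regions:
        seq = region.sequence
        iv = region.interval
        best = None
        for flip in (False, True):
            s = reverse_complement(seq) if flip else seq
            bits, matched, span = _score_windowed(cm, s)
            if best is None or bits > best[0]:
                best = (bits, matched, span, flip)
        bits, matched, span, flip = best
        if not np.isfinite(bits):
            continue
        n_search = (2.0 * genome_length / cm.clen if genome_length
                    else max(1.0, 2.0 * len(seq) / cm.clen))
        ev = cm.evalue(bits, n_search)
        cov = matched / cm.clen
        a, b = span
        if b <= a:
            continue
        # region.sequence is oriented along the region strand; the scored
        # string s is that sequence (flip=False) or its reverse complement.
        orientation = "+" if (iv.strand == "+") == (not flip) else "-"
        if orientation == "+":
            fa, fb = iv.start + a, iv.start + b
        else:
            fa, fb = iv.end - b, iv.end - a
        accepted = bits >= cm.GA and ev < e_max and cov >= min_coverage
        strand = orientation
        hits.append(CmHit(
            interval=GenomicInterval(iv.contig_id, fa, fb, strand),
            bitscore=bits, evalue=ev, model_coverage=cov,
            family_id=cm.family_id, rna_class=cm.rna_class,
            status="accepted" if accepted else "raw",
            evidence=evidence,
        ))
    hits.sort(key=lambda h: (h.interval.contig_id, h.interval.start,
                             -h.bitscore))
    return hits


def resolve_overlaps(hits: list[CmHit]) -> list[CmHit]:
    """Merge overlapping same-family hits; keep the best across families.

    Same-family overlaps merge to the coordinate hull keeping the maximum
    bitscore; overlaps between different families keep the hit with the
    higher bitscore, ties broken by smaller E-value, then lexicographic
    family id.
    """
    # pass 1: same-family hull merge
    by_family: dict[tuple, list[CmHit]] = {}
    for h in hits:
        by_family.setdefault((h.family_id, h.interval.contig_id), []).append(h)
    merged: list[CmHit] = []
    for (_fam, _c), group in sorted(by_family.items()):
        group.sort(key=lambda h: h.interval.start)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.interval.start < cur.interval.end:
                best = max(cur, nxt, key=lambda h: (h.bitscore, -h.evalue))
                cur = replace(best, interval=GenomicInterval(
                    cur.interval.contig_id, cur.interval.start,
                    max(cur.interval.end, nxt.interval.end),
                    best.interval.strand),
                    evidence=cur.evidence | nxt.evidence)
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    # pass 2: cross-family best-hit selection
    merged.sort(key=lambda h: (h.interval.contig_id, h.interval.start))
    out: list[CmHit] = []
    for h in merged:
        keep = True
        drop = []
        for i, other in enumerate(out):
            if h.interval.overlap(other.interval) > 0:
                better = _better(h, other)
                if better is h:
                    drop.append(i)
                else:
                    keep = False
                    break
        if keep:
            for i in reversed(drop):
                out.pop(i)
            out.append(h)
    out.sort(key=lambda h: (h.interval.contig_id, h.interval.start,
                            h.family_id))
    return out


def _better(a: CmHit, b: CmHit) -> CmHit:
    ka = (a.bitscore, -a.evalue, b.family_id)
    kb = (b.bitscore, -b.evalue, a.family_id)
    return a if ka >= kb else b


def curate_final(hit: CmHit, genome, cm: CovarianceModel,
                 flank: int = 300, e_max: float = 0.01):
    """Final curation: re-extract with 300 nt flanks, re-score globally.

    The locus is emitted only if the re-scored E-value is < ``e_max`` and
    the bitscore is strictly greater than GA (stricter than the inclusive
    screening rule, so borderline hits at exactly GA are dropped here).
    Coordinates are tightened to the re-scored parse footprint.  Returns
    an :class:`AnnotatedLocus` or None.
    """
    contig = {c.id: c for c in genome}[hit.interval.contig_id]
    a = hit.interval.start - flank
    b = hit.interval.end + flank
    clipped = a < 0 or b > contig.length
    a = max(0, a)
    b = min(contig.length, b)
    seq = contig.sequence[a:b]
    best = None
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        bits, matched, span = _score_windowed(cm, s)
        if best is None or bits > best[0]:
            best = (bits, matched, span, strand)
    bits, matched, span, strand = best
    if not np.isfinite(bits):
        return None
    n_search = max(1.0, 2.0 * len(seq) / cm.clen)
    ev = cm.evalue(bits, n_search)
    if not (ev < e_max and bits > cm.GA):
        return None
    lo, hi = span
    if strand == "-":
        lo, hi = len(seq) - hi, len(seq) - lo
    return AnnotatedLocus(
        family_id=hit.family_id, rna_class=hit.rna_class,
        interval=GenomicInterval(contig.id, a + lo, a + hi, strand),
        bitscore=bits, evalue=ev, clipped=clipped,
        evidence=hit.evidence,
    )
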