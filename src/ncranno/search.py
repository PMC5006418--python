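"""Word-seeded local alignment under sensitivity-tuned scoring strategies.

Eight blastn-style parameter settings plus the blastn default are bundled as
presets.  Hits are found by exact word seeding, ungapped X-drop extension and
banded affine-gap extension, and assigned E-values through Karlin–Altschul
statistics ``E = K * m * n * exp(-lambda * S)``.  The gapped lambda is
approximated by the ungapped solution, so E-values serve ranking and
thresholding rather than literal probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .seqio import Contig, GenomicInterval, reverse_complement

__all__ = [
    "ScoringScheme",
    "ScoringStatistics",
    "HSP",
    "STRATEGY_IDS",
    "make_strategy",
    "solve_statistics",
    "GenomeIndex",
    "search",
    "encode",
]

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_WALL = np.int8(5)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8: A=0 C=1 G=2 T=3, anything else N=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """One search strategy: match/mismatch rewards, affine gap costs, word
    size, E-value cutoff and the informational theoretical frequency."""

    strategy_id: str
    r: int
    q: int
    G: int
    E_ext: int
    W: int
    e_cut: float
    TF: float | None = None  # informational only, never used in scoring

    def __post_init__(self):
        if self.r <= 0 or self.q >= 0:
            raise ValueError("match reward must be >0 and mismatch penalty <0")
        if self.W < 4:
            raise ValueError("word size must be >= 4")
        if self.e_cut <= 0:
            raise ValueError("E-value cutoff must be > 0")


# Preset table: (r, q, G, e_cut, E_ext, W, TF).  Cutoffs listed as NA in the
# source default to 10, the blastn default's value.
_PRESETS = {
    "1": (5, -4, 10, None, 6, 7, 0.69),
    "2": (4, -5, 3, None, 5, 7, None),
    "3": (5, -4, 25, None, 10, 7, 0.69),
    "4": (4, -5, 12, None, 8, 7, None),
    "5": (4, -5, 3, 20.0, 5, 7, None),
    "6": (5, -4, 25, 20.0, 10, 7, 0.69),
    "7": (4, -5, 3, 1000.0, 5, 7, None),
    "8": (5, -4, 25, 1000.0, 10, 7, 0.69),
    "default": (1, -3, 5, 10.0, 2, 11, 0.99),
}

STRATEGY_IDS = tuple(_PRESETS)


def make_strategy(strategy_id, **overrides) -> ScoringScheme:
    """Return a preset scoring strategy, optionally overriding fields."""
    key = str(strategy_id)
    if key not in _PRESETS:
        raise ValueError(
            f"unknown strategy {strategy_id!r}; valid ids: {list(_PRESETS)}"
        )
    r, q, G, e_cut, E_ext, W, TF = _PRESETS[key]
    scheme = ScoringScheme(
        strategy_id=key, r=r, q=q, G=G,
        E_ext=E_ext, W=W, e_cut=10.0 if e_cut is None else e_cut, TF=TF,
    )
    return replace(scheme, **overrides) if overrides else scheme


@dataclass(frozen=True)
class ScoringStatistics:
    """Karlin–Altschul parameters solved for one scoring scheme."""

    lambda_ka: float
    K: float
    background: tuple[float, float, float, float]
    target_frequency: float


def solve_statistics(scheme: ScoringScheme, background=None) -> ScoringStatistics:
    """Solve for the Karlin–Altschul lambda and K of an ungapped scheme.

    lambda is the unique positive root of
    ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` found by bisection; K uses the
    geometric-series approximation
    ``K = lambda * |E[S]| * exp(-lambda*r) / (1 - exp(-lambda*(r - q)))``.
    ``target_frequency`` is the expected identity of optimal alignments,
    ``sum_i p_i^2 exp(lambda * r)``.
    """
    p = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("background must be a probability 4-vector")
    pmatch = float((p ** 2).sum())
    r, q = scheme.r, scheme.q
    expected = pmatch * r + (1.0 - pmatch) * q
    if expected >= 0:
        raise ValueError(
            "invalid scoring system: expected score per position is "
            f"{expected:.4f} >= 0, no positive lambda exists"
        )

    def f(lam):
        return pmatch * np.exp(lam * r) + (1.0 - pmatch) * np.exp(lam * q) - 1.0

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("failed to bracket lambda")
    while True:
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) < 1e-9 or (hi - lo) < 1e-15:
            break
        if val < 0:
            lo = mid
        else:
            hi = mid
    lam = mid
    K = lam * abs(expected) * np.exp(-lam * r) / (1.0 - np.exp(-lam * (r - q)))
    tf = pmatch * float(np.exp(lam * r))
    return ScoringStatistics(lam, float(K), tuple(p), tf)


@dataclass(frozen=True)
class HSP:
    """A high-scoring segment pair between a query and the genome."""

    query_id: str
    interval: GenomicInterval
    query_span: tuple[int, int]
    score: int
    identity: float
    evalue: float
    strategy_id: str
    matches: int = 0
    aln_len: int = 0

    @property
    def query_coverage_length(self) -> int:
        return self.query_span[1] - self.query_span[0]


class GenomeIndex:
    """Concatenated, encoded genome with exact-word lookup tables.

    Contigs are joined with impassable wall characters so seeds and
    extensions never bridge contigs.  Word tables are built per word size on
    first use and cached.
    """

    _WALL_LEN = 32

    def __init__(self, contigs: list[Contig]):
        self.contigs = list(contigs)
        parts = []
        starts = []
        pos = 0
        wall = np.full(self._WALL_LEN, _WALL, dtype=np.int8)
        for c in self.contigs:
            starts.append(pos)
            parts.append(encode(c.sequence))
            pos += c.length
            parts.append(wall)
            pos += self._WALL_LEN
        self.arr = (np.concatenate(parts) if parts
                    else np.zeros(0, dtype=np.int8))
        self.starts = np.asarray(starts, dtype=np.int64)
        self.total_length = sum(c.length for c in self.contigs)
        counts = np.bincount(self.arr[self.arr < 4], minlength=4).astype(float)
        self.background = (
            tuple(counts / counts.sum()) if counts.sum() > 0
            else (0.25, 0.25, 0.25, 0.25)
        )
        self._kmer_cache: dict[int, tuple] = {}

    def contig_of(self, pos: int) -> int:
        return int(np.searchsorted(self.starts, pos, side="right") - 1)

    def kmer_table(self, W: int):
        if W not in self._kmer_cache:
            self._kmer_cache[W] = _build_kmer_table(self.arr, W)
        return self._kmer_cache[W]


def _build_kmer_table(arr: np.ndarray, W: int):
    n = arr.shape[0]
    if n < W:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty
    a = arr.astype(np.int64)
    codes = np.zeros(n - W + 1, dtype=np.int64)
    invalid = np.zeros(n - W + 1, dtype=bool)
    for k in range(W):
        win = a[k : n - W + 1 + k]
        codes = codes * 4 + win
        invalid |= win >= 4
    positions = np.nonzero(~invalid)[0].astype(np.int64)
    vcodes = codes[~invalid]
    order = np.argsort(vcodes, kind="stable")
    return vcodes[order], positions[order]


def _query_codes(qarr: np.ndarray, W: int):
    n = qarr.shape[0]
    a = qarr.astype(np.int64)
    codes = np.zeros(n - W + 1, dtype=np.int64)
    invalid = np.zeros(n - W + 1, dtype=bool)
    for k in range(W):
        win = a[k : n - W + 1 + k]
        codes = codes * 4 + win
        invalid |= win >= 4
    codes[invalid] = -1
    return codes


def search(query, genome, scheme: ScoringScheme,
           stats: ScoringStatistics | None = None, *,
           xdrop: int | None = None, band: int = 40,
           gapped_margin: int = 6, top_k: int = 50) -> list[HSP]:
    """Search one query against the genome on both strands.

    Minus-strand hits are found by searching the reverse-complemented query
    and are reported in forward-strand coordinates with strand ``-``.  Only
    HSPs with ``evalue <= scheme.e_cut`` are returned, in deterministic
    order (contig, start, strand, descending score).

    ``xdrop`` defaults to ``20 * r``; ``band`` is the full width of the
    banded gapped extension; ``gapped_margin`` (in match-score units) is the
    ungapped-score surplus required to trigger gapped extension — the top
    ``top_k`` ungapped segments per strand are always extended.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    if stats is None:
        stats = solve_statistics(scheme, index.background)
    W = scheme.W
    qseq = query.sequence
    if len(qseq) < W:
        warnings.warn(
            f"query {query.id!r} shorter than word size {W}; no search done"
        )
        return []
    if xdrop is None:
        xdrop = 20 * scheme.r
    half_band = max(1, band // 2)
    m = len(qseq)
    n_space = 2 * index.total_length
    sorted_codes, sorted_pos = index.kmer_table(W)

    raw: dict[tuple, HSP] = {}
    for strand in "+-":
        s = qseq if strand == "+" else reverse_complement(qseq)
        qarr = encode(s)
        if sorted_codes.shape[0] == 0:
            continue
        qcodes = _query_codes(qarr, W)
        valid_q = np.nonzero(qcodes >= 0)[0]
        if valid_q.shape[0] == 0:
            continue
        lo = np.searchsorted(sorted_codes, qcodes[valid_q], side="left")
        hi = np.searchsorted(sorted_codes, qcodes[valid_q], side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        qpos = np.repeat(valid_q, counts).astype(np.int64)
        gpos = np.empty(total, dtype=np.int64)
        out = 0
        for qi, l, h in zip(valid_q, lo, hi):
            c = h - l
            if c:
                gpos[out : out + c] = sorted_pos[l:h]
                out += c
        score = np.empty(total, dtype=np.int64)
        lext = np.empty(total, dtype=np.int64)
        rext = np.empty(total, dtype=np.int64)
        _kernels.ungapped_extend_batch(
            qarr, index.arr, qpos, gpos, W, scheme.r, scheme.q,
            float(xdrop), score, lext, rext,
        )
        # deduplicate ungapped segments per (diagonal, segment end)
        seg_end = gpos + W + rext
        diag = gpos - qpos
        order = np.lexsort((-score, seg_end, diag))
        seen: set[tuple[int, int]] = set()
        kept: list[int] = []
        for idx in order:
            key = (int(diag[idx]), int(seg_end[idx]))
            if key not in seen:
                seen.add(key)
                kept.append(int(idx))
        kept_arr = np.asarray(kept, dtype=np.int64)
        kept_scores = score[kept_arr]
        trigger = W * scheme.r + gapped_margin * scheme.r
        selected = kept_arr[kept_scores >= trigger]
        if selected.shape[0] < min(top_k, kept_arr.shape[0]):
            by_score = kept_arr[np.argsort(-kept_scores, kind="stable")]
            selected = np.unique(np.concatenate([selected, by_score[:top_k]]))
        for idx in selected:
            hsp = _gapped_hsp(
                qarr, index, int(qpos[idx]), int(gpos[idx]), scheme,
                half_band, float(xdrop),
            )
            if hsp is None:
                continue
            gstart, gend, qs_, qe_, sc, mt, cl = hsp
            ci = index.contig_of(gstart)
            contig = index.contigs[ci]
            cstart = int(index.starts[ci])
            a, b = gstart - cstart, gend - cstart
            if not (0 <= a < b <= contig.length):
                continue  # extension touched a wall boundary artifact
            if strand == "+":
                span = (qs_, qe_)
            else:
                span = (m - qe_, m - qs_)
            ev = stats.K * m * n_space * np.exp(-stats.lambda_ka * sc)
            if ev > scheme.e_cut:
                continue
            key = (contig.id, a, b, strand)
            cand = HSP(
                query_id=query.id,
                interval=GenomicInterval(contig.id, a, b, strand),
                query_span=span,
                score=int(sc),
                identity=mt / cl if cl else 0.0,
                evalue=float(ev),
                strategy_id=scheme.strategy_id,
                matches=mt,
                aln_len=cl,
            )
            prev = raw.get(key)
            if prev is None or cand.score > prev.score:
                raw[key] = cand
    hits = sorted(
        raw.values(),
        key=lambda h: (h.interval.contig_id, h.interval.start,
                       h.interval.strand, -h.score, h.query_span),
    )
    return hits


def _gapped_hsp(qarr, index, qpos, gpos, scheme, half_band, xdrop):
    """Banded affine extension around one seed; returns concatenated-genome
    coordinates or None if the extension degenerates."""
    W = scheme.W
    r, q, go, ge = scheme.r, scheme.q, scheme.G, scheme.E_ext
    # right extension
    qr = np.ascontiguousarray(qarr[qpos + W:])
    glim = gpos + W + qr.shape[0] + half_band + 1
    gr = np.ascontiguousarray(index.arr[gpos + W : glim])
    rb, ri, rj, rm, rc = _kernels.gotoh_extend(
        qr, gr, float(r), float(q), float(go), float(ge), half_band, xdrop
    )
    # left extension (reverse both)
    ql = np.ascontiguousarray(qarr[:qpos][::-1])
    glo = max(0, gpos - ql.shape[0] - half_band - 1)
    gl = np.ascontiguousarray(index.arr[glo:gpos][::-1])
    lb, li, lj, lm, lc = _kernels.gotoh_extend(
        ql, gl, float(r), float(q), float(go), float(ge), half_band, xdrop
    )
    score = W * r + rb + lb
    if score <= 0:
        return None
    matches = W + rm + lm
    cols = W + rc + lc
    gstart = gpos - lj
    gend = gpos + W + rj
    qstart = qpos - li
    qend = qpos + W + ri
    if gend <= gstart or qend <= qstart:
        return None
    return gstart, gend, qstart, qend, score, matches, cols
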