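"""Profile hidden Markov models built from seed alignments, and a genome
scanner that reports envelope regions below a configurable E-value.

The model is a standard match/insert/delete profile with Smith–Waterman
style local entry and exit: any match state can start an alignment (uniform
entry ``1/M``) and any match state can end one (constant per-state exit
probability, certain exit at the last node).  Scores are log-odds against a
mononucleotide null model taken from the seed's residue composition.
E-values come from a maximum-likelihood Gumbel fit to scores of shuffled
genome windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._stats import fit_gumbel_censored
from .search import encode
from .seqio import GenomicInterval, SeedAlignment, reverse_complement

__all__ = ["ProfileHMM", "HmmHit", "build_phmm", "score_sequence", "search_phmm"]

LN2 = math.log(2.0)
_GAPS = {"-", "."}


@dataclass
class ProfileHMM:
    family_id: str
    M: int
    match_emissions: np.ndarray      # (M, 4) probabilities
    insert_emission: np.ndarray      # (4,) background
    null: np.ndarray                 # (4,) background
    # transition probability arrays indexed by source node (size M+1)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    exit_prob: float = 0.05
    rna_class: str = "misc_RNA"
    match_columns: list[int] = field(default_factory=list)

    def _log_arrays(self):
        lo = np.zeros((self.M, 5))
        with np.errstate(divide="ignore"):
            lo[:, :4] = np.log(self.match_emissions) - np.log(self.null)
        lo[:, 4] = lo[:, :4].min(axis=1)  # N scores as worst case
        def lg(a):
            with np.errstate(divide="ignore"):
                return np.where(a > 0, np.log(np.maximum(a, 1e-300)), _kernels.NEG)
        log_exit = np.full(self.M, math.log(self.exit_prob))
        log_exit[-1] = 0.0
        return (lo, lg(self.t_mm), lg(self.t_mi), lg(self.t_md),
                lg(self.t_im), lg(self.t_ii), lg(self.t_dm), lg(self.t_dd),
                math.log(1.0 / self.M), log_exit)


@dataclass(frozen=True)
class HmmHit:
    """An envelope region reported by the HMM genome scan."""

    interval: GenomicInterval
    bitscore: float
    evalue: float
    family_id: str


def build_phmm(seed: SeedAlignment, exit_prob: float = 0.05) -> ProfileHMM:
    """Build a profile HMM from a seed alignment.

    Match columns are those with fewer than 50 % gap characters; emission
    and transition counts receive Laplace (+1) pseudocounts.  The null model
    is the seed's residue composition.
    """
    if not seed.rows:
        raise ValueError("seed alignment has no rows")
    rows = list(seed.rows.values())
    ncol = len(rows[0])
    nrow = len(rows)
    match_cols = [
        c for c in range(ncol)
        if sum(r[c] in _GAPS for r in rows) / nrow < 0.5
    ]
    M = len(match_cols)
    if M == 0:
        raise ValueError("alignment has zero match columns; cannot build model")
    col_rank = {c: k for k, c in enumerate(match_cols)}
    idx = {b: i for i, b in enumerate("ACGT")}

    emis = np.ones((M, 4))  # +1 pseudocount
    null = np.ones(4)
    for r in rows:
        for c, ch in enumerate(r):
            if ch in idx:
                null[idx[ch]] += 1
                if c in col_rank:
                    emis[col_rank[c], idx[ch]] += 1
    emis /= emis.sum(axis=1, keepdims=True)
    null /= null.sum()

    # transition counts from per-row state paths over nodes 1..M
    c_mm = np.ones(M + 1); c_mi = np.ones(M + 1); c_md = np.ones(M + 1)
    c_im = np.ones(M + 1); c_ii = np.ones(M + 1)
    c_dm = np.ones(M + 1); c_dd = np.ones(M + 1)
    for r in rows:
        prev = None  # ('M'|'D', node)
        pending_ins = 0
        for c, ch in enumerate(r):
            if c in col_rank:
                k = col_rank[c] + 1
                cur = ("M", k) if ch in idx else ("D", k)
                if prev is not None:
                    pk = prev[1]
                    if pending_ins and prev[0] == "M":
                        c_mi[pk] += 1
                        c_ii[pk] += pending_ins - 1
                        c_im[pk] += 1
                    elif prev[0] == "M":
                        (c_mm if cur[0] == "M" else c_md)[pk] += 1
                    else:
                        (c_dm if cur[0] == "M" else c_dd)[pk] += 1
                    if pending_ins and prev[0] == "D":
                        # inserts after a delete are attached to the node's
                        # insert state via the match route approximation
                        pass
                prev = cur
                pending_ins = 0
            elif ch in idx:
                pending_ins += 1
    def norm(*arrs):
        tot = sum(arrs)
        return [a / tot for a in arrs]
    t_mm, t_mi, t_md = norm(c_mm, c_mi, c_md)
    t_im, t_ii = norm(c_im, c_ii)
    t_dm, t_dd = norm(c_dm, c_dd)
    # carve out the local exit mass from match-state sources
    scale = 1.0 - exit_prob
    return ProfileHMM(
        family_id=seed.family_id, M=M,
        match_emissions=emis, insert_emission=null.copy(), null=null,
        t_mm=t_mm * scale, t_mi=t_mi * scale, t_md=t_md * scale,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        exit_prob=exit_prob, rna_class=seed.rna_class,
        match_columns=match_cols,
    )


def consensus_sequence(seed: SeedAlignment) -> str:
    """Majority residue per match column (<50 % gaps), ties by ACGT order."""
    model = build_phmm(seed)
    return "".join("ACGT"[int(np.argmax(row))] for row in model.match_emissions)


def score_sequence(phmm: ProfileHMM, seq: str):
    """Return ``(viterbi_bits, forward_bits, envelope)`` for one sequence.

    The envelope is the maximal contiguous region whose posterior
    probability of being generated by the model is at least 0.5.
    """
    if not seq:
        raise ValueError("empty sequence")
    x = encode(seq)
    args = phmm._log_arrays()
    vit = _kernels.phmm_viterbi(x, *args) / LN2
    post, fwd_nats = _kernels.phmm_posterior(x, *args)
    fwd = fwd_nats / LN2
    envelope = _max_run(post >= 0.5)
    if envelope is None:
        top = int(np.argmax(post))
        envelope = (top, top + 1)
    return vit, fwd, envelope


def _max_run(mask: np.ndarray):
    best = None
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None:
        n = len(mask)
        if best is None or n - start > best[1] - best[0]:
            best = (start, n)
    return best


def search_phmm(phmm: ProfileHMM, genome, e_max: float = 0.01,
                null_samples: int = 1000, seed: int = 0,
                prefilter_factor: float = 100.0) -> list[HmmHit]:
    """Scan the genome with windows of length 2M, stride M, both strands.

    Calibration: ``null_samples`` genome windows are mononucleotide-shuffled
    and scored; Gumbel location/scale are fit by maximum likelihood
    separately for the fast Viterbi pass and the forward pass.  Windows are
    prefiltered on Viterbi E-value (with a generous ``prefilter_factor``
    margin), survivors rescored with forward, overlapping passing windows
    merged, and the posterior envelope of each merged region reported.
    Only hits with forward E-value <= ``e_max`` are emitted.
    """
    if null_samples < 100:
        raise ValueError("null_samples must be >= 100 for calibration")
    rng = np.random.default_rng(seed)
    args = phmm._log_arrays()
    M = phmm.M
    wlen = 2 * M
    windows = []  # (contig_idx, start, end)
    for ci, contig in enumerate(genome):
        L = contig.length
        if L < 10:
            continue
        pos = 0
        while True:
            end = min(L, pos + wlen)
            windows.append((ci, pos, end))
            if end >= L:
                break
            pos += M
    if not windows:
        return []
    n_windows = 2 * len(windows)  # both strands

    # --- calibration on shuffled windows
    null_v = np.empty(null_samples)
    null_f = np.empty(null_samples)
    pick = rng.integers(0, len(windows), size=null_samples)
    for i, wi in enumerate(pick):
        ci, a, b = windows[wi]
        x = encode(genome[ci].sequence[a:b])
        x = rng.permutation(x)
        null_v[i] = _kernels.phmm_viterbi(x, *args)
        null_f[i] = _kernels.phmm_forward(x, *args)
    vloc, vscale = _fit_gumbel(null_v)
    floc, fscale = _fit_gumbel(null_f)

    def e_of(score, loc, scale):
        z = (score - loc) / scale
        # expected count over the scanned windows
        return n_windows * float(-np.expm1(-np.exp(-z)))

    # --- scan
    passing = []  # (ci, start, end, strand, fwd_nats)
    vit_cut = vloc + vscale * math.log(
        n_windows / (prefilter_factor * e_max)
    ) if e_max > 0 else np.inf
    for ci, a, b in windows:
        raw = genome[ci].sequence[a:b]
        for strand in "+-":
            s = raw if strand == "+" else reverse_complement(raw)
            x = encode(s)
            v = _kernels.phmm_viterbi(x, *args)
            if v < vit_cut:
                continue
            f = _kernels.phmm_forward(x, *args)
            if e_of(f, floc, fscale) <= e_max:
                passing.append((ci, a, b, strand, f))
    # --- merge overlapping windows per contig/strand, envelope per region
    hits: list[HmmHit] = []
    passing.sort(key=lambda t: (t[0], t[3], t[1]))
    i = 0
    while i < len(passing):
        ci, a, b, strand, f = passing[i]
        j = i + 1
        while (j < len(passing) and passing[j][0] == ci
               and passing[j][3] == strand and passing[j][1] <= b):
            b = max(b, passing[j][2])
            j += 1
        region = genome[ci].sequence[a:b]
        s = region if strand == "+" else reverse_complement(region)
        x = encode(s)
        post, fwd_nats = _kernels.phmm_posterior(x, *args)
        env = _max_run(post >= 0.5)
        if env is not None:
            lo, hi = env
            if strand == "-":
                lo, hi = len(s) - hi, len(s) - lo
            ev = e_of(fwd_nats, floc, fscale)
            if ev <= e_max:
                hits.append(HmmHit(
                    interval=GenomicInterval(genome[ci].id, a + lo, a + hi,
                                             strand),
                    bitscore=fwd_nats / LN2,
                    evalue=ev,
                    family_id=phmm.family_id,
                ))
        i = j
    hits.sort(key=lambda h: (h.interval.contig_id, h.interval.start,
                             h.interval.strand))
    return hits


def _fit_gumbel(scores: np.ndarray):
    return fit_gumbel_censored(scores)
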