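"""Shuffle-null false-positive estimation and sensitivity/specificity per
search strategy and RNA class (the confusion-matrix evaluation).

For each family, shuffled copies of the query are processed exactly like the
real query — search, filter, merge, candidate extension and optionally
model validation — and every shuffled sequence that still yields a passing
candidate counts as one false positive.  Sensitivity = TP/(TP+FN) and
specificity = TN/(FP+TN); undefined ratios propagate as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .filters import FilterParams, build_candidates, filter_hsps, merge_hsps
from .search import GenomeIndex, make_strategy, search
from .seqio import QueryRecord

__all__ = [
    "ConfusionMatrix",
    "shuffle_sequence",
    "evaluate_strategy",
    "sens_spec",
]


@dataclass
class ConfusionMatrix:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    strategy_id: str = ""
    rna_class: str = ""

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")


def sens_spec(cm: ConfusionMatrix):
    """Sensitivity TP/(TP+FN) and specificity TN/(FP+TN); NaN when the
    denominator is zero."""
    sens = cm.TP / (cm.TP + cm.FN) if (cm.TP + cm.FN) > 0 else math.nan
    spec = cm.TN / (cm.FP + cm.TN) if (cm.FP + cm.TN) > 0 else math.nan
    return sens, spec


def shuffle_sequence(seq: str, n: int = 1000, seed: int = 0,
                     order: str = "mono") -> list[str]:
    """Generate ``n`` shuffles of ``seq``.

    ``mono``: Fisher–Yates permutation preserving mononucleotide
    composition.  ``di``: Altschul–Erickson shuffle preserving the exact
    dinucleotide count vector (random Eulerian walk on the transition
    multigraph).  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if order == "mono":
        letters = np.array(list(seq))
        return ["".join(rng.permutation(letters)) for _ in range(n)]
    if order == "di":
        return [_doublet_shuffle(seq, rng) for _ in range(n)]
    raise ValueError("order must be 'mono' or 'di'")


def _doublet_shuffle(seq: str, rng) -> str:
    """Altschul–Erickson dinucleotide-preserving shuffle."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges.keys() | {last})
    for _ in range(1000):
        # pick a random last edge out of every vertex except `last`; the
        # shuffle is valid iff those chosen edges form a tree rooted at last
        chosen = {}
        for v in vertices:
            if v == last or not edges.get(v):
                continue
            chosen[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in chosen:
            seen = {v}
            cur = v
            while cur != last:
                nxt = chosen.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if not ok:
            continue
        out_lists = {}
        for v, targets in edges.items():
            rest = list(targets)
            if v in chosen:
                rest.remove(chosen[v])
            rng.shuffle(rest)
            if v in chosen:
                rest.append(chosen[v])
            out_lists[v] = rest
        walk = [first]
        cur = first
        while out_lists.get(cur):
            nxt = out_lists[cur].pop(0)
            walk.append(nxt)
            cur = nxt
        if len(walk) == len(seq):
            return "".join(walk)
    return seq  # pathological composition; identity is still a valid shuffle


def _passing_candidates(query: QueryRecord, index: GenomeIndex, scheme,
                        params: FilterParams, genome, validate=None):
    hsps = search(query, index, scheme)
    kept = filter_hsps(hsps, len(query.sequence), params)
    merged = merge_hsps(kept, len(query.sequence), params)
    merged = filter_hsps(merged, len(query.sequence), params)
    cands = build_candidates(merged, genome, len(query.sequence),
                             query.family_id, query.rna_class, params)
    if validate is not None and cands:
        cands = [c for c in cands if validate(c)]
    return cands


def evaluate_strategy(strategy_id, families, genome, *,
                      nulls_per_family: int = 1000, seed: int = 0,
                      params: FilterParams = FilterParams(),
                      validate=None, order: str = "mono"):
    """Confusion matrices per RNA class for one search strategy.

    ``families`` is a list of ``(QueryRecord, truth_loci)`` where the truth
    loci are :class:`~ncranno.seqio.GenomicInterval`-bearing records of the
    planted (or collated) annotation.  TP counts truth loci recovered by a
    passing candidate at >= 50 % reciprocal overlap; FP counts shuffled
    query sequences that still yield a passing candidate.  ``validate``
    optionally applies downstream (covariance-model) validation to
    candidates, mirroring a full-pipeline treatment of the nulls.
    """
    scheme = make_strategy(strategy_id)
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    contigs = index.contigs
    out: dict[str, ConfusionMatrix] = {}
    rng = np.random.default_rng(seed)
    for query, truth in families:
        cmx = out.setdefault(
            query.rna_class,
            ConfusionMatrix(strategy_id=str(strategy_id),
                            rna_class=query.rna_class),
        )
        cands = _passing_candidates(query, index, scheme, params, contigs,
                                    validate)
        recovered = 0
        for t in truth:
            iv = t.interval if hasattr(t, "interval") else t
            hit = any(
                c.interval.overlap(iv) >= 0.5 * max(iv.length, 1)
                and c.interval.overlap(iv) >= 0.5 * c.interval.length
                for c in cands
            )
            recovered += bool(hit)
        cmx.TP += recovered
        cmx.FN += len(truth) - recovered
        sub = int(rng.integers(0, 2**31 - 1))
        for shuffled in shuffle_sequence(query.sequence, nulls_per_family,
                                         seed=sub, order=order):
            null_q = QueryRecord(query.family_id, query.rna_class,
                                 query.species_tag, shuffled)
            if _passing_candidates(null_q, index, scheme, params, contigs,
                                   validate):
                cmx.FP += 1
            else:
                cmx.TN += 1
    return out
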