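"""Rule-based HSP filtering, same-strand merging and candidate extension.

The four rules that turn raw local-alignment hits into candidate regions:

1. a hit covers at least 40 % of the query length (inclusive),
2. the HSP alignment is longer than 20 columns (strict),
3. query and hit are at least 75 % identical (inclusive),
4. same-query HSPs close together on the same strand are merged, provided
   the merged span does not exceed 125 % of the query length.

Surviving hits are extended to the length expected from the query plus 10 nt
of flanking sequence on either side, and near-identical regions supported by
different queries of one family are collapsed with their provenance kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .search import HSP
from .seqio import GenomicInterval, reverse_complement

__all__ = [
    "FilterParams",
    "CandidateRegion",
    "filter_hsps",
    "merge_hsps",
    "build_candidates",
]


@dataclass(frozen=True)
class FilterParams:
    min_query_cov: float = 0.40
    min_hsp_len: int = 21       # strict: alignments of exactly 20 fail
    min_identity: float = 0.75
    merge_cap: float = 1.25
    max_gap: int = 30
    flank: int = 10
    collapse_overlap: float = 0.90


@dataclass
class CandidateRegion:
    """A genomic interval proposed as an ncRNA locus, with provenance."""

    family_id: str
    rna_class: str
    interval: GenomicInterval
    sequence: str
    source_hsps: list[HSP] = field(default_factory=list)
    supporting_strategies: set[str] = field(default_factory=set)
    supporting_species: set[str] = field(default_factory=set)


def filter_hsps(hsps: list[HSP], query_length: int,
                params: FilterParams = FilterParams()) -> list[HSP]:
    """Keep HSPs meeting the coverage, length and identity rules.

    Coverage and identity thresholds are inclusive; the length threshold is
    strict (an alignment of exactly 20 columns is rejected).  Input order is
    preserved.
    """
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    out = []
    for h in hsps:
        cov = (h.query_span[1] - h.query_span[0]) / query_length
        if cov < params.min_query_cov:
            continue
        if h.aln_len < params.min_hsp_len:
            continue
        if h.identity < params.min_identity:
            continue
        out.append(h)
    return out


def merge_hsps(hsps: list[HSP], query_length: int,
               params: FilterParams = FilterParams()) -> list[HSP]:
    """Greedy left-to-right merge of nearby same-strand HSPs of one query.

    HSPs on the same contig and strand whose genomic gap is at most
    ``max_gap`` are merged into their coordinate hull, but only while the
    hull stays within ``merge_cap`` (125 %) of the query length.  Merged
    score is the sum of member scores; merged identity is the match-weighted
    mean.  Opposite strands are never merged.
    """
    cap = params.merge_cap * query_length
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.interval.contig_id, h.interval.strand), []).append(h)
    merged: list[HSP] = []
    for (_contig, _strand), members in sorted(groups.items()):
        members = sorted(members, key=lambda h: (h.interval.start, h.interval.end))
        current = members[0]
        for nxt in members[1:]:
            gap = nxt.interval.start - current.interval.end
            hull_end = max(current.interval.end, nxt.interval.end)
            hull_len = hull_end - current.interval.start
            if gap <= params.max_gap and hull_len <= cap:
                current = _merge_pair(current, nxt, hull_end)
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda h: (h.interval.contig_id, h.interval.start,
                               h.interval.strand))
    return merged


def _merge_pair(a: HSP, b: HSP, hull_end: int) -> HSP:
    matches = a.matches + b.matches
    aln_len = a.aln_len + b.aln_len
    qspan = (min(a.query_span[0], b.query_span[0]),
             max(a.query_span[1], b.query_span[1]))
    return replace(
        a,
        interval=GenomicInterval(a.interval.contig_id, a.interval.start,
                                 hull_end, a.interval.strand),
        query_span=qspan,
        score=a.score + b.score,
        identity=matches / aln_len if aln_len else 0.0,
        matches=matches,
        aln_len=aln_len,
        evalue=min(a.evalue, b.evalue),
    )


def build_candidates(hsps: list[HSP], genome, query_length: int,
                     family_id: str, rna_class: str,
                     params: FilterParams = FilterParams()) -> list[CandidateRegion]:
    """Extend filtered/merged hits to expected query length plus flanks.

    Each hit is extended symmetrically (centered on the hit) to
    ``query_length``, then ``flank`` nt are added on either side, clipping
    at contig bounds.  Regions from different queries of the same family
    with >= 90 % reciprocal overlap on the same contig and strand are
    collapsed into one region whose supporting species/strategy sets
    accumulate.
    """
    contig_by_id = {c.id: c for c in genome}
    regions: list[CandidateRegion] = []
    for h in hsps:
        contig = contig_by_id[h.interval.contig_id]
        start, end = h.interval.start, h.interval.end
        deficit = query_length - (end - start)
        if deficit > 0:
            left = deficit // 2
            right = deficit - left
            start -= left
            end += right
            if start < 0:  # clipped at contig start: push right
                end = min(contig.length, end - start)
                start = 0
            if end > contig.length:
                start = max(0, start - (end - contig.length))
                end = contig.length
        start = max(0, start - params.flank)
        end = min(contig.length, end + params.flank)
        iv = GenomicInterval(h.interval.contig_id, start, end, h.interval.strand)
        seq = contig.sequence[start:end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        species = h.query_id.split("|")[-1] if "|" in h.query_id else h.query_id
        region = CandidateRegion(
            family_id=family_id,
            rna_class=rna_class,
            interval=iv,
            sequence=seq,
            source_hsps=[h],
            supporting_strategies={h.strategy_id},
            supporting_species={species},
        )
        target = _find_collapsible(regions, region, params.collapse_overlap)
        if target is None:
            regions.append(region)
        else:
            target.source_hsps.append(h)
            target.supporting_strategies |= region.supporting_strategies
            target.supporting_species |= region.supporting_species
    regions.sort(key=lambda c: (c.interval.contig_id, c.interval.start,
                                c.interval.strand))
    return regions


def _find_collapsible(regions, region, min_reciprocal):
    for existing in regions:
        a, b = existing.interval, region.interval
        if a.contig_id != b.contig_id or a.strand != b.strand:
            continue
        ov = a.overlap(b)
        if ov >= min_reciprocal * a.length and ov >= min_reciprocal * b.length:
            return existing
    return None
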