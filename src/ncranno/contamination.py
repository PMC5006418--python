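"""Two-rule screening of assembly contigs against contaminant references.

Rule A (hsp_rule): a contig carrying any local alignment to a contaminant
reference with E < 1e-10, identity > 75 % and alignment length > 20 nt is
flagged.  Rule B (genome_rule): a contig whose merged alignment footprint
covers >= 70 % of the contig at >= 80 % (match-weighted) identity is
flagged.  "Similarity" and "identity" are both implemented as alignment
identity; the footprint counts overlapping alignments once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .search import GenomeIndex, ScoringScheme, make_strategy, search

__all__ = ["ContaminationCall", "screen"]


@dataclass(frozen=True)
class ContaminationCall:
    contig_id: str
    rule: str                # "hsp_rule" or "genome_rule"
    best_evalue: float
    identity: float
    coverage: float          # fraction of the contig covered by alignments
    source_id: str


def screen(contigs, contaminant_db, scheme: ScoringScheme | None = None, *,
           hsp_e_max: float = 1e-10, hsp_min_identity: float = 0.75,
           hsp_min_len: int = 21, genome_min_cov: float = 0.70,
           genome_min_identity: float = 0.80):
    """Flag likely contaminant contigs; returns ``(calls, clean_genome)``.

    ``clean_genome`` is the input minus every flagged contig; flagged and
    clean sets partition the input.  One call per contig is reported,
    preferring the HSP rule when both fire.
    """
    if not contaminant_db:
        raise ValueError("contaminant database is empty")
    if scheme is None:
        scheme = make_strategy("default", e_cut=1.0)
    index = GenomeIndex(contigs)
    lengths = {c.id: c.length for c in contigs}
    per_contig: dict[str, list] = {}
    for ref in contaminant_db:
        for h in search(ref, index, scheme):
            per_contig.setdefault(h.interval.contig_id, []).append((ref.id, h))

    calls = []
    for contig_id, pairs in sorted(per_contig.items()):
        hsp_call = None
        for source, h in pairs:
            if (h.evalue < hsp_e_max and h.identity > hsp_min_identity
                    and h.aln_len >= hsp_min_len):
                if hsp_call is None or h.evalue < hsp_call.best_evalue:
                    hsp_call = ContaminationCall(
                        contig_id, "hsp_rule", h.evalue, h.identity,
                        h.interval.length / lengths[contig_id], source,
                    )
        if hsp_call is not None:
            calls.append(hsp_call)
            continue
        # rule B: merged footprint at sufficient identity
        ivs = sorted((h.interval.start, h.interval.end) for _, h in pairs)
        covered = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
        total_matches = sum(h.matches for _, h in pairs)
        total_cols = sum(h.aln_len for _, h in pairs)
        wid = total_matches / total_cols if total_cols else 0.0
        cov = covered / lengths[contig_id]
        if cov >= genome_min_cov and wid >= genome_min_identity:
            best = min(pairs, key=lambda p: p[1].evalue)
            calls.append(ContaminationCall(
                contig_id, "genome_rule", best[1].evalue, wid, cov, best[0],
            ))
    flagged = {c.contig_id for c in calls}
    clean = [c for c in contigs if c.id not in flagged]
    return calls, clean
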