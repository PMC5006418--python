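"""Synthetic fragmented genomes with planted ncRNA homologs.

The generator emulates the statistical structure of a highly fragmented,
AT-rich draft assembly: i.i.d. background at GC 0.36, log-normal contig
lengths truncated to [200 nt, 25 kb] so that most contigs are sub-kilobase,
planted family copies at controlled percent identity with known edit
traces, pseudogenized (truncated, extra-mutated) copies, and contaminant
contigs copied from a bacterial-like reference set at 95-100 % identity.
Every planted feature is reported in a machine-readable truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Contig, GenomicInterval, QueryRecord, SeedAlignment, \
    reverse_complement

__all__ = [
    "FamilySpec",
    "SyntheticSpec",
    "TruthRecord",
    "generate_background",
    "mutate_to_identity",
    "make_seed_family",
    "make_queries",
    "seed_consensus",
    "build_genome",
    "write_truth",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_GAPS = {"-", "."}


@dataclass
class FamilySpec:
    seed: SeedAlignment
    copies: int = 10
    target_identity: float = 0.85
    indel_rate: float = 0.02
    pseudogene_fraction: float = 0.2


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic genome.

    Defaults follow the assembly the pipeline was designed around: GC 0.36,
    contigs mostly shorter than 1 kb (log-normal, median 450 nt, sigma
    0.75, truncated to [200, 25000]).
    """

    genome_length: int = 2_000_000
    contig_median: int = 450
    contig_sigma: float = 0.75
    contig_min: int = 200
    contig_max: int = 25_000
    gc: float = 0.36
    families: list[FamilySpec] = field(default_factory=list)
    contaminant_contigs: int = 5
    contaminant_gc: float = 0.50
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    family_id: str
    rna_class: str
    interval: GenomicInterval
    realized_identity: float
    is_pseudogene: bool = False


def generate_background(length: int, gc: float = 0.36, seed=0) -> str:
    """I.i.d. background: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def mutate_to_identity(seq: str, target_identity: float,
                       indel_rate: float = 0.0, seed=0):
    """Mutate ``seq`` to a chosen pairwise identity, known from the edit
    trace.

    Identity is matches / alignment columns of the true alignment implied
    by the edits (each insertion adds a column, each deletion turns one
    into a gap).  The number of substitutions is solved from the sampled
    indel counts so the realized identity lands on the target exactly up to
    integer rounding.  Returns ``(mutant, realized_identity)``.
    """
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must be in [0, 1]")
    if target_identity >= 1.0 and indel_rate == 0.0:
        return seq, 1.0
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    L = len(seq)
    n_ins = int(rng.binomial(L, indel_rate / 2))
    n_del = int(rng.binomial(L, indel_rate / 2))
    cols = L + n_ins
    n_sub = int(round(L - n_del - target_identity * cols))
    n_sub = max(0, min(n_sub, L - n_del))
    realized = (L - n_del - n_sub) / cols
    positions = rng.permutation(L)
    del_pos = set(positions[:n_del].tolist())
    sub_pos = set(positions[n_del : n_del + n_sub].tolist())
    ins_pos = set(rng.integers(0, L + 1, size=n_ins).tolist()) if n_ins else set()
    out = []
    for i, ch in enumerate(seq):
        if i in ins_pos:
            out.append(str(rng.choice(_BASES)))
        if i in del_pos:
            continue
        if i in sub_pos:
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        else:
            out.append(ch)
    if L in ins_pos:
        out.append(str(rng.choice(_BASES)))
    return "".join(out), realized


def make_seed_family(family_id: str, rna_class: str, length: int = 80,
                     n_rows: int = 10, stem: int = 10, seed=0,
                     row_divergence: float = 0.08) -> SeedAlignment:
    """Generate a hairpin-structured family seed alignment.

    The consensus carries a ``stem``-pair helix with a loop, flanked by
    unpaired columns; rows diverge from the consensus at
    ``row_divergence`` per column, with compensatory (pair-preserving)
    changes in the stem so the alignment has genuine covariation signal.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    loop = max(4, length - 2 * stem - 2 * ((length - 2 * stem) // 3))
    flank = (length - 2 * stem - loop) // 2
    loop = length - 2 * stem - 2 * flank
    left = "".join(rng.choice(_BASES, size=stem))
    right = "".join(_COMP[b] for b in reversed(left))
    cons = (
        "".join(rng.choice(_BASES, size=flank)) + left
        + "".join(rng.choice(_BASES, size=loop)) + right
        + "".join(rng.choice(_BASES, size=flank))
    )
    ss = "." * flank + "(" * stem + "." * loop + ")" * stem + "." * flank
    rows = {}
    pair = {flank + k: flank + stem + loop + (stem - 1 - k) for k in range(stem)}
    for ri in range(n_rows):
        row = list(cons)
        for c in range(length):
            if rng.random() < row_divergence:
                if c in pair:
                    nb = str(rng.choice(_BASES))
                    row[c] = nb
                    row[pair[c]] = _COMP[nb]
                elif c in pair.values():
                    continue  # handled with its partner
                else:
                    row[c] = str(rng.choice([b for b in "ACGT" if b != row[c]]))
        rows[f"sp{ri}"] = "".join(row)
    aln = SeedAlignment(family_id, rows, ss, rna_class)
    aln.validate()
    return aln


def seed_consensus(seed_aln: SeedAlignment) -> str:
    """Majority residue per match column (<50 % gaps), ties by ACGT order."""
    rows = list(seed_aln.rows.values())
    nrow = len(rows)
    out = []
    for c in range(len(seed_aln.ss_cons)):
        col = [r[c] for r in rows]
        if sum(ch in _GAPS for ch in col) / nrow >= 0.5:
            continue
        counts = {b: col.count(b) for b in "ACGT"}
        out.append(max("ACGT", key=lambda b: counts[b]))
    return "".join(out)


def make_queries(seed_aln: SeedAlignment, species=("CIN", "DRE", "XTR"),
                 identity: float = 0.90, seed=0) -> list[QueryRecord]:
    """Species-tagged query variants of the family consensus."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    cons = seed_consensus(seed_aln)
    out = []
    for tag in species:
        mut, _ = mutate_to_identity(cons, identity, 0.0, rng)
        out.append(QueryRecord(seed_aln.family_id, seed_aln.rna_class, tag, mut))
    return out


def _contig_lengths(spec: SyntheticSpec, rng) -> list[int]:
    lengths = []
    total = 0
    mu = np.log(spec.contig_median)
    while total < spec.genome_length:
        l = int(np.exp(rng.normal(mu, spec.contig_sigma)))
        l = max(spec.contig_min, min(spec.contig_max, l))
        l = min(l, spec.genome_length - total) if \
            spec.genome_length - total > spec.contig_min else l
        lengths.append(max(spec.contig_min, l))
        total += lengths[-1]
    return lengths


def build_genome(spec: SyntheticSpec):
    """Generate contigs, planted-feature truth and contaminant report.

    Returns ``(contigs, truth, contaminants)`` where ``contaminants`` is a
    dict with the reference database (``db``) and the ids of planted
    contaminant contigs (``planted_ids``).  Planted intervals never overlap
    each other or contig boundaries; pseudogene copies are truncated to
    40-70 % length with extra substitutions and flagged.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _contig_lengths(spec, rng)
    contigs = [Contig(f"ctg{i:06d}", generate_background(l, spec.gc, rng))
               for i, l in enumerate(lengths)]
    seqs = {c.id: list(c.sequence) for c in contigs}
    occupied: dict[str, list[tuple[int, int]]] = {c.id: [] for c in contigs}

    truth: list[TruthRecord] = []
    for fam in spec.families:
        cons = seed_consensus(fam.seed)
        n_pseudo = int(round(fam.copies * fam.pseudogene_fraction))
        for ci in range(fam.copies):
            pseudo = ci < n_pseudo
            mut, realized = mutate_to_identity(
                cons, fam.target_identity, fam.indel_rate, rng)
            if pseudo:
                frac = rng.uniform(0.4, 0.7)
                keep = max(10, int(len(mut) * frac))
                start = int(rng.integers(0, len(mut) - keep + 1))
                mut = mut[start : start + keep]
                mut, extra = mutate_to_identity(
                    mut, max(0.0, fam.target_identity - 0.15), 0.0, rng)
                realized = realized * extra
            strand = "+" if rng.random() < 0.5 else "-"
            insert = mut if strand == "+" else reverse_complement(mut)
            placed = _place(rng, contigs, occupied, len(insert))
            if placed is None:
                raise ValueError(
                    "genome too small to host the requested copies without "
                    "overlap"
                )
            cid, pos = placed
            seqs[cid][pos : pos + len(insert)] = list(insert)
            truth.append(TruthRecord(
                fam.seed.family_id, fam.seed.rna_class,
                GenomicInterval(cid, pos, pos + len(insert), strand),
                realized, pseudo,
            ))

    # contaminant references and planted contaminant contigs
    db = []
    planted_ids = []
    if spec.contaminant_contigs > 0:
        n_refs = max(1, spec.contaminant_contigs // 2)
        db = [Contig(f"bact{i:03d}",
                     generate_background(2000, spec.contaminant_gc, rng))
              for i in range(n_refs)]
        for j in range(spec.contaminant_contigs):
            ref = db[int(rng.integers(len(db)))]
            l = int(min(ref.length,
                        max(spec.contig_min,
                            np.exp(rng.normal(np.log(spec.contig_median),
                                              spec.contig_sigma)))))
            start = int(rng.integers(0, ref.length - l + 1))
            ident = rng.uniform(0.95, 1.0)
            piece, _ = mutate_to_identity(ref.sequence[start : start + l],
                                          ident, 0.0, rng)
            cid = f"ctg{len(contigs) + j:06d}"
            contigs.append(Contig(cid, piece))
            seqs[cid] = list(piece)
            planted_ids.append(cid)

    out_contigs = [Contig(c.id, "".join(seqs[c.id])) for c in contigs]
    truth.sort(key=lambda t: (t.interval.contig_id, t.interval.start))
    return out_contigs, truth, {"db": db, "planted_ids": planted_ids}


def _place(rng, contigs, occupied, need, margin: int = 25, tries: int = 200):
    eligible = [c for c in contigs if c.length >= need + 2 * margin]
    if not eligible:
        return None
    for _ in range(tries):
        c = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(margin, c.length - need - margin + 1))
        if all(pos + need <= s or pos >= e for s, e in occupied[c.id]):
            occupied[c.id].append((pos, pos + need))
            return c.id, pos
    return None


def write_truth(truth: list[TruthRecord], path_tsv, path_gff=None) -> None:
    """Truth table as TSV (and optionally GFF3, 1-based inclusive)."""
    with open(path_tsv, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tfamily_id\trna_class\t"
                 "realized_identity\tis_pseudogene\n")
        for t in truth:
            iv = t.interval
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                     f"{t.family_id}\t{t.rna_class}\t"
                     f"{t.realized_identity:.4f}\t{int(t.is_pseudogene)}\n")
    if path_gff:
        with open(path_gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, t in enumerate(truth, 1):
                iv = t.interval
                fh.write(f"{iv.contig_id}\ttruth\t{t.rna_class}\t"
                         f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                         f"ID=truth{i};family_id={t.family_id};"
                         f"pseudogene={int(t.is_pseudogene)}\n")
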