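"""End-to-end orchestration of the annotation stages, in the order:

contamination screen -> multi-strategy local search -> filter/merge/extend
-> profile-HMM search (independent candidate source) -> covariance-model
validation of the union of candidate sources -> overlap resolution -> final
300 nt curation -> GFF3/TSV emission.

blast-derived and HMM-derived candidates are kept as separate evidence
tracks until CM validation and then unioned, so the final annotation
records which search route(s) support each locus.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cm as cmmod
from . import contamination as contmod
from . import phmm as phmmmod
from .filters import FilterParams, build_candidates, filter_hsps, merge_hsps
from .search import GenomeIndex, make_strategy, search
from .seqio import (Contig, GenomicInterval, QueryRecord, read_fasta,
                    read_stockholm, reverse_complement, write_annotations)

__all__ = ["RunConfig", "PipelineResult", "annotate", "run_annotation",
           "load_config", "build_family_models"]

DEFAULT_STRATEGIES = ("1", "2", "3", "4", "5", "6", "7", "8", "default")


@dataclass
class RunConfig:
    genome: str = ""
    queries: str = ""
    seeds: list[str] = field(default_factory=list)
    contaminants: str | None = None
    tree: str | None = None
    matrix: str | None = None
    outdir: str = "ncranno_out"
    strategies: list[str] = field(default_factory=lambda: list(DEFAULT_STRATEGIES))
    seed: int = 0
    min_query_cov: float = 0.40
    min_hsp_len: int = 21
    min_identity: float = 0.75
    merge_cap: float = 1.25
    max_gap: int = 30
    flank: int = 10
    hmm_e_max: float = 0.01
    cm_e_max: float = 0.01
    cm_min_coverage: float = 0.70
    null_samples: int = 1000
    calibration_n: int = 1000
    curation_flank: int = 300
    ga: dict = field(default_factory=dict)  # optional per-family GA override

    def filter_params(self) -> FilterParams:
        return FilterParams(self.min_query_cov, self.min_hsp_len,
                            self.min_identity, self.merge_cap,
                            self.max_gap, self.flank)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


@dataclass
class PipelineResult:
    loci: list
    cm_hits: list
    blast_candidates: dict
    hmm_candidates: dict
    contamination_calls: list
    clean_genome: list
    summary: pd.DataFrame
    log: list[str] = field(default_factory=list)
    rejections: list = field(default_factory=list)


@dataclass
class _Region:
    """Minimal region object handed to CM validation."""
    family_id: str
    rna_class: str
    interval: GenomicInterval
    sequence: str


def build_family_models(seeds, *, calibration_n=1000, seed=0, ga=None,
                        taxon_filter=None):
    """Profile HMM and calibrated covariance model for every seed alignment."""
    ga = ga or {}
    models = {}
    for aln in seeds:
        p = phmmmod.build_phmm(aln)
        c = cmmod.build_cm(aln, taxon_filter=taxon_filter)
        cmmod.calibrate_cm(c, n=calibration_n, seed=seed,
                           ga=ga.get(aln.family_id))
        models[aln.family_id] = (p, c)
    return models


def annotate(genome, queries, seeds, contaminants=None,
             config: RunConfig | None = None, models=None) -> PipelineResult:
    """Run the complete annotation on in-memory objects.

    ``genome``: list of Contig; ``queries``: list of QueryRecord grouped by
    family through their ``family_id``; ``seeds``: list of SeedAlignment
    (one per family); ``contaminants``: optional list of Contig references.
    Deterministic for a fixed config seed.
    """
    config = config or RunConfig()
    params = config.filter_params()
    log: list[str] = []

    # Stockholm files carry no RNA class; inherit it from the family's
    # queries so summaries and GFF3 report the right class.
    class_by_family = {q.family_id: q.rna_class for q in queries}
    for s in seeds:
        if s.rna_class == "misc_RNA" and s.family_id in class_by_family:
            s.rna_class = class_by_family[s.family_id]

    # stage 1: contamination screen
    calls = []
    clean = list(genome)
    if contaminants:
        calls, clean = contmod.screen(clean, contaminants)
        log.append(f"contamination_screen: {len(genome)} contigs in, "
                   f"{len(clean)} clean, {len(calls)} flagged")
    index = GenomeIndex(clean)

    if models is None:
        models = build_family_models(
            seeds, calibration_n=config.calibration_n, seed=config.seed,
            ga=config.ga)
    seeds_by_family = {s.family_id: s for s in seeds}

    # stage 2-3: multi-strategy search, filter/merge/extend per family
    by_family: dict[str, list[QueryRecord]] = collections.defaultdict(list)
    for q in queries:
        by_family[q.family_id].append(q)
    blast_candidates = {}
    n_hsps = 0
    for fam, fam_queries in sorted(by_family.items()):
        pooled = []
        for q in fam_queries:
            qlen = len(q.sequence)
            for sid in config.strategies:
                scheme = make_strategy(sid)
                hsps = search(q, index, scheme)
                n_hsps += len(hsps)
                kept = filter_hsps(hsps, qlen, params)
                merged = merge_hsps(kept, qlen, params)
                pooled.extend(filter_hsps(merged, qlen, params))
        qlen = max(len(q.sequence) for q in fam_queries)
        rna_class = fam_queries[0].rna_class
        blast_candidates[fam] = build_candidates(
            pooled, clean, qlen, fam, rna_class, params)
    n_blast = sum(len(v) for v in blast_candidates.values())
    log.append(f"blast_search: {n_hsps} raw HSPs -> {n_blast} candidate "
               f"regions after filtering/merging/extension")

    # stage 4: profile-HMM search as an independent candidate track
    hmm_candidates = {}
    contig_by_id = {c.id: c for c in clean}
    for fam, (p, c) in sorted(models.items()):
        hits = phmmmod.search_phmm(
            p, clean, e_max=config.hmm_e_max,
            null_samples=config.null_samples, seed=config.seed)
        regions = []
        for h in hits:
            iv = h.interval
            contig = contig_by_id[iv.contig_id]
            pad = config.flank
            a = max(0, iv.start - pad)
            b = min(contig.length, iv.end + pad)
            seq = contig.sequence[a:b]
            if iv.strand == "-":
                seq = reverse_complement(seq)
            regions.append(_Region(
                fam, seeds_by_family[fam].rna_class,
                GenomicInterval(iv.contig_id, a, b, iv.strand), seq))
        hmm_candidates[fam] = regions
    n_hmm = sum(len(v) for v in hmm_candidates.values())
    log.append(f"hmm_search: {n_hmm} envelope candidates at "
               f"E<={config.hmm_e_max}")

    # stage 5: CM validation of both candidate tracks
    all_hits = []
    for fam, (p, c) in sorted(models.items()):
        for track, regions in (("blast", blast_candidates.get(fam, [])),
                               ("hmm", hmm_candidates.get(fam, []))):
            hits = cmmod.search_cm(
                c, regions, genome_length=index.total_length,
                e_max=config.cm_e_max, min_coverage=config.cm_min_coverage,
                evidence=frozenset({track}))
            all_hits.extend(hits)
    accepted = [h for h in all_hits if h.status == "accepted"]
    log.append(f"cm_validation: {len(all_hits)} scored regions, "
               f"{len(accepted)} accepted (GA/E/coverage)")

    # stage 6: overlap resolution
    resolved = cmmod.resolve_overlaps(accepted)
    log.append(f"overlap_resolution: {len(accepted)} -> {len(resolved)} hits")

    # stage 7: final curation with 300 nt flanks
    loci = []
    rejections = []
    for h in resolved:
        locus = cmmod.curate_final(h, clean, models[h.family_id][1],
                                   flank=config.curation_flank,
                                   e_max=config.cm_e_max)
        if locus is None:
            rejections.append(h)
        else:
            loci.append(locus)
    log.append(f"curation: {len(resolved)} in, {len(loci)} curated loci, "
               f"{len(rejections)} rejected")

    rows = []
    per_class = collections.defaultdict(lambda: [set(), 0])
    for l in loci:
        per_class[l.rna_class][0].add(l.family_id)
        per_class[l.rna_class][1] += 1
    for rc in sorted(per_class):
        fams, n = per_class[rc]
        rows.append({"rna_class": rc, "families": len(fams), "loci": n})
    summary = pd.DataFrame(rows, columns=["rna_class", "families", "loci"])
    return PipelineResult(loci, resolved, blast_candidates, hmm_candidates,
                          calls, clean, summary, log, rejections)


def run_annotation(config: RunConfig) -> PipelineResult:
    """File-based entry point: read inputs, annotate, write all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = [r for r in read_fasta(config.genome) if isinstance(r, Contig)]
    queries = [r for r in read_fasta(config.queries)
               if isinstance(r, QueryRecord)]
    seeds = [read_stockholm(p) for p in config.seeds]
    contaminants = None
    if config.contaminants:
        contaminants = [r for r in read_fasta(config.contaminants)
                        if isinstance(r, Contig)]
    result = annotate(genome, queries, seeds, contaminants, config)
    write_annotations(result.loci, result.clean_genome,
                      outdir / "annotation.gff3", outdir / "annotation.tsv")
    result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    if result.contamination_calls:
        with open(outdir / "contamination.tsv", "w") as fh:
            fh.write("contig\trule\tbest_evalue\tidentity\tcoverage\tsource\n")
            for c in result.contamination_calls:
                fh.write(f"{c.contig_id}\t{c.rule}\t{c.best_evalue:.3g}\t"
                         f"{c.identity:.3f}\t{c.coverage:.3f}\t{c.source_id}\n")
    return result
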