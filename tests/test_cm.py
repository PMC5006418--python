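"""Covariance-model construction, CYK scoring, calibration, acceptance
criteria, overlap resolution and final curation."""

import numpy as np
import pytest

from conftest import random_dna
from ncranno.cm import (CmHit, build_cm, calibrate_cm, curate_final, cyk,
                        resolve_overlaps, search_cm)
from ncranno.filters import CandidateRegion
from ncranno.seqio import Contig, GenomicInterval, SeedAlignment, \
    reverse_complement
from ncranno.simulate import make_seed_family, mutate_to_identity, \
    seed_consensus
from oracles import cyk_oracle


def hairpin_seed():
    rows = {f"r{i}": "GGACGTCC" for i in range(4)}
    return SeedAlignment("hp", rows, "((....))")


class TestBuild:
    def test_structure_driven_topology(self):
        m = build_cm(hairpin_seed())
        assert m.node_kinds == ["ROOT", "MATP", "MATP", "MATL", "MATL",
                                "MATL", "MATL", "END"]
        assert m.clen == 8

    def test_taxon_filter_changes_emissions_not_topology(self):
        rows = {"metazoa1": "GGACGTCC", "metazoa2": "GGACGTCC",
                "fungus1": "GGTTTTCC", "fungus2": "GGTTTTCC"}
        aln = SeedAlignment("hp", rows, "((....))")
        full = build_cm(aln)
        filt = build_cm(aln, taxon_filter={"metazoa1", "metazoa2"})
        assert filt.node_kinds == full.node_kinds
        assert filt.consensus != full.consensus or not np.allclose(
            filt.eL, full.eL, atol=1e-12)

    def test_empty_taxon_filter_rejected(self):
        with pytest.raises(ValueError, match="removed every row"):
            build_cm(hairpin_seed(), taxon_filter={"nobody"})

    def test_pair_into_dropped_column_rejected(self):
        rows = {"a": "G-ACGTCC", "b": "G-ACGTCC", "c": "GCACGTCC"}
        # column 1 is majority-gap (dropped) but pairs with column 6
        aln = SeedAlignment("bad", rows, "((....))")
        with pytest.raises(ValueError, match="spans a dropped"):
            build_cm(aln)

    def test_conserved_gc_pair_dominates_pair_emission(self):
        m = build_cm(hairpin_seed())
        s_mp = [i for i, k in enumerate(m.stype) if k == 3][0]
        lo = m.eP[s_mp].reshape(5, 5)[:4, :4]
        logbg = np.log(m.background)
        joint = np.exp(lo + logbg[:, None] + logbg[None, :])
        g, c = 2, 1
        assert joint[g, c] == joint.max()
        assert joint[g, c] == pytest.approx(5 / 20)  # 4 rows + pseudocounts


class TestCyk:
    @pytest.mark.parametrize("name,ss,rowseq", [
        ("hairpin", "((....))", "GGACGTCC"),
        ("bulge", "..((..))..", "ATGGTACCAT"),
        ("two_stem", "((..))((..))", "GGAACCTTGGAA"),
    ])
    def test_cyk_equals_parse_enumeration(self, name, ss, rowseq, rng):
        m = build_cm(SeedAlignment(name, {f"r{i}": rowseq for i in range(3)},
                                   ss))
        for L in (4, 6, 8, 9):
            s = random_dna(rng, L)
            bits, _ = cyk(m, s)
            assert bits == pytest.approx(cyk_oracle(m, s), abs=5e-3)

    def test_consensus_has_full_model_coverage(self):
        m = build_cm(hairpin_seed())
        _, matched = cyk(m, m.consensus)
        assert matched == m.clen

    def test_sequence_local_scoring_ignores_flanks(self):
        m = build_cm(hairpin_seed())
        b1, _ = cyk(m, m.consensus)
        b2, _ = cyk(m, "TTT" + m.consensus + "AAAT")
        assert b2 == pytest.approx(b1, abs=1e-4)

    def test_window_cap_enforced(self):
        m = build_cm(hairpin_seed())
        with pytest.raises(ValueError, match="windowed search"):
            cyk(m, "A" * (m.max_window + 1))


class TestCalibration:
    def test_supplied_ga_is_untouched(self):
        m = build_cm(hairpin_seed())
        calibrate_cm(m, n=150, seed=0, ga=30.0)
        assert m.GA == 30.0
        calibrate_cm(m, n=150, seed=1)
        assert m.GA == 30.0  # already set, left alone

    def test_default_ga_is_max_null_plus_two(self):
        m = build_cm(hairpin_seed())
        calibrate_cm(m, n=150, seed=0)
        assert m.GA == pytest.approx(m._null_scores.max() + 2.0)

    def test_median_null_evalue_near_half_n(self):
        fam = make_seed_family("calfam", "snRNA", length=50, seed=2)
        m = build_cm(fam)
        calibrate_cm(m, n=400, seed=3)
        med = float(np.median(m._null_scores))
        e = m.evalue(med, n_search=400)
        assert 0.35 * 400 <= e <= 0.95 * 400

    def test_degenerate_null_distribution_is_an_error(self):
        rows = {f"r{i}": "AAAAAAAAAA" for i in range(3)}
        m = build_cm(SeedAlignment("mono", rows, "." * 10))
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_cm(m, n=120, seed=0)

    def test_minimum_shuffle_count(self):
        m = build_cm(hairpin_seed())
        with pytest.raises(ValueError, match="n >= 100"):
            calibrate_cm(m, n=50)


def _region(seq, contig="c1", start=0, strand="+"):
    return CandidateRegion("fam", "snRNA",
                           GenomicInterval(contig, start, start + len(seq),
                                           strand), seq)


class TestAcceptance:
    @pytest.fixture(scope="class")
    def model(self):
        fam = make_seed_family("accfam", "snRNA", length=70, seed=4)
        m = build_cm(fam)
        calibrate_cm(m, n=300, seed=5)
        return m

    def test_uncalibrated_model_refused(self):
        m = build_cm(hairpin_seed())
        with pytest.raises(ValueError, match="calibrated"):
            search_cm(m, [_region("ACGTACGT")])

    def test_ga_boundary_not_lower_than(self, model):
        region = _region(model.consensus)
        bits = search_cm(model, [region], genome_length=10_000)[0].bitscore
        old_ga = model.GA
        try:
            model.GA = bits  # exactly at the threshold: inclusive rule
            assert search_cm(model, [region],
                             genome_length=10_000)[0].status == "accepted"
            model.GA = bits + 0.1
            assert search_cm(model, [region],
                             genome_length=10_000)[0].status == "raw"
        finally:
            model.GA = old_ga

    def test_low_coverage_rejected(self, model):
        # a 60 % truncation cannot supply residues for 70 % of the model
        frag = model.consensus[: int(0.6 * model.clen)]
        hit = search_cm(model, [_region(frag)], genome_length=10_000)[0]
        assert hit.model_coverage < 0.70
        assert hit.status == "raw"

    def test_planted_instances_accepted_across_replicates(self, model):
        """Full-length copies at 85 % identity pass GA/E/coverage in at
        least 9 of 10 seeded replicates."""
        ok = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            mut, _ = mutate_to_identity(model.consensus, 0.85, 0.02, rng)
            seq = (random_dna(rng, 15) + mut + random_dna(rng, 15))
            hits = search_cm(model, [_region(seq)], genome_length=2_000_000)
            ok += any(h.status == "accepted" for h in hits)
        assert ok >= 9

    def test_minus_strand_region_recovered(self, model):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 10) + model.consensus + random_dna(rng, 10)
        region = _region(reverse_complement(seq), start=500)
        hit = search_cm(model, [region], genome_length=10_000)[0]
        assert hit.status == "accepted"


def _hit(fam, start, end, bits, ev=1e-6, contig="c1", cov=0.9):
    return CmHit(GenomicInterval(contig, start, end), bits, ev, cov, fam,
                 status="accepted")


class TestOverlapResolution:
    def test_same_family_hits_merged_to_hull(self):
        out = resolve_overlaps([_hit("U6", 100, 160, 40),
                                _hit("U6", 150, 210, 35)])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 210)
        assert out[0].bitscore == 40

    def test_cross_family_best_bitscore_wins(self):
        out = resolve_overlaps([_hit("U6", 100, 160, 40),
                                _hit("U5", 150, 210, 35)])
        assert [h.family_id for h in out] == ["U6"]

    def test_tie_broken_by_smaller_evalue(self):
        out = resolve_overlaps([_hit("U6", 100, 160, 40, ev=1e-4),
                                _hit("U5", 150, 210, 40, ev=1e-5)])
        assert [h.family_id for h in out] == ["U5"]

    def test_no_cross_family_overlaps_remain(self):
        hits = [_hit("a", 0, 50, 10), _hit("b", 40, 90, 12),
                _hit("c", 80, 130, 11), _hit("a", 200, 250, 9)]
        out = resolve_overlaps(hits)
        for i, h in enumerate(out):
            for other in out[i + 1:]:
                if h.family_id != other.family_id:
                    assert h.interval.overlap(other.interval) == 0


class TestCuration:
    @pytest.fixture(scope="class")
    def setup(self):
        fam = make_seed_family("curfam", "snRNA", length=70, seed=9)
        m = build_cm(fam)
        calibrate_cm(m, n=300, seed=5)
        rng = np.random.default_rng(31)
        mut, _ = mutate_to_identity(m.consensus, 0.88, 0.01, rng)
        left, right = random_dna(rng, 400), random_dna(rng, 400)
        contig = Contig("c1", left + mut + right)
        truth = (400, 400 + len(mut))
        hit = _hit("curfam", truth[0] - 5, truth[1] + 5, 50)
        return m, [contig], hit, truth

    def test_true_locus_survives_with_tight_footprint(self, setup):
        m, genome, hit, truth = setup
        locus = curate_final(hit, genome, m)
        assert locus is not None
        assert abs(locus.interval.start - truth[0]) <= 5
        assert abs(locus.interval.end - truth[1]) <= 5
        assert not locus.clipped

    def test_curation_threshold_is_strict(self, setup):
        m, genome, hit, _ = setup
        locus = curate_final(hit, genome, m)
        old_ga = m.GA
        try:
            m.GA = locus.bitscore  # re-scored bits equal GA -> strict reject
            assert curate_final(hit, genome, m) is None
        finally:
            m.GA = old_ga

    def test_contig_edge_curation_is_clipped(self, setup):
        m, genome, _, truth = setup
        rng = np.random.default_rng(77)
        mut, _ = mutate_to_identity(m.consensus, 0.9, 0.0, rng)
        edge_contig = Contig("c2", mut + random_dna(rng, 400))
        hit = _hit("curfam", 0, len(mut), 50, contig="c2")
        locus = curate_final(hit, [edge_contig], m)
        assert locus is not None
        assert locus.clipped
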