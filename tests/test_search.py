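"""Scoring strategies, Karlin-Altschul statistics and seeded search."""

import numpy as np
import pytest

from conftest import random_dna
from ncranno.search import (GenomeIndex, make_strategy, search,
                            solve_statistics)
from ncranno.seqio import Contig, QueryRecord, reverse_complement
from ncranno.simulate import mutate_to_identity
from oracles import optimum_contains_word, smith_waterman_affine


class TestStrategyPresets:
    @pytest.mark.parametrize("sid,expected", [
        ("default", (1, -3, 5, 2, 11, 10.0)),
        (8, (5, -4, 25, 10, 7, 1000.0)),
        (2, (4, -5, 3, 5, 7, 10.0)),   # NA expectation cutoff -> 10
        (1, (5, -4, 10, 6, 7, 10.0)),
        (7, (4, -5, 3, 5, 7, 1000.0)),
    ])
    def test_preset_values(self, sid, expected):
        s = make_strategy(sid)
        assert (s.r, s.q, s.G, s.E_ext, s.W, s.e_cut) == expected

    def test_unknown_id_lists_valid_ids(self):
        with pytest.raises(ValueError, match="default"):
            make_strategy("99")

    def test_overrides(self):
        s = make_strategy("default", e_cut=0.5, W=8)
        assert s.e_cut == 0.5 and s.W == 8


class TestStatistics:
    def test_lambda_root_for_blastn_default(self):
        st = solve_statistics(make_strategy("default"))
        assert st.lambda_ka == pytest.approx(1.374, abs=2e-3)
        # root property: sum p_i p_j exp(lambda s_ij) = 1
        p = 0.25
        val = (4 * p * p * np.exp(st.lambda_ka * 1)
               + 12 * p * p * np.exp(st.lambda_ka * -3))
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_target_frequency_matches_expected_identity(self):
        st = solve_statistics(make_strategy("default"))
        assert st.target_frequency == pytest.approx(0.99, abs=0.005)
        st8 = solve_statistics(make_strategy(8))
        assert st8.target_frequency == pytest.approx(0.65, abs=0.01)

    def test_positive_expected_score_is_invalid(self):
        with pytest.raises(ValueError, match="invalid scoring"):
            solve_statistics(make_strategy("default", q=-1, r=5))


class TestSearch:
    def test_exact_planted_query(self, rng):
        q = random_dna(rng, 40)
        genome = [Contig("c1", random_dna(rng, 3000) + q + random_dna(rng, 3000))]
        for sid in ("default", "8"):
            scheme = make_strategy(sid)
            hits = search(QueryRecord("f", "miRNA", "CIN", q), genome, scheme)
            top = max(hits, key=lambda h: h.score)
            assert top.identity == 1.0
            assert top.score == 40 * scheme.r
            assert top.query_span == (0, 40)
            assert (top.interval.start, top.interval.end) == (3000, 3040)

    def test_minus_strand_symmetry(self, rng):
        q = random_dna(rng, 40)
        bg = random_dna(rng, 4000)
        fwd = [Contig("c1", bg[:2000] + q + bg[2000:])]
        rev = [Contig("c1", bg[:2000] + reverse_complement(q) + bg[2000:])]
        qr = QueryRecord("f", "miRNA", "CIN", q)
        scheme = make_strategy("default")
        h1 = search(qr, fwd, scheme)[0]
        h2 = search(qr, rev, scheme)[0]
        assert h2.interval.strand == "-"
        assert h2.score == h1.score
        assert (h2.interval.start, h2.interval.end) == (2000, 2040)

    def test_short_query_warns_and_returns_empty(self, rng):
        genome = [Contig("c1", random_dna(rng, 500))]
        with pytest.warns(UserWarning, match="shorter than word size"):
            hits = search(QueryRecord("f", "miRNA", "CIN", "ACGTAC"),
                          genome, make_strategy("default"))
        assert hits == []

    def test_n_never_seeds(self, rng):
        # query of Ns against itself: no word can seed
        genome = [Contig("c1", "N" * 50 + random_dna(rng, 200))]
        hits = search(QueryRecord("f", "miRNA", "CIN", "N" * 30), genome,
                      make_strategy("default"))
        assert hits == []

    def test_deterministic_output_order(self, rng):
        q = random_dna(rng, 50)
        pieces = [random_dna(rng, 500) + mutate_to_identity(q, 0.9, 0, rng)[0]
                  for _ in range(4)]
        genome = [Contig(f"c{i}", p) for i, p in enumerate(pieces)]
        qr = QueryRecord("f", "snRNA", "CIN", q)
        h1 = search(qr, genome, make_strategy("7"))
        h2 = search(qr, genome, make_strategy("7"))
        assert h1 == h2

    @pytest.mark.parametrize("sid", ["default", "7", "8"])
    def test_seeded_score_equals_full_smith_waterman(self, sid, rng):
        """On instances whose optimum contains an exact word, the seeded
        banded extension recovers the full affine local-alignment optimum."""
        scheme = make_strategy(sid, e_cut=1e12)
        checked = 0
        while checked < 12:
            core = random_dna(rng, 60)
            m1, _ = mutate_to_identity(core, 0.84, 0.01, rng)
            m2, _ = mutate_to_identity(core, 0.84, 0.01, rng)
            a = random_dna(rng, 70) + m1 + random_dna(rng, 70)
            b = random_dna(rng, 50) + m2 + random_dna(rng, 80)
            opt, pairs = smith_waterman_affine(
                a, b, scheme.r, scheme.q, scheme.G, scheme.E_ext)
            if not optimum_contains_word(a, b, pairs, scheme.W):
                continue
            checked += 1
            hits = search(QueryRecord("f", "miRNA", "CIN", a),
                          [Contig("c", b)], scheme)
            assert max(h.score for h in hits) == opt

    def test_relaxing_ecut_never_loses_hits(self, rng):
        """Strategies 3 and 8 share scores; 8's looser cutoff is a superset."""
        q = random_dna(rng, 60)
        mut, _ = mutate_to_identity(q, 0.75, 0.02, rng)
        genome = [Contig("c1", random_dna(rng, 5000) + mut
                         + random_dna(rng, 5000))]
        qr = QueryRecord("f", "snRNA", "CIN", q)
        strict = search(qr, genome, make_strategy(3))
        loose = search(qr, genome, make_strategy(8))
        key = lambda h: (h.interval.contig_id, h.interval.start,
                         h.interval.end, h.interval.strand)
        assert {key(h) for h in strict} <= {key(h) for h in loose}

    def test_union_of_strategies_beats_default_at_high_divergence(self):
        """At 65-75 % planted identity the sensitivity-tuned ensemble
        recovers at least as many loci as blastn defaults, and strictly
        more in at least one replicate."""
        strictly_more = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            q = random_dna(rng, 90)
            planted = []
            contigs = []
            for i in range(6):
                ident = rng.uniform(0.65, 0.75)
                mut, _ = mutate_to_identity(q, ident, 0.01, rng)
                contigs.append(Contig(f"c{i}", random_dna(rng, 800) + mut
                                      + random_dna(rng, 800)))
                planted.append((f"c{i}", 800, 800 + len(mut)))
            index = GenomeIndex(contigs)
            qr = QueryRecord("f", "snRNA", "CIN", q)

            def recovered(hits):
                found = set()
                for cid, s, e in planted:
                    for h in hits:
                        iv = h.interval
                        if iv.contig_id == cid and \
                                min(e, iv.end) - max(s, iv.start) > 0.5 * (e - s):
                            found.add(cid)
                            break
                return found

            default_found = recovered(search(qr, index, make_strategy("default")))
            union_found = set()
            for sid in "12345678":
                union_found |= recovered(search(qr, index, make_strategy(sid)))
            assert default_found <= union_found
            if len(union_found) > len(default_found):
                strictly_more += 1
        assert strictly_more >= 1
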