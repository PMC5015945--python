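"""Search engine, hit merging, top-hit selection, reciprocity, synteny."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincphylo.align import local_align
from lincphylo.config import PipelineConfig, ScoringScheme, karlin_altschul_lambda
from lincphylo.genome import Genome, encode
from lincphylo.homology import (LocusHit, anchor_top_hits, check_reciprocity,
                                check_synteny, merge_hits, search, top_hit)
from lincphylo.intervals import GenomeInterval

from conftest import random_dna


def sw_affine_oracle(q: str, s: str, match=1, mismatch=-2, open_=5, ext=2):
    """Plain-python full Smith-Waterman with gap cost open + ext*L."""
    n, m = len(q), len(s)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if q[i - 1] == s[j - 1] and q[i - 1] in "ACGT" else mismatch
            E[i][j] = max(E[i][j - 1] - ext, H[i][j - 1] - open_ - ext)
            F[i][j] = max(F[i - 1][j] - ext, H[i - 1][j] - open_ - ext)
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def mutate(rng, seq, p):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestScoringScheme:
    def test_lambda_solves_karlin_altschul_identity(self, scheme):
        lam = scheme.ka_lambda
        assert 0.25 * np.exp(lam * 1) + 0.75 * np.exp(lam * -2) == pytest.approx(1.0)

    def test_lambda_requires_negative_expected_score(self):
        with pytest.raises(ValueError):
            karlin_altschul_lambda(1, 2)

    def test_evalue_monotone_decreasing_in_score(self, scheme):
        es = [scheme.evalue(s, 400, 10**6) for s in range(10, 100, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestSearch:
    def test_exact_self_match(self, rng, scheme):
        q = random_dna(rng, 60)
        g = Genome("sp", {"c1": "T" * 300 + q + "T" * 300})
        hits = search(q, g, scheme, 10.0)
        best = hits[0]
        assert best.score == len(q)
        assert (best.interval.start, best.interval.end) == (300, 360)
        assert best.evalue == min(h.evalue for h in hits)

    def test_no_shared_kmer_no_hit(self, scheme):
        g = Genome("sp", {"c1": "T" * 500})
        assert search("ACGTACGTACGT", g, scheme, 10.0) == []

    def test_query_shorter_than_word_warns_empty(self, scheme):
        g = Genome("sp", {"c1": "ACGTACGT"})
        with pytest.warns(UserWarning):
            assert search("ACGTA", g, scheme, 10.0) == []

    def test_best_hit_score_matches_full_dp_oracle(self, scheme):
        """Planted 85%-identity copy: engine score == Smith-Waterman."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            q = random_dna(rng, 60)
            copy = mutate(rng, q, 0.15)
            g_seq = random_dna(rng, 200) + copy + random_dna(rng, 140)
            g = Genome("sp", {"c1": g_seq})
            hits = search(q, g, scheme, 10.0)
            assert hits, "planted copy not found"
            # compare against the full-DP local alignment on both strands
            from lincphylo.genome import revcomp
            expected = max(sw_affine_oracle(q, g_seq),
                           sw_affine_oracle(revcomp(q), g_seq))
            assert hits[0].score == expected

    def test_minus_strand_hit_found(self, rng, scheme):
        from lincphylo.genome import revcomp
        q = random_dna(rng, 50)
        g = Genome("sp", {"c1": "A" * 200 + revcomp(q) + "A" * 200})
        hits = search(q, g, scheme, 10.0)
        assert hits[0].interval.strand == "-"
        assert (hits[0].interval.start, hits[0].interval.end) == (200, 250)

    def test_no_overlapping_same_strand_hits_after_merge(self, rng, scheme):
        q = random_dna(rng, 60)
        seq = ("T" * 100 + q + "T" * 30 + q[:40] + "T" * 100)
        g = Genome("sp", {"c1": seq})
        merged = merge_hits(search(q, g, scheme, 10.0), len(q))
        by_strand = {}
        for h in merged:
            by_strand.setdefault(h.interval.strand, []).append(h.interval)
        for ivs in by_strand.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start


def _hit(chrom, start, end, score, ev, strand="+", qid="q"):
    return LocusHit(qid, GenomeInterval("sp", chrom, start, end, strand),
                    score, ev, (0, end - start))


class TestMergeAndTop:
    def test_close_hits_merge(self):
        hits = [_hit("c1", 100, 200, 50, 1e-30), _hit("c1", 250, 350, 40, 1e-25)]
        merged = merge_hits(hits, 300)  # gap 50 < 300
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 350)
        assert merged[0].score == 50 and merged[0].evalue == 1e-30

    def test_distant_hits_not_merged(self):
        hits = [_hit("c1", 100, 200, 50, 1e-30), _hit("c1", 600, 700, 40, 1e-25)]
        assert len(merge_hits(hits, 300)) == 2  # gap 400 >= 300

    def test_different_strand_or_chrom_never_merged(self):
        hits = [_hit("c1", 100, 200, 50, 1e-30),
                _hit("c1", 210, 300, 40, 1e-25, strand="-"),
                _hit("c2", 210, 300, 40, 1e-25)]
        assert len(merge_hits(hits, 500)) == 3

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 30),
                              st.sampled_from([1e-10, 1e-20, 1e-30])),
                    min_size=1, max_size=8),
           st.integers(5, 40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_merge_idempotent(self, raw, qlen):
        hits = [_hit("c1", s, s + l, l, ev) for s, l, ev in raw]
        once = merge_hits(hits, qlen)
        twice = merge_hits(once, qlen)
        assert [(h.interval.start, h.interval.end) for h in once] == \
               [(h.interval.start, h.interval.end) for h in twice]

    def test_top_hit_selection(self):
        assert top_hit([]) is None
        a = _hit("c1", 0, 10, 10, 1e-10)
        assert top_hit([a]) is a
        b = _hit("c1", 50, 60, 20, 1e-10)
        assert top_hit([a, b]) is b  # equal E, higher score wins
        c = _hit("a1", 0, 10, 10, 1e-10)
        assert top_hit([a, c]) is c  # fully tied: lexicographic chrom
        assert top_hit([c, a]) is c  # stable across input order


class TestReciprocitySynteny:
    def _two_copy_fixture(self, rng, scheme):
        """Focal genome with two paralogous loci; subject genome whose
        locus is much closer to focal copy B than to copy A."""
        anc = random_dna(rng, 120)
        copy_a = mutate(rng, anc, 0.25)
        copy_b = mutate(rng, anc, 0.02)
        focal = Genome("F", {"c1": random_dna(rng, 150) + copy_a
                             + random_dna(rng, 200) + copy_b + random_dna(rng, 150)})
        subject_locus = mutate(rng, copy_b, 0.02)
        subject = Genome("S", {"c1": random_dna(rng, 150) + subject_locus
                               + random_dna(rng, 150)})
        iv_a = GenomeInterval("F", "c1", 150, 150 + len(copy_a), "+")
        iv_b = GenomeInterval("F", "c1", 350 + len(copy_a),
                              350 + len(copy_a) + len(copy_b), "+")
        return focal, subject, iv_a, iv_b

    def test_ortholog_is_reciprocal(self, scheme):
        rng = np.random.default_rng(9)
        focal, subject, iv_a, iv_b = self._two_copy_fixture(rng, scheme)
        hits = search(focal.fetch(iv_b), subject, scheme, 1e-3, "q")
        best = top_hit(merge_hits(hits, iv_b.length))
        assert check_reciprocity(best, subject, focal, iv_b, scheme, 1e-3)

    def test_paralog_fails_reciprocity(self, scheme):
        """Back-search from the subject locus prefers the other focal
        copy, so the hit for the distant paralog is not reciprocal."""
        rng = np.random.default_rng(9)
        focal, subject, iv_a, iv_b = self._two_copy_fixture(rng, scheme)
        hits = search(focal.fetch(iv_a), subject, scheme, 1.0, "q")
        best = top_hit(merge_hits(hits, iv_a.length))
        assert best is not None
        assert not check_reciprocity(best, subject, focal, iv_a, scheme, 1e-3)

    def test_no_back_hit_fails_reciprocity(self, rng, scheme):
        subject = Genome("S", {"c1": random_dna(rng, 400)})
        focal = Genome("F", {"c1": random_dna(rng, 400)})
        fake = _hit("c1", 100, 200, 20, 1e-6)
        fake = LocusHit("q", GenomeInterval("S", "c1", 100, 200, "+"),
                        20, 1e-6, (0, 100))
        qiv = GenomeInterval("F", "c1", 100, 200, "+")
        assert not check_reciprocity(fake, subject, focal, qiv, scheme, 1e-20)

    def test_synteny_collinear_vs_translocated(self, scheme, config):
        rng = np.random.default_rng(3)
        anchor = random_dna(rng, 300)
        locus = random_dna(rng, 100)
        # collinear: anchor ortholog next to the locus hit
        near = Genome("S", {"c1": anchor + random_dna(rng, 200) + locus
                            + random_dna(rng, 200)})
        hit = top_hit(search(locus, near, scheme, 1e-3, "q"))
        ahits = anchor_top_hits([anchor], near, scheme, 1e-3)
        assert check_synteny(hit, ahits, config)
        # translocated: anchor on another chromosome
        far = Genome("S", {"c1": random_dna(rng, 200) + locus + random_dna(rng, 200),
                           "c2": anchor + random_dna(rng, 100)})
        hit2 = top_hit(search(locus, far, scheme, 1e-3, "q"))
        ahits2 = anchor_top_hits([anchor], far, scheme, 1e-3)
        assert not check_synteny(hit2, ahits2, config)

    def test_synteny_window_respected(self, config):
        hit = _hit("c1", 1000, 1100, 50, 1e-30)
        near = _hit("c1", 1200, 1500, 40, 1e-25)
        far = LocusHit("a", GenomeInterval("sp", "c1", 200_000, 200_300, "+"),
                       40, 1e-25, (0, 300))
        assert check_synteny(hit, [near], config)
        assert not check_synteny(hit, [far], config)


class TestBlastAdapter:
    def test_engine_agrees_with_external_blastn(self, scheme):
        """Internal engine and NCBI blastn (same parameters) return the
        same raw score and subject interval for planted diverged copies."""
        from lincphylo.blast_adapter import blastn_search
        rng = np.random.default_rng(7)
        for _ in range(4):
            q = random_dna(rng, 200)
            copy = mutate(rng, q, 0.15)
            g = Genome("S", {"c1": random_dna(rng, 400) + copy
                             + random_dna(rng, 400)})
            ours = top_hit(merge_hits(search(q, g, scheme, 1e-3), len(q)))
            theirs = blastn_search(q, g, 1e-3)
            assert ours is not None and theirs
            t = theirs[0]
            assert ours.score == t.score
            assert (ours.interval.start, ours.interval.end) == \
                (t.interval.start, t.interval.end)

    def test_blast6_parser_strand_convention(self):
        from lincphylo.blast_adapter import parse_blast6
        line = "q\tc1\t95.0\t100\t5\t0\t1\t100\t250\t151\t1e-40\t180\t90"
        (hit,) = parse_blast6(line, "sp")
        assert hit.interval.strand == "-"
        assert (hit.interval.start, hit.interval.end) == (150, 250)
        assert hit.score == 90 and hit.q_span == (0, 100)
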