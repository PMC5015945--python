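"""Feature classification, Fisher tests, correlations, miRNA scoring,
structure proxy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from lincphylo.features import (depth_stratified_proportions,
                                expression_depth_correlation, fisher_exact,
                                gene_proximity_vs_conservation,
                                interval_overlap_class, mfe_proxy_per_nt,
                                mirna_expectation, nearest_distance,
                                nussinov_pairs)
from lincphylo.genome import revcomp
from lincphylo.intervals import GenomeInterval


def iv(start, end, chrom="c1"):
    return GenomeInterval("sp", chrom, start, end, "+")


class TestIntervalOverlapClass:
    def test_boundary_ten_nt_inside(self):
        assert interval_overlap_class(iv(100, 500), [iv(490, 600)], 10) == "inside"
        assert interval_overlap_class(iv(100, 500), [iv(491, 600)], 10) != "inside"

    def test_near_classes(self):
        assert interval_overlap_class(iv(100, 500), [iv(505, 600)], 10) == "within_100bp"
        assert interval_overlap_class(iv(100, 500), [iv(750, 900)], 10) == "within_500bp"
        assert interval_overlap_class(iv(100, 500), [iv(5000, 5100)], 10) == "none"

    def test_cns_any_overlap(self):
        assert interval_overlap_class(iv(100, 500), [iv(499, 600)], 1, ()) == "inside"

    def test_agrees_with_naive_scan(self, rng):
        """Brute-force re-derivation over random interval pairs."""
        def naive(locus, annots, min_nt, near):
            best = None
            for a in annots:
                ov = max(0, min(locus.end, a.end) - max(locus.start, a.start))
                if ov >= min_nt:
                    return "inside"
                # sub-threshold overlap is distance zero
                d = max(locus.start - a.end, a.start - locus.end, 0)
                best = d if best is None else min(best, d)
            if best is not None:
                for dd in sorted(near):
                    if best <= dd:
                        return f"within_{dd}bp"
            return "none"

        for _ in range(300):
            l0 = int(rng.integers(0, 2000))
            locus = iv(l0, l0 + int(rng.integers(50, 400)))
            annots = []
            for _ in range(int(rng.integers(1, 5))):
                a0 = int(rng.integers(0, 2500))
                annots.append(iv(a0, a0 + int(rng.integers(10, 300))))
            got = interval_overlap_class(locus, annots, 10, (100, 500))
            assert got == naive(locus, annots, 10, (100, 500))

    def test_translation_invariance(self, rng):
        locus = iv(100, 400)
        annots = [iv(450, 700), iv(900, 1000)]
        base = interval_overlap_class(locus, annots, 10, (100, 500))
        for shift in (13, 1000, 54321):
            moved = interval_overlap_class(
                iv(100 + shift, 400 + shift),
                [iv(a.start + shift, a.end + shift) for a in annots],
                10, (100, 500))
            assert moved == base

    def test_nearest_distance(self):
        assert nearest_distance(iv(100, 200), [iv(300, 400), iv(250, 260)]) == 50
        assert nearest_distance(iv(100, 200), [iv(150, 400)]) == 0
        assert nearest_distance(iv(100, 200), []) is None


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestFisher:
    def test_symmetric_table(self):
        """[[2,1],[1,2]]: every table is no more probable than observed."""
        p, odds = fisher_exact([[2, 1], [1, 2]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(4.0)

    def test_stress_counts_strongly_significant(self):
        """147/1736 vs 339/1785 stress-responsive loci: p < 1e-4."""
        p, _ = fisher_exact([[147, 1736 - 147], [339, 1785 - 339]])
        assert p < 1e-4

    def test_zero_margin_degenerate(self):
        p, odds = fisher_exact([[0, 5], [0, 7]])
        assert p == 1.0
        assert np.isnan(odds)

    def test_odds_ratio_conventions(self):
        assert fisher_exact([[3, 0], [2, 5]])[1] == float("inf")

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p, _ = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-9)


class TestDepthStratified:
    def test_reported_stress_proportions(self):
        """The species-specific and 13-My bins reproduce 8.5% / 19.0%."""
        rows = ([(f"a{i}", 0.0, i < 147) for i in range(1736)]
                + [(f"b{i}", 13.0, i < 339) for i in range(1785)])
        df = pd.DataFrame(rows, columns=["locus_id", "depth_age_Mya",
                                         "stress_responsive"])
        out = depth_stratified_proportions(df, "stress_responsive")
        assert out.iloc[0].pct == pytest.approx(100 * 147 / 1736, abs=0.01)
        assert out.iloc[1].pct == pytest.approx(100 * 339 / 1785, abs=0.01)
        assert out.iloc[1].fisher_p_vs_shallowest < 1e-4

    def test_all_false_flags(self):
        df = pd.DataFrame({"locus_id": list("abcd"),
                           "depth_age_Mya": [0, 0, 13, 13],
                           "flag": [False] * 4})
        out = depth_stratified_proportions(df, "flag")
        assert (out.pct == 0).all()
        assert (out.fisher_p_vs_shallowest == 1.0).all()


class TestExpressionCorrelation:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({
            "depth_age_Mya": np.linspace(0, 60, 30),
            "mean_fpkm": 10.0 ** np.linspace(0, 3, 30)})
        r, slope, p, n = expression_depth_correlation(df)
        assert r == pytest.approx(1.0, abs=1e-6)
        assert p < 1e-10 and n == 30

    def test_permuted_null_not_significant_on_average(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(20):
            df = pd.DataFrame({
                "depth_age_Mya": rng.choice([0, 13, 18, 42], 200),
                "mean_fpkm": 10.0 ** rng.normal(0, 0.5, 200)})
            ps.append(expression_depth_correlation(df)[2])
        assert np.mean(ps) > 0.2  # roughly uniform null

    def test_missing_expression_excluded(self):
        df = pd.DataFrame({"depth_age_Mya": [0, 13, 42, 54],
                           "mean_fpkm": [1.0, 2.0, np.nan, 4.0]})
        assert expression_depth_correlation(df)[3] == 3


class TestGeneProximity:
    def test_constant_proximity_zero_by_convention(self):
        df = pd.DataFrame({"nearest_gene_bp": [100] * 10,
                           "conserved": [True] * 5 + [False] * 5})
        r, p = gene_proximity_vs_conservation(df)
        assert r == 0.0 and p == 1.0

    def test_planted_covariation_detected(self):
        rng = np.random.default_rng(1)
        cons = rng.random(400) < 0.5
        dist = np.where(cons, 200, 2000) + rng.integers(0, 300, 400)
        df = pd.DataFrame({"nearest_gene_bp": dist, "conserved": cons})
        r, p = gene_proximity_vs_conservation(df, n_perm=2000,
                                              rng=np.random.default_rng(2))
        assert p < 0.01 and r < 0

    def test_independent_null(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"nearest_gene_bp": rng.integers(0, 5000, 300),
                           "conserved": rng.random(300) < 0.3})
        _, p = gene_proximity_vs_conservation(df, n_perm=1000,
                                              rng=np.random.default_rng(4))
        assert p > 0.001


class TestMirnaExpectation:
    def test_perfect_complement_zero(self):
        m = "ACGUACGUACGUACGUACGU"  # 20 nt
        target = "TTTT" + revcomp(m.replace("U", "T")) + "TTTT"
        score, pos = mirna_expectation(target, m)
        assert score == 0.0 and pos == 4

    def test_wobble_position_weights(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def perfect_target(m):
            k = len(m)
            return [comp[m[k - 1 - j]] for j in range(k)]

        # miRNA G at position 15 against target U: wobble outside the
        # 2-13 seed scores +0.5
        m15 = "A" * 14 + "G" + "A" * 5
        t = perfect_target(m15)
        t[20 - 15] = "T"  # the base pairing miRNA position 15
        s15, _ = mirna_expectation("".join(t), m15)
        assert s15 == pytest.approx(0.5)
        # the same wobble at position 5, inside the seed, is doubled
        m5 = "A" * 4 + "G" + "A" * 15
        t = perfect_target(m5)
        t[20 - 5] = "T"
        s5, _ = mirna_expectation("".join(t), m5)
        assert s5 == pytest.approx(1.0)

    def test_matches_bruteforce_offset_scan(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def brute(t, m, k=20):
            m = m[:k]
            best = None
            for off in range(len(t) - len(m) + 1):
                s = 0.0
                for i, mb in enumerate(m):
                    tb = t[off + len(m) - 1 - i]
                    if tb == comp[mb]:
                        pen = 0.0
                    elif (mb, tb) in (("G", "T"), ("T", "G")):
                        pen = 0.5
                    else:
                        pen = 1.0
                    if 2 <= i + 1 <= 13:
                        pen *= 2
                    s += pen
                if best is None or s < best:
                    best = s
            return best

        from conftest import random_dna
        for _ in range(50):
            t = random_dna(rng, int(rng.integers(40, 120)))
            m = random_dna(rng, 20)
            expected = brute(t, m)
            got = mirna_expectation(t, m, cutoff=float("inf"))
            assert got[0] == pytest.approx(expected)

    def test_cutoff_filters(self, rng):
        from conftest import random_dna
        t = random_dna(rng, 300)
        m = random_dna(rng, 20)
        assert mirna_expectation(t, m, cutoff=2.0) is None or \
            mirna_expectation(t, m, cutoff=2.0)[0] <= 2.0


class TestNussinov:
    def test_hairpin_example(self):
        assert nussinov_pairs("GGGAAACCC") == 3
        assert mfe_proxy_per_nt("GGGAAACCC") == pytest.approx(-3 / 9)

    def test_unpairable_sequence(self):
        assert nussinov_pairs("AAAAAAA") == 0
        assert mfe_proxy_per_nt("AAAAAAA") == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        """DP equals brute-force maximum over all nested structures."""
        import functools
        pairs = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
                 ("G", "T"), ("T", "G")}

        def brute(seq, min_loop=3):
            @functools.lru_cache(None)
            def f(i, j):
                if j - i < min_loop + 1:
                    return 0
                best = f(i + 1, j)
                for k in range(i + min_loop + 1, j + 1):
                    if (seq[i], seq[k]) in pairs:
                        best = max(best, 1 + f(i + 1, k - 1) + f(k + 1, j))
                return best
            return f(0, len(seq) - 1) if seq else 0

        from conftest import random_dna
        for _ in range(80):
            s = random_dna(rng, int(rng.integers(1, 13)))
            assert nussinov_pairs(s) == brute(s)
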