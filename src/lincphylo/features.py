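"""Feature annotation and conservation-correlate statistics.

Per-locus features: TE overlap class (inside with >= 10 nt, within
100 bp, within 500 bp, none), CNS overlap (any >= 1 nt), distance to
the nearest protein-coding gene, mean FPKM over four tissues,
stress-responsiveness, a secondary-structure proxy (Nussinov base-pair
maximization per nt), and miRNA target sites scored with a
psRNATarget-style expectation score.

Statistics mirror the conservation-correlate analyses: proportions
stratified by conservation depth with Fisher's exact tests against the
shallowest bin, log-expression vs depth by least squares with Pearson's
r, and a permutation test for gene-proximity vs conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numba import njit
from scipy import stats

from .genome import encode
from .intervals import GenomeInterval

LOG_FPKM_PSEUDOCOUNT = 0.01


@dataclass
class FeatureRecord:
    locus_id: str
    depth_age_Mya: float = 0.0
    conserved: bool = False
    te_class: str = "none"
    cns_overlap: bool = False
    nearest_gene_bp: int = -1
    mean_fpkm: float = float("nan")
    stress_responsive: bool = False
    mfe_proxy_per_nt: float = 0.0
    mirna_hits: list = field(default_factory=list)  # (mirna_id, score, pos)


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------

def interval_overlap_class(locus: GenomeInterval,
                           annot: list[GenomeInterval],
                           min_nt: int = 10,
                           near_bps: tuple[int, ...] = (100, 500)) -> str:
    """Overlap class of a locus against an annotation track.

    ``inside`` iff some annotation interval overlaps the locus by at
    least ``min_nt``; otherwise ``within_<d>bp`` for the smallest
    configured distance d with an interval within d bp on the same
    chromosome; otherwise ``none``. For CNS use min_nt=1.
    """
    best_gap = None
    for iv in annot:
        if (iv.species_id, iv.chrom) != (locus.species_id, locus.chrom):
            continue
        if locus.overlap(iv) >= min_nt:
            return "inside"
        if locus.overlap(iv) > 0:
            gap = 0  # sub-threshold overlap counts as distance zero
        else:
            gap = locus.gap_to(iv)
        if gap is not None:
            best_gap = gap if best_gap is None else min(best_gap, gap)
    if best_gap is not None:
        for d in sorted(near_bps):
            if best_gap <= d:
                return f"within_{d}bp"
    return "none"


def nearest_distance(locus: GenomeInterval,
                     annot: list[GenomeInterval]) -> int | None:
    """Distance to the nearest interval of a track (0 if overlapping)."""
    best = None
    for iv in annot:
        if (iv.species_id, iv.chrom) != (locus.species_id, locus.chrom):
            continue
        g = locus.gap_to(iv)
        if g is not None:
            best = g if best is None else min(best, g)
    return best


def build_interval_tree(annot: list[GenomeInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in annot:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table -> (p, odds ratio).

    p sums the hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one. The odds
    ratio is (a d)/(b c), with inf when b c = 0 and a d > 0, and nan
    for the doubly degenerate 0/0 case.
    """
    ((a, b), (c, d)) = table
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    return float(res.pvalue), odds


def depth_stratified_proportions(records: pd.DataFrame, flag: str,
                                 depth_col: str = "depth_age_Mya") -> pd.DataFrame:
    """Per-depth-bin proportion of a boolean flag, with Fisher tests.

    Loci are binned by conservation-depth age; each deeper bin is
    tested (Fisher's exact, two-sided) against the shallowest bin
    (the species-specific loci).
    """
    df = records.dropna(subset=[flag]).copy()
    df[flag] = df[flag].astype(bool)
    ages = sorted(df[depth_col].unique())
    rows = []
    base = df[df[depth_col] == ages[0]]
    b_yes, b_no = int(base[flag].sum()), int((~base[flag]).sum())
    for age in ages:
        sub = df[df[depth_col] == age]
        yes, no = int(sub[flag].sum()), int((~sub[flag]).sum())
        if age == ages[0]:
            p = 1.0
        else:
            p, _ = fisher_exact([[yes, no], [b_yes, b_no]])
        prop = 100.0 * yes / max(1, yes + no)
        rows.append((age, yes, yes + no, round(prop, 4), p))
    return pd.DataFrame(rows, columns=[
        "depth_age_Mya", "n_flagged", "n_total", "pct", "fisher_p_vs_shallowest"])


def expression_depth_correlation(records: pd.DataFrame,
                                 fpkm_col: str = "mean_fpkm",
                                 depth_col: str = "depth_age_Mya"):
    """Pearson r and OLS slope of log10(FPKM + 0.01) on depth age.

    Records without expression are excluded. Returns (r, slope, p,
    n) with p the t-test p-value for the slope.
    """
    df = records.dropna(subset=[fpkm_col])
    x = df[depth_col].to_numpy(dtype=float)
    y = np.log10(df[fpkm_col].to_numpy(dtype=float) + LOG_FPKM_PSEUDOCOUNT)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0, 1.0, len(x)
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.pvalue), len(x)


def gene_proximity_vs_conservation(records: pd.DataFrame,
                                   n_perm: int = 10_000,
                                   rng: np.random.Generator | None = None):
    """Point-biserial correlation of conservation with gene distance.

    Permutation p-value over ``n_perm`` shuffles of the conserved flag
    (two-sided on |r|). Constant proximity returns r = 0 by convention.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    df = records.dropna(subset=["nearest_gene_bp"])
    df = df[df.nearest_gene_bp >= 0]
    y = df["nearest_gene_bp"].to_numpy(dtype=float)
    g = df["conserved"].to_numpy(dtype=bool)
    if len(y) < 3 or np.ptp(y) == 0 or g.all() or not g.any():
        return 0.0, 1.0
    gz = (g - g.mean()) / g.std()
    yz = (y - y.mean()) / y.std()
    r_obs = float(np.mean(gz * yz))
    # permutation null on the flag, vectorized in blocks
    count = 0
    for start in range(0, n_perm, 500):
        b = min(500, n_perm - start)
        perms = np.argsort(rng.random((b, len(g))), axis=1)
        rs = (gz[perms] * yz).mean(axis=1)
        count += int((np.abs(rs) >= abs(r_obs)).sum())
    return r_obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# miRNA expectation score
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def mirna_expectation(lincrna: str, mirna: str, score_len: int = 20,
                      cutoff: float = 2.0) -> tuple[float, int] | None:
    """Best psRNATarget-style expectation score of a miRNA on a target.

    The miRNA (given 5'->3', T==U) is slid over the target at every
    ungapped offset; within each window of up to ``score_len`` miRNA
    positions: perfect complement 0, G:U wobble +0.5, mismatch +1, with
    penalties doubled at miRNA positions 2-13 (the 5' seed). Returns
    (best score, 0-based target start) or None when no window scores
    at or below the cutoff.
    """
    t = encode(lincrna.upper().replace("U", "T"))
    m = encode(mirna.upper().replace("U", "T"))[:score_len]
    k = len(m)
    if k == 0 or len(t) < k:
        return None
    n_off = len(t) - k + 1
    # miRNA position i (0-based) pairs target base at off + (k - 1 - i):
    # the duplex is antiparallel, miRNA 5' end meets target 3' end
    comp = np.array([3, 2, 1, 0, 9], dtype=np.int16)  # N complements nothing
    tgt = np.lib.stride_tricks.sliding_window_view(t, k)[:, ::-1].astype(np.int16)
    mb = m.astype(np.int16)[None, :]
    pen = np.ones((n_off, k))
    pen[tgt == comp[m][None, :]] = 0.0
    wobble = ((mb == 2) & (tgt == 3)) | ((mb == 3) & (tgt == 2))
    pen[wobble & (pen > 0)] = 0.5
    seed = (np.arange(1, k + 1) >= 2) & (np.arange(1, k + 1) <= 13)
    pen[:, seed] *= 2.0
    scores = pen.sum(axis=1)
    off = int(np.argmin(scores))
    best = float(scores[off])
    if best > cutoff:
        return None
    return best, off


# ---------------------------------------------------------------------------
# structure proxy
# ---------------------------------------------------------------------------

_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}  # AU/UA CG/GC GU/UG


def nussinov_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (AU, GC, GU; hairpin >= 3)."""
    x = encode(seq.upper().replace("U", "T"))
    n = len(x)
    if n == 0:
        return 0
    pairable = np.zeros((5, 5), dtype=np.bool_)
    for a, b in _PAIRS:
        pairable[a, b] = True
    return int(_nussinov_kernel(x, pairable, min_loop))


@njit(cache=True)
def _nussinov_kernel(x, pairable, min_loop):
    n = len(x)
    dp = np.zeros((n, n), dtype=np.int32)
    for s in range(min_loop + 1, n):
        for i in range(n - s):
            j = i + s
            best = dp[i + 1, j - 1] + 1 if pairable[x[i], x[j]] else 0
            if dp[i + 1, j] > best:
                best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp[0, n - 1]


def mfe_proxy_per_nt(seq: str, min_loop: int = 3) -> float:
    """Length-normalized folding proxy: -(max base pairs)/length.

    Stands in for a thermodynamic minimum free energy per nt: more
    pairable sequence gives a more negative value.
    """
    if len(seq) == 0:
        return 0.0
    return -nussinov_pairs(seq, min_loop) / len(seq)
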