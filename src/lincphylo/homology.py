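"""Seeded nucleotide similarity search and homolog promotion.

The engine finds exact shared k-mers (default k=8) on both strands,
clusters them by diagonal (two-hit rule), and computes the optimal local
alignment over each cluster window under the +1/-2 match/mismatch and
5 + 2L affine gap costs. Significance is the Karlin-Altschul E-value
E = K * m * n * exp(-lambda * S).

A hit becomes a homolog call only after the three published criteria:
sequence similarity (E <= strict cutoff), reciprocity (the hit, searched
back against the focal genome, returns the query locus), and synteny
(a flanking-gene anchor maps near the hit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .align import local_align_banded
from .config import PipelineConfig, ScoringScheme
from .genome import Genome, encode, kmer_codes, revcomp_codes
from .intervals import GenomeInterval

# diagonal band within which seeds are clustered together, the flanking
# pad added around a cluster window before alignment, and a cap on how
# many clusters are extended per (chromosome, strand), best-seeded first
_DIAG_BAND = 3
_WINDOW_PAD = 48
_MAX_CLUSTERS = 40


@dataclass(frozen=True)
class LocusHit:
    """A similarity hit of one query in one subject genome."""

    query_id: str
    interval: GenomeInterval
    score: int
    evalue: float
    q_span: tuple[int, int]

    def sort_key(self):
        return (self.evalue, -self.score, self.interval.chrom, self.interval.start)


@dataclass(frozen=True)
class HomologCall:
    """A top hit annotated with the reciprocity and synteny checks."""

    hit: LocusHit
    reciprocal: bool
    syntenic: bool
    gene_overlap: str | None = None

    def is_homolog(self, strict_evalue: float) -> bool:
        return self.reciprocal and self.syntenic and self.hit.evalue <= strict_evalue


def _cluster_seeds(qpos: np.ndarray, gpos: np.ndarray, query_len: int,
                   min_seeds: int = 1, k: int = 0):
    """Group seeds into tight diagonal clusters.

    Seeds are sorted by (diagonal, genome position); a new cluster
    starts when the diagonal jumps by more than the band (indels shift
    the diagonal by their length, so nearby diagonals are one cluster)
    or the genome position jumps by more than the query length.
    Clusters with fewer than ``min_seeds`` seeds — or, when
    ``min_seeds > 1``, spanning less than one word length on the query
    (overlapping k-mers of a single short exact match are not
    independent evidence) — are dropped. Returns (qlo, qhi, glo, ghi,
    diag_lo, diag_hi, n) tuples sorted by descending seed count.
    """
    diag = gpos - qpos
    order = np.lexsort((gpos, diag))
    diag, qpos, gpos = diag[order], qpos[order], gpos[order]
    brk = np.empty(len(diag), dtype=bool)
    brk[0] = True
    dd = np.diff(diag)
    dg = np.diff(gpos)
    brk[1:] = (dd > _DIAG_BAND) | ((dd == 0) & (dg > query_len + 64)) | (dd < 0)
    starts = np.nonzero(brk)[0]
    sizes = np.diff(np.append(starts, len(diag)))
    qlo = np.minimum.reduceat(qpos, starts)
    qhi = np.maximum.reduceat(qpos, starts)
    glo = np.minimum.reduceat(gpos, starts)
    ghi = np.maximum.reduceat(gpos, starts)
    dlo = np.minimum.reduceat(diag, starts)
    dhi = np.maximum.reduceat(diag, starts)
    keep = sizes >= min_seeds
    if min_seeds > 1:
        keep &= (qhi - qlo) >= k
    idx = np.nonzero(keep)[0]
    out = []
    for i in idx:
        a, b = starts[i], starts[i] + sizes[i]
        # independent evidence = words in distinct query windows of
        # size k (overlapping k-mers of one exact run count once)
        n_indep = len(np.unique(qpos[a:b] // max(1, k)))
        if n_indep < min_seeds:
            continue
        out.append((int(qlo[i]), int(qhi[i]), int(glo[i]), int(ghi[i]),
                    int(dlo[i]), int(dhi[i]), n_indep))
    out.sort(key=lambda c: (-c[6], c[2]))
    return out


def _search_one_strand(q: np.ndarray, query_id: str, genome: Genome,
                       scheme: ScoringScheme, e_cutoff: float,
                       strand: str, orig_len: int) -> list[LocusHit]:
    k = scheme.word_size
    qpos_all, qcodes = kmer_codes(q, k)
    if len(qpos_all) == 0:
        return []
    db_len = genome.total_length
    if len(q) < 3 * k:
        min_seeds = 1
    elif e_cutoff <= 1e-10:
        # a strict-significance hit implies high identity, hence many
        # independent words; 4+ filters diagonal coincidences cheaply
        min_seeds = 4
    else:
        min_seeds = 2
    hits: list[LocusHit] = []
    idx = genome.global_index(k)
    qpos, gpos = idx.lookup_many(qcodes, qpos_all)
    if len(gpos) == 0:
        return hits
    aligned: list[tuple[int, int]] = []
    n_ext = 0
    for qlo, qhi, glo, ghi, dmin, dmax, n in _cluster_seeds(
            qpos, gpos, len(q), min_seeds=min_seeds, k=k):
        if n_ext >= _MAX_CLUSTERS:
            break
        # skip clusters already covered by an aligned window
        if any(ws <= glo and ghi <= we for ws, we in aligned):
            continue
        n_ext += 1
        ci, chrom, glo_local = idx.locate(glo)
        codes = genome.chroms[chrom]
        off = int(idx.offsets[ci])
        ghi_local = min(ghi - off, len(codes) - 1)
        w_start = max(0, glo_local - qlo - _WINDOW_PAD)
        w_end = min(len(codes), ghi_local + k + (len(q) - qhi) + _WINDOW_PAD)
        aligned.append((w_start + off, w_end + off))
        # diagonal band (window coords) covering the cluster's seeds
        score, qs, qe, ss, se = local_align_banded(
            q, codes[w_start:w_end], (dmin - off) - w_start,
            (dmax - off) - w_start, scheme)
        if score <= 0:
            continue
        ev = scheme.evalue(score, len(q), db_len)
        if ev > e_cutoff:
            continue
        if strand == "-":
            q_span = (orig_len - qe, orig_len - qs)
        else:
            q_span = (qs, qe)
        hits.append(LocusHit(
            query_id=query_id,
            interval=GenomeInterval(genome.species_id, chrom,
                                    w_start + ss, w_start + se, strand),
            score=score, evalue=ev, q_span=q_span))
    return hits


def _dedupe(hits: list[LocusHit]) -> list[LocusHit]:
    """Drop hits contained in a better same-strand hit (adjacent clusters
    can rediscover the same alignment)."""
    out: list[LocusHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.interval.start)):
        iv = h.interval
        if any(o.interval.strand == iv.strand and o.interval.chrom == iv.chrom
               and o.interval.start <= iv.start and iv.end <= o.interval.end
               for o in out):
            continue
        out.append(h)
    return out


def search(query: str | np.ndarray, genome: Genome, scheme: ScoringScheme,
           e_cutoff: float, query_id: str = "query") -> list[LocusHit]:
    """All significant local hits of ``query`` in ``genome``, both strands.

    Returns hits with E <= ``e_cutoff`` sorted by ascending E-value.
    Queries shorter than the word size produce an empty result with a
    warning (no seed can exist).
    """
    q = encode(query) if isinstance(query, str) else np.asarray(query, dtype=np.uint8)
    if len(q) < scheme.word_size:
        warnings.warn(f"query {query_id!r} shorter than word size "
                      f"{scheme.word_size}; no hits possible")
        return []
    hits = _search_one_strand(q, query_id, genome, scheme, e_cutoff, "+", len(q))
    hits += _search_one_strand(revcomp_codes(q), query_id, genome, scheme,
                               e_cutoff, "-", len(q))
    return sorted(_dedupe(hits), key=LocusHit.sort_key)


def merge_hits(hits: list[LocusHit], query_len: int) -> list[LocusHit]:
    """Union same-chromosome, same-strand hits closer than the query length.

    Two hits whose gap is smaller than the original query size are merged
    into one interval; the merged hit keeps the best score and E-value.
    Idempotent.
    """
    groups: dict[tuple, list[LocusHit]] = {}
    for h in hits:
        groups.setdefault((h.interval.species_id, h.interval.chrom,
                           h.interval.strand), []).append(h)
    out: list[LocusHit] = []
    for _, group in sorted(groups.items()):
        group.sort(key=lambda h: (h.interval.start, h.interval.end))
        cur = group[0]
        for h in group[1:]:
            gap = h.interval.start - cur.interval.end
            if gap < query_len:
                best = cur if (cur.evalue, -cur.score) <= (h.evalue, -h.score) else h
                cur = replace(best, interval=replace(
                    cur.interval, start=min(cur.interval.start, h.interval.start),
                    end=max(cur.interval.end, h.interval.end)),
                    score=max(cur.score, h.score),
                    evalue=min(cur.evalue, h.evalue))
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return sorted(out, key=LocusHit.sort_key)


def top_hit(hits: list[LocusHit]) -> LocusHit | None:
    """Minimal E-value; ties by higher score, then (chrom, start)."""
    if not hits:
        return None
    return min(hits, key=LocusHit.sort_key)


def check_reciprocity(hit: LocusHit, subject_genome: Genome,
                      focal_genome: Genome, query_interval: GenomeInterval,
                      scheme: ScoringScheme, e_cutoff: float) -> bool:
    """Back-search the hit sequence against the focal genome.

    True iff the merged top back-hit overlaps the original query
    interval by >= 1 bp (strand ignored).
    """
    subject_seq = subject_genome.fetch_codes(hit.interval)
    back = search(subject_seq, focal_genome, scheme, e_cutoff,
                  query_id=f"{hit.query_id}|back")
    back = merge_hits(back, len(subject_seq))
    best = top_hit(back)
    if best is None:
        return False
    iv = best.interval
    probe = GenomeInterval(iv.species_id, iv.chrom, iv.start, iv.end, ".")
    target = GenomeInterval(query_interval.species_id, query_interval.chrom,
                            query_interval.start, query_interval.end, ".")
    return probe.overlap(target) >= 1


def anchor_top_hits(anchor_seqs, subject_genome: Genome,
                    scheme: ScoringScheme, e_cutoff: float) -> list[LocusHit]:
    """Merged top hit of each flanking anchor in the subject genome."""
    tops = []
    for i, seq in enumerate(anchor_seqs):
        if seq is None or len(seq) == 0:
            continue
        hs = search(seq, subject_genome, scheme, e_cutoff, query_id=f"anchor{i}")
        hs = merge_hits(hs, len(seq))
        t = top_hit(hs)
        if t is not None:
            tops.append(t)
    return tops


def check_synteny(hit: LocusHit, anchor_hits: list[LocusHit],
                  config: PipelineConfig) -> bool:
    """True iff an anchor's top hit lies within the synteny window of the hit.

    ``anchor_hits`` are the subject-genome top hits of the focal query's
    flanking protein-coding genes (or 5-kb flank sequences when genes
    are absent), from :func:`anchor_top_hits`.
    """
    for a in anchor_hits:
        gap = hit.interval.gap_to(a.interval)
        if gap is not None and gap <= config.synteny_window_bp:
            return True
    return False
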