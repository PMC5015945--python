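"""Family construction, conservation criterion, and coding filters.

A family is one focal query lincRNA plus at most one promoted homolog
per subject species. A family is *conserved* when it contains at least
``min_family_species`` species (counting the focal one) with at least
one member from lineage II — i.e. the locus was present in the common
ancestor of the two lineages. Conservation depth is the MRCA of the
focal species and the most divergent species with a member.

Two filters flag families whose conservation is explained by coding
potential rather than a conserved noncoding locus: a long-ORF screen on
the query, and a permutation test for a conserved reading frame across
the family alignment (synonymous substitutions outnumbering
nonsynonymous ones and frame disruptions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import glocal_project
from .config import PipelineConfig, ScoringScheme
from .genome import Genome, encode, revcomp_codes
from .homology import HomologCall, LocusHit, merge_hits, search, top_hit
from .tree import Clade, SpeciesTree

GAP = 5  # alignment gap code (bases are 0..3, N is 4)

# codon -> amino acid lookup over codes 0..63 (AAA..TTT, base order ACGT)
_BASES = "ACGT"
_CODON_AA = np.empty(64, dtype="U1")
from Bio.Seq import Seq as _Seq  # noqa: E402

for _i in range(64):
    codon = _BASES[_i >> 4] + _BASES[(_i >> 2) & 3] + _BASES[_i & 3]
    _CODON_AA[_i] = str(_Seq(codon).translate())


@dataclass
class Family:
    """One query lincRNA and its homologous loci across species."""

    query_id: str
    members: dict[str, LocusHit] = field(default_factory=dict)  # species -> hit
    lineage_ii: bool = False
    conserved: bool = False
    depth_label: str | None = None
    depth_age: float = 0.0
    coding_orf: bool = False
    known_ncrna: bool = False
    coding_pvalue: float | None = None

    @property
    def n_species(self) -> int:
        return len(self.members) + 1  # + focal

    def species(self) -> list[str]:
        return sorted(self.members)


def build_families(calls: dict[str, dict[str, HomologCall]],
                   tree: SpeciesTree, config: PipelineConfig) -> list[Family]:
    """Assemble per-query families and enforce member uniqueness.

    ``calls`` maps query_id -> species -> HomologCall (the top hit of
    that query in that species, annotated). Only promoted calls
    (reciprocal, syntenic, strict E-value) become members. A locus
    claimed by more than one family goes to the family where it has the
    lowest E-value (ties: higher score, then lexicographic query id)
    and is removed from the others.
    """
    families = {qid: Family(query_id=qid) for qid in sorted(calls)}
    claims = []  # (evalue, -score, query_id, species, hit)
    for qid in sorted(calls):
        for sp, call in sorted(calls[qid].items()):
            if call is not None and call.is_homolog(config.strict_evalue):
                claims.append((call.hit.evalue, -call.hit.score, qid, sp, call.hit))
    claims.sort(key=lambda c: (c[0], c[1], c[2]))
    accepted: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for ev, negs, qid, sp, hit in claims:
        key = (sp, hit.interval.chrom)
        taken = accepted.setdefault(key, [])
        if any(s < hit.interval.end and hit.interval.start < e
               for s, e, _ in taken):
            continue  # overlaps a better claim: contested locus lost
        taken.append((hit.interval.start, hit.interval.end, qid))
        families[qid].members[sp] = hit

    lineage_II = {sp for sp, lin in tree.lineage.items() if lin == "II"}
    for fam in families.values():
        fam.lineage_ii = bool(set(fam.members) & lineage_II)
        fam.conserved = (fam.n_species >= config.min_family_species) \
            and fam.lineage_ii
        node = tree.mrca([tree.focal] + list(fam.members)) if fam.members \
            else tree.leaf(tree.focal)
        fam.depth_label, fam.depth_age = node.label, node.age
    return [families[qid] for qid in sorted(families)]


# ---------------------------------------------------------------------------
# coding filters
# ---------------------------------------------------------------------------

def orf_screen(seq: str, threshold_aa: int = 100) -> bool:
    """True iff any of the six reading frames holds an ORF > threshold aa.

    An ORF is ATG..stop; its length in amino acids counts the initiator
    Met and excludes the stop, so ATG + 99 codons + TAA is exactly 100
    aa and does NOT trip a threshold of 100.
    """
    from .genome import revcomp

    for s in (seq.upper(), revcomp(seq.upper())):
        for frame in range(3):
            start = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i:i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in ("TAA", "TAG", "TGA") and start is not None:
                    if (i - start) // 3 > threshold_aa:
                        return True
                    start = None
    return False


def family_alignment(query_seq: str, member_seqs: dict[str, str],
                     scheme: ScoringScheme) -> tuple[list[str], np.ndarray]:
    """Focal-anchored alignment: members projected onto query columns.

    Each member is globally aligned to the query with free end gaps and
    stacked on the query's coordinates; insertions relative to the query
    are dropped. Both member orientations are tried and the better-
    scoring one kept (homolog intervals are strand-aware, but callers
    may pass plus-strand sequence). Returns (row names, matrix) where
    the matrix holds base codes 0..3, N=4, gap=5; row 0 is the query.
    """
    q = encode(query_seq)
    names = ["query"]
    rows = [q.astype(np.int8)]
    for sp in sorted(member_seqs):
        s = encode(member_seqs[sp])
        sc_f, proj_f = glocal_project(q, s, scheme)
        sc_r, proj_r = glocal_project(q, revcomp_codes(s), scheme)
        proj = proj_f if sc_f >= sc_r else proj_r
        rows.append(np.where(proj < 0, GAP, proj).astype(np.int8))
        names.append(sp)
    return names, np.vstack(rows)


def _coding_statistic(mat: np.ndarray) -> int:
    """Best-frame conserved-ORF statistic of an alignment matrix.

    Per non-query row and codon (relative to the query row's frame):
    +1 for a synonymous difference from the query codon, -1 for a
    nonsynonymous one, -3 for a frame-disrupting gap (gap count not a
    multiple of 3) or an in-frame stop. Maximized over the three frames.
    """
    return int(max(_frame_statistic(mat, f) for f in range(3)))


def _frame_statistic(mat: np.ndarray, frame: int) -> int:
    L = mat.shape[1]
    nc = (L - frame) // 3
    if nc == 0:
        return 0
    sub = mat[:, frame:frame + 3 * nc].reshape(mat.shape[0], nc, 3)
    return int(_frame_statistic_batch(sub[None, ...])[0])


def _frame_statistic_batch(sub: np.ndarray) -> np.ndarray:
    """Vectorized statistic for a batch of (nperm, nseq, ncodon, 3) arrays."""
    valid = (sub < 4).all(axis=3)
    gaps = (sub == GAP).sum(axis=3)
    disrupt = (gaps % 3) != 0
    codon = (np.where(sub < 4, sub, 0) * np.array([16, 4, 1])).sum(axis=3)
    aa = _CODON_AA[codon]
    q_aa = aa[:, :1, :]
    q_codon = codon[:, :1, :]
    q_valid = valid[:, :1, :]
    both = valid[:, 1:, :] & q_valid
    same_codon = (codon[:, 1:, :] == q_codon) & both
    same_aa = (aa[:, 1:, :] == q_aa) & both
    # only stops INTRODUCED relative to the query count against the frame
    stops = (aa[:, 1:, :] == "*") & both & ~same_codon
    syn = (same_aa & ~same_codon & ~stops).sum(axis=(1, 2))
    nonsyn = (~same_aa & both & ~stops).sum(axis=(1, 2))
    bad = disrupt[:, 1:, :].sum(axis=(1, 2)) + stops.sum(axis=(1, 2))
    return syn - nonsyn - 3 * bad


def conserved_coding_test(mat: np.ndarray, n_perm: int = 1000,
                          alpha: float = 0.001,
                          rng: np.random.Generator | None = None
                          ) -> tuple[float | None, bool]:
    """Permutation test for a conserved reading frame across a family.

    The observed statistic is compared to its distribution under random
    column order (column shuffling destroys codon structure but keeps
    the per-column substitution pattern). Returns ``(p, coding_flag)``;
    alignments with fewer than 4 rows are skipped (``(None, False)``),
    mirroring the published protocol which only tested >= 4-taxon
    alignments.
    """
    if mat.shape[0] < 4:
        return None, False
    if rng is None:
        rng = np.random.default_rng(0)
    # restrict to columns without gaps or Ns: column shuffling scatters
    # indel runs and would make any gapped alignment look extreme
    # against its own null regardless of coding structure
    mat = mat[:, (mat < 4).all(axis=0)]
    if mat.shape[1] < 30:
        return None, False
    t_obs = _coding_statistic(mat)
    L = mat.shape[1]
    nc3 = L - (L % 3)
    exceed = 0
    chunk = 200
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((b, L)), axis=1)
        shuffled = mat[:, perms]                   # (nseq, b, L)
        shuffled = np.transpose(shuffled, (1, 0, 2))
        t_perm = np.full(b, -(10 ** 9))
        for f in range(3):
            nc = (L - f) // 3
            if nc == 0:
                continue
            sub = shuffled[:, :, f:f + 3 * nc].reshape(b, mat.shape[0], nc, 3)
            t_perm = np.maximum(t_perm, _frame_statistic_batch(sub))
        exceed += int((t_perm >= t_obs).sum())
        done += b
    p = (1 + exceed) / (1 + n_perm)
    return p, p < alpha


def known_ncrna_screen(query: str, library: Genome | None,
                       scheme: ScoringScheme, e_cutoff: float) -> bool:
    """True iff the query matches the known-ncRNA library at the cutoff.

    The library is an input FASTA (e.g. structured-RNA motifs); an
    absent/empty library screens nothing.
    """
    if library is None or library.total_length == 0:
        return False
    hits = search(query, library, scheme, e_cutoff)
    hits = merge_hits(hits, len(query))
    return top_hit(hits) is not None
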