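"""Loss vs decay classification for species missing a strict homolog.

A conserved family implies the locus existed in the lineage I/II common
ancestor, so a species without a strict homolog either deleted the
locus (*loss*) or diverged past the strict cutoff (*decay*). The
classifier re-searches the query and its flanking anchor genes at the
relaxed cutoff: a relaxed query hit linked to an anchor hit — same
chromosome, within max(10 kb, the focal query-to-anchor distance) — is
decay; anything else is loss.

Per-species proportions are then compared with pairwise two-proportion
score tests under a Bonferroni correction; species whose corrected
tests are non-significant are grouped (connected components).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd
from scipy.stats import norm

from .config import PipelineConfig
from .genome import Genome
from .homology import anchor_top_hits, merge_hits, search
from .intervals import GenomeInterval


@dataclass(frozen=True)
class LossDecayCall:
    family_id: str
    species_id: str
    state: str                              # present | decayed | lost
    relaxed_hit: GenomeInterval | None = None
    anchor_hit: GenomeInterval | None = None
    link_bp: int | None = None


def classify_missing(family_id: str, query_seq: str, anchor_seqs: list,
                     focal_anchor_dist: int, subject_genome: Genome,
                     config: PipelineConfig) -> LossDecayCall:
    """Classify one missing (family, species) pair as decayed or lost.

    ``anchor_seqs`` are the focal flanking-gene (or 5-kb flank)
    sequences; ``focal_anchor_dist`` is the distance from the query
    locus to its nearest anchor gene in the focal genome — the link
    threshold is max(decay_link_bp, this distance), honoring loci whose
    nearest gene is farther than 10 kb.
    """
    scheme = config.scoring
    qhits = merge_hits(search(query_seq, subject_genome, scheme,
                              config.relaxed_evalue, query_id=family_id),
                       len(query_seq))
    ahits = anchor_top_hits(anchor_seqs, subject_genome, scheme,
                            config.relaxed_evalue)
    effective = max(config.decay_link_bp, int(focal_anchor_dist))
    best = None
    for qh in qhits:  # already sorted by ascending E
        for ah in ahits:
            gap = qh.interval.gap_to(ah.interval)
            if gap is not None and gap <= effective:
                best = (qh, ah, gap)
                break
        if best:
            break
    if best:
        qh, ah, gap = best
        return LossDecayCall(family_id, subject_genome.species_id, "decayed",
                             qh.interval, ah.interval, gap)
    return LossDecayCall(
        family_id, subject_genome.species_id, "lost",
        qhits[0].interval if qhits else None,
        ahits[0].interval if ahits else None, None)


def proportion_score_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided score (pooled z) test for a difference of proportions.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion. A degenerate pooled proportion (0 or 1) gives z = 0,
    p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    pool = (x1 + x2) / (n1 + n2)
    if pool <= 0.0 or pool >= 1.0:
        return 0.0, 1.0
    se = (pool * (1 - pool) * (1 / n1 + 1 / n2)) ** 0.5
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), min(1.0, p)


def group_species(calls: list[LossDecayCall] | pd.DataFrame, metric: str,
                  n_evaluated: dict[str, int] | None = None,
                  alpha: float = 0.01) -> pd.DataFrame:
    """Group species whose ``metric`` (decayed|lost) proportions are
    statistically indistinguishable.

    All pairwise score tests are Bonferroni-corrected at
    alpha / C(k, 2); an edge joins each non-significant pair and groups
    are the connected components. Components that are not cliques are
    flagged (the grouping is then order-free but not transitive).
    """
    if isinstance(calls, list):
        df = pd.DataFrame([(c.family_id, c.species_id, c.state) for c in calls],
                          columns=["family_id", "species_id", "state"])
    else:
        df = calls
    species = sorted(df.species_id.unique())
    if n_evaluated is None:
        n_evaluated = df.groupby("species_id").size().to_dict()
    x = {sp: int(((df.species_id == sp) & (df.state == metric)).sum())
         for sp in species}
    n = {sp: int(n_evaluated[sp]) for sp in species}
    n_pairs = max(1, len(species) * (len(species) - 1) // 2)
    thr = alpha / n_pairs
    G = nx.Graph()
    G.add_nodes_from(species)
    for a, b in combinations(species, 2):
        _, p = proportion_score_test(x[a], n[a], x[b], n[b])
        if p >= thr:
            G.add_edge(a, b)
    rows = []
    for gi, comp in enumerate(sorted(nx.connected_components(G), key=min)):
        members = sorted(comp)
        props = [100.0 * x[sp] / n[sp] for sp in members]
        sub = G.subgraph(comp)
        clique = sub.number_of_edges() == len(comp) * (len(comp) - 1) // 2
        rows.append((metric, gi + 1, ",".join(members),
                     round(min(props), 2), round(max(props), 2), clique))
    return pd.DataFrame(rows, columns=[
        "metric", "group", "members", "min_pct", "max_pct", "is_clique"])
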