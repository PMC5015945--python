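"""Search one focal lincRNA against every other genome and apply the
three homolog criteria: similarity (E <= 1e-20), reciprocity, synteny.

Prints the top hit per species and which criteria it passes. Species
beyond the locus' birth node should yield no hit; the rest should pass
all three checks unless the locus was planted lost or decayed there.
"""

from lincphylo.config import PipelineConfig
from lincphylo.evaluation import truth_state
from lincphylo.homology import (anchor_top_hits, check_reciprocity,
                                check_synteny, merge_hits, search, top_hit)
from lincphylo.pipeline import Dataset, find_anchors
from lincphylo.simulate import SimParams, simulate

sim = simulate(SimParams(n_loci=30, rng_seed=4))
ds = Dataset.from_sim(sim)
cfg = PipelineConfig()

# pick a deeply conserved query (born at or above the lineage split)
deep = sim.truth.loci[sim.truth.loci.birth_age >= 42].locus_id
qid, qseq, qiv = next(q for q in ds.queries if q[0] in set(deep))
print(f"query {qid} ({len(qseq)} nt), born {sim.truth.loci.set_index('locus_id').birth_age[qid]:.0f} Mya")

anchors, _ = find_anchors(qiv, ds.genes["Ath"], ds.genomes["Ath"], cfg)
for sp in ds.tree.leaf_names:
    if sp == "Ath":
        continue
    genome = ds.genomes[sp]
    hits = merge_hits(search(qseq, genome, cfg.scoring, cfg.strict_evalue),
                      len(qseq))
    best = top_hit(hits)
    truth = truth_state(sim, qid, sp)  # any surviving copy counts
    if best is None:
        print(f"  {sp:4s}: no hit at 1e-20 (truth: {truth})")
        continue
    recip = check_reciprocity(best, genome, ds.genomes["Ath"], qiv,
                              cfg.scoring, cfg.strict_evalue)
    ahits = anchor_top_hits(anchors, genome, cfg.scoring, cfg.strict_evalue)
    synt = check_synteny(best, ahits, cfg)
    mark = "homolog" if (recip and synt) else "rejected"
    print(f"  {sp:4s}: {best.interval.chrom}:{best.interval.start}-"
          f"{best.interval.end}({best.interval.strand}) score={best.score} "
          f"E={best.evalue:.1e} reciprocal={recip} syntenic={synt} "
          f"-> {mark} (truth: {truth})")
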