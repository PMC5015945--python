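"""Cluster homolog calls into families and apply the conservation
criterion: at least four species including one from lineage II means
the locus already existed in the lineage I/II common ancestor (~42 Mya).

Each family is also screened for coding potential (long ORFs and a
permutation test for a conserved reading frame) and against a known-
ncRNA library; conserved families failing neither screen form the
conserved noncoding set.
"""

from lincphylo.config import PipelineConfig
from lincphylo.pipeline import (Dataset, conserved_noncoding, families_stage,
                                homology_stage)
from lincphylo.simulate import SimParams, simulate

sim = simulate(SimParams(n_loci=30, rng_seed=4))
ds = Dataset.from_sim(sim)
cfg = PipelineConfig(rng_seed=4)

calls, anchors = homology_stage(ds, cfg)
fams, alignments = families_stage(ds, calls, cfg, n_perm=500)

print(f"{len(fams)} families from {len(ds.queries)} queries")
print(f"{sum(f.conserved for f in fams)} conserved "
      f"(>= {cfg.min_family_species} species incl. lineage II)")
print(f"{len(conserved_noncoding(fams))} conserved and noncoding\n")

print("query     n_sp conserved depth(My) coding_p")
for f in fams:
    if not f.members:
        continue
    p = "-" if f.coding_pvalue is None else f"{f.coding_pvalue:.3f}"
    print(f"{f.query_id:9s} {f.n_species:4d} {str(f.conserved):9s} "
          f"{f.depth_age:8.0f} {p:>8s}")
print("\ndepth(My) is the age of the most recent common ancestor implied "
      "by the most divergent species carrying a homolog")
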