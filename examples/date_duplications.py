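"""Date lincRNA duplications by gene-tree/species-tree reconciliation.

Duplications are planted on the branch entering the lineage I/II
ancestor (42 Mya); gene trees built from all surviving copies are
reconciled and the inferred duplication events are binned by species-
tree node. Most recovered events should sit at the planted node.
"""

from collections import Counter

from lincphylo.config import PipelineConfig
from lincphylo.evaluation import multicopy_duplication_binning
from lincphylo.simulate import SimParams, default_species_tree, simulate

tree = default_species_tree()
split = tree.mrca([sp for sp, lin in tree.lineage.items()
                   if lin in ("I", "II")]).label
params = SimParams(
    n_loci=40, rng_seed=6, dup_prob=0.5, dup_node_labels=(split,),
    decay_prob=0.0, wgd_extra_loss=0.0,
    birth_weights={tree.root.label: 0.3,
                   tree.mrca(["Ath", "Aar"]).label: 0.7},
    tree=tree)
params.tree.wgd.clear()
sim = simulate(params)

print(f"planted {len(sim.truth.duplications)} duplications, all on the "
      f"branch entering node {split} (42 Mya)")

res = multicopy_duplication_binning(sim, PipelineConfig(rng_seed=6))
print(f"\nreconciled {res['n_loci']} gene trees "
      f"({res['n_inferred']} duplication events inferred)")
print(f"planted events recovered: {res['n_recovered']}/{res['n_planted']}")
print(f"recovered events dated to the planted node: "
      f"{100 * res['binned_of_recovered']:.1f}%")
print(f"event-level purity (inferred events at a planted node): "
      f"{100 * res['event_purity']:.1f}%")
print("\nevents at other nodes come from gene-tree estimation noise "
      "(a misplaced leaf with high bootstrap support forces an extra "
      "duplication under parsimony)")
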