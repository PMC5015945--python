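"""Classify missing loci of conserved families as decayed or lost.

A conserved family implies the lineage I/II ancestor carried the locus,
so an ingroup species without a strict homolog either deleted it (loss)
or let it diverge past the strict cutoff (decay). Decay is called when
a relaxed-threshold (1e-5) hit lies within max(10 kb, focal anchor
distance) of a flanking-gene hit on the same chromosome.

Species are then grouped by pairwise two-proportion score tests with a
Bonferroni correction; at realistic family counts the grouping isolates
the mesopolyploid (recent-WGD) species, which lose loci fastest.
"""

from lincphylo.config import PipelineConfig
from lincphylo.evaluation import (lossdecay_accuracy,
                                  planted_rate_group_scenario, wgd_isolation)
from lincphylo.pipeline import (Dataset, families_stage, homology_stage,
                                lossdecay_stage)
from lincphylo.simulate import SimParams, default_species_tree, simulate

sim = simulate(SimParams(n_loci=40, rng_seed=8))
ds = Dataset.from_sim(sim)
cfg = PipelineConfig(rng_seed=8)
calls, anchors = homology_stage(ds, cfg)
fams, _ = families_stage(ds, calls, cfg, n_perm=300)
ldc, lddf, groups = lossdecay_stage(ds, fams, anchors, cfg)

n_missing = (lddf.state != "present").sum()
print(f"{len(lddf)} (family, species) pairs; {n_missing} missing a strict "
      f"homolog and classified:")
print(lddf[lddf.state != "present"]
      .groupby("state").size().to_string())
acc, dec_recall, n = lossdecay_accuracy(sim, ldc)
if n:
    print(f"\nagreement with the planted truth: {100 * acc:.0f}% of {n}")

print("\nspecies grouping at planted mesopolyploid loss rates "
      "(1023 families):")
_, big_groups = planted_rate_group_scenario(8, n_families=1023)
print(big_groups.to_string(index=False))
iso = wgd_isolation(big_groups, default_species_tree(),
                    {"Bra", "Bol", "Lal"}, metric="lost")
print(f"\nWGD species isolated for metric=lost: {iso}")
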