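# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `lincphylo`, in the order the pipeline runs.

## Similarity search and E-values

The engine finds exact shared 8-mers between query and genome (both
strands), clusters seeds by diagonal (seeds within 3 diagonals of each
other and within one query length along the genome form one cluster —
indels shift the diagonal by their length), and demands *independent*
evidence before extending: seeds are counted once per 8-nt query
window, so the overlapping 8-mers of a single chance exact run do not
qualify a cluster. Strict searches (E ≤ 10⁻¹⁰) require 4 independent
words, relaxed searches 2; at most 40 clusters are extended per
genome, best-seeded first. Each surviving cluster window is aligned
with a banded affine Smith–Waterman (band = the cluster's diagonal
range ± 24) under the +1/−2, gap 5 + 2L costs; the start coordinate
comes from re-running the same kernel on reversed prefixes. Within the
band this is the *optimal* local alignment — the engine's scores are
tested for equality against a full dynamic-programming oracle — rather
than a heuristic X-drop extension; realistic alignments (point
substitutions plus 1–5-nt indels) stay inside the band.

E-values use the ungapped Karlin–Altschul theory: λ = 1.3327 solves
¼e^λ + ¾e^(−2λ) = 1 for the +1/−2 scores under uniform base
frequencies, and K is fixed at 0.46, a calibration constant of the
same order BLASTN reports for these scores. Ns never match. m is the
query length and n the total genome length. Because gapped λ is
slightly smaller than ungapped λ, the E-values are mildly conservative
for gapped alignments; every threshold in the pipeline (10⁻²⁰, 10⁻⁵)
was chosen on the same scale, so the comparison is internally
consistent.

Merging unions same-chromosome, same-strand hits whose gap is smaller
than the query length (merged score = max, E = min; the operation is
idempotent). The paper trail for strand handling in merging is empty,
so merging is per-strand by design. Top-hit selection orders by
(E, −score, chromosome, start), which makes every downstream stage
deterministic.

Reciprocity re-searches the hit sequence against the focal genome at
the same strict cutoff (the protocol leaves the back-search cutoff
unstated) and requires ≥ 1 bp overlap with the query locus. Synteny
requires the top subject-genome hit of a flanking anchor (nearest
annotated gene up/downstream, else a 5-kb flank) within 50 kb of the
lincRNA hit — the source protocol fixes the anchors but not a distance
threshold; 50 kb is configurable (`synteny_window_bp`).

## Families and coding screens

Families are per-query, one member per species. Uniqueness across
families is enforced globally: claims are sorted by (E, −score,
query id) and an interval overlapping an already-granted claim in the
same species is dropped. *Conserved* means ≥ 4 species including the
focal one with ≥ 1 lineage-II member; depth is the MRCA of the focal
species and the family's most divergent member, reported as a dated
node.

The family alignment is focal-anchored: each member is globally
aligned to the query (free end gaps, both orientations tried) and
projected onto query columns; insertions relative to the query are
dropped. This replaces a general multiple aligner deterministically
and is exact for the star-shaped families the pipeline builds.

The conserved-reading-frame test computes, over the best of the three
query frames, T = #synonymous − #nonsynonymous − 3·(#frame-disrupting
gaps + #introduced stops), comparing member codons to the query codon.
The null distribution comes from shuffling alignment columns
(default 1000 permutations; p = (1 + #{T* ≥ T})/(1 + N)). Columns
containing a gap or N are removed first: column shuffling scatters
indel runs, and with gaps retained any gapped alignment looks extreme
against its own null regardless of coding structure. Only introduced
stops (codon differs from the query's) count against the frame, so an
alignment of identical sequences scores T = 0 with p = 1. Alignments
with fewer than 4 rows (or fewer than 30 gap-free columns) are not
tested, mirroring the source protocol's ≥ 4-taxon restriction. The
test claims planted-signal recovery — a synonymous-only substitution
process is detected at p < 0.001 — not equivalence to a phylogenetic
codon model.

The ORF screen counts an ORF as ATG..stop with aa length (initiator
included, stop excluded) strictly greater than 100; a 100-aa ORF does
not trip it. The known-ncRNA screen is the same search engine against
a user-supplied FASTA library at the relaxed cutoff.

## Gene trees and reconciliation

Distances are Jukes–Cantor with pairwise deletion of gap/N columns and
a saturation cap d = 5.0 at p ≥ 0.75. Neighbor-joining follows the
Saitou–Nei Q-criterion with negative branch lengths clamped to zero
and ties broken to the lowest index pair. Supports are column-
bootstrap percentages over 100 replicates; an alignment with no
variable column gets supports of 0 (the resampling signal is
undefined).

Reconciliation: internal branches under 70% support are contracted;
every rooting of the collapsed tree is evaluated; polytomies are
resolved exactly (exhaustive enumeration) up to degree 6 and by
species-guided greedy pairing above; the rooting minimizing
(duplications, losses, canonical newick) wins. Events follow LCA
mapping — duplication iff M(v) ∈ {M(children)} — and losses use the
standard path-skip count. The chosen cost is tested for equality
against a brute-force minimum over all rootings and resolutions for
every gene-tree topology up to 6 leaves. Gene-tree leaves may be
plain species names or `species|copy_id` for multi-copy trees.

A structural caveat, measured on simulations: with one member per
species (top hits), most planted duplications are *unidentifiable* —
orthologs out-compete paralogs for the top hit, and a duplication is
visible only when losses leave paralogs as top hits in species
spanning the duplication node. Duplication dating is therefore
validated on fully sampled multi-copy gene trees (every planted copy a
leaf), where events planted on the lineage-split branch are dated to
that node for ≥ 90% of recovered events; the residual misdatings are
gene-tree estimation noise (a misplaced high-support leaf forces an
extra parsimony duplication).

## Loss vs decay

Decay means the locus is still there but diverged past the strict
cutoff: a relaxed (10⁻⁵) query hit on the same chromosome as a relaxed
anchor-gene hit, within max(10 kb, the query's focal-genome anchor
distance). Everything else is loss. Only ingroup (lineage I/II)
species are classified — outgroup absence predates the conserved
ancestor and carries no signal. Species grouping runs all pairwise
two-proportion score tests (pooled-variance z), Bonferroni-corrects at
α/C(k,2), joins non-significant pairs and reports connected
components, flagging components that are not cliques (a proportion
gradient can chain distinguishable species into one component; the
flag makes that visible rather than hiding it).

Decayed recall is rate-limited by information, not implementation: a
decay switch far from the tips accumulates 8× substitutions for tens
of My and falls below even the relaxed threshold, where it is
indistinguishable from a deletion. At the default decay settings
roughly a third of classified truth-decayed loci are in that regime.

## Feature statistics

TE classes: `inside` at ≥ 10 nt overlap, else `within_100bp` /
`within_500bp` by distance (sub-threshold overlap counts as distance
zero), else `none`; CNS overlap needs ≥ 1 nt. Fisher's exact test is
two-sided (conditional hypergeometric; delegated to scipy and verified
against full enumeration). Expression uses log₁₀(mean FPKM + 0.01) —
the pseudocount is ours; the source plots a log scale without stating
a transform — regressed on depth age with Pearson's r. Gene proximity
vs conservation is a point-biserial correlation with a 10 000-shuffle
permutation p. The miRNA expectation score slides the miRNA over the
target at every ungapped offset: complement 0, G:U wobble 0.5,
mismatch 1, doubled at miRNA positions 2–13; a hit needs score ≤ 2.0
over a 20-nt window. Gapped duplexes are not scored: a gap would cost
≥ 2 penalty units and cannot produce a hit the ungapped scan misses at
this cutoff. The folding proxy is Nussinov base-pair maximization
(AU/GC/GU, hairpin ≥ 3), negated and divided by length, standing in
for a thermodynamic MFE per nt; it preserves ordering by pairability,
not absolute energies.

## The generator as study conditions

Defaults: 11-taxon ultrametric chronogram with node ages 13/18/30/
42/54/65 My, focal species `Ath`, lineages I (Ath, Aly, Cru, Cgr, Lal)
and II (Bra, Bol, Spa, Esa), WGD flags on the Bra+Bol ancestor and the
Lal branch; 400-nt loci; birth-node weights 0.30/0.30/0.12/0.08/0.12/
0.05/0.03 from the species-specific tip to the root, emulating the
observed depth distribution; substitution rate 0.002/site/My under
Jukes–Cantor (uniform bases, closed-form calibration); indels at 0.1
per substitution, lengths 1–5; loss 0.02 and decay switching 0.03 per
branch per copy; decay multiplier 8×; local duplication 0.05 per
branch; WGD doubling followed by +0.15 deletion probability on and
below WGD nodes; CNS islands (36 nt, 0.05× rate, never interrupted by
TEs or indels) in 40% of loci; 900-nt anchor genes at 0.2× rate,
always retained and collinear; TEs only near shallow-born loci in the
focal genome (2% inside, 5% within 100 bp, 10% within 500 bp of
eligible loci); log₁₀FPKM ~ N(0.01·birth age, 0.5) with four noisy
tissue replicates; stress flags ~ Bernoulli(logit⁻¹(−2.4 + 0.04·age)),
matching an ~8% baseline among species-specific loci. Queries are the
focal species' surviving original copies — its "annotation".

What the generator does *not* emulate: rate heterogeneity across sites
and lineages (real divergence saturates much faster than JC at equal
path length, which is why real deep-homolog recovery is far below the
simulator's), base-composition bias, structured repeat families,
segmental rearrangements beyond single-locus translocation, and
annotation error in the query set. Passing the recovery tests
therefore demonstrates the pipeline's correctness on data obeying its
own model, not field performance on real genomes.

One deliberate interaction is worth naming: WGD doubling *offsets*
elevated post-WGD deletion at the locus level — a lineage loses its
locus only when every copy is deleted — so the realized loss contrast
between WGD and non-WGD species is much weaker than the per-copy
rates suggest, and at realistic conserved-family counts (~90 per 500
loci) the Bonferroni-corrected grouping cannot isolate the WGD
species from the end-to-end run alone. The grouping statistic is
therefore validated directly at planted per-species rates that mirror
the mesopolyploid pattern (≈12% loss in WGD species, 3–4% in
non-polyploids, <1% in the focal species' sister) with 1023 families,
where isolation is robust.

## Problem sizes and determinism

The end-to-end validation uses 500 loci × 11 genomes (~3.5 Mb each);
calibration runs use 120–200 loci; exhaustive oracles run to 6 leaves
(reconciliation), n = 60 (Fisher) and 12 nt (Nussinov). All
stochastic stages draw from `numpy` Generator streams keyed by
(seed, stage name), so a single seed reproduces every number, and
re-running one stage reproduces its draws regardless of what ran
before it.
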