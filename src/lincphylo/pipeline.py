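"""End-to-end orchestration: homology -> families -> trees -> loss/decay
-> features, over an in-memory dataset or a directory of standard files.

Each stage is a plain function over explicit inputs so that any stage
can be run (and tested) in isolation; :func:`run_all` chains them and
collects the report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reports
from .config import PipelineConfig
from .families import (Family, build_families, conserved_coding_test,
                       family_alignment, known_ncrna_screen, orf_screen)
from .features import (FeatureRecord, depth_stratified_proportions,
                       expression_depth_correlation, fisher_exact,
                       gene_proximity_vs_conservation, interval_overlap_class,
                       mfe_proxy_per_nt, mirna_expectation, nearest_distance)
from .genome import Genome, read_genome
from .homology import (HomologCall, anchor_top_hits, check_reciprocity,
                       check_synteny, merge_hits, search, top_hit)
from .intervals import GenomeInterval
from .loss_decay import LossDecayCall, classify_missing, group_species
from .phylogeny import (ReconciledTree, bootstrap_supports, reconcile,
                        summarize_duplications)
from .tree import SpeciesTree, read_species_tree


@dataclass
class Dataset:
    """Everything the pipeline consumes."""

    tree: SpeciesTree
    genomes: dict[str, Genome]
    queries: list[tuple[str, str, GenomeInterval]]
    genes: dict[str, list[tuple[str, GenomeInterval]]]
    repeats: dict[str, list[tuple[str, GenomeInterval]]] = field(default_factory=dict)
    cns: dict[str, list[tuple[str, GenomeInterval]]] = field(default_factory=dict)
    expression: pd.DataFrame | None = None
    stress: pd.DataFrame | None = None
    mirnas: list[tuple[str, str]] = field(default_factory=list)
    ncrna_library: Genome | None = None

    @classmethod
    def from_sim(cls, sim) -> "Dataset":
        return cls(tree=sim.tree, genomes=sim.genomes, queries=sim.queries,
                   genes=sim.genes, repeats=sim.repeats, cns=sim.cns,
                   expression=sim.truth.expression, stress=sim.truth.stress)

    @classmethod
    def from_dir(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        tree = read_species_tree(path / "species_tree.nwk",
                                 path / "lineages.tsv")
        species = tree.leaf_names
        genomes = {sp: read_genome(path / f"{sp}.fasta", sp) for sp in species}
        genes = {sp: reports.read_gff3_genes(path / f"{sp}.genes.gff3", sp)
                 for sp in species}
        repeats = {sp: reports.read_bed(path / f"{sp}.repeats.bed", sp)
                   for sp in species if (path / f"{sp}.repeats.bed").exists()}
        cns = {sp: reports.read_bed(path / f"{sp}.cns.bed", sp)
               for sp in species if (path / f"{sp}.cns.bed").exists()}
        from Bio import SeqIO
        qseqs = {r.id: str(r.seq) for r in
                 SeqIO.parse(str(path / "queries.fasta"), "fasta")}
        qbed = reports.read_bed(path / "queries.bed", tree.focal)
        queries = [(name, qseqs[name], iv) for name, iv in qbed]
        expr = stress = None
        if (path / "expression.tsv").exists():
            expr = pd.read_csv(path / "expression.tsv", sep="\t")
        if (path / "stress.tsv").exists():
            stress = pd.read_csv(path / "stress.tsv", sep="\t")
        mirnas = []
        if (path / "mirnas.fasta").exists():
            mirnas = [(r.id, str(r.seq)) for r in
                      SeqIO.parse(str(path / "mirnas.fasta"), "fasta")]
        lib = None
        if (path / "ncrna_library.fasta").exists():
            lib = read_genome(path / "ncrna_library.fasta", "ncrna_library")
        return cls(tree=tree, genomes=genomes, queries=queries, genes=genes,
                   repeats=repeats, cns=cns, expression=expr, stress=stress,
                   mirnas=mirnas, ncrna_library=lib)


def find_anchors(query_iv: GenomeInterval, focal_genes, focal_genome: Genome,
                 config: PipelineConfig):
    """Flanking anchors of a focal query: nearest gene up- and downstream
    on its chromosome, or 5-kb flank sequences where genes are absent.

    Returns (anchor_seqs, nearest_gene_distance_bp).
    """
    up = down = None
    for gid, iv in focal_genes:
        if iv.chrom != query_iv.chrom:
            continue
        if iv.end <= query_iv.start:
            if up is None or iv.end > up[1].end:
                up = (gid, iv)
        elif iv.start >= query_iv.end:
            if down is None or iv.start < down[1].start:
                down = (gid, iv)
    seqs, dists = [], []
    for side, fallback in ((up, "up"), (down, "down")):
        if side is not None:
            seqs.append(focal_genome.fetch(side[1]))
            dists.append(query_iv.gap_to(side[1]))
        else:
            L = config.flank_bp_when_no_gene
            if fallback == "up":
                s, e = max(0, query_iv.start - L), query_iv.start
            else:
                s = query_iv.end
                e = min(focal_genome.chrom_length(query_iv.chrom), query_iv.end + L)
            if e - s >= config.scoring.word_size:
                seqs.append(focal_genome.fetch(GenomeInterval(
                    query_iv.species_id, query_iv.chrom, s, e, "+")))
                dists.append(0)
    nearest = min([d for d in dists if d is not None], default=0)
    return seqs, int(nearest)


# ---------------------------------------------------------------------------
# stage 1: homology
# ---------------------------------------------------------------------------

def homology_stage(ds: Dataset, config: PipelineConfig):
    """Top hit + reciprocity + synteny for every (query, subject genome).

    Returns (calls, anchors) where calls[query_id][species] is a
    HomologCall or None and anchors[query_id] = (anchor_seqs, distance).
    """
    scheme = config.scoring
    focal = ds.tree.focal
    focal_genome = ds.genomes[focal]
    calls: dict[str, dict[str, HomologCall | None]] = {}
    anchors: dict[str, tuple[list, int]] = {}
    subject_species = [sp for sp in ds.tree.leaf_names if sp != focal]
    for qid, qseq, qiv in ds.queries:
        anchors[qid] = find_anchors(qiv, ds.genes.get(focal, []),
                                    focal_genome, config)
        calls[qid] = {}
        for sp in subject_species:
            genome = ds.genomes[sp]
            hits = search(qseq, genome, scheme, config.strict_evalue, qid)
            hits = merge_hits(hits, len(qseq))
            best = top_hit(hits)
            if best is None:
                calls[qid][sp] = None
                continue
            recip = check_reciprocity(best, genome, focal_genome, qiv,
                                      scheme, config.strict_evalue)
            ahits = anchor_top_hits(anchors[qid][0], genome, scheme,
                                    config.strict_evalue)
            synt = check_synteny(best, ahits, config)
            overlap_gene = None
            for gid, giv in ds.genes.get(sp, []):
                if best.interval.overlap(giv) >= 1:
                    overlap_gene = gid
                    break
            calls[qid][sp] = HomologCall(hit=best, reciprocal=recip,
                                         syntenic=synt,
                                         gene_overlap=overlap_gene)
    return calls, anchors


# ---------------------------------------------------------------------------
# stage 2: families (+ filters)
# ---------------------------------------------------------------------------

def families_stage(ds: Dataset, calls, config: PipelineConfig,
                   n_perm: int = 1000):
    """Build families, apply the ORF / conserved-ORF / known-ncRNA screens.

    Returns (families, alignments) with alignments cached for the tree
    stage: query-anchored matrices for families with >= 1 member.
    """
    fams = build_families(calls, ds.tree, config)
    qseq = {qid: seq for qid, seq, _ in ds.queries}
    rng = config.rng("coding_test")
    alignments: dict[str, tuple[list[str], np.ndarray]] = {}
    for fam in fams:
        fam.coding_orf = orf_screen(qseq[fam.query_id], config.orf_aa_threshold)
        if ds.ncrna_library is not None:
            fam.known_ncrna = known_ncrna_screen(
                qseq[fam.query_id], ds.ncrna_library, config.scoring,
                config.relaxed_evalue)
        if fam.members:
            member_seqs = {sp: ds.genomes[sp].fetch(hit.interval)
                           for sp, hit in fam.members.items()}
            names, mat = family_alignment(qseq[fam.query_id], member_seqs,
                                          config.scoring)
            names = [ds.tree.focal] + names[1:]
            alignments[fam.query_id] = (names, mat)
            if mat.shape[0] >= 4:
                p, flag = conserved_coding_test(mat, n_perm=n_perm, rng=rng)
                fam.coding_pvalue = p
                fam.coding_orf = fam.coding_orf or flag
    return fams, alignments


def conserved_noncoding(fams: list[Family]) -> list[Family]:
    """The conserved set: conserved families with neither coding nor
    known-ncRNA flag set."""
    return [f for f in fams if f.conserved and not f.coding_orf
            and not f.known_ncrna]


# ---------------------------------------------------------------------------
# stage 3: gene trees + reconciliation
# ---------------------------------------------------------------------------

def trees_stage(ds: Dataset, fams: list[Family], alignments,
                config: PipelineConfig):
    """Bootstrap NJ trees and reconciliation for the conserved set."""
    recs: dict[str, ReconciledTree] = {}
    trees = {}
    for fam in conserved_noncoding(fams):
        if fam.query_id not in alignments:
            continue
        names, mat = alignments[fam.query_id]
        if len(names) < 3:
            continue
        rng = config.rng(f"bootstrap:{fam.query_id}")
        gt = bootstrap_supports(mat, names, reps=config.bootstrap_reps, rng=rng)
        trees[fam.query_id] = gt
        recs[fam.query_id] = reconcile(gt, ds.tree,
                                       collapse_pct=config.support_collapse_pct)
    summary = summarize_duplications(recs, ds.tree,
                                     max_backbone=config.max_backbone_dups)
    return trees, recs, summary


def events_table(recs: dict[str, ReconciledTree],
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-family reconciliation events: one row per duplication, plus
    total-loss and backbone bookkeeping."""
    max_backbone = (config or PipelineConfig()).max_backbone_dups
    rows = []
    for fam_id, rec in sorted(recs.items()):
        backbone_ids = {id(n) for n in rec.species_tree.backbone()}
        if not rec.duplications:
            rows.append((fam_id, "", "", 0, rec.n_loss, False,
                         rec.backbone_dups > max_backbone))
        for k, evname in rec.events.items():
            if evname != "duplication":
                continue
            node = rec.mapping[k]
            rows.append((fam_id, node.label, node.age, 1, rec.n_loss,
                         id(node) in backbone_ids,
                         rec.backbone_dups > max_backbone))
    return pd.DataFrame(rows, columns=[
        "family", "node", "age_Mya", "n_dup", "n_loss", "backbone_flag",
        "excluded_highly_duplicated"])


# ---------------------------------------------------------------------------
# stage 4: loss / decay
# ---------------------------------------------------------------------------

def lossdecay_stage(ds: Dataset, fams: list[Family], anchors,
                    config: PipelineConfig):
    """Classify every missing species of every conserved family."""
    qseq = {qid: seq for qid, seq, _ in ds.queries}
    focal = ds.tree.focal
    calls: list[LossDecayCall] = []
    conserved = conserved_noncoding(fams)
    # only ingroup species: a conserved family implies presence in the
    # lineage I/II ancestor, so absence there is loss or decay; outgroup
    # absence predates the locus and is uninformative
    ingroup = [sp for sp in ds.tree.leaf_names
               if sp != focal and ds.tree.lineage.get(sp) in ("I", "II")]
    for fam in conserved:
        aseqs, adist = anchors[fam.query_id]
        for sp in ingroup:
            if sp in fam.members:
                calls.append(LossDecayCall(fam.query_id, sp, "present"))
                continue
            calls.append(classify_missing(fam.query_id, qseq[fam.query_id],
                                          aseqs, adist, ds.genomes[sp], config))
    n_eval = {sp: len(conserved) for sp in ingroup}
    df = pd.DataFrame(
        [(c.family_id, c.species_id, c.state,
          str(c.relaxed_hit) if c.relaxed_hit else "",
          str(c.anchor_hit) if c.anchor_hit else "",
          c.link_bp if c.link_bp is not None else "")
         for c in calls],
        columns=["family_id", "species_id", "state", "relaxed_hit",
                 "anchor_hit", "link_bp"])
    groups = pd.concat([group_species(df, "decayed", n_eval),
                        group_species(df, "lost", n_eval)],
                       ignore_index=True)
    return calls, df, groups


def control_lossdecay(ds: Dataset, fams: list[Family],
                      config: PipelineConfig,
                      max_loci: int | None = None) -> pd.DataFrame:
    """Loss/decay of protein-coding control loci (the flanking genes).

    The upstream anchor gene of each conserved family is run through
    the same classification (with the downstream gene as its anchor);
    slow-evolving, never-deleted genes should come out overwhelmingly
    present, mirroring the protein-coding comparison lincRNA turnover
    is judged against.
    """
    focal = ds.tree.focal
    gene_by_id = {gid: iv for gid, iv in ds.genes.get(focal, [])}
    ingroup = [sp for sp in ds.tree.leaf_names
               if sp != focal and ds.tree.lineage.get(sp) in ("I", "II")]
    rows = []
    conserved = conserved_noncoding(fams)
    if max_loci is not None:
        conserved = conserved[:max_loci]
    for fam in conserved:
        gl, gr = f"{fam.query_id}_gL", f"{fam.query_id}_gR"
        if gl not in gene_by_id or gr not in gene_by_id:
            continue
        qseq = ds.genomes[focal].fetch(gene_by_id[gl])
        anchor = [ds.genomes[focal].fetch(gene_by_id[gr])]
        dist = gene_by_id[gl].gap_to(gene_by_id[gr]) or 0
        for sp in ingroup:
            hits = merge_hits(search(qseq, ds.genomes[sp], config.scoring,
                                     config.strict_evalue, gl), len(qseq))
            if top_hit(hits) is not None:
                rows.append((gl, sp, "present"))
                continue
            call = classify_missing(gl, qseq, anchor, dist,
                                    ds.genomes[sp], config)
            rows.append((gl, sp, call.state))
    return pd.DataFrame(rows, columns=["family_id", "species_id", "state"])


# ---------------------------------------------------------------------------
# stage 5: features
# ---------------------------------------------------------------------------

def features_stage(ds: Dataset, fams: list[Family], config: PipelineConfig,
                   compute_mfe: bool = True):
    """Per-locus feature records and the conservation-correlate tests."""
    focal = ds.tree.focal
    fam_by_q = {f.query_id: f for f in fams}
    noncoding = {f.query_id for f in conserved_noncoding(fams)}
    expr = mean_fpkm_by_locus(ds.expression)
    stress = stress_by_locus(ds.stress)
    recs = []
    for qid, qseq, qiv in ds.queries:
        fam = fam_by_q[qid]
        rec = FeatureRecord(locus_id=qid)
        rec.depth_age_Mya = fam.depth_age
        rec.conserved = qid in noncoding
        rec.te_class = interval_overlap_class(
            qiv, [iv for _, iv in ds.repeats.get(focal, [])],
            min_nt=config.te_min_overlap_nt, near_bps=config.te_near_bp)
        rec.cns_overlap = interval_overlap_class(
            qiv, [iv for _, iv in ds.cns.get(focal, [])],
            min_nt=1, near_bps=()) == "inside"
        nd = nearest_distance(qiv, [iv for _, iv in ds.genes.get(focal, [])])
        rec.nearest_gene_bp = -1 if nd is None else nd
        rec.mean_fpkm = expr.get(qid, float("nan"))
        rec.stress_responsive = stress.get(qid, False)
        if compute_mfe:
            rec.mfe_proxy_per_nt = mfe_proxy_per_nt(qseq)
        for mid, mseq in ds.mirnas:
            hit = mirna_expectation(qseq, mseq,
                                    score_len=config.mirna_score_len,
                                    cutoff=config.mirna_expectation_cutoff)
            if hit is not None:
                rec.mirna_hits.append((mid, hit[0], hit[1]))
        recs.append(rec)
    df = pd.DataFrame([{
        "locus_id": r.locus_id, "depth_age_Mya": r.depth_age_Mya,
        "conserved": r.conserved, "te_class": r.te_class,
        "cns_overlap": r.cns_overlap, "nearest_gene_bp": r.nearest_gene_bp,
        "mean_fpkm": r.mean_fpkm, "stress_responsive": r.stress_responsive,
        "mfe_proxy_per_nt": r.mfe_proxy_per_nt,
        "mirna_hits": ";".join(f"{m}:{s:g}@{p}" for m, s, p in r.mirna_hits),
    } for r in recs])

    stats_rows = []
    strat = depth_stratified_proportions(df, "stress_responsive")
    for row in strat.itertuples(index=False):
        stats_rows.append(("stress_pct_depth_%g" % row.depth_age_Mya,
                           row.pct, row.fisher_p_vs_shallowest, row.n_total))
    cons, noncons = df[df.conserved], df[~df.conserved]
    if len(cons) and len(noncons):
        p_cns, _ = fisher_exact([[int(cons.cns_overlap.sum()),
                                  int((~cons.cns_overlap).sum())],
                                 [int(noncons.cns_overlap.sum()),
                                  int((~noncons.cns_overlap).sum())]])
        stats_rows.append(("cns_conserved_pct",
                           100.0 * cons.cns_overlap.mean(), p_cns, len(cons)))
        stats_rows.append(("cns_nonconserved_pct",
                           100.0 * noncons.cns_overlap.mean(), p_cns,
                           len(noncons)))
        te_in = df.te_class == "inside"
        p_te, _ = fisher_exact([[int(te_in[df.conserved].sum()),
                                 int((~te_in[df.conserved]).sum())],
                                [int(te_in[~df.conserved].sum()),
                                 int((~te_in[~df.conserved]).sum())]])
        stats_rows.append(("te_inside_conserved_pct",
                           100.0 * te_in[df.conserved].mean(), p_te, len(cons)))
        stats_rows.append(("te_inside_nonconserved_pct",
                           100.0 * te_in[~df.conserved].mean(), p_te,
                           len(noncons)))
    r, slope, p_expr, n_expr = expression_depth_correlation(df)
    stats_rows.append(("expression_depth_pearson_r", r, p_expr, n_expr))
    stats_rows.append(("expression_depth_slope", slope, p_expr, n_expr))
    r_prox, p_prox = gene_proximity_vs_conservation(
        df, rng=config.rng("proximity_perm"))
    stats_rows.append(("gene_proximity_r", r_prox, p_prox, len(df)))
    stats = pd.DataFrame(stats_rows, columns=["test", "value", "p", "n"])
    return recs, df, stats


def mean_fpkm_by_locus(expression: pd.DataFrame | None) -> dict[str, float]:
    if expression is None or expression.empty:
        return {}
    vals = expression.set_index("locus_id")
    return vals.mean(axis=1, numeric_only=True).to_dict()


def stress_by_locus(stress: pd.DataFrame | None) -> dict[str, bool]:
    if stress is None or stress.empty:
        return {}
    vals = stress.set_index("locus_id")
    return (vals.sum(axis=1, numeric_only=True) > 0).to_dict()


# ---------------------------------------------------------------------------
# all together
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    calls: dict
    families: list[Family]
    alignments: dict
    gene_trees: dict
    reconciliations: dict
    dup_summary: pd.DataFrame
    lossdecay_calls: list[LossDecayCall]
    lossdecay_df: pd.DataFrame
    groups: pd.DataFrame
    feature_records: list[FeatureRecord]
    features_df: pd.DataFrame
    stats_df: pd.DataFrame

    def families_df(self) -> pd.DataFrame:
        rows = []
        for f in self.families:
            members = ";".join(
                f"{sp}:{h.interval.chrom}:{h.interval.start}-"
                f"{h.interval.end}:{h.interval.strand}"
                for sp, h in sorted(f.members.items()))
            rows.append((f.query_id, f.n_species, f.lineage_ii,
                         f.conserved, f.depth_label, f.depth_age,
                         f.coding_orf, f.known_ncrna,
                         "" if f.coding_pvalue is None else f.coding_pvalue,
                         members))
        return pd.DataFrame(rows, columns=[
            "query_id", "n_species", "lineageII_present", "conserved",
            "depth_node", "depth_age_Mya", "coding_flag", "ncrna_flag",
            "coding_p", "members"])

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"families": self.families_df(),
                "events": events_table(self.reconciliations),
                "duplications": self.dup_summary,
                "loss_decay": self.lossdecay_df,
                "groups": self.groups,
                "features": self.features_df,
                "stats": self.stats_df}

    def write(self, outdir: str | Path) -> dict:
        return reports.write_report(self.tables(), outdir)


def run_all(ds: Dataset, config: PipelineConfig | None = None,
            n_perm: int = 1000, compute_mfe: bool = True) -> PipelineResult:
    config = config or PipelineConfig()
    calls, anchors = homology_stage(ds, config)
    fams, alignments = families_stage(ds, calls, config, n_perm=n_perm)
    trees, recs, dup_summary = trees_stage(ds, fams, alignments, config)
    ld_calls, ld_df, groups = lossdecay_stage(ds, fams, anchors, config)
    frecs, fdf, stats = features_stage(ds, fams, config, compute_mfe=compute_mfe)
    return PipelineResult(calls=calls, families=fams, alignments=alignments,
                          gene_trees=trees, reconciliations=recs,
                          dup_summary=dup_summary, lossdecay_calls=ld_calls,
                          lossdecay_df=ld_df, groups=groups,
                          feature_records=frecs, features_df=fdf,
                          stats_df=stats)
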