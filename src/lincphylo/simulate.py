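"""Synthetic multi-species genomes with planted lincRNA histories.

The generator evolves lincRNA loci along a dated species tree under a
Jukes-Cantor substitution process (uniform base frequencies, rate in
substitutions/site/Myr) and plants the full menu of evolutionary events
the pipeline is meant to recover:

* birth on a chosen species-tree node (the locus exists only in that
  clade),
* per-branch deletion (*loss*) and per-branch switching into a
  hyper-mutating *decay* mode (rate multiplied by ``decay_multiplier``),
* local (tandem) duplications and whole-genome-duplication nodes where
  every surviving copy duplicates, followed by elevated deletion,
* slow-evolving CNS islands inside a subset of loci,
* TE insertions inside or near focal-species loci (never interrupting a
  CNS island),
* flanking protein-coding anchor genes, always retained and collinear,
* expression and stress-response covariates whose means depend on the
  birth-node age.

Every emitted interval is recorded in a :class:`TruthTable`, the oracle
against which the pipeline's calls are scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import rng_stream
from .genome import Genome, decode, encode, revcomp_codes, write_genome
from .intervals import GenomeInterval
from .tree import Clade, SpeciesTree

# ---------------------------------------------------------------------------
# default study system: an 11-taxon chronogram shaped like the Brassicaceae
# ---------------------------------------------------------------------------

DEFAULT_NEWICK = (
    "((((((Ath:13,Aly:13):5,(Cru:9,Cgr:9):9):12,Lal:30):12,"
    "((Bra:20,Bol:20):12,(Spa:25,Esa:25):7):10):12,Aar:54):11,Tha:65);"
)
DEFAULT_LINEAGES = {
    "Ath": "I", "Aly": "I", "Cru": "I", "Cgr": "I", "Lal": "I",
    "Bra": "II", "Bol": "II", "Spa": "II", "Esa": "II",
    "Aar": "outgroup", "Tha": "outgroup",
}
# mesopolyploids: a shared WGD below the Bra+Bol ancestor and an
# independent one on the Lal terminal branch
DEFAULT_WGD = (frozenset({"Bra", "Bol"}), frozenset({"Lal"}))

# birth-node weights keyed by node age (My), emulating the observed
# depth distribution: many species-specific and recently emerged loci,
# progressively fewer deep ones
DEFAULT_BIRTH_WEIGHTS_BY_AGE = {
    0.0: 0.30, 13.0: 0.30, 18.0: 0.12, 30.0: 0.08,
    42.0: 0.12, 54.0: 0.05, 65.0: 0.03,
}


def default_species_tree() -> SpeciesTree:
    from .tree import parse_newick
    return SpeciesTree(root=parse_newick(DEFAULT_NEWICK),
                       lineage=DEFAULT_LINEAGES, focal="Ath",
                       wgd_nodes=DEFAULT_WGD)


def expected_divergence(branch_path_Myr: float, rate: float) -> float:
    """Expected p-distance after evolving for a total path length t.

    Jukes-Cantor forward formula p = 3/4 (1 - exp(-4/3 rate t)).
    """
    if branch_path_Myr < 0:
        raise ValueError("negative time")
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * branch_path_Myr))


@dataclass
class SimParams:
    """Generator parameters. Defaults are the study conditions.

    Rates are per site per Myr; probabilities are per branch per locus
    copy unless noted.
    """

    tree: SpeciesTree = field(default_factory=default_species_tree)
    n_loci: int = 200
    locus_len: int = 400
    birth_weights: dict[str, float] | None = None  # node label -> weight
    subst_rate: float = 0.002
    indel_rate: float = 0.1          # indel events per substitution event
    loss_prob: float = 0.02
    decay_prob: float = 0.03
    decay_multiplier: float = 8.0
    dup_prob: float = 0.05
    dup_node_labels: tuple[str, ...] | None = None  # restrict local dups
    wgd_extra_loss: float = 0.15     # added to loss_prob on/below WGD nodes
    te_library: list[str] | None = None
    te_insert_prob: float = 0.10
    cns_frac: float = 0.40
    cns_len: int = 36
    cns_rate_multiplier: float = 0.05
    flank_gene_len: int = 900
    flank_rate_multiplier: float = 0.2
    spacer_len: tuple[int, int] = (1000, 1400)
    loci_per_chrom: int = 50
    synteny_break_prob: float = 0.0
    expr_mu0: float = 0.0
    expr_beta: float = 0.01          # log10-FPKM per Myr of birth-node age
    expr_sigma: float = 0.5
    stress_alpha0: float = -2.4
    stress_alpha1: float = 0.04      # logit per Myr of birth-node age
    rng_seed: int = 0
    max_genome_bp: int = 50_000_000

    def __post_init__(self) -> None:
        for p in (self.loss_prob, self.decay_prob, self.dup_prob,
                  self.te_insert_prob, self.cns_frac, self.wgd_extra_loss,
                  self.synteny_break_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.subst_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if not self.cns_len < self.locus_len:
            raise ValueError("cns_len must be smaller than locus_len")

    def resolve_birth_weights(self) -> tuple[list[Clade], np.ndarray]:
        backbone = self.tree.backbone()
        nodes = list(backbone[:-1]) + [self.tree.leaf(self.tree.focal)]
        if self.birth_weights is not None:
            w = np.array([self.birth_weights.get(n.label, 0.0) for n in nodes])
        else:
            w = np.array([DEFAULT_BIRTH_WEIGHTS_BY_AGE.get(round(n.age, 6), np.nan)
                          for n in nodes])
            if np.isnan(w).any():      # custom tree: uniform over backbone
                w = np.ones(len(nodes))
        if w.sum() <= 0:
            raise ValueError("birth weights sum to zero")
        return nodes, w / w.sum()


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Complete generative history of every planted locus copy.

    ``states`` holds one row per (copy, species) with state in
    {present, decayed, lost, absent} ('absent' = the species is outside
    the birth clade) and the genomic interval for present/decayed
    copies. ``duplications`` has one row per duplication event (local or
    WGD) with the species-tree node it occurred on.
    """

    loci: pd.DataFrame          # copy_id, locus_id, birth_label, birth_age, has_cns
    states: pd.DataFrame        # copy_id, locus_id, species, state, chrom, start, end, strand
    duplications: pd.DataFrame  # copy_id, parent_copy, locus_id, node_label, node_age, kind
    te: pd.DataFrame            # species, copy_id, te_class, chrom, start, end
    expression: pd.DataFrame    # locus_id, fpkm_1..fpkm_4
    stress: pd.DataFrame        # locus_id, stress_1..stress_4

    def state_of(self, copy_id: str, species: str) -> str:
        df = self.states
        row = df[(df.copy_id == copy_id) & (df.species == species)]
        return row.iloc[0].state if len(row) else "absent"

    def intervals_for(self, locus_id: str, species: str,
                      states=("present", "decayed")) -> list[GenomeInterval]:
        df = self.states
        rows = df[(df.locus_id == locus_id) & (df.species == species)
                  & df.state.isin(states)]
        return [GenomeInterval(r.species, r.chrom, int(r.start), int(r.end), r.strand)
                for r in rows.itertuples()]

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        self.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
        self.states.to_csv(outdir / "truth_states.tsv", sep="\t", index=False)
        self.duplications.to_csv(outdir / "truth_duplications.tsv", sep="\t", index=False)
        self.te.to_csv(outdir / "truth_te.tsv", sep="\t", index=False)
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        self.stress.to_csv(outdir / "stress.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence evolution primitives
# ---------------------------------------------------------------------------

def _jc_mutate(seq: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """One JC step of total branch length mu = rate * t (subst/site)."""
    if mu <= 0:
        return seq.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * mu))
    out = seq.copy()
    hit = rng.random(len(seq)) < p_change
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


class _Copy:
    __slots__ = ("id", "seq", "cns", "decayed")

    def __init__(self, id_: str, seq: np.ndarray, cns: tuple[int, int] | None,
                 decayed: bool = False):
        self.id = id_
        self.seq = seq
        self.cns = cns
        self.decayed = decayed

    def clone(self, new_id: str) -> "_Copy":
        return _Copy(new_id, self.seq.copy(), self.cns, self.decayed)


def _evolve_branch(cp: _Copy, t: float, params: SimParams,
                   rng: np.random.Generator) -> None:
    rate = params.subst_rate * (params.decay_multiplier if cp.decayed else 1.0)
    mu = rate * t
    seq = cp.seq
    if cp.cns is not None:
        s, e = cp.cns
        seq = seq.copy()
        seq[:s] = _jc_mutate(seq[:s], mu, rng)
        seq[s:e] = _jc_mutate(seq[s:e], mu * params.cns_rate_multiplier, rng)
        seq[e:] = _jc_mutate(seq[e:], mu, rng)
    else:
        seq = _jc_mutate(seq, mu, rng)
    # indels: expected count proportional to substitution events
    n_indel = rng.poisson(params.indel_rate * mu * len(seq))
    cns = cp.cns
    for _ in range(n_indel):
        ln = int(rng.integers(1, 6))
        if rng.random() < 0.5 and len(seq) > ln + 10:  # deletion
            pos = int(rng.integers(0, len(seq) - ln))
            if cns is not None and pos + ln > cns[0] and pos < cns[1]:
                continue  # never disturb the CNS island
            seq = np.delete(seq, slice(pos, pos + ln))
            if cns is not None and pos < cns[0]:
                cns = (cns[0] - ln, cns[1] - ln)
        else:  # insertion
            pos = int(rng.integers(0, len(seq) + 1))
            if cns is not None and cns[0] < pos < cns[1]:
                continue
            ins = rng.integers(0, 4, size=ln).astype(np.uint8)
            seq = np.insert(seq, pos, ins)
            if cns is not None and pos <= cns[0]:
                cns = (cns[0] + ln, cns[1] + ln)
    cp.seq = seq
    cp.cns = cns


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    params: SimParams
    tree: SpeciesTree
    genomes: dict[str, Genome]
    queries: list[tuple[str, str, GenomeInterval]]   # (query_id, seq, focal interval)
    genes: dict[str, list[tuple[str, GenomeInterval]]]
    lincrnas: dict[str, list[tuple[str, GenomeInterval]]]
    repeats: dict[str, list[tuple[str, GenomeInterval]]]
    cns: dict[str, list[tuple[str, GenomeInterval]]]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA + GFF3 + BED + TSV + params JSON for every species."""
        from . import reports
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, g in self.genomes.items():
            write_genome(g, outdir / f"{sp}.fasta")
            reports.write_gff3(self.genes[sp], outdir / f"{sp}.genes.gff3")
            reports.write_bed(self.lincrnas[sp], outdir / f"{sp}.lincrnas.bed")
            reports.write_bed(self.repeats.get(sp, []), outdir / f"{sp}.repeats.bed")
            reports.write_bed(self.cns.get(sp, []), outdir / f"{sp}.cns.bed")
        with open(outdir / "queries.fasta", "w") as fh:
            for qid, seq, _ in self.queries:
                fh.write(f">{qid}\n{seq}\n")
        reports.write_bed([(qid, iv) for qid, _, iv in self.queries],
                          outdir / "queries.bed")
        (outdir / "species_tree.nwk").write_text(self.tree.root.newick() + "\n")
        lin = pd.DataFrame({
            "species_id": list(self.tree.lineage),
            "lineage": list(self.tree.lineage.values()),
            "focal": [1 if s == self.tree.focal else 0 for s in self.tree.lineage]})
        lin.to_csv(outdir / "lineages.tsv", sep="\t", index=False)
        self.truth.write(outdir)
        p = {k: v for k, v in self.params.__dict__.items()
             if k not in ("tree", "te_library")}
        p["te_library"] = self.params.te_library
        (outdir / "params.json").write_text(json.dumps(p, indent=1, default=str))


def _default_te_library(rng: np.random.Generator) -> list[str]:
    return [decode(rng.integers(0, 4, size=int(n)).astype(np.uint8))
            for n in (180, 250, 320)]


def simulate(params: SimParams) -> SimResult:
    """Run the generator; see the module docstring for the model."""
    tree = params.tree
    seed = params.rng_seed
    rng_anc = rng_stream(seed, "sim.ancestral")
    rng_evo = rng_stream(seed, "sim.evolve")
    rng_evt = rng_stream(seed, "sim.events")
    rng_pla = rng_stream(seed, "sim.placement")
    rng_cov = rng_stream(seed, "sim.covariates")

    te_library = params.te_library or _default_te_library(rng_stream(seed, "sim.te"))
    birth_nodes, birth_w = params.resolve_birth_weights()
    # nodes at/below a WGD node get the elevated deletion probability
    wgd_ids: set[int] = set()
    for node in tree.root.preorder():
        if tree.is_wgd(node) or any(id(a) in tree.wgd for a in node.ancestors()):
            wgd_ids.add(id(node))

    width = len(str(params.n_loci))

    loci_rows, state_rows, dup_rows, te_rows = [], [], [], []
    expr_rows, stress_rows = [], []
    # per-species layout accumulators
    parts: dict[str, list[np.ndarray]] = {sp: [] for sp in tree.leaf_names}
    cursor: dict[str, int] = {sp: 0 for sp in tree.leaf_names}
    chrom_no: dict[str, int] = {sp: 1 for sp in tree.leaf_names}
    genes: dict[str, list] = {sp: [] for sp in tree.leaf_names}
    lincs: dict[str, list] = {sp: [] for sp in tree.leaf_names}
    repeats: dict[str, list] = {sp: [] for sp in tree.leaf_names}
    cns_bed: dict[str, list] = {sp: [] for sp in tree.leaf_names}
    chroms: dict[str, dict[str, str]] = {sp: {} for sp in tree.leaf_names}
    queries: list[tuple[str, str, GenomeInterval]] = []

    est_block = (params.locus_len + 2 * params.flank_gene_len
                 + 4 * params.spacer_len[1] + 600)
    if est_block * params.n_loci > params.max_genome_bp:
        raise ValueError("expected genome length exceeds max_genome_bp cap")

    def emit(sp: str, seq: np.ndarray) -> tuple[int, int]:
        start = cursor[sp]
        parts[sp].append(seq)
        cursor[sp] += len(seq)
        return start, cursor[sp]

    def spacer(sp: str) -> None:
        n = int(rng_pla.integers(params.spacer_len[0], params.spacer_len[1] + 1))
        emit(sp, rng_pla.integers(0, 4, size=n).astype(np.uint8))

    def chrom_name(sp: str) -> str:
        return f"chr{chrom_no[sp]}"

    def flush_chrom(sp: str) -> None:
        if parts[sp]:
            chroms[sp][chrom_name(sp)] = decode(np.concatenate(parts[sp]))
            parts[sp].clear()
            cursor[sp] = 0
            chrom_no[sp] += 1

    for li in range(params.n_loci):
        locus_id = f"L{li + 1:0{width}d}"
        birth = birth_nodes[int(rng_evt.choice(len(birth_nodes), p=birth_w))]

        anc = rng_anc.integers(0, 4, size=params.locus_len).astype(np.uint8)
        cns = None
        if rng_anc.random() < params.cns_frac:
            off = int(rng_anc.integers(20, params.locus_len - params.cns_len - 20))
            cns = (off, off + params.cns_len)
        gene_l = rng_anc.integers(0, 4, size=params.flank_gene_len).astype(np.uint8)
        gene_r = rng_anc.integers(0, 4, size=params.flank_gene_len).astype(np.uint8)

        # ---- evolve anchor genes over the whole tree (never lost) ----
        gene_seqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def descend_genes(node: Clade, gl: np.ndarray, gr: np.ndarray) -> None:
            if node.is_leaf():
                gene_seqs[node.name] = (gl, gr)
                return
            for child in node.children:
                t = node.age - child.age
                mu = params.subst_rate * params.flank_rate_multiplier * t
                descend_genes(child, _jc_mutate(gl, mu, rng_evo),
                              _jc_mutate(gr, mu, rng_evo))

        descend_genes(tree.root, gene_l, gene_r)

        # ---- evolve locus copies from the birth node down ----
        survivors: dict[str, list[_Copy]] = {}
        lost_in: dict[str, list[str]] = {sp: [] for sp in tree.leaf_names}
        dup_counter = [0]

        def record_lost(node: Clade, copy_id: str) -> None:
            for leaf in node.leaves():
                lost_in[leaf.name].append(copy_id)

        def descend(node: Clade, copies: list[_Copy]) -> None:
            if node.is_leaf():
                survivors[node.name] = copies
                return
            for child in node.children:
                t = node.age - child.age
                extra = params.wgd_extra_loss if id(child) in wgd_ids else 0.0
                new_copies: list[_Copy] = []
                for cp in copies:
                    batch = [cp.clone(cp.id)]
                    if tree.is_wgd(child):
                        dup_counter[0] += 1
                        twin = cp.clone(f"{cp.id}.d{dup_counter[0]}")
                        dup_rows.append((twin.id, cp.id, locus_id,
                                         child.label, child.age, "wgd"))
                        batch.append(twin)
                    for c in batch:
                        if rng_evt.random() < min(1.0, params.loss_prob + extra):
                            record_lost(child, c.id)
                            continue
                        if not c.decayed and rng_evt.random() < params.decay_prob:
                            c.decayed = True
                        dup_allowed = (params.dup_node_labels is None
                                       or child.label in params.dup_node_labels)
                        if dup_allowed and rng_evt.random() < params.dup_prob:
                            dup_counter[0] += 1
                            twin = c.clone(f"{c.id}.d{dup_counter[0]}")
                            dup_rows.append((twin.id, c.id, locus_id,
                                             child.label, child.age, "local"))
                            _evolve_branch(twin, t, params, rng_evo)
                            new_copies.append(twin)
                        _evolve_branch(c, t, params, rng_evo)
                        new_copies.append(c)
                descend(child, new_copies)

        descend(birth, [_Copy(locus_id, anc, cns)])

        loci_rows.append((locus_id, locus_id, birth.label, birth.age,
                          cns is not None))

        # ---- lay the block down in every genome ----
        all_copy_ids = sorted({locus_id}
                              | {r[0] for r in dup_rows if r[2] == locus_id}
                              | {c.id for sps in survivors.values() for c in sps})
        for sp in tree.leaf_names:
            chrom = chrom_name(sp)
            spacer(sp)
            s, e = emit(sp, gene_seqs.get(sp, (gene_l, gene_r))[0])
            genes[sp].append((f"{locus_id}_gL",
                              GenomeInterval(sp, chrom, s, e, "+")))
            spacer(sp)
            copies_here = survivors.get(sp, [])
            placed: set[str] = set()
            for cp in copies_here:
                strand = "+" if rng_pla.random() < 0.5 else "-"
                seq = cp.seq if strand == "+" else revcomp_codes(cp.seq)
                te_class = "none"
                te_seq = None
                if sp == tree.focal and birth.age < 42.0 and cp.cns is None:
                    u = rng_pla.random()
                    te_seq = te_library[int(rng_pla.integers(len(te_library)))]
                    if u < 0.2 * params.te_insert_prob:
                        te_class = "inside"
                    elif u < 0.7 * params.te_insert_prob:
                        te_class = "within_100bp"
                    elif u < 1.7 * params.te_insert_prob:
                        te_class = "within_500bp"
                    else:
                        te_seq = None
                if te_class == "inside":
                    te_codes = encode(te_seq)
                    pos = int(rng_pla.integers(20, len(seq) - 20))
                    seq = np.concatenate([seq[:pos], te_codes, seq[pos:]])
                s, e = emit(sp, seq)
                iv = GenomeInterval(sp, chrom, s, e, strand)
                state = "decayed" if cp.decayed else "present"
                state_rows.append((cp.id, locus_id, sp, state, chrom, s, e, strand))
                lincs[sp].append((cp.id, iv))
                if te_class == "inside":
                    te_s = s + pos
                    te_rows.append((sp, cp.id, "inside", chrom, te_s,
                                    te_s + len(te_seq)))
                    repeats[sp].append((f"TE_{cp.id}",
                                        GenomeInterval(sp, chrom, te_s,
                                                       te_s + len(te_seq), "+")))
                elif te_class in ("within_100bp", "within_500bp"):
                    lo, hi = (5, 95) if te_class == "within_100bp" else (105, 495)
                    d = int(rng_pla.integers(lo, hi))
                    gap = rng_pla.integers(0, 4, size=d).astype(np.uint8)
                    emit(sp, gap)
                    ts, te_ = emit(sp, encode(te_seq))
                    te_rows.append((sp, cp.id, te_class, chrom, ts, te_))
                    repeats[sp].append((f"TE_{cp.id}",
                                        GenomeInterval(sp, chrom, ts, te_, "+")))
                if cp.cns is not None and te_class != "inside":
                    if strand == "+":
                        cs, ce = s + cp.cns[0], s + cp.cns[1]
                    else:
                        cs, ce = e - cp.cns[1], e - cp.cns[0]
                    cns_bed[sp].append((f"CNS_{cp.id}",
                                        GenomeInterval(sp, chrom, cs, ce, strand)))
                if sp == tree.focal and state == "present" and cp.id == locus_id:
                    queries.append((cp.id, decode(cp.seq), iv))
                placed.add(cp.id)
                emit(sp, rng_pla.integers(0, 4, size=120).astype(np.uint8))
            spacer(sp)
            s, e = emit(sp, gene_seqs.get(sp, (gene_l, gene_r))[1])
            genes[sp].append((f"{locus_id}_gR",
                              GenomeInterval(sp, chrom, s, e, "+")))
            spacer(sp)
            # absent / lost bookkeeping
            clade_leaves = birth.leaf_names()
            for cid in all_copy_ids:
                if cid in placed:
                    continue
                if sp in clade_leaves and cid in lost_in[sp]:
                    state_rows.append((cid, locus_id, sp, "lost",
                                       "", -1, -1, "."))
                else:
                    # outside the birth clade, or a duplicate that only
                    # ever arose in a sibling subtree
                    state_rows.append((cid, locus_id, sp, "absent",
                                       "", -1, -1, "."))
        if (li + 1) % params.loci_per_chrom == 0:
            for sp in tree.leaf_names:
                flush_chrom(sp)

        # ---- covariates for the focal query ----
        if queries and queries[-1][0] == locus_id:
            x = rng_cov.normal(params.expr_mu0 + params.expr_beta * birth.age,
                               params.expr_sigma)
            tissues = 10.0 ** (x + rng_cov.normal(0, 0.1, size=4))
            expr_rows.append((locus_id, *np.round(tissues, 4)))
            p_stress = 1.0 / (1.0 + np.exp(-(params.stress_alpha0
                                             + params.stress_alpha1 * birth.age)))
            flags = (rng_cov.random(4) < p_stress).astype(int)
            stress_rows.append((locus_id, *flags))

    for sp in tree.leaf_names:
        flush_chrom(sp)

    genomes = {sp: Genome(sp, chroms[sp]) for sp in tree.leaf_names}
    truth = TruthTable(
        loci=pd.DataFrame(loci_rows, columns=[
            "copy_id", "locus_id", "birth_label", "birth_age", "has_cns"]),
        states=pd.DataFrame(state_rows, columns=[
            "copy_id", "locus_id", "species", "state", "chrom",
            "start", "end", "strand"]),
        duplications=pd.DataFrame(dup_rows, columns=[
            "copy_id", "parent_copy", "locus_id", "node_label",
            "node_age", "kind"]),
        te=pd.DataFrame(te_rows, columns=[
            "species", "copy_id", "te_class", "chrom", "start", "end"]),
        expression=pd.DataFrame(expr_rows, columns=[
            "locus_id", "fpkm_flower", "fpkm_leaf", "fpkm_silique", "fpkm_root"]),
        stress=pd.DataFrame(stress_rows, columns=[
            "locus_id", "stress_aba", "stress_cold", "stress_drought",
            "stress_salt"]),
    )
    return SimResult(params=params, tree=tree, genomes=genomes, queries=queries,
                     genes=genes, lincrnas=lincs, repeats=repeats, cns=cns_bed,
                     truth=truth)
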