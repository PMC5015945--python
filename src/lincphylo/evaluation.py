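"""Scoring pipeline output against a simulation's truth table.

The truth table records, for every planted locus copy and species, the
generative state (present / decayed / lost / absent) and the emitted
interval. These helpers compare the pipeline's homolog calls, family
flags, loss/decay classifications and reconciled duplications to that
ground truth.
"""

from __future__ import annotations

import pandas as pd

from .families import Family
from .loss_decay import LossDecayCall
from .simulate import SimResult
from .tree import SpeciesTree


def _truth_hits(sim: SimResult):
    """(locus_id, species) -> list of (chrom, start, end, state)."""
    out: dict[tuple[str, str], list] = {}
    for r in sim.truth.states.itertuples():
        if r.state in ("present", "decayed"):
            out.setdefault((r.locus_id, r.species), []).append(
                (r.chrom, int(r.start), int(r.end), r.state))
    return out


def _overlaps_truth(hit_interval, truth_rows) -> bool:
    return any(hit_interval.chrom == c and hit_interval.start < e
               and s < hit_interval.end for c, s, e, _ in truth_rows)


def homolog_recall_precision(sim: SimResult, calls: dict, strict_evalue: float,
                             max_age: float = 42.0) -> tuple[float, float, int, int]:
    """Recall of planted present loci and precision of promoted calls.

    Both are restricted to subject species whose divergence from the
    focal species is at most ``max_age`` My. Recall: fraction of
    (query, species) pairs with a planted *present* copy for which a
    promoted homolog call overlaps a planted interval of that locus.
    Precision: fraction of promoted calls overlapping a planted
    (present or decayed) interval of their own locus.
    """
    truth = _truth_hits(sim)
    tree = sim.tree
    focal = tree.focal
    near = {sp for sp in tree.leaf_names
            if sp != focal and tree.mrca([focal, sp]).age <= max_age}
    tp = fn = 0
    n_calls = n_good = 0
    present = {k for k, rows in truth.items()
               if any(st == "present" for *_, st in rows)}
    for qid, by_sp in calls.items():
        for sp in near:
            call = by_sp.get(sp)
            promoted = call is not None and call.is_homolog(strict_evalue)
            if promoted:
                n_calls += 1
                rows = truth.get((qid, sp), [])
                if rows and _overlaps_truth(call.hit.interval, rows):
                    n_good += 1
            if (qid, sp) in present:
                if promoted and _overlaps_truth(call.hit.interval,
                                                truth[(qid, sp)]):
                    tp += 1
                else:
                    fn += 1
    recall = tp / max(1, tp + fn)
    precision = n_good / max(1, n_calls)
    return recall, precision, tp + fn, n_calls


def conserved_flag_agreement(sim: SimResult, fams: list[Family],
                             min_family_species: int = 4) -> tuple[float, int]:
    """Fraction of families whose conserved flag matches the truth.

    Truth-side conservation: the locus was born at or above the lineage
    I/II split AND survives (state present) in >= min_family_species
    species including the focal one, at least one from lineage II.
    """
    tree = sim.tree
    split_age = tree.mrca([sp for sp, lin in tree.lineage.items()
                           if lin in ("I", "II")]).age
    lin2 = {sp for sp, lin in tree.lineage.items() if lin == "II"}
    birth = sim.truth.loci.set_index("locus_id").birth_age.to_dict()
    st = sim.truth.states
    present = st[st.state == "present"]
    by_locus = present.groupby("locus_id").species.apply(set).to_dict()
    n = agree = 0
    for fam in fams:
        locus = fam.query_id
        sp_present = by_locus.get(locus, set())
        truth_cons = (birth.get(locus, 0.0) >= split_age - 1e-9
                      and len(sp_present) >= min_family_species
                      and bool(sp_present & lin2))
        n += 1
        agree += (truth_cons == fam.conserved)
    return agree / max(1, n), n


def truth_state(sim: SimResult, locus_id: str, species: str) -> str:
    """Aggregate truth state of a locus lineage in one species.

    present if any copy survives intact; else decayed if any copy is
    decaying in place; else lost if any copy was deleted; else absent.
    """
    st = sim.truth.states
    rows = st[(st.locus_id == locus_id) & (st.species == species)]
    states = set(rows.state)
    for s in ("present", "decayed", "lost"):
        if s in states:
            return s
    return "absent"


def lossdecay_accuracy(sim: SimResult, calls: list[LossDecayCall]
                       ) -> tuple[float, float, int]:
    """(state accuracy, decayed recall, n) over classified pairs.

    Accuracy is measured over classifier outputs whose truth state is
    decayed or lost; decayed recall over the decayed subset.
    """
    n = correct = 0
    n_dec = dec_correct = 0
    for c in calls:
        if c.state == "present":
            continue
        t = truth_state(sim, c.family_id, c.species_id)
        if t not in ("decayed", "lost"):
            continue
        n += 1
        correct += (c.state == t)
        if t == "decayed":
            n_dec += 1
            dec_correct += (c.state == "decayed")
    return (correct / max(1, n), dec_correct / max(1, n_dec), n)


def _member_copy(sim: SimResult, locus_id: str, species: str, interval):
    """Which planted copy a family member's interval corresponds to."""
    st = sim.truth.states
    rows = st[(st.locus_id == locus_id) & (st.species == species)
              & st.state.isin(["present", "decayed"])]
    for r in rows.itertuples():
        if r.chrom == interval.chrom and interval.start < r.end \
                and r.start < interval.end:
            return r.copy_id
    return None


def duplication_node_recovery(sim: SimResult, fams: list[Family],
                              recs: dict) -> tuple[float, int]:
    """Fraction of identifiable planted duplications recovered at their node.

    A planted duplication is *identifiable* in a top-hit-per-species
    family only when members descend from both sides of the event and
    the species MRCA of those members is the event's node — otherwise
    the one-copy-per-species sampling cannot express the event. For
    each identifiable event, the family's reconciliation must place a
    duplication at exactly that species-tree node.
    """
    tree = sim.tree
    fam_by_q = {f.query_id: f for f in fams}
    n_ident = n_rec = 0
    for ev in sim.truth.duplications.itertuples():
        locus, child = ev.locus_id, ev.copy_id
        fam = fam_by_q.get(locus)
        rec = recs.get(locus)
        if fam is None or rec is None:
            continue
        # map each member (and the focal query) to its planted copy
        side_species: dict[bool, set] = {True: set(), False: set()}
        focal_copy = locus  # the query is the original copy
        side_species[focal_copy == child or focal_copy.startswith(child + ".")
                     ].add(tree.focal)
        for sp, hit in fam.members.items():
            cp = _member_copy(sim, locus, sp, hit.interval)
            if cp is None:
                continue
            child_side = cp == child or cp.startswith(child + ".")
            side_species[child_side].add(sp)
        if not side_species[True] or not side_species[False]:
            continue
        lca = tree.mrca(side_species[True] | side_species[False])
        if lca.label != ev.node_label:
            continue
        n_ident += 1
        if any(lbl == ev.node_label for lbl, _ in rec.duplications):
            n_rec += 1
    return n_rec / max(1, n_ident), n_ident


def multicopy_duplication_binning(sim: SimResult, config,
                                  max_loci: int | None = None) -> dict:
    """Reconciliation's duplication dating on fully sampled gene trees.

    For every locus with surviving copies in >= 3 leaves, a gene tree is
    built from ALL planted copies (leaves named species|copy), bootstrap
    supports computed, and the tree reconciled. Returns a dict with

    * ``binned_of_recovered``: of the loci whose planted duplication was
      recovered (any inferred duplication), the fraction with an
      inferred duplication at the planted node;
    * ``event_purity``: fraction of ALL inferred duplication events
      that sit at a planted node (extra events from gene-tree noise
      lower this);
    * counts ``n_planted``, ``n_recovered``, ``n_inferred``, ``n_loci``.
    """
    from .families import family_alignment
    from .genome import decode
    from .intervals import GenomeInterval
    from .phylogeny import bootstrap_supports, reconcile

    st = sim.truth.states
    rows = st[st.state == "present"]
    planted = sim.truth.duplications.groupby("locus_id").node_label.apply(set)
    n_events = n_at_node = n_loci = 0
    n_planted = n_recovered = n_binned = 0
    loci = list(sim.truth.loci.locus_id)
    if max_loci is not None:
        loci = loci[:max_loci]
    for lid in loci:
        sub = rows[rows.locus_id == lid]
        if len(sub) < 3 or lid not in planted.index:
            continue
        seqs, names = [], []
        anchor = None
        for r in sub.itertuples():
            iv = GenomeInterval(r.species, r.chrom, int(r.start),
                                int(r.end), r.strand)
            s = sim.genomes[r.species].fetch(iv)
            if r.species == sim.tree.focal and anchor is None:
                anchor = s
            seqs.append(s)
            names.append(f"{r.species}|{r.copy_id}")
        if anchor is None:
            anchor = seqs[0]
        member_seqs = dict(zip(names, seqs))
        row_names, mat = family_alignment(anchor, member_seqs, config.scoring)
        names_out = row_names[1:]  # drop the anchor row name ("query")
        mat = mat[1:]
        if mat.shape[0] < 3:
            continue
        rng = config.rng(f"multicopy:{lid}")
        gt = bootstrap_supports(mat, names_out, reps=config.bootstrap_reps,
                                rng=rng)
        rec = reconcile(gt, sim.tree,
                        collapse_pct=config.support_collapse_pct)
        n_loci += 1
        n_planted += 1
        inferred = [lbl for lbl, _age in rec.duplications]
        for lbl in inferred:
            n_events += 1
            if lbl in planted.loc[lid]:
                n_at_node += 1
        if inferred:
            n_recovered += 1
            if any(lbl in planted.loc[lid] for lbl in inferred):
                n_binned += 1
    return {
        "binned_of_recovered": n_binned / max(1, n_recovered),
        "event_purity": n_at_node / max(1, n_events),
        "n_planted": n_planted,
        "n_recovered": n_recovered,
        "n_inferred": n_events,
        "n_loci": n_loci,
    }


# Per-species loss/decay percentages used as planted rates for the
# species-grouping check. They emulate the mesopolyploid fractionation
# pattern: recently whole-genome-duplicated species (B. rapa,
# B. oleracea, L. alabamica) lose lincRNA loci at ~12%, non-polyploid
# ingroup species at 3-4%, and the closest relative of the focal
# species at under 1%; decay rates are higher and group differently.
PLANTED_LOSS_PCT = {"Bra": 13.0, "Bol": 12.4, "Lal": 11.8,
                    "Cgr": 2.8, "Cru": 3.2, "Esa": 3.6, "Spa": 4.0,
                    "Aly": 0.8}
PLANTED_DECAY_PCT = {"Spa": 19.6, "Bol": 18.7, "Bra": 17.8, "Lal": 17.0,
                     "Esa": 14.8, "Cru": 13.9, "Cgr": 13.0, "Aly": 1.0}


def planted_rate_group_scenario(seed: int, n_families: int = 1023,
                                alpha: float = 0.01):
    """Draw per-species loss/decay states at the planted rates and group.

    Returns (calls df, groups df) — the direct planted-effect check of
    the pairwise score tests + Bonferroni grouping at the sample size
    the loss/decay analysis runs at.
    """
    import numpy as np

    from .config import rng_stream
    from .loss_decay import group_species

    rng = rng_stream(seed, "planted_groups")
    rows = []
    for sp in sorted(PLANTED_LOSS_PCT):
        pl = PLANTED_LOSS_PCT[sp] / 100.0
        pd_ = PLANTED_DECAY_PCT[sp] / 100.0
        u = rng.random(n_families)
        for i in range(n_families):
            if u[i] < pl:
                state = "lost"
            elif u[i] < pl + pd_:
                state = "decayed"
            else:
                state = "present"
            rows.append((f"f{i}", sp, state))
    calls = pd.DataFrame(rows, columns=["family_id", "species_id", "state"])
    n_eval = {sp: n_families for sp in PLANTED_LOSS_PCT}
    groups = pd.concat([group_species(calls, "decayed", n_eval, alpha=alpha),
                        group_species(calls, "lost", n_eval, alpha=alpha)],
                       ignore_index=True)
    return calls, groups


def wgd_isolation(groups: pd.DataFrame, tree: SpeciesTree,
                  wgd_species: set[str], metric: str = "lost") -> bool:
    """True iff no loss group mixes WGD and non-WGD species."""
    sub = groups[groups.metric == metric]
    for row in sub.itertuples():
        members = set(row.members.split(","))
        if members & wgd_species and members - wgd_species:
            return False
    return True
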