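"""Distances, neighbor joining, bootstrap, reconciliation (with a
brute-force duplication-loss oracle)."""

import itertools

import numpy as np
import pytest

from lincphylo.phylogeny import (ReconciledTree, _score_rooted, all_rootings,
                                 bootstrap_supports, collapse_low_support,
                                 distance_matrix, jc_distance,
                                 neighbor_joining, reconcile,
                                 summarize_duplications)
from lincphylo.tree import Clade, SpeciesTree, parse_newick


class TestJCDistance:
    def test_identical_zero(self):
        a = np.zeros(100, dtype=np.int8)
        assert jc_distance(a, a) == 0.0

    def test_closed_form_p_ten_percent(self):
        a = np.zeros(100, dtype=np.int8)
        b = a.copy()
        b[:10] = 1
        assert jc_distance(a, b) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_cap(self):
        a = np.zeros(100, dtype=np.int8)
        b = np.ones(100, dtype=np.int8)
        assert jc_distance(a, b) == 5.0

    def test_gap_and_n_columns_excluded(self):
        a = np.array([0, 0, 0, 0, 5], dtype=np.int8)
        b = np.array([0, 0, 0, 4, 0], dtype=np.int8)
        assert jc_distance(a, b) == 0.0  # only 3 shared valid columns


def tree_distances(root):
    """Leaf-to-leaf path lengths of a tree with branch lengths."""
    leaves = root.leaves()
    names = [l.name for l in leaves]
    D = {}

    def depth_map(node, acc, out):
        if node.is_leaf():
            out[node.name] = acc
        for c in node.children:
            depth_map(c, acc + c.length, out)

    # path length via LCA on the rooted representation
    def path(a, b):
        pa = {}
        n = a
        d = 0.0
        while n is not None:
            pa[id(n)] = d
            d += n.length or 0.0
            n = n.parent
        n, d = b, 0.0
        while id(n) not in pa:
            d += n.length or 0.0
            n = n.parent
        return d + pa[id(n)]

    leaf_by_name = {l.name: l for l in leaves}
    out = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            out[i, j] = out[j, i] = path(leaf_by_name[a], leaf_by_name[names[j]])
    return names, out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        t = neighbor_joining(D, ["a", "b", "c"])
        lens = {l.name: l.length for l in t.leaves()}
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        assert lens["a"] == pytest.approx(1.0)
        assert lens["b"] == pytest.approx(2.0)
        assert lens["c"] == pytest.approx(4.0)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)): additive distances
        D = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        t = neighbor_joining(D, list("ABCD"))
        names, got = tree_distances(t)
        order = [names.index(x) for x in "ABCD"]
        np.testing.assert_allclose(got[np.ix_(order, order)], D, atol=1e-9)

    def test_tie_break_deterministic(self):
        D = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(D, list("abcde"))
        t2 = neighbor_joining(D.copy(), list("abcde"))
        assert t1.canonical_newick() == t2.canonical_newick()

    def test_nj_consistent_on_random_additive_matrices(self):
        """NJ recovers topology and path lengths from additive data."""
        rng = np.random.default_rng(17)
        for trial in range(15):
            n = int(rng.integers(4, 9))
            names = [f"t{i}" for i in range(n)]
            # random binary tree with random positive lengths
            nodes = [Clade(nm, length=float(rng.uniform(0.5, 3))) for nm in names]
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                a, b = nodes[j], nodes[i]
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
                parent = Clade(children=[a, b],
                               length=float(rng.uniform(0.5, 3)))
                nodes.append(parent)
            true = Clade(children=nodes)
            tnames, D = tree_distances(true)
            est = neighbor_joining(D, tnames)
            enames, got = tree_distances(est)
            order = [enames.index(x) for x in tnames]
            np.testing.assert_allclose(got[np.ix_(order, order)], D, atol=1e-8)


def make_mat(rows):
    return np.array(rows, dtype=np.int8)


class TestBootstrap:
    def test_identical_sequences_zero_supports(self):
        mat = np.tile(np.arange(4, dtype=np.int8), (5, 20))
        t = bootstrap_supports(mat, [f"s{i}" for i in range(5)], reps=30,
                               rng=np.random.default_rng(0))
        sup = [n.support for n in t.postorder()
               if not n.is_leaf() and n is not t and n.support is not None]
        assert sup and all(s == 0 for s in sup)

    def test_planted_split_high_support(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 4, 200).astype(np.int8)
        cladeA = [base.copy() for _ in range(3)]
        other = base.copy()
        other[:80] = (other[:80] + 1) % 4  # strongly diverged clade
        cladeB = [other.copy() for _ in range(3)]
        for i, r in enumerate(cladeA + cladeB):  # sprinkle noise
            idx = rng.choice(200, 6, replace=False)
            r[idx] = (r[idx] + 1 + i % 3) % 4
        mat = np.vstack(cladeA + cladeB)
        names = ["a1", "a2", "a3", "b1", "b2", "b3"]
        t = bootstrap_supports(mat, names, reps=100,
                               rng=np.random.default_rng(1))
        target = frozenset(["a1", "a2", "a3"])
        found = None
        for node in t.postorder():
            if node is t or node.is_leaf():
                continue
            side = node.leaf_names()
            if side == target or side == frozenset(names) - target:
                found = node.support
        assert found is not None and found >= 95

    def test_supports_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 4, size=(5, 100)).astype(np.int8)
        names = list("abcde")
        t1 = bootstrap_supports(mat, names, reps=50, rng=np.random.default_rng(7))
        t2 = bootstrap_supports(mat, names, reps=50, rng=np.random.default_rng(7))
        s1 = sorted((n.support or 0) for n in t1.postorder() if not n.is_leaf())
        s2 = sorted((n.support or 0) for n in t2.postorder() if not n.is_leaf())
        assert s1 == s2


SPECIES_TREE = SpeciesTree(
    parse_newick("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);"),
    {"A": "I", "B": "I", "C": "II", "D": "II", "E": "outgroup"}, focal="A")


def brute_min_cost(unrooted, st):
    """Exhaustive minimum (dups, losses) over all rootings."""
    best = None
    for rooted in all_rootings(unrooted):
        d, l, _, _ = _score_rooted(rooted, st)
        if best is None or (d, l) < best:
            best = (d, l)
    return best


def unrooted_topologies(leaf_names):
    """All unrooted binary topologies over the given (multiset of) leaves."""
    if len(leaf_names) == 3:
        yield Clade(children=[Clade(leaf_names[0]), Clade(leaf_names[1]),
                              Clade(leaf_names[2])])
        return
    first, rest = leaf_names[0], leaf_names[1:]
    for t in unrooted_topologies(rest):
        edges = [(n, c) for n in t.postorder() for c in n.children]
        for n, c in edges:
            t2 = t.copy()
            # find corresponding edge in the copy by position
            e2 = [(x, y) for x in t2.postorder() for y in x.children]
            p, child = e2[edges.index((n, c))]
            mid = Clade(children=[Clade(first)])
            i = p.children.index(child)
            mid.children.append(child)
            child.parent = mid
            p.children[i] = mid
            mid.parent = p
            yield t2


class TestReconcile:
    def test_congruent_tree_zero_events(self):
        gt = parse_newick("(((A:1,B:1)100:1,(C:1,D:1)100:1)100:1,E:1);")
        rec = reconcile(gt, SPECIES_TREE)
        assert rec.n_dup == 0 and rec.n_loss == 0
        assert all(ev == "speciation" for ev in rec.events.values())

    def test_textbook_two_copy_duplication(self):
        st = SpeciesTree(parse_newick("(A:1,B:1);"), {"A": "I", "B": "II"},
                         focal="A")
        gt = parse_newick("((A:1,B:1)100:1,(A:1,B:1)100:1);")
        rec = reconcile(gt, st)
        assert rec.n_dup == 1
        dup_nodes = [lbl for lbl, _ in rec.duplications]
        assert dup_nodes == [st.root.label]

    def test_unknown_species_rejected(self):
        gt = parse_newick("((A:1,Z:1):1,B:1);")
        with pytest.raises(KeyError, match="Z"):
            reconcile(gt, SPECIES_TREE)

    def test_duplication_criterion_invariant(self):
        """event(v) == duplication iff M(v) in {M(children)} on every output."""
        rng = np.random.default_rng(5)
        species = ["A", "B", "C", "D", "E"]
        for _ in range(20):
            leaves = [species[i] for i in rng.integers(0, 5, 5)]
            if len(set(leaves)) < 2:
                continue
            tops = list(unrooted_topologies(leaves))
            gt = tops[int(rng.integers(0, len(tops)))]
            rec = reconcile(gt, SPECIES_TREE)
            for node in rec.root.postorder():
                if node.is_leaf():
                    continue
                m = rec.mapping[id(node)]
                kids = [rec.mapping[id(c)] for c in node.children]
                assert (rec.events[id(node)] == "duplication") == (m in kids)

    @pytest.mark.parametrize("leaves", [
        ["A", "B", "C", "D", "E"],
        ["A", "A", "B", "C", "D"],
        ["A", "B", "B", "C", "C"],
        ["A", "A", "B", "B", "C", "D"],
        ["A", "B", "C", "D", "E", "A"],
    ])
    def test_oracle_equality_exhaustive(self, leaves):
        """Chosen reconciliation cost equals the exhaustive minimum over
        all rootings, for every unrooted topology on these leaves."""
        for gt in unrooted_topologies(leaves):
            rec = reconcile(gt, SPECIES_TREE)
            d, l = brute_min_cost(gt, SPECIES_TREE)
            assert (rec.n_dup, rec.n_loss) == (d, l), gt.canonical_newick()

    def test_low_support_branch_rearranged_to_species_topology(self):
        """A conflicting branch with weak support is collapsed and
        re-resolved congruently: no duplication is inferred."""
        gt = parse_newick("(((A:1,C:1)40:1,(B:1,D:1)45:1)100:1,E:1);")
        rec = reconcile(gt, SPECIES_TREE, collapse_pct=70)
        assert rec.n_dup == 0
        strong = parse_newick("(((A:1,C:1)95:1,(B:1,D:1)95:1)100:1,E:1);")
        rec2 = reconcile(strong, SPECIES_TREE, collapse_pct=70)
        assert rec2.n_dup > 0

    def test_collapse_polytomy_oracle(self):
        """With collapsed branches, the chosen cost equals the minimum
        over all rootings and binary re-resolutions."""
        from lincphylo.phylogeny import _binary_resolutions
        gt = parse_newick("(((A:1,C:1)10:1,(B:1,D:1)20:1)100:1,E:1);")
        collapsed = collapse_low_support(gt, 70)
        best = None
        for rooted in all_rootings(collapsed):
            # brute-force every polytomy resolution of this rooting
            def expand(node):
                node.children = [expand(c) for c in node.children]
                for c in node.children:
                    c.parent = node
                return node
            stack = [rooted]
            # enumerate resolutions recursively
            def all_res(node):
                subs = [list(all_res(c)) for c in node.children]
                for combo in itertools.product(*subs):
                    if len(combo) <= 2:
                        if node.is_leaf():
                            yield Clade(name=node.name)
                        else:
                            yield Clade(children=[c.copy() for c in combo])
                    else:
                        for t in _binary_resolutions(list(combo)):
                            yield t.copy()
            for cand in all_res(rooted):
                d, l, _, _ = _score_rooted(cand, SPECIES_TREE)
                if best is None or (d, l) < best:
                    best = (d, l)
        rec = reconcile(gt, SPECIES_TREE, collapse_pct=70)
        assert (rec.n_dup, rec.n_loss) == best


class TestSummarize:
    def _mock_rec(self, st, dup_labels, backbone_count):
        rec = ReconciledTree(root=Clade("A"), species_tree=st)
        rec.duplications = [(lbl, st.node_by_label(lbl).age)
                            for lbl in dup_labels]
        rec.backbone_dups = backbone_count
        # put events/mapping in the shape summarize expects
        for i, lbl in enumerate(dup_labels):
            marker = Clade(f"d{i}")
            rec.events[id(marker)] = "duplication"
            rec.mapping[id(marker)] = st.node_by_label(lbl)
            rec.__dict__.setdefault("_markers", []).append(marker)
        return rec

    def test_highly_duplicated_family_excluded(self, fixture_tree):
        st = fixture_tree
        root_lbl = st.root.label
        ok = self._mock_rec(st, [root_lbl], 1)
        bad = self._mock_rec(st, [root_lbl] * 4, 4)
        df = summarize_duplications({"f1": ok, "f2": bad}, st, max_backbone=3)
        assert df.attrs["n_excluded"] == 1
        assert df.attrs["excluded"] == ["f2"]
        assert df[df.node_label == root_lbl].n_duplications.iloc[0] == 1

    def test_no_duplications_all_bins_zero(self, fixture_tree):
        rec = ReconciledTree(root=Clade("Ath"), species_tree=fixture_tree)
        df = summarize_duplications({"f": rec}, fixture_tree)
        assert (df.n_duplications == 0).all()
        assert df.attrs["n_families_with_dup"] == 0
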