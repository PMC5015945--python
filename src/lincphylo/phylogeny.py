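"""Gene trees and species-tree reconciliation.

Per-family gene trees are inferred with Jukes-Cantor distances and
neighbor-joining, with column-bootstrap supports. Reconciliation embeds
the gene tree into the species tree: branches below a support threshold
are collapsed, every rooting of the collapsed tree is scored, polytomies
are resolved to minimize duplications then losses, and the rooting with
the minimal (duplications, losses) — ties broken by canonical newick —
wins. Events follow the LCA-mapping criterion: a node is a duplication
iff its species mapping equals a child's mapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Clade, SpeciesTree

JC_SATURATION_CAP = 5.0
_EXACT_POLYTOMY_LIMIT = 6


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jc_distance(row_a: np.ndarray, row_b: np.ndarray,
                cap: float = JC_SATURATION_CAP) -> float:
    """Jukes-Cantor distance between two aligned rows.

    Columns with a gap or N in either row are excluded. p >= 0.75 (or no
    valid columns) returns the saturation cap.
    """
    valid = (row_a < 4) & (row_b < 4)
    n = int(valid.sum())
    if n == 0:
        return cap
    p = float((row_a[valid] != row_b[valid]).mean())
    if p >= 0.75:
        return cap
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def distance_matrix(mat: np.ndarray, cap: float = JC_SATURATION_CAP) -> np.ndarray:
    n = mat.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jc_distance(mat[i], mat[j], cap)
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, names: list[str]) -> Clade:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The returned Clade has three children at its (arbitrary) top node
    for n >= 3. Negative branch lengths are clamped to zero; ties in
    the Q criterion break to the lowest (i, j) index pair.
    """
    n = len(names)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    if n == 2:
        return Clade(children=[Clade(names[0], length=D[0, 1] / 2),
                               Clade(names[1], length=D[0, 1] / 2)])
    D = D.astype(float).copy()
    nodes = [Clade(nm) for nm in names]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)          # argmin is the first minimum: lowest (i,j)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        a, b = nodes[active[i]], nodes[active[j]]
        a.length, b.length = max(0.0, li), max(0.0, lj)
        parent = Clade(children=[a, b])
        # distances from the new node
        k_idx = [x for x in active if x not in (active[i], active[j])]
        new = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in k_idx:
            D[new, k] = D[k, new] = 0.5 * (D[active[i], k] + D[active[j], k] - dij)
        active = [x for x in active if x not in (active[i], active[j])] + [new]
    # join the last three around a central node
    a, b, c = (nodes[x] for x in active)
    dab = D[active[0], active[1]]
    dac = D[active[0], active[2]]
    dbc = D[active[1], active[2]]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return Clade(children=[a, b, c])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(unrooted: Clade, all_names: frozenset) -> dict[frozenset, Clade]:
    """Internal-edge bipartitions, normalized to the side without the
    lexicographically smallest leaf."""
    ref = min(all_names)
    out = {}
    for node in unrooted.postorder():
        if node is unrooted or node.is_leaf():
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(all_names - side) < 2:
            continue
        key = side if ref not in side else all_names - side
        out[key] = node
    return out


def bootstrap_supports(mat: np.ndarray, names: list[str], reps: int = 100,
                       rng: np.random.Generator | None = None,
                       cap: float = JC_SATURATION_CAP) -> Clade:
    """NJ tree from the full alignment with column-bootstrap supports.

    Support of an internal branch = % of replicate trees containing the
    same bipartition. An alignment with no variable column yields a
    tree with all supports 0 (no resampling signal exists).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    tree = neighbor_joining(distance_matrix(mat, cap), names)
    all_names = frozenset(names)
    bips = _bipartitions(tree, all_names)
    for node in bips.values():
        node.support = 0.0
    variable = any((mat[0] != mat[i]).any() for i in range(1, mat.shape[0]))
    if not variable or not bips:
        return tree
    counts = {key: 0 for key in bips}
    L = mat.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_tree = neighbor_joining(distance_matrix(mat[:, cols], cap), names)
        for key in _bipartitions(rep_tree, all_names):
            if key in counts:
                counts[key] += 1
    for key, node in bips.items():
        node.support = 100.0 * counts[key] / reps
    return tree


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

@dataclass
class ReconciledTree:
    """A rooted, resolved gene tree embedded in the species tree."""

    root: Clade
    species_tree: SpeciesTree
    events: dict[int, str] = field(default_factory=dict)       # id(node) -> event
    mapping: dict[int, Clade] = field(default_factory=dict)    # id(node) -> sp node
    duplications: list[tuple[str, float]] = field(default_factory=list)
    n_dup: int = 0
    n_loss: int = 0
    backbone_dups: int = 0


def leaf_species(name: str) -> str:
    """Gene-tree leaves are species names, optionally 'species|copy_id'."""
    return name.split("|", 1)[0]


def _lca(a: Clade, b: Clade, depth: dict[int, int]) -> Clade:
    while a is not b:
        if depth[id(a)] >= depth[id(b)]:
            a = a.parent
        else:
            b = b.parent
    return a


def _score_rooted(root: Clade, st: SpeciesTree) -> tuple[int, int, dict, dict]:
    """LCA mapping, events and the duplication/loss count of a rooted
    binary gene tree whose leaves are species names."""
    depth = st._depth
    mapping: dict[int, Clade] = {}
    events: dict[int, str] = {}
    dups = losses = 0
    for node in root.postorder():
        if node.is_leaf():
            mapping[id(node)] = st.leaf(leaf_species(node.name))
            continue
        c1, c2 = node.children
        m1, m2 = mapping[id(c1)], mapping[id(c2)]
        m = _lca(m1, m2, depth)
        mapping[id(node)] = m
        if m is m1 or m is m2:
            events[id(node)] = "duplication"
            dups += 1
            losses += (depth[id(m1)] - depth[id(m)]) + (depth[id(m2)] - depth[id(m)])
        else:
            events[id(node)] = "speciation"
            losses += (depth[id(m1)] - depth[id(m)] - 1) + (depth[id(m2)] - depth[id(m)] - 1)
    return dups, losses, mapping, events


def collapse_low_support(unrooted: Clade, threshold: float) -> Clade:
    """Contract internal edges whose support is below the threshold."""
    tree = unrooted.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node is tree or node.is_leaf():
                continue
            if node.support is not None and node.support < threshold:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx:idx + 1] = node.children
                for c in node.children:
                    c.parent = parent
                changed = True
                break
    return tree


def _adjacency(unrooted: Clade) -> tuple[list, dict]:
    nodes = list(unrooted.postorder())
    adj: dict[int, list[Clade]] = {id(n): [] for n in nodes}
    for n in nodes:
        for c in n.children:
            adj[id(n)].append(c)
            adj[id(c)].append(n)
    return nodes, adj


def unroot(tree: Clade) -> Clade:
    """Splice out a degree-2 root so the top node is a true unrooted
    junction (trifurcation or leaf pair)."""
    tree = tree.copy()
    while len(tree.children) == 2:
        internal = next((c for c in tree.children if not c.is_leaf()), None)
        if internal is None:
            break
        other = [c for c in tree.children if c is not internal]
        tree = Clade(children=internal.children + other)
    return tree


def all_rootings(unrooted: Clade) -> list[Clade]:
    """One rooted tree per edge of the unrooted tree (root inserted on
    that edge), preserving polytomies elsewhere. A degree-2 top node
    (a rooted input) is spliced out first."""
    unrooted = unroot(unrooted)
    nodes, adj = _adjacency(unrooted)

    def orient(node: Clade, came_from: Clade | None) -> Clade:
        kids = [nb for nb in adj[id(node)] if nb is not came_from]
        if not kids:
            return Clade(name=node.name)
        return Clade(name=node.name,
                     children=[orient(k, node) for k in kids])

    rootings = []
    for n in nodes:
        for c in n.children:
            rootings.append(Clade(children=[orient(c, n), orient(n, c)]))
    if not rootings:  # single node
        rootings.append(unrooted.copy())
    return rootings


def _binary_resolutions(subtrees: list[Clade]):
    """All binary trees over the given subtrees ((2k-3)!! of them)."""
    if len(subtrees) == 1:
        yield subtrees[0]
        return
    if len(subtrees) == 2:
        yield Clade(children=[s.copy() for s in subtrees])
        return
    first, rest = subtrees[0], subtrees[1:]
    # join `first` with every element / every internal edge of every
    # resolution of the rest
    for tree in _binary_resolutions(rest):
        for target in list(tree.postorder()):
            new = Clade(children=[first.copy()])
            if target.parent is None:
                new.children.append(target)
                target.parent = new
                yield new
                new.children.remove(target)
                target.parent = None
            else:
                p = target.parent
                i = p.children.index(target)
                new.children.append(target)
                target.parent = new
                p.children[i] = new
                new.parent = p
                yield tree
                p.children[i] = target
                target.parent = p


def _shapes(idxs: tuple):
    """All binary tree shapes over the given item indices, as nested
    2-tuples ((2k-3)!! of them)."""
    if len(idxs) == 1:
        yield idxs[0]
        return
    first = idxs[0]
    for sub in _shapes(idxs[1:]):
        yield from _insert_shape(first, sub)


def _insert_shape(x, shape):
    yield (x, shape)
    if isinstance(shape, tuple):
        a, b = shape
        for s in _insert_shape(x, a):
            yield (s, b)
        for s in _insert_shape(x, b):
            yield (a, s)


def _score_shape(shape, maps, depth):
    """(mapping, dups, losses) of a resolution shape, scored locally.

    The species mapping of the polytomy root and every untouched
    subtree cost are invariant under the resolution, so the local
    duplication/loss sum over the shape's internal nodes is an exact
    total-cost comparator."""
    if not isinstance(shape, tuple):
        return maps[shape], 0, 0
    ma, da, la = _score_shape(shape[0], maps, depth)
    mb, db, lb = _score_shape(shape[1], maps, depth)
    m = _lca(ma, mb, depth)
    d, l = da + db, la + lb
    if m is ma or m is mb:
        d += 1
        l += (depth[id(ma)] - depth[id(m)]) + (depth[id(mb)] - depth[id(m)])
    else:
        l += (depth[id(ma)] - depth[id(m)] - 1) + (depth[id(mb)] - depth[id(m)] - 1)
    return m, d, l


def _shape_canon(shape, kids) -> str:
    if not isinstance(shape, tuple):
        return kids[shape].canonical_newick().rstrip(";")
    parts = sorted((_shape_canon(shape[0], kids), _shape_canon(shape[1], kids)))
    return "(" + ",".join(parts) + ")"


def _build_shape(shape, kids) -> Clade:
    if not isinstance(shape, tuple):
        return kids[shape]
    return Clade(children=[_build_shape(shape[0], kids),
                           _build_shape(shape[1], kids)])


def _resolve_polytomies(root: Clade, st: SpeciesTree) -> Clade:
    """Resolve every polytomy, minimizing duplications then losses.

    Exact enumeration per polytomy up to degree 6 (scored locally over
    the children's species mappings); above that, a species-guided
    greedy that repeatedly joins the pair of children whose mapped LCA
    is deepest (optimal for the duplication count).
    """
    root = root.copy()
    depth = st._depth

    def resolve(node: Clade) -> Clade:
        node.children = [resolve(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) <= 2:
            return node
        kids = node.children
        if len(kids) <= _EXACT_POLYTOMY_LIMIT:
            maps = [st.mrca({leaf_species(nm) for nm in c.leaf_names()})
                    for c in kids]
            best = None
            for shape in _shapes(tuple(range(len(kids)))):
                _, d, l = _score_shape(shape, maps, depth)
                if best is None or (d, l) < best[0]:
                    best = ((d, l), [shape])
                elif (d, l) == best[0]:
                    best[1].append(shape)
            if len(best[1]) > 1:
                shape = min(best[1], key=lambda s: _shape_canon(s, kids))
            else:
                shape = best[1][0]
            chosen = _build_shape(shape, kids)
            for c in chosen.children:
                c.parent = chosen
        else:
            chosen = _greedy_resolve(kids, st)
        if node.parent is None:
            return chosen
        chosen.parent = node.parent
        return chosen

    out = resolve(root)
    out.parent = None
    return out


def _greedy_resolve(kids: list[Clade], st: SpeciesTree) -> Clade:
    depth = st._depth
    items = [k.copy() for k in kids]

    def map_of(n: Clade) -> Clade:
        return st.mrca({leaf_species(nm) for nm in n.leaf_names()})

    while len(items) > 1:
        maps = [map_of(n) for n in items]
        best = None
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                m = _lca(maps[i], maps[j], depth)
                key = (-depth[id(m)], i, j)
                if best is None or key < best:
                    best = key
                    bi, bj = i, j
        joined = Clade(children=[items[bi], items[bj]])
        items = [x for k, x in enumerate(items) if k not in (bi, bj)] + [joined]
    return items[0]


def reconcile(gene_tree: Clade, st: SpeciesTree,
              collapse_pct: float = 70.0) -> ReconciledTree:
    """Root and reconcile a (possibly unrooted) gene tree.

    Branches with bootstrap support below ``collapse_pct`` are collapsed
    first; every rooting of the result is scored after polytomy
    resolution; the rooting minimizing (duplications, losses, canonical
    newick) wins. Raises KeyError naming any leaf species absent from
    the species tree.
    """
    for leaf in gene_tree.leaves():
        if leaf_species(leaf.name) not in st.leaf_names:
            raise KeyError(f"gene-tree species {leaf.name!r} not in species tree")
    collapsed = collapse_low_support(gene_tree, collapse_pct)
    best = None
    for rooted in all_rootings(collapsed):
        resolved = _resolve_polytomies(rooted, st)
        d, l, mapping, events = _score_rooted(resolved, st)
        key = (d, l, resolved.canonical_newick())
        if best is None or key < best[0]:
            best = (key, resolved, mapping, events)
    (d, l, _), resolved, mapping, events = best
    backbone_ids = {id(n) for n in st.backbone()}
    dups = [(mapping[k].label, mapping[k].age)
            for k, ev in events.items() if ev == "duplication"]
    backbone_dups = sum(1 for k, ev in events.items()
                        if ev == "duplication" and id(mapping[k]) in backbone_ids)
    return ReconciledTree(root=resolved, species_tree=st, events=events,
                          mapping=mapping, duplications=sorted(dups),
                          n_dup=d, n_loss=l, backbone_dups=backbone_dups)


def summarize_duplications(recs: dict[str, ReconciledTree], st: SpeciesTree,
                           max_backbone: int = 3) -> pd.DataFrame:
    """Bin backbone duplication events by species-tree node.

    Families with more than ``max_backbone`` backbone duplications are
    excluded (highly duplicated families). Returns one row per backbone
    node with the number of events and of families with >= 1 event
    there, plus summary attributes in ``df.attrs``.
    """
    backbone = st.backbone()
    backbone_ids = {id(n) for n in backbone}
    events_per_node = {n.label: 0 for n in backbone}
    fams_per_node = {n.label: set() for n in backbone}
    included, excluded, fams_with_dup = [], [], set()
    for fam_id, rec in sorted(recs.items()):
        if rec.backbone_dups > max_backbone:
            excluded.append(fam_id)
            continue
        included.append(fam_id)
        for k, ev in rec.events.items():
            if ev != "duplication":
                continue
            node = rec.mapping[k]
            if id(node) in backbone_ids:
                events_per_node[node.label] += 1
                fams_per_node[node.label].add(fam_id)
                fams_with_dup.add(fam_id)
    df = pd.DataFrame({
        "node_label": [n.label for n in backbone],
        "node_age_Mya": [n.age for n in backbone],
        "n_duplications": [events_per_node[n.label] for n in backbone],
        "n_families": [len(fams_per_node[n.label]) for n in backbone],
    })
    df.attrs["n_included"] = len(included)
    df.attrs["n_excluded"] = len(excluded)
    df.attrs["n_families_with_dup"] = len(fams_with_dup)
    df.attrs["excluded"] = excluded
    return df
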