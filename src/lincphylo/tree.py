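"""Rooted, dated species trees and the shared tree node type.

The species tree is the coordinate system for the whole pipeline:
conservation depth is a node of this tree, duplications are dated by
mapping onto its nodes, and the simulator evolves sequences along its
branches. Node ages are in Mya; the tree must be ultrametric.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

ULTRAMETRIC_TOL = 1e-6


class Clade:
    """A minimal mutable tree node shared by species trees and gene trees."""

    __slots__ = ("name", "children", "parent", "length", "support", "age", "label")

    def __init__(self, name=None, children=None, length=None, support=None):
        self.name = name
        self.children: list[Clade] = children or []
        for c in self.children:
            c.parent = self
        self.parent: Clade | None = None
        self.length = length
        self.support = support
        self.age: float | None = None
        self.label: str | None = None

    # -- traversal -----------------------------------------------------
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())

    def copy(self) -> "Clade":
        node = Clade(self.name, [c.copy() for c in self.children],
                     self.length, self.support)
        node.age = self.age
        node.label = self.label
        return node

    def ancestors(self):
        n = self
        while n is not None:
            yield n
            n = n.parent

    # -- serialization -------------------------------------------------
    def newick(self, lengths: bool = True, supports: bool = False) -> str:
        def fmt(n: Clade) -> str:
            if n.is_leaf():
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if supports and n.support is not None:
                    s += f"{n.support:g}"
                elif n.name:
                    s += n.name
            if lengths and n.length is not None:
                s += f":{n.length:g}"
            return s

        return fmt(self) + ";"

    def canonical_newick(self) -> str:
        """Topology-only newick with sorted children; a total order on trees."""
        def fmt(n: Clade) -> str:
            if n.is_leaf():
                return n.name or ""
            return "(" + ",".join(sorted(fmt(c) for c in n.children)) + ")"

        return fmt(self) + ";"

    def __repr__(self) -> str:
        return f"Clade({self.canonical_newick()})"


def parse_newick(newick: str) -> Clade:
    """Parse a newick string into a :class:`Clade` tree (via dendropy)."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             suppress_leaf_node_taxa=True)

    def convert(dnode) -> Clade:
        children = [convert(c) for c in dnode.child_nodes()]
        if dnode.taxon is not None:
            name = dnode.taxon.label.replace(" ", "_")
        elif not children:
            name = (dnode.label or "").replace(" ", "_")
        else:
            name = dnode.label
        node = Clade(name=name, children=children, length=dnode.edge.length)
        if dnode.label is not None and children:
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        return node

    return convert(tree.seed_node)


class SpeciesTree:
    """Rooted binary ultrametric species phylogeny with lineage labels.

    Parameters
    ----------
    root : Clade
        Rooted binary tree with branch lengths in Myr.
    lineage : dict
        leaf name -> "I" | "II" | "outgroup"; must cover all leaves.
    focal : str
        The focal species (the query genome; the role A. thaliana plays).
    wgd_nodes : iterable of frozenset, optional
        Leaf-sets whose MRCAs carry a whole-genome duplication flag.
    """

    def __init__(self, root: Clade, lineage: dict[str, str], focal: str,
                 wgd_nodes=(), tol: float = ULTRAMETRIC_TOL):
        self.root = root
        self.lineage = dict(lineage)
        self.focal = focal
        self._validate_and_age(tol)
        self._label_nodes()
        self._leaf_map = {n.name: n for n in root.leaves()}
        if focal not in self._leaf_map:
            raise ValueError(f"focal species {focal!r} is not a leaf")
        self._depth = {}
        for node in root.preorder():
            self._depth[id(node)] = 0 if node.parent is None else self._depth[id(node.parent)] + 1
        self.wgd: set[int] = set()
        for leafset in wgd_nodes:
            self.wgd.add(id(self.mrca(leafset)))

    # -- construction helpers ------------------------------------------
    def _validate_and_age(self, tol: float) -> None:
        depths: dict[int, float] = {id(self.root): 0.0}
        leaf_depths = []
        for node in self.root.preorder():
            if node.parent is not None:
                if node.length is None:
                    raise ValueError("species tree branch without length")
                depths[id(node)] = depths[id(node.parent)] + node.length
            if node.is_leaf():
                if node.name is None:
                    raise ValueError("unlabeled leaf in species tree")
                if node.name not in self.lineage:
                    raise ValueError(f"leaf {node.name!r} missing from lineage map")
                leaf_depths.append(depths[id(node)])
            elif len(node.children) != 2:
                raise ValueError("species tree must be binary")
        height = max(leaf_depths)
        if max(leaf_depths) - min(leaf_depths) > tol:
            raise ValueError(
                f"species tree is not ultrametric: leaf depths span "
                f"[{min(leaf_depths):g}, {max(leaf_depths):g}]"
            )
        for node in self.root.preorder():
            node.age = 0.0 if node.is_leaf() else height - depths[id(node)]
        for node in self.root.preorder():
            for c in node.children:
                if not node.age > c.age:
                    raise ValueError("internal node age not greater than child age")

    def _label_nodes(self) -> None:
        for node in self.root.postorder():
            if node.is_leaf():
                node.label = node.name
            else:
                reps = sorted(min(c.leaf_names()) for c in node.children)
                node.label = "+".join(reps)

    # -- queries --------------------------------------------------------
    @property
    def leaves(self) -> list[Clade]:
        return self.root.leaves()

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def leaf(self, name: str) -> Clade:
        return self._leaf_map[name]

    def depth(self, node: Clade) -> int:
        return self._depth[id(node)]

    def mrca(self, names) -> Clade:
        names = list(names)
        node = self._leaf_map[names[0]]
        rest = set(names[1:])
        while not rest <= node.leaf_names():
            node = node.parent
        return node

    def age_of(self, names) -> float:
        return self.mrca(names).age

    def backbone(self) -> list[Clade]:
        """Nodes on the path root -> focal leaf (inclusive)."""
        path = list(self.leaf(self.focal).ancestors())
        return list(reversed(path))

    def is_wgd(self, node: Clade) -> bool:
        return id(node) in self.wgd

    def node_by_label(self, label: str) -> Clade:
        for node in self.root.preorder():
            if node.label == label:
                return node
        raise KeyError(label)

    def ingroup_lineages(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {"I": set(), "II": set(), "outgroup": set()}
        for sp, lin in self.lineage.items():
            out[lin].add(sp)
        return out


def read_species_tree(newick: str | Path, lineage_map: str | Path | dict,
                      focal: str | None = None, wgd_nodes=(),
                      tol: float = ULTRAMETRIC_TOL) -> SpeciesTree:
    """Build a :class:`SpeciesTree` from newick + a lineage-label TSV.

    The TSV needs columns ``species_id`` and ``lineage``; an optional
    ``focal`` column (0/1) designates the focal species if the ``focal``
    argument is not given.
    """
    text = str(newick)
    p = Path(text) if len(text) < 260 and "\n" not in text else None
    if p is not None and p.exists():
        text = p.read_text()
    root = parse_newick(text)

    if isinstance(lineage_map, (str, Path)):
        df = pd.read_csv(lineage_map, sep="\t", dtype=str)
        lineage = dict(zip(df["species_id"], df["lineage"]))
        if focal is None and "focal" in df.columns:
            marked = df.loc[df["focal"].astype(int) == 1, "species_id"].tolist()
            if len(marked) != 1:
                raise ValueError("lineage map must mark exactly one focal species")
            focal = marked[0]
    else:
        lineage = dict(lineage_map)
    if focal is None:
        raise ValueError("no focal species designated")
    return SpeciesTree(root, lineage, focal, wgd_nodes=wgd_nodes, tol=tol)
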