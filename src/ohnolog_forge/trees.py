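"""Rooted-tree primitives: a lightweight node class, newick/NHX round-tripping
(parsing delegated to dendropy) and the species tree used for reconciliation.

Gene trees carry reconciliation annotations on internal nodes (event, mapped
taxon, species-intersection support, bootstrap).  The species tree exposes the
ancestor/descendant queries that LCA mapping and duplication timing need.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy

from .errors import InputError

SPECIATION = "speciation"
DUPLICATION = "duplication"


class TreeNode:
    """A node of a rooted tree.

    ``name`` is the gene id (leaves), taxon name (species-tree internals) or a
    stable node label (gene-tree internals).  Reconciliation fills ``event``,
    ``taxon`` and ``sis``; simulators may fill ``bootstrap``.
    """

    __slots__ = ("name", "children", "parent", "event", "taxon", "sis", "bootstrap")

    def __init__(self, name: Optional[str] = None):
        self.name = name
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.event: Optional[str] = None
        self.taxon: Optional[str] = None
        self.sis: Optional[float] = None
        self.bootstrap: Optional[float] = None

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def internal_nodes(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if not n.is_leaf]

    def ancestors(self, include_self: bool = False) -> Iterator["TreeNode"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def is_ancestor_of(self, other: "TreeNode") -> bool:
        return any(a is self for a in other.ancestors())

    # -- serialisation -----------------------------------------------------
    def to_newick(self, annotate: bool = False) -> str:
        """Newick string; with ``annotate`` internal nodes carry NHX comments
        (``ev``/``tx``/``sis``/``b``) so reconciled trees survive a round trip."""

        def fmt(node: TreeNode) -> str:
            label = node.name or ""
            if node.is_leaf:
                body = label
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
            if annotate and not node.is_leaf:
                tags = []
                if node.event:
                    tags.append(f"ev={'D' if node.event == DUPLICATION else 'S'}")
                if node.taxon:
                    tags.append(f"tx={node.taxon}")
                if node.sis is not None:
                    tags.append(f"sis={node.sis:g}")
                if node.bootstrap is not None:
                    tags.append(f"b={node.bootstrap:g}")
                if tags:
                    body += "[&&NHX:" + ":".join(tags) + "]"
            return body

        return fmt(self) + ";"

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name)
        clone.event, clone.taxon, clone.sis, clone.bootstrap = (
            self.event, self.taxon, self.sis, self.bootstrap)
        for child in self.children:
            clone.add_child(child.copy())
        return clone


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    name = None
    if dnode.taxon is not None:
        name = dnode.taxon.label
    elif dnode.label:
        name = dnode.label
    node = TreeNode(name.replace(" ", "_") if name else None)
    comments = list(dnode.comments or [])
    for comment in comments:
        if comment.startswith("&&NHX"):
            for field in comment.split(":")[1:]:
                key, _, val = field.partition("=")
                if key == "ev":
                    node.event = DUPLICATION if val == "D" else SPECIATION
                elif key == "tx":
                    node.taxon = val
                elif key == "sis":
                    node.sis = float(val)
                elif key == "b":
                    node.bootstrap = float(val)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(newick: str) -> TreeNode:
    """Parse one rooted newick (optionally NHX-annotated) tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"cannot parse newick: {exc}") from exc
    return _from_dendropy(tree.seed_node)


def read_newick_file(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


class SpeciesTree:
    """Rooted species tree with uniquely named internal taxa.

    Provides LCA queries over species leaves and the rank/ordering helpers
    ("is taxon X younger than Y") that duplication timing relies on.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.by_name: dict[str, TreeNode] = {}
        self.depth: dict[str, int] = {}
        synth = 0
        for node in root.preorder():
            if node.name is None:
                # unnamed internal: synthesize a stable name from child leaves
                tips = sorted(node.leaf_names())
                node.name = f"clade_{tips[0]}_{tips[-1]}"
                synth += 1
            if node.name in self.by_name:
                raise InputError(f"duplicate taxon name in species tree: {node.name}")
            self.by_name[node.name] = node
            self.depth[node.name] = (
                0 if node.parent is None else self.depth[node.parent.name] + 1
            )
        self.n_synthesized_names = synth
        self.species = set(root.leaf_names())

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        return cls(parse_newick(newick))

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    def node(self, name: str) -> TreeNode:
        try:
            return self.by_name[name]
        except KeyError:
            raise InputError(f"unknown taxon or species: {name!r}") from None

    def lca(self, names) -> TreeNode:
        """LCA of a set of species/taxon names."""
        nodes = [self.node(n) for n in set(names)]
        if not nodes:
            raise InputError("LCA of an empty name set")
        paths = []
        for node in nodes:
            path = list(node.ancestors(include_self=True))[::-1]  # root..node
            paths.append(path)
        lca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                lca = level[0]
            else:
                break
        return lca

    def is_ancestor_or_equal(self, a: str, b: str) -> bool:
        """True if taxon ``a`` is ancestral to or equal to taxon ``b``."""
        na, nb = self.node(a), self.node(b)
        return na is nb or na.is_ancestor_of(nb)

    def is_strictly_younger(self, a: str, b: str) -> bool:
        """True if taxon ``a`` lies strictly inside the clade of taxon ``b``."""
        return a != b and self.node(b).is_ancestor_of(self.node(a))


def resolve_multifurcations(root: TreeNode) -> int:
    """Resolve every multifurcation to an arbitrary ladder (first-listed child
    order), flagging the synthetic nodes with ``sis = 0.0`` so downstream
    SIS filtering drops any duplication they might induce.  Returns the number
    of nodes inserted."""
    inserted = 0
    for node in list(root.postorder()):
        while len(node.children) > 2:
            right = node.children.pop()
            left = node.children.pop()
            merged = TreeNode()
            merged.sis = 0.0
            merged.add_child(left)
            merged.add_child(right)
            node.add_child(merged)
            inserted += 1
    return inserted


def suppress_unary(root: TreeNode) -> TreeNode:
    """Collapse unary nodes (post-pruning cleanup); returns the new root."""
    def collapse(node: TreeNode) -> TreeNode:
        node.children = [collapse(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) == 1:
            child = node.children[0]
            child.parent = node.parent
            return child
        return node

    new_root = collapse(root)
    new_root.parent = None
    return new_root


def prune_leaves(root: TreeNode, keep: Callable[[TreeNode], bool]) -> Optional[TreeNode]:
    """Drop leaves failing ``keep`` and suppress resulting unary nodes.
    Returns None if nothing survives."""
    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            return node if keep(node) else None
        kept = [c for c in (prune(child) for child in node.children) if c is not None]
        if not kept:
            return None
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    survivor = prune(root)
    if survivor is None:
        return None
    return suppress_unary(survivor)
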