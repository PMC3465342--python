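"""Phylogenetic tree container used throughout the package.

A :class:`Phylotree` is a light node-based tree.  Unrooted trees are stored
rooted at an arbitrary internal vertex of degree three (the usual convention
for unrooted binary trees); ``rooted`` records whether the root is meaningful.
Newick parsing is delegated to dendropy; writing is direct.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

import dendropy

__all__ = ["Node", "Phylotree", "robinson_foulds"]


class Node:
    __slots__ = ("children", "parent", "length", "label", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.label = label
        self.annotations: dict = {}

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Phylotree:
    """Binary tree over taxon labels with optional branch lengths.

    Parameters
    ----------
    root
        Root node.  For ``rooted=False`` the root should be an internal
        vertex of degree three (or a leaf-pair cherry for two taxa).
    rooted
        Whether the root placement is meaningful.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "Phylotree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)
        if rooted is None:
            # a bifurcating root means a rooted tree by convention
            rooted = (bool(dt.is_rooted)
                      or len(dt.seed_node.child_nodes()) == 2)

        def convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            n = Node(label=label, length=dn.edge.length)
            if n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length {n.length}")
            for c in dn.child_nodes():
                n.add_child(convert(c))
            return n

        tree = cls(convert(dt.seed_node), rooted=rooted)
        if not rooted and len(tree.root.children) == 2 and tree.n_leaves > 2:
            tree.unroot()
        return tree

    def to_newick(self, include_lengths: bool = True, label_key: str | None = None,
                  precision: int = 10) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if label_key is not None and label_key in n.annotations:
                    s += str(n.annotations[label_key])
                elif n.label:
                    s += str(n.label)
            if include_lengths and n.length is not None:
                s += f":{n.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    # ------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(label)

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        below: dict[Node, set] = {}
        for n in self.postorder():
            below[n] = {n.label} if n.is_leaf else set().union(*(below[c] for c in n.children))
            if want <= below[n]:
                return n
        raise KeyError(f"taxa {want} not all present")

    # ------------------------------------------------------------- structure
    def copy(self) -> "Phylotree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.annotations = dict(n.annotations)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return Phylotree(clone(self.root), rooted=self.rooted)

    def unroot(self) -> "Phylotree":
        """Collapse a degree-2 root into a trident; marks the tree unrooted."""
        r = self.root
        while len(r.children) == 2 and any(not c.is_leaf for c in r.children):
            keep = next(c for c in r.children if not c.is_leaf)
            other = next(c for c in r.children if c is not keep)
            if keep.length is not None or other.length is not None:
                other.length = (other.length or 0.0) + (keep.length or 0.0)
            for gc in list(keep.children):
                r.children.append(gc)
                gc.parent = r
            r.children.remove(keep)
            r = self.root
        self.rooted = False
        return self

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Phylotree":
        """Return a copy rooted on the edge above ``child`` (matched by split)."""
        t = self.copy()
        target = _match_node(t, child)
        return _reroot(t, target, fraction)

    def root_with_outgroup(self, outgroup: Iterable[str]) -> "Phylotree":
        og = set(outgroup)
        t = self.copy()
        for n in t.postorder():
            if n is t.root:
                continue
            s = set(leaf_set(n))
            if s == og:
                return _reroot(t, n, 0.5)
        raise ValueError("outgroup is not a clade of this tree")

    def prune_taxa(self, labels: Iterable[str]) -> "Phylotree":
        """Return a copy with the given taxa removed (degree-2 vertices suppressed)."""
        drop = set(labels)
        t = self.copy()
        changed = True
        while changed:
            changed = False
            for n in list(t.postorder()):
                if (n.is_leaf and (n.label in drop or n.label is None)
                        and n.parent is not None):
                    n.parent.children.remove(n)
                    changed = True
            # suppress unary internals
            for n in list(t.postorder()):
                if not n.is_leaf and len(n.children) == 1 and n.parent is not None:
                    c = n.children[0]
                    if c.length is not None or n.length is not None:
                        c.length = (c.length or 0.0) + (n.length or 0.0)
                    i = n.parent.children.index(n)
                    n.parent.children[i] = c
                    c.parent = n.parent
                    changed = True
        while not t.root.is_leaf and len(t.root.children) == 1:
            t.root = t.root.children[0]
            t.root.parent = None
            t.root.length = None
        return t

    # ----------------------------------------------------------- comparison
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized as the side lacking the
        lexicographically smallest taxon (rooting-independent)."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out = set()
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            side = frozenset(leaf_set(n))
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(side)
        return out

    def clades(self) -> set[frozenset]:
        """Rooted clades (leaf sets below each internal node except the root)."""
        out = set()
        for n in self.postorder():
            if n.is_leaf or n is self.root:
                continue
            out.add(frozenset(leaf_set(n)))
        return out

    def has_clade(self, taxa: Iterable[str]) -> bool:
        """True if ``taxa`` form a split of the unrooted tree."""
        want = frozenset(taxa)
        all_taxa = frozenset(self.taxa)
        comp = all_taxa - want
        for n in self.postorder():
            s = frozenset(leaf_set(n))
            if s == want or s == comp:
                return True
        return False


def leaf_set(node: Node) -> list[str]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return out


def _match_node(tree: Phylotree, ref: Node) -> Node:
    want = frozenset(leaf_set(ref))
    for n in tree.postorder():
        if frozenset(leaf_set(n)) == want and n is not tree.root:
            return n
    raise ValueError("no matching node in tree copy")


def _reroot(t: Phylotree, target: Node, fraction: float) -> Phylotree:
    """Destructively reroot ``t`` on the edge above ``target``."""
    old_len = target.length
    new_root = Node()
    # reverse parent pointers from target's parent up to the old root
    path = []
    p = target.parent
    while p is not None:
        path.append(p)
        p = p.parent
    target.parent.children.remove(target)
    prev = new_root
    prev_len = None if old_len is None else old_len * (1 - fraction)
    for node in path:
        if node.parent is not None:
            node.parent.children.remove(node)
        nl = node.length
        node.length = prev_len
        prev_len = nl
        prev.add_child(node)
        prev = node
    # suppress the old root if it became unary
    last = path[-1] if path else None
    if last is not None and len(last.children) == 1:
        c = last.children[0]
        if c.length is not None or last.length is not None:
            c.length = (c.length or 0.0) + (last.length or 0.0)
        gp = last.parent
        i = gp.children.index(last)
        gp.children[i] = c
        c.parent = gp
    target.length = None if old_len is None else old_len * fraction
    new_root.children.insert(0, target)
    target.parent = new_root
    t.root = new_root
    t.rooted = True
    return t


def robinson_foulds(a: Phylotree, b: Phylotree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric split difference)."""
    if set(a.taxa) != set(b.taxa):
        raise ValueError("trees are over different taxon sets")
    return len(a.bipartitions() ^ b.bipartitions())


def random_topology(taxa: list[str], rng) -> Phylotree:
    """Uniform-ish random unrooted binary topology by sequential insertion."""
    taxa = list(taxa)
    if len(taxa) < 3:
        root = Node()
        for t in taxa:
            root.add_child(Node(t))
        return Phylotree(root, rooted=False)
    order = list(taxa)
    rng.shuffle(order)
    root = Node()
    for t in order[:3]:
        root.add_child(Node(t))
    tree = Phylotree(root, rooted=False)
    for t in order[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[rng.integers(len(edges))]
        attach_on_edge(tree, target, Node(t))
    return tree


def attach_on_edge(tree: Phylotree, edge_child: Node, subtree: Node) -> Node:
    """Insert a new internal vertex on the edge above ``edge_child`` and hang
    ``subtree`` from it.  Returns the new vertex."""
    parent = edge_child.parent
    new = Node()
    i = parent.children.index(edge_child)
    parent.children[i] = new
    new.parent = parent
    if edge_child.length is not None:
        new.length = edge_child.length / 2
        edge_child.length = edge_child.length / 2
    new.add_child(edge_child)
    new.add_child(subtree)
    return new


def detach(tree: Phylotree, node: Node) -> None:
    """Remove the subtree at ``node``; suppress the resulting unary vertex."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if parent is tree.root:
        if len(parent.children) == 1 and not parent.children[0].is_leaf:
            tree.root = parent.children[0]
            tree.root.parent = None
            tree.root.length = None
    elif len(parent.children) == 1:
        c = parent.children[0]
        if c.length is not None or parent.length is not None:
            c.length = (c.length or 0.0) + (parent.length or 0.0)
        gp = parent.parent
        i = gp.children.index(parent)
        gp.children[i] = c
        c.parent = gp


def all_unrooted_topologies(taxa: list[str]) -> Iterator[Phylotree]:
    """Enumerate all (2n-5)!! unrooted binary topologies by leaf insertion."""
    taxa = list(taxa)
    if len(taxa) < 3:
        root = Node()
        for t in taxa:
            root.add_child(Node(t))
        yield Phylotree(root, rooted=False)
        return

    def build(labels):
        if len(labels) == 3:
            root = Node()
            for t in labels:
                root.add_child(Node(t))
            yield Phylotree(root, rooted=False)
            return
        last = labels[-1]
        for sub in build(labels[:-1]):
            edges = [n for n in sub.postorder() if n is not sub.root]
            for k in range(len(edges)):
                t2 = sub.copy()
                edges2 = [n for n in t2.postorder() if n is not t2.root]
                attach_on_edge(t2, edges2[k], Node(last))
                yield t2

    yield from build(taxa)
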