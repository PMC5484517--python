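"""Phylogenetic trees with branch lengths and edge-attached supports.

Trees are stored rooted-in-memory: an unrooted tree is represented with a
trifurcating (or higher-degree) root, a rooted tree with a bifurcating root
and ``rooted=True``.  Bootstrap supports live on *edges* (stored on the child
node of each parent-child edge) so they survive rerooting: a support is a
property of the bipartition an edge induces, not of a node.

Newick parsing is delegated to dendropy; serialization is an in-repo
canonical writer (children ordered by smallest contained leaf label) so that
topologically identical trees produce byte-identical output.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} len={self.length:g}>"


class PhyloTree:
    """A leaf-labelled tree with non-negative branch lengths.

    ``rooted`` marks whether the root placement is meaningful.  Leaf labels
    must be unique and branch lengths non-negative.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, support_convention: str = "internal_label") -> "PhyloTree":
        return parse_newick(text, support_convention)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def _validate(self):
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node.length < 0:
                raise TreeError(f"negative branch length on {node.name or 'internal'}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for node in self.postorder():
            if node.is_leaf and node.name == name:
                return node
        raise TreeError(f"leaf {name!r} not found")

    def edges(self) -> list[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Edges whose removal induces a non-trivial bipartition."""
        n_total = len(self.leaves())
        out = []
        for node in self.edges():
            below = len(_leafset(node))
            if 2 <= below <= n_total - 2:
                out.append(node)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, with_support: bool = False):
        """Non-trivial bipartitions as canonical frozensets.

        Canonical side: the smaller side; ties broken by lexicographically
        smallest sorted label tuple.  With ``with_support=True`` returns a
        dict bipartition -> support (None when absent).  For a rooted binary
        tree the two root edges induce the same bipartition; it is reported
        once (support taken from either edge, preferring a non-None value).
        """
        all_leaves = frozenset(self.leaf_names())
        n = len(all_leaves)
        result: dict[frozenset, float | None] = {}
        for node in self.postorder():
            if node.parent is None or node.is_leaf:
                continue
            side = _leafset(node)
            if len(side) < 2 or len(side) > n - 2:
                continue
            key = canonical_side(side, all_leaves)
            if key in result and result[key] is not None:
                continue
            result[key] = node.support
        if with_support:
            return result
        return set(result)

    # -- rerooting ---------------------------------------------------------

    def reroot_at_node(self, node: Node) -> None:
        """Make ``node`` the root by reversing parent pointers in place.

        Edge attributes (length, support) belong to edges: when the
        parent-child direction of an edge flips, its attributes move to the
        new child.  A degree-2 former root is spliced out.
        """
        if node is self.root:
            return
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        # path = [node, p1, ..., old_root]; edge (p_i, p_{i+1}) carries the
        # attrs currently stored on p_i
        attrs = [(p.length, p.support) for p in path[:-1]]
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
        node.parent = None
        for (length, support), new_child in zip(attrs, path[1:]):
            new_child.length = length
            new_child.support = support
        node.length = 0.0
        node.support = None
        self.root = node
        old_root = path[-1]
        if len(old_root.children) == 1:
            _suppress_unifurcation(old_root)
        self.rooted = False

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> None:
        """Root the tree on the edge above ``child``.

        A new degree-2 root splits the edge; ``fraction`` of its length goes
        to the side of ``child``'s old parent.  Both halves keep the original
        edge's support (they induce the same bipartition).
        """
        parent = child.parent
        if parent is None:
            raise TreeError("cannot root above the root")
        length, support = child.length, child.support
        self.reroot_at_node(parent)
        parent = child.parent  # may have been spliced; re-resolve
        parent.children.remove(child)
        child.parent = None
        rest: Node = parent
        if len(parent.children) == 1 and parent.parent is None:
            # old root left with a single child: splice it out
            rest = parent.children[0]
            rest.length += parent.length
            if rest.support is None:
                rest.support = parent.support
            rest.parent = None
            parent.children = []
        new_root = Node()
        new_root.add_child(child)
        new_root.add_child(rest)
        child.length = length * (1.0 - fraction)
        child.support = support
        if rest is parent:
            rest.length = length * fraction
            rest.support = support
        else:
            rest.length += length * fraction
        self.root = new_root
        self.rooted = True

    def unroot(self) -> None:
        """Collapse a bifurcating root into a trifurcation (in place)."""
        if len(self.root.children) == 2:
            internal = [c for c in self.root.children if not c.is_leaf]
            if not internal:
                raise TreeError("cannot unroot a 2-leaf tree")
            self.reroot_at_node(internal[0])
        self.rooted = False

    # -- misc --------------------------------------------------------------

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def __str__(self):
        return write_newick(self)


def _leafset(node: Node) -> frozenset:
    out = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur.name)
        else:
            stack.extend(cur.children)
    return frozenset(out)


def leafset_below(node: Node) -> frozenset:
    return _leafset(node)


def canonical_side(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if tuple(sorted(side)) <= tuple(sorted(other)) else other


def _suppress_unifurcation(node: Node) -> None:
    """Splice out a degree-2 node (one child, possibly a parent)."""
    (child,) = node.children
    parent = node.parent
    if parent is None:
        return
    child.length += node.length
    if child.support is None:
        child.support = node.support
    idx = parent.children.index(node)
    parent.children[idx] = child
    child.parent = parent
    node.children = []
    node.parent = None


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, support_convention: str = "internal_label") -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Under the ``internal_label`` convention, numeric internal-node labels are
    interpreted as bootstrap supports of the edge above the node.  Missing
    branch lengths default to 0.
    """
    if support_convention not in ("internal_label", "comment"):
        raise ValueError(f"unknown support convention {support_convention!r}")
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick string must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
        else:
            node = Node(length=dnode.edge.length or 0.0)
            label = dnode.label
            if label is not None:
                if support_convention == "internal_label" and _is_number(label):
                    node.support = float(label)
                else:
                    node.name = label
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _fmt_length(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: PhyloTree, with_lengths: bool = True,
                 with_supports: bool = True) -> str:
    """Canonical Newick serialization.

    Children are ordered by the smallest leaf label contained in each
    subtree, so two topologically identical trees (regardless of their
    in-memory child order) serialize to byte-identical strings.  Branch
    lengths are printed with 6 significant digits; supports as internal node
    labels.
    """

    def render(node: Node) -> tuple[str, str]:
        # returns (min_leaf_label, newick_fragment)
        suffix = ""
        if with_lengths and node.parent is not None:
            suffix = f":{_fmt_length(node.length)}"
        if node.is_leaf:
            return node.name, f"{node.name}{suffix}"
        parts = sorted(render(c) for c in node.children)
        label = ""
        if with_supports and node.support is not None and node.parent is not None:
            label = _fmt_length(node.support)
        elif node.name:
            label = node.name
        body = "(" + ",".join(p[1] for p in parts) + ")" + label
        return parts[0][0], body + suffix

    if tree.root.is_leaf:
        return f"{tree.root.name}:{_fmt_length(tree.root.length)};"
    return render(tree.root)[1] + ";"


def read_tree_newick(path, support_convention: str = "internal_label") -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), support_convention)


def write_tree_newick(tree: PhyloTree, path=None) -> str:
    text = write_newick(tree)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unweighted Robinson-Foulds distance (bipartition symmetric difference)."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise TreeError("trees have different leaf sets")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)
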