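"""Rooted trees, Newick I/O, and composite-tree topology operations.

The :class:`Tree` here is a deliberately small rooted-tree container: labeled
tips, optional internal labels, optional non-negative branch lengths, and
polytomies allowed.  Parsing and serialization are delegated to dendropy; the
Newick dialect treats underscores in unquoted labels as literal characters
(species-name style, ``Mnemiopsis_leidyi``), and labels containing spaces or
other special characters are quoted on output.

Topology operations support assembling a composite phylogeny from published
subtrees (:func:`graft_clade`), building alternative rooting scenarios such as
ctenophore-sister vs sponge-sister (:func:`swap_sister_lineage`), and the
branch-length sensitivity transforms (:func:`set_equal_branch_lengths`,
:func:`make_ultrametric`).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "write_newick_file",
    "graft_clade",
    "swap_sister_lineage",
    "set_equal_branch_lengths",
    "replace_tip",
    "drop_tips",
    "make_ultrametric",
    "is_ultrametric",
]


class TreeError(ValueError):
    """Structural error on a tree operation (bad labels, non-monophyly...)."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class Node:
    """A node in a rooted tree.

    Attributes
    ----------
    label : str or None
        Tip labels are required and unique; internal labels optional.
    length : float or None
        Branch length of the edge above this node; ``None`` means absent
        (distinct from zero).  The root's length is ignored.
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length}>"


class Tree:
    """A rooted tree with labeled tips and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("every tip must carry a non-empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label: {node.label!r}")
                seen.add(node.label)
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} above {node.label!r}"
                )
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("broken parent link")

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        """Children before parents; iterative to tolerate deep trees."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_tips(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_tip(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"tip {label!r} not found")

    def find_node(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise TreeError(f"node {label!r} not found")

    # -- structure queries ----------------------------------------------

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(labels)
        if not want:
            raise TreeError("empty label set")
        have = set(self.leaf_labels())
        missing = want - have
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(want) == 1:
            return self.find_tip(next(iter(want)))
        # count of wanted tips below each node; first covering node in postorder
        below: dict[int, int] = {}
        for node in self.postorder():
            if node.is_leaf:
                c = 1 if node.label in want else 0
            else:
                c = sum(below[id(ch)] for ch in node.children)
            below[id(node)] = c
            if c == len(want):
                return node
        raise TreeError("unreachable")  # pragma: no cover

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        want = set(labels)
        node = self.mrca(want)
        return {leaf.label for leaf in _subtree_leaves(node)} == want

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths; absent lengths raise."""
        out: dict[str, float] = {}
        acc: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is not self.root:
                if node.length is None:
                    raise TreeError(f"branch length absent above {node.label!r}")
                acc[id(node)] = acc[id(node.parent)] + node.length
            if node.is_leaf:
                out[node.label] = acc[id(node)]
        return out

    def branch_lengths(self) -> dict[str, float]:
        """label -> stem length for every labeled node with a length."""
        out = {}
        for node in self.postorder():
            if node is self.root or node.label is None or node.length is None:
                continue
            out[node.label] = node.length
        return out

    def total_length(self) -> float:
        return sum(
            n.length for n in self.postorder()
            if n is not self.root and n.length is not None
        )

    # -- copying & transforms -------------------------------------------

    def copy(self) -> "Tree":
        # iterative clone (deep recursion unsafe on big caterpillar trees)
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(mapping[id(child)])
            mapping[id(node)] = new
        return Tree(mapping[id(self.root)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return _node_eq(self.root, other.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {self.n_tips} tips>"


def _subtree_leaves(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def _node_eq(a: Node, b: Node) -> bool:
    if a.label != b.label or len(a.children) != len(b.children):
        return False
    la = a.length
    lb = b.length
    if (la is None) != (lb is None):
        return False
    if la is not None and abs(la - lb) > 1e-12 * max(1.0, abs(la)):
        return False
    return all(_node_eq(ca, cb) for ca, cb in zip(a.children, b.children))


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def convert(dnode: dendropy.Node) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    # iterative
    mapping: dict[int, Node] = {}
    for dnode in dtree.postorder_node_iter():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(mapping[id(dchild)])
        mapping[id(dnode)] = node
    root = mapping[id(dtree.seed_node)]
    root.length = None  # dendropy may carry a root edge; the root has no branch
    return Tree(root)


def _to_dendropy(tree: Tree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    mapping: dict[int, dendropy.Node] = {}
    for node in tree.postorder():
        dnode = dendropy.Node()
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = taxa.new_taxon(label=node.label)
        elif node.label is not None:
            dnode.label = node.label
        for child in node.children:
            dnode.add_child(mapping[id(child)])
        mapping[id(node)] = dnode
    dtree.seed_node = mapping[id(tree.root)]
    return dtree


def read_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Underscores in unquoted labels are literal; quoted labels may contain
    spaces.  Missing branch lengths stay ``None``.  Raises
    :class:`NewickParseError` (with the reader's line/column diagnostics) on
    malformed input and :class:`TreeError` on duplicate tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(str(exc)) from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> Tree:
    with open(path, encoding="utf-8") as fh:
        return read_newick(fh.read())


def write_newick(tree: Tree) -> str:
    """Serialize to single-line Newick; ``read_newick`` round-trips it."""
    dtree = _to_dendropy(tree)
    out = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier="",
    )
    return out.strip()


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Topology operations
# ---------------------------------------------------------------------------


def graft_clade(backbone: Tree, clade_tips: Iterable[str], donor: Tree) -> Tree:
    """Replace a monophyletic clade of ``backbone`` with the ``donor`` tree.

    The clade spanned by ``clade_tips`` (a single tip may act as a
    placeholder) is excised and the donor's root takes its place, inheriting
    the excised clade's stem branch length.  Donor tip labels must not
    collide with the remaining backbone tips.  This is the composite-tree
    assembly step: a coarse backbone is refined by grafting in densely
    sampled published subtrees.
    """
    clade_tips = set(clade_tips)
    result = backbone.copy()
    target = result.mrca(clade_tips)
    if {leaf.label for leaf in _subtree_leaves(target)} != clade_tips:
        raise TreeError(f"clade tips {sorted(clade_tips)} are not monophyletic")
    if target is result.root:
        raise TreeError("cannot graft over the entire backbone")
    remaining = set(result.leaf_labels()) - clade_tips
    collide = remaining & set(donor.leaf_labels())
    if collide:
        raise TreeError(f"donor labels collide with backbone: {sorted(collide)}")
    incoming = donor.copy().root
    incoming.length = target.length  # inherit the stem
    parent = target.parent
    idx = parent.children.index(target)
    parent.children[idx] = incoming
    incoming.parent = parent
    target.parent = None
    return Tree(result.root)


def swap_sister_lineage(tree: Tree, clade_tips: Iterable[str]) -> Tree:
    """Re-root the ingroup so the named clade is sister to all other ingroup tips.

    The ingroup is the root child whose subtree contains ``clade_tips``
    (outgroups, the other root children, are untouched).  Within-clade
    topology and branch lengths are preserved; the moved clade keeps its own
    stem length, and the stem of its new sister group accumulates the lengths
    of any branches collapsed by the rearrangement.  Used to switch between
    the ctenophore-sister and sponge-sister hypotheses for the animal root.
    """
    clade_tips = set(clade_tips)
    result = tree.copy()
    clade = result.mrca(clade_tips)
    if {leaf.label for leaf in _subtree_leaves(clade)} != clade_tips:
        raise TreeError(f"clade tips {sorted(clade_tips)} are not monophyletic")
    if clade is result.root:
        raise TreeError("clade is the whole tree")
    # ingroup root: the root child on the path to the clade
    ingroup = clade
    while ingroup.parent is not result.root:
        ingroup = ingroup.parent
    if clade is ingroup:
        raise TreeError("clade is the entire ingroup; nothing to swap")
    if clade.parent is ingroup and len(ingroup.children) == 2:
        return result  # already sister to the rest of the ingroup

    root = result.root
    ingroup_stem = ingroup.length
    ingroup_idx = root.children.index(ingroup)

    # detach the clade, then suppress the degree-1 nodes it leaves behind,
    # summing lengths into the surviving child's stem
    parent = clade.parent
    parent.remove_child(clade)
    rest = ingroup
    node = parent
    while node is not None and len(node.children) == 1:
        child = node.children[0]
        up = node.parent
        if node is ingroup:
            # the old ingroup root vanishes; its stem is reused below for the
            # new ingroup node, so the survivor keeps only the collapsed
            # intermediate lengths it already absorbed
            child.parent = None
            rest = child
            break
        if not (child.length is None and node.length is None):
            child.length = (child.length or 0.0) + (node.length or 0.0)
        idx = up.children.index(node)
        up.children[idx] = child
        child.parent = up
        node.parent = None
        node = up
    if rest is ingroup:
        root.remove_child(ingroup)
        ingroup.length = 0.0 if ingroup.length is not None else None

    new_ingroup = Node(label=None, length=ingroup_stem)
    new_ingroup.add_child(clade)  # clade keeps its own stem length
    new_ingroup.add_child(rest)
    root.children.insert(ingroup_idx, new_ingroup)
    new_ingroup.parent = root
    return Tree(result.root)


def set_equal_branch_lengths(tree: Tree, value: float = 1.0) -> Tree:
    """Return a copy with every branch length set to ``value``.

    The equal-branch-length rerun asks how much the reconstruction depends on
    molecular branch-length estimates rather than topology alone.
    """
    if not value > 0:
        raise TreeError(f"branch length must be positive, got {value}")
    result = tree.copy()
    for node in result.postorder():
        if node is not result.root:
            node.length = float(value)
    return result


def replace_tip(tree: Tree, old_label: str, new_label: str) -> Tree:
    """Rename one tip; topology and branch lengths are untouched.

    Models taxon-substitution sensitivity checks (e.g. swapping
    *Xenoturbella bocki* for *X. profunda*, whose coded sexual modes differ).
    """
    if old_label == new_label or new_label in set(tree.leaf_labels()):
        raise TreeError(f"label {new_label!r} already present")
    result = tree.copy()
    result.find_tip(old_label).label = new_label
    return Tree(result.root)


def drop_tips(tree: Tree, labels: Iterable[str]) -> Tree:
    """Remove the named tips, suppressing degree-1 nodes (lengths summed).

    Used to drop outgroups before ancestral-state reconstruction.
    """
    labels = set(labels)
    missing = labels - set(tree.leaf_labels())
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(labels) >= tree.n_tips - 1:
        raise TreeError("cannot drop all (or all but one) tips")
    result = tree.copy()
    root = result.root
    for label in labels:
        tip = next(n for n in _subtree_leaves(root) if n.label == label)
        parent = tip.parent
        parent.remove_child(tip)
        node = parent
        while node is not None and len(node.children) == 1:
            child = node.children[0]
            up = node.parent
            if up is None:  # root became degree-1: its child is the new root
                child.parent = None
                child.length = None
                root = child
                break
            child.length = (
                None
                if child.length is None and node.length is None
                else (child.length or 0.0) + (node.length or 0.0)
            )
            idx = up.children.index(node)
            up.children[idx] = child
            child.parent = up
            node = up
    return Tree(root)


def is_ultrametric(tree: Tree, rel_tol: float = 1e-9) -> bool:
    depths = list(tree.depths().values())
    spread = max(depths) - min(depths)
    scale = max(max(depths), 1e-300)
    return spread <= rel_tol * scale


def make_ultrametric(tree: Tree, method: str = "mean-path-length") -> Tree:
    """Transform branch lengths so all root-to-tip paths are equal.

    Mean-path-length smoothing: each internal node's age is the mean, over
    the tips in its subtree, of the path length from the node down to the
    tip; branch lengths become parent age minus child age.  Ages are clamped
    bottom-up so they never decrease toward the root (a child deeper than its
    parent's raw mean would otherwise produce a negative branch).
    Deterministic and parameter-free, unlike penalized-likelihood dating.
    """
    if method != "mean-path-length":
        raise ValueError(f"unknown method {method!r}")
    if tree.n_tips < 2:
        raise TreeError("need at least 2 tips")
    result = tree.copy()
    age: dict[int, float] = {}
    ntips: dict[int, int] = {}
    pathsum: dict[int, float] = {}  # sum over subtree tips of node->tip path
    for node in result.postorder():
        if node.is_leaf:
            age[id(node)] = 0.0
            ntips[id(node)] = 1
            pathsum[id(node)] = 0.0
        else:
            s = 0.0
            n = 0
            for child in node.children:
                if child.length is None:
                    raise TreeError(
                        f"branch length absent above {child.label!r}"
                    )
                s += pathsum[id(child)] + child.length * ntips[id(child)]
                n += ntips[id(child)]
            ntips[id(node)] = n
            pathsum[id(node)] = s
            raw = s / n
            age[id(node)] = max(raw, max(age[id(c)] for c in node.children))
    for node in result.postorder():
        if node is not result.root:
            node.length = age[id(node.parent)] - age[id(node)]
    return Tree(result.root)
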