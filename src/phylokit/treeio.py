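"""Phylogenetic tree containers and restructuring operations.

Trees are edge-weighted, with branch lengths in expected substitutions per
site. A tree whose base node has exactly two children is treated as rooted;
a basal multifurcation means the tree is an unrooted representation. Branch
lengths may be absent (``None``); statistics that need them raise instead of
assuming zero.

Parsing of Newick and NEXUS tree blocks is delegated to dendropy; the
in-memory representation here is deliberately small so that the
restructuring operations (outgroup rooting, unrooting, polytomy resolution)
are fully deterministic and easy to audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "TreeParseError",
    "Node",
    "PhyloTree",
    "TreeCollection",
    "parse_newick",
    "write_newick",
    "read_tree_file",
    "set_outgroup",
    "unroot_tree",
    "resolve_polytomy",
]


class TreeError(ValueError):
    """Invalid tree or invalid operation on a tree."""


class TreeParseError(TreeError):
    """Malformed Newick/NEXUS input."""


class Node:
    """A single tree node: leaf label, support label, branch length, children.

    ``length`` is the length of the edge to the parent (``None`` for the
    root, or when the input supplied no length). ``support`` carries an
    internal-node label verbatim; it plays no role in any statistic.
    """

    __slots__ = ("label", "support", "length", "children", "parent")

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label: str | None = label
        self.support: str | None = support
        self.length: float | None = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def copy(self) -> "Node":
        dup = Node(label=self.label, length=self.length, support=self.support)
        for child in self.children:
            dup.add_child(child.copy())
        return dup


class PhyloTree:
    """An edge-weighted phylogenetic tree with uniquely labeled leaves."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        labels = [leaf.label for leaf in self.leaves()]
        if any(not lab for lab in labels):
            raise TreeError("every leaf must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.root.preorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on edge above {node.label or 'internal node'}")

    # -- structure queries ------------------------------------------------

    def leaves(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def edges(self) -> list[Node]:
        """Every non-root node, i.e. one entry per edge (the child end)."""
        return [n for n in self.root.preorder() if n is not self.root]

    def has_lengths(self) -> bool:
        return all(n.length is not None for n in self.edges())

    def require_lengths(self) -> None:
        for node in self.edges():
            if node.length is None:
                where = node.label or "an internal edge"
                raise TreeError(f"branch length missing on the edge above {where}")

    def total_branch_length(self) -> float:
        self.require_lengths()
        return sum(n.length for n in self.edges())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.n_leaves} leaves, rooted={self.is_rooted})"


@dataclass
class TreeCollection:
    """An ordered list of named trees read from one or more files."""

    entries: list[tuple[str, PhyloTree]] = field(default_factory=list)

    def __post_init__(self):
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise TreeError("tree source names must be unique within a collection")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def trees(self) -> list[PhyloTree]:
        return [tree for _, tree in self.entries]


# -- parsing and writing --------------------------------------------------


def _from_dendropy(dnode) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else None
    support = None
    if dnode.child_nodes():
        support = dnode.label
        label = None
    node = Node(label=label, length=dnode.edge.length, support=support)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _convert(dtree: dendropy.Tree) -> PhyloTree:
    root = _from_dendropy(dtree.seed_node)
    root.length = None  # a length on the root edge has no meaning here
    return PhyloTree(root)


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Single-quoted labels are honored, underscores in unquoted labels are
    preserved verbatim, and square-bracket comments are dropped.
    """
    if not text or not text.strip():
        raise TreeParseError("empty Newick input (position 0)")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise TreeParseError(f"Newick statement must end with ';' (position {len(stripped)})")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    tree = _convert(dtree)
    if tree.root.is_leaf and tree.root.label is None:
        raise TreeParseError("no leaves found in Newick input (position 0)")
    return tree


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;, \t\n'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(value: float) -> str:
    if math.isnan(value) or math.isinf(value):
        raise TreeError("branch lengths must be finite")
    return f"{value:.10g}"


def _node_newick(node: Node) -> str:
    if node.is_leaf:
        out = _quote_label(node.label or "")
    else:
        inner = ",".join(_node_newick(c) for c in node.children)
        out = f"({inner})"
        if node.support:
            out += _quote_label(node.support)
    if node.length is not None:
        out += f":{_format_length(node.length)}"
    return out


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to a single ';'-terminated Newick line.

    Lengths are emitted with up to 10 significant digits; internal labels
    (support values) carried through parsing are written back.
    """
    return _node_newick(tree.root) + ";"


def read_tree_file(path, fmt: str = "newick") -> TreeCollection:
    """Read every tree in a Newick or NEXUS file into a collection.

    Entries are named by the file stem, suffixed ``_1``, ``_2``, ... when the
    file holds more than one tree. NEXUS translate tables are applied.
    """
    path = Path(path)
    if fmt not in ("newick", "nexus"):
        raise TreeError(f"unknown tree format: {fmt!r}")
    if not path.exists() or not path.read_text().strip():
        raise TreeParseError(f"no trees found in {path.name}")
    try:
        dtrees = dendropy.TreeList.get(
            path=str(path),
            schema=fmt,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeParseError(f"could not read {path.name} as {fmt}: {exc}") from exc
    if len(dtrees) == 0:
        raise TreeParseError(f"no trees found in {path.name}")
    stem = path.stem
    entries = []
    for i, dtree in enumerate(dtrees, start=1):
        name = stem if len(dtrees) == 1 else f"{stem}_{i}"
        entries.append((name, _convert(dtree)))
    return TreeCollection(entries)


# -- restructuring --------------------------------------------------------


def _leafset(node: Node) -> frozenset[str]:
    return frozenset(n.label for n in node.preorder() if n.is_leaf)


def _merge_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _suppress_unifurcations(root: Node) -> None:
    for node in list(root.preorder()):
        if node is not root and (node.parent is None or node not in node.parent.children):
            continue  # already spliced out
        while len(node.children) == 1 and node is not root:
            only = node.children[0]
            only.length = _merge_lengths(node.length, only.length)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = only
            only.parent = parent
            node = only
    while len(root.children) == 1 and root.children[0].children:
        only = root.children[0]
        only.parent = None
        only.length = None
        root.children = []
        root.label, root.support = only.label, only.support
        root.children = only.children
        for c in root.children:
            c.parent = root


def _reroot_on_edge(tree: PhyloTree, child: Node) -> PhyloTree:
    """Re-root on the edge above ``child``, splitting it into equal halves."""
    edge_len = child.length
    half = None if edge_len is None else edge_len / 2.0
    parent = child.parent
    chain = []
    node = parent
    while node is not None:
        chain.append(node)
        node = node.parent
    orig_len = {id(n): n.length for n in chain}

    parent.children.remove(child)
    new_root = Node()
    new_root.add_child(child)
    child.length = half
    new_root.add_child(parent)
    parent.length = half
    parent.parent = new_root
    for lower, upper in zip(chain, chain[1:]):
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.parent = lower
        upper.length = orig_len[id(lower)]
    chain[-1].support = None  # the old basal node carried no meaningful support
    _suppress_unifurcations(new_root)
    return PhyloTree(new_root)


def set_outgroup(tree: PhyloTree, taxa) -> PhyloTree:
    """Root the tree so that one root child subtends exactly ``taxa``.

    The attachment edge is split into two equal halves (so root-to-tip
    lengths depend on this convention). The outgroup must be separable by a
    single edge; the leaf-to-leaf patristic distances are unchanged.
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise TreeError("outgroup taxon set is empty")
    all_leaves = frozenset(tree.leaf_labels())
    unknown = taxa - all_leaves
    if unknown:
        raise TreeError(f"unknown outgroup labels: {sorted(unknown)}")
    if taxa == all_leaves:
        raise TreeError("outgroup cannot contain every leaf: no edge separates it")

    work = tree.copy()
    target = None
    outgroup_is_below = True
    complement_hit = None
    for node in work.root.preorder():
        if node is work.root:
            continue
        below = _leafset(node)
        if below == taxa:
            target = node
            outgroup_is_below = True
            break
        if below == all_leaves - taxa and complement_hit is None:
            complement_hit = node
    if target is None and complement_hit is not None:
        target = complement_hit
        outgroup_is_below = False
    if target is None:
        raise TreeError(
            "outgroup is not separable by a single edge: "
            f"no split matches {sorted(taxa)} | {sorted(all_leaves - taxa)}"
        )
    rooted = _reroot_on_edge(work, target)
    if not outgroup_is_below:
        rooted.root.children.reverse()
    return rooted


def unroot_tree(tree: PhyloTree) -> PhyloTree:
    """Convert a rooted tree to its unrooted representation.

    The two edges incident to the old root are merged (lengths summed) and
    the merged edge is attached under the first-listed root child, so the
    result is deterministic for a given input. Total branch length and the
    patristic matrix are conserved. Already-unrooted trees are returned
    unchanged (a copy).
    """
    if tree.n_leaves < 3:
        raise TreeError("unrooting needs at least 3 leaves")
    work = tree.copy()
    if not work.is_rooted:
        return work
    first, second = work.root.children
    if first.children:
        base, moved = first, second
    else:
        base, moved = second, first
    merged = _merge_lengths(first.length, second.length)
    base.parent = None
    base.length = None
    moved.length = merged
    base.add_child(moved)
    return PhyloTree(base)


def resolve_polytomy(tree: PhyloTree, inserted_length: float = 0.0) -> PhyloTree:
    """Resolve every multifurcation into nested bifurcations.

    Children are grouped left-to-right in input order: a node with children
    (k1, k2, k3, k4) becomes (k1, (k2, (k3, k4))). Inserted edges carry
    ``inserted_length`` (default 0, which leaves the patristic matrix
    unchanged). The result is strictly bifurcating, root included.
    """
    if inserted_length < 0:
        raise TreeError("inserted_length must be non-negative")
    work = tree.copy()

    def _resolve(node: Node) -> None:
        for child in node.children:
            _resolve(child)
        while len(node.children) > 2:
            rest = node.children[1:]
            group = Node(length=float(inserted_length))
            for r in rest:
                group.add_child(r)
            node.children = [node.children[0]]
            node.add_child(group)
            node = group

    _resolve(work.root)
    return PhyloTree(work.root)
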