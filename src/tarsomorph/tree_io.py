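"""Rooted phylogenies from Newick, with branches addressed by the leaf set
they subtend.

Branch lengths present in an input Newick are *not* consumed by the
analysis chain — the landmark-parsimony step derives its own lengths — but
they are retained as ``duration`` attributes (default 1.0) because the
synthetic-data generator uses them as Brownian-motion time.  Polytomies are
accepted; supertrees commonly contain them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

import dendropy

__all__ = ["TreeNode", "PhyloTree", "NewickParseError", "parse_newick", "find_branch"]

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """Raised for malformed Newick input."""


class TreeNode:
    __slots__ = ("id", "label", "children", "parent", "duration")

    def __init__(
        self,
        label: str | None = None,
        duration: float = 1.0,
    ) -> None:
        self.id: str = ""
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.duration = duration

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r})"


class PhyloTree:
    """A rooted tree over taxon labels with stable branch identifiers.

    Every non-root node identifies the branch between itself and its
    parent.  Leaves are identified by their taxon label; internal nodes get
    deterministic postorder ids ``N1, N2, ...`` so that reports and JSON
    round trips are stable.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._assign_ids()
        labels = [n.label for n in self.leaves()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise NewickParseError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dupes}")
        self._by_id = {n.id: n for n in self.postorder()}
        self._subtended = {
            n.id: frozenset(
                leaf.label for leaf in self._leaves_below(n)
            )
            for n in self.postorder()
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def _assign_ids(self) -> None:
        counter = 0
        for node in self.postorder():
            if node.is_leaf:
                node.id = str(node.label)
            else:
                counter += 1
                node.id = f"N{counter}"

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [str(n.label) for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def branches(self) -> list[str]:
        """Branch ids: the id of every non-root node (its stem branch)."""
        return [n.id for n in self.postorder() if not n.is_root]

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"no node {node_id!r} in tree") from None

    @staticmethod
    def _leaves_below(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return [node]
        out: list[TreeNode] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def subtended_leaves(self, branch_id: str) -> frozenset[str]:
        """Leaf labels below the branch's child node."""
        if branch_id not in self._subtended:
            raise KeyError(f"no branch {branch_id!r} in tree")
        return self._subtended[branch_id]

    def n_leaves(self) -> int:
        return len(self._subtended[self.root.id])

    # -- serialisation -----------------------------------------------------

    def to_newick(self, durations: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                base = str(node.label)
            else:
                base = "(" + ",".join(render(c) for c in node.children) + ")"
            if durations and not node.is_root:
                base += f":{node.duration:g}"
            return base

        return render(self.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string.

    Input branch lengths are kept as per-branch durations (default 1.0
    where missing); a notice is logged when any are present because the
    parsimony analysis ignores them.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("Newick string must end in ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    any_lengths = any(
        e.length is not None for e in dtree.preorder_edge_iter() if e.head_node is not dtree.seed_node
    )
    if any_lengths:
        logger.info(
            "input Newick carries branch lengths; the parsimony analysis "
            "derives its own lengths and keeps these only as durations"
        )

    def convert(dnode: dendropy.Node) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(
            label=label,
            duration=float(dnode.edge.length) if dnode.edge.length is not None else 1.0,
        )
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf:
        raise NewickParseError("tree has a single node; need at least 2 leaves")
    return PhyloTree(root)


def find_branch(tree: PhyloTree, clade_leaves: Iterable[str]) -> str:
    """Return the id of the branch whose child node subtends exactly
    ``clade_leaves`` — e.g. the Erythrosuchidae + Eucrocopoda stem.

    Errors name the offending leaves when the set is not monophyletic in
    this tree, and reject the full leaf set (the root has no stem branch).
    """
    clade = frozenset(clade_leaves)
    if not clade:
        raise ValueError("clade must contain at least one leaf")
    all_leaves = tree.subtended_leaves(tree.root.id)
    unknown = clade - all_leaves
    if unknown:
        raise ValueError(f"leaves not in tree: {sorted(unknown)}")
    if clade == all_leaves:
        raise ValueError("clade spans all leaves; the root has no stem branch")
    for branch_id in tree.branches():
        if tree.subtended_leaves(branch_id) == clade:
            return branch_id
    # diagnose: leaves dragged in by the MRCA
    best: frozenset[str] | None = None
    for branch_id in tree.branches():
        s = tree.subtended_leaves(branch_id)
        if clade <= s and (best is None or len(s) < len(best)):
            best = s
    extra = sorted(best - clade) if best else sorted(all_leaves - clade)
    raise ValueError(
        f"clade is not monophyletic in this tree; its smallest containing "
        f"branch also subtends {extra}"
    )
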