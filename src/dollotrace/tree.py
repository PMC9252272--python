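"""Rooted trees over sample leaves.

The trees built here are polarized by a hypothetical all-absent ancestor:
an artificial taxon carrying state 0 at every locus that sits above the
ingroup root.  The ancestor is implicit — ``Tree.root`` is the ingroup
MRCA, and the edge entering it (the "pre-root branch", branch id
``"root"``) is where characters present in every sample are gained.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

from .core import ValidationError


class TreeNode:
    __slots__ = ("name", "children", "parent", "support", "branch_id", "annotations")

    def __init__(self, name: Optional[str] = None, children: Optional[list] = None):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.support: Optional[float] = None
        self.branch_id: Optional[str] = None
        self.annotations: dict = {}
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name or self.branch_id or 'internal'})"


class Tree:
    """A rooted tree whose leaves are sample labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValidationError("every leaf must be named")
        if len(set(names)) != len(names):
            raise ValidationError("leaf labels must be unique")

    # ---------------------------------------------------------------- construction
    @classmethod
    def from_topology(cls, topo, names: Optional[Sequence[str]] = None) -> "Tree":
        """Build a tree from nested tuples of leaf indices (or labels).

        ``((0, 1), (2, 3))`` with ``names=["A","B","C","D"]`` gives the tree
        ``((A,B),(C,D))``.
        """

        def build(t) -> TreeNode:
            if isinstance(t, tuple):
                return TreeNode(children=[build(x) for x in t])
            label = names[t] if names is not None else str(t)
            return TreeNode(name=label)

        return cls(build(topo))

    def to_topology(self, index_of: dict[str, int]):
        """Inverse of :meth:`from_topology` (binary trees only)."""

        def conv(node: TreeNode):
            if node.is_leaf:
                return index_of[node.name]
            if len(node.children) != 2:
                raise ValidationError("topology export requires a binary tree")
            return (conv(node.children[0]), conv(node.children[1]))

        return conv(self.root)

    def copy(self) -> "Tree":
        def dup(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name)
            new.support = node.support
            new.branch_id = node.branch_id
            new.annotations = dict(node.annotations)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return Tree(dup(self.root))

    # ---------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, visited = stack.pop()
            if visited:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # ---------------------------------------------------------------- clades
    def clade_of(self, node: TreeNode) -> frozenset[str]:
        return frozenset(
            n.name for n in self._subtree_postorder(node) if n.is_leaf
        )

    def _subtree_postorder(self, node: TreeNode) -> Iterator[TreeNode]:
        stack = [node]
        while stack:
            cur = stack.pop()
            yield cur
            stack.extend(cur.children)

    def clades(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Rooted clades (leaf sets of internal nodes, incl. the full set).

        With ``include_trivial`` singleton leaf clades are included too.
        """
        result: set[frozenset[str]] = set()
        clade_by_node: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                clade = frozenset([node.name])
            else:
                clade = frozenset().union(
                    *(clade_by_node[id(c)] for c in node.children)
                )
            clade_by_node[id(node)] = clade
            if include_trivial or not node.is_leaf:
                result.add(clade)
        return result

    def node_clades(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` to the node's leaf set, for every node."""
        clades: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                clades[id(node)] = frozenset([node.name])
            else:
                clades[id(node)] = frozenset().union(
                    *(clades[id(c)] for c in node.children)
                )
        return clades

    def mrca(self, names: Iterable[str]) -> TreeNode:
        target = frozenset(names)
        if not target:
            raise ValidationError("MRCA of an empty leaf set is undefined")
        missing = target - set(self.leaf_names())
        if missing:
            raise ValidationError(f"unknown leaves: {sorted(missing)}")
        clades = self.node_clades()
        node = self.root
        while True:
            carriers = [c for c in node.children if target <= clades[id(c)]]
            if len(carriers) == 1:
                node = carriers[0]
            else:
                return node

    # ---------------------------------------------------------------- branch ids
    def assign_branch_ids(self) -> dict[str, TreeNode]:
        """Label the edge entering each node with a stable branch id.

        The ingroup root's incoming edge (from the hypothetical all-absent
        ancestor) is ``"root"``; leaf branches are named after the leaf;
        other internal branches get ``b1, b2, ...`` in preorder, so ids are
        reproducible for a fixed topology and child order.
        """
        mapping: dict[str, TreeNode] = {}
        counter = 1
        for node in self.preorder():
            if node is self.root:
                node.branch_id = "root"
            elif node.is_leaf:
                node.branch_id = node.name
            else:
                node.branch_id = f"b{counter}"
                counter += 1
            mapping[node.branch_id] = node
        return mapping

    def branch_ids(self) -> list[str]:
        """Branch ids in preorder; assigns them first if absent."""
        if self.root.branch_id is None:
            self.assign_branch_ids()
        return [n.branch_id for n in self.preorder()]

    def branch_clades(self) -> dict[str, frozenset[str]]:
        """Map branch id -> clade subtended by that branch."""
        if self.root.branch_id is None:
            self.assign_branch_ids()
        clades = self.node_clades()
        return {n.branch_id: clades[id(n)] for n in self.preorder()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({len(self.leaf_names())} leaves)"
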