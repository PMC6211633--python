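"""Minimal rooted representation of an (unrooted) gene tree.

A tree is a :class:`TreeNode` whose root may be multifurcating; leaf labels
are unique.  Branch lengths are attached to the child end of each edge.
Internal nodes may carry a bootstrap-style ``support`` value in [0, 1].
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    # -- construction -------------------------------------------------
    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    # -- queries ------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.traverse_preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leaf_name_set(self) -> frozenset:
        return frozenset(self.leaf_names())

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths between every pair of leaves.

        Used by tests to verify additivity of neighbor-joining output.
        """
        # distance from each node down to each descendant leaf
        down: dict[int, dict[str, float]] = {}

        def fill(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                d = {node.name: 0.0}
            else:
                d = {}
                for child in node.children:
                    for leaf, dist in fill(child).items():
                        d[leaf] = dist + (child.length or 0.0)
            down[id(node)] = d
            return d

        fill(self)
        out: dict[tuple[str, str], float] = {}

        def collect(node: TreeNode) -> None:
            kids = node.children
            for i in range(len(kids)):
                di = down[id(kids[i])]
                li = kids[i].length or 0.0
                for j in range(i + 1, len(kids)):
                    dj = down[id(kids[j])]
                    lj = kids[j].length or 0.0
                    for a, da in di.items():
                        for b, db in dj.items():
                            key = (a, b) if a < b else (b, a)
                            out[key] = da + li + db + lj
            for child in kids:
                collect(child)

        collect(self)
        return out

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<TreeNode {self.name!r} {kind}>"


GeneTree = TreeNode
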