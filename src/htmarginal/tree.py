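"""Dimension trees and matricization for hierarchical Tucker tensors.

A dimension tree is a binary tree over the mode set {0, ..., d-1} (modes are
0-based internally).  The root carries all modes; every inner node splits its
modes into the first ceil(m/2) and remaining floor(m/2) positions *in leaf
order*; leaves carry single modes.  The leaf order is the knob that controls
achievable ranks: grouping strongly interacting automata in the same subtree
keeps the ranks of the corresponding matricizations low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DimensionTree", "balanced_tree", "matricize"]


@dataclass
class Node:
    """Tree node; ``modes`` lists the 0-based modes of its subtree in leaf order."""

    index: int
    modes: tuple[int, ...]
    left: int = -1
    right: int = -1
    parent: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.left < 0


@dataclass
class DimensionTree:
    """Binary dimension tree with nodes stored in a flat list (root at 0)."""

    d: int
    nodes: list[Node]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for node in self.nodes:
            if node.is_leaf:
                if len(node.modes) != 1:
                    raise ValueError("leaves must carry exactly one mode")
                seen.update(node.modes)
            else:
                left = self.nodes[node.left]
                right = self.nodes[node.right]
                if set(left.modes) & set(right.modes):
                    raise ValueError("children mode sets must be disjoint")
                if tuple(left.modes) + tuple(right.modes) != tuple(node.modes):
                    raise ValueError("children must partition the parent's modes")
        if seen != set(range(self.d)):
            raise ValueError("every mode must appear in exactly one leaf")

    @property
    def root(self) -> Node:
        return self.nodes[0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    def inner_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    def leaf_of_mode(self, mode: int) -> Node:
        for node in self.nodes:
            if node.is_leaf and node.modes[0] == mode:
                return node
        raise KeyError(mode)

    def postorder(self) -> list[Node]:
        """Children before parents."""
        out: list[Node] = []

        def visit(idx: int) -> None:
            node = self.nodes[idx]
            if not node.is_leaf:
                visit(node.left)
                visit(node.right)
            out.append(node)

        visit(0)
        return out

    def preorder(self) -> list[Node]:
        """Parents before children."""
        out: list[Node] = []
        stack = [0]
        while stack:
            node = self.nodes[stack.pop()]
            out.append(node)
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)
        return out

    @property
    def leaf_order(self) -> tuple[int, ...]:
        return tuple(self.root.modes)

    def to_newick(self) -> str:
        """Nested-parentheses rendering (1-based mode labels) for inspection."""

        def render(idx: int) -> str:
            node = self.nodes[idx]
            if node.is_leaf:
                return str(node.modes[0] + 1)
            return f"({render(node.left)},{render(node.right)})"

        return render(0) + ";"


def balanced_tree(d: int, leaf_order: tuple[int, ...] | None = None) -> DimensionTree:
    """Canonical balanced dimension tree.

    Splits each node's modes into the first ceil(m/2) and remaining
    floor(m/2) positions in leaf order.  ``leaf_order`` is a permutation of
    ``range(d)`` assigning automata to leaf positions; identity gives the
    canonical tree (root children {1..ceil(d/2)} and the rest, in 1-based
    mode labels).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if leaf_order is None:
        leaf_order = tuple(range(d))
    leaf_order = tuple(int(i) for i in leaf_order)
    if sorted(leaf_order) != list(range(d)):
        raise ValueError(f"leaf_order must be a permutation of 0..{d - 1}")

    nodes: list[Node] = []

    def build(modes: tuple[int, ...], parent: int) -> int:
        idx = len(nodes)
        nodes.append(Node(index=idx, modes=modes, parent=parent))
        if len(modes) > 1:
            split = (len(modes) + 1) // 2
            nodes[idx].left = build(modes[:split], idx)
            nodes[idx].right = build(modes[split:], idx)
        return idx

    build(leaf_order, -1)
    return DimensionTree(d=d, nodes=nodes)


def matricize(b: np.ndarray, t: tuple[int, ...] | list[int]) -> np.ndarray:
    """Matricization B^(t) of a dense tensor.

    Rows are indexed by the modes in ``t`` (0-based, listed order), columns by
    the complement in increasing mode order; within each composite index the
    first listed mode varies fastest (Fortran ordering).  Only consistency
    matters for singular values and error bounds.
    """
    t = tuple(int(i) for i in t)
    if len(t) == 0:
        raise ValueError("mode subset t must be nonempty")
    d = b.ndim
    if any(i < 0 or i >= d for i in t) or len(set(t)) != len(t):
        raise ValueError("t must be a set of valid modes")
    s = tuple(i for i in range(d) if i not in set(t))
    rows = int(np.prod([b.shape[i] for i in t])) if t else 1
    perm = t + s
    return np.transpose(b, perm).reshape(rows, -1, order="F")
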