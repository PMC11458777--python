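"""Light-weight tree containers used by the parsimony machinery.

Leaves of an :class:`UnrootedTree` are the integers ``0..n_leaves-1`` and
carry names; internal nodes are integers ``>= n_leaves``.  The container is
deliberately minimal — adjacency dict plus leaf names — because the search
code mutates topologies in place millions of times and must stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple


class UnrootedTree:
    """Unrooted binary tree over named leaves.

    Parameters
    ----------
    adj : dict mapping node id -> list of neighbour ids.  Leaves have degree
        1, internal nodes degree 3.
    leaf_names : names for leaves 0..n-1, in leaf-id order.
    """

    __slots__ = ("adj", "leaf_names")

    def __init__(self, adj: Dict[int, List[int]], leaf_names: Sequence[str]):
        self.adj = adj
        self.leaf_names = list(leaf_names)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def edges(self) -> List[Tuple[int, int]]:
        """Deterministically ordered list of (u, v) edges with u < v."""
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> List[Tuple[int, int]]:
        n = self.n_leaves
        return [(u, v) for u, v in self.edges() if u >= n and v >= n]

    def copy(self) -> "UnrootedTree":
        return UnrootedTree({k: list(v) for k, v in self.adj.items()}, self.leaf_names)

    def next_node_id(self) -> int:
        return max(self.adj) + 1 if self.adj else 0

    # -- construction -----------------------------------------------------

    @classmethod
    def initial_triplet(cls, leaf_names: Sequence[str], leaves: Sequence[int]) -> "UnrootedTree":
        """Three-leaf tree (the unique unrooted topology) over the given leaf ids."""
        a, b, c = leaves
        hub = len(leaf_names)
        adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
        return cls(adj, leaf_names)

    def insert_leaf(self, leaf: int, edge: Tuple[int, int]) -> int:
        """Attach ``leaf`` on ``edge`` via a fresh internal node; returns its id."""
        u, v = edge
        w = self.next_node_id()
        self.adj[u][self.adj[u].index(v)] = w
        self.adj[v][self.adj[v].index(u)] = w
        self.adj[w] = [u, v, leaf]
        self.adj[leaf] = [w]
        return w

    def remove_leaf(self, leaf: int) -> None:
        """Detach a pendant leaf and splice out its (now degree-2) hub."""
        (w,) = self.adj[leaf]
        rest = [x for x in self.adj[w] if x != leaf]
        if len(rest) != 2:
            raise ValueError("cannot splice hub of degree != 3")
        u, v = rest
        self.adj[u][self.adj[u].index(w)] = v
        self.adj[v][self.adj[v].index(w)] = u
        del self.adj[w]
        del self.adj[leaf]

    # -- canonical form ----------------------------------------------------

    def topology_key(self) -> frozenset:
        """Set of non-trivial splits (as frozensets of leaf ids) — topology hash."""
        splits = set()
        for u, v in self.internal_edges():
            side = frozenset(self._leaves_behind(u, v))
            comp = frozenset(range(self.n_leaves)) - side
            splits.add(min(side, comp, key=sorted))
        return frozenset(splits)

    def _leaves_behind(self, away_from: int, start: int) -> List[int]:
        """Leaf ids reachable from ``start`` without crossing ``away_from``."""
        seen = {away_from, start}
        stack = [start]
        out = []
        while stack:
            x = stack.pop()
            if self.is_leaf(x):
                out.append(x)
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out


@dataclass
class RootedTree:
    """Rooted tree: children lists keyed by node id, root of degree 2."""

    root: int
    children: Dict[int, List[int]]
    leaf_names: List[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def postorder(self) -> Iterator[int]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or self.is_leaf(node):
                yield node
            else:
                stack.append((node, True))
                for c in reversed(self.children.get(node, [])):
                    stack.append((c, False))

    def leaf_depths(self) -> Dict[str, int]:
        """Number of internal nodes (root included) on each root->leaf path."""
        depths: Dict[str, int] = {}
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            if self.is_leaf(node):
                depths[self.leaf_names[node]] = d
            else:
                for c in self.children.get(node, []):
                    stack.append((c, d + 1))
        return depths

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if self.is_leaf(node):
                return self.leaf_names[node]
            return "(" + ",".join(fmt(c) for c in self.children[node]) + ")"

        return fmt(self.root) + ";"


def root_at_node(tree: UnrootedTree, root: int, skip: Tuple[int, ...] = ()) -> RootedTree:
    """Orient an unrooted tree away from ``root``; ``skip`` nodes are pruned."""
    children: Dict[int, List[int]] = {}
    seen = {root, *skip}
    stack = [root]
    while stack:
        x = stack.pop()
        kids = [y for y in tree.adj[x] if y not in seen]
        children[x] = kids
        for y in kids:
            seen.add(y)
            stack.append(y)
    return RootedTree(root=root, children=children, leaf_names=list(tree.leaf_names))
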