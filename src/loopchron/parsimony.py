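"""Wagner parsimony on ordered multistate characters, rooting and chronologies.

The tree of domains is inferred under linear-cost (Wagner) parsimony:
character states are linearly ordered and a change from state *i* to *j*
costs ``|i - j|``.  Tree length is computed with Sankoff's dynamic
programme; the min-plus convolution against the linear cost matrix is a
1-D distance transform, done here with two ``minimum.accumulate`` passes,
so scoring a tree is O(nodes x characters x states).

Rooting follows the Lundberg 'ancestor' implementation: a hypothetical
all-maximum-state (or all-minimum-state) ancestor is attached to every
branch in turn and the most parsimonious attachment becomes the root.
Relative leaf ages are node distances (nd): the number of internal nodes
between root and leaf, rescaled to [0, 1], with 0 the oldest; a linear
molecular clock converts nd to Gya.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .census import CharacterMatrix
from .trees import RootedTree, UnrootedTree, root_at_node

logger = logging.getLogger(__name__)

DEFAULT_CLOCK_ANCHORS = ((0.0, 3.8), (1.0, 0.0))


# ---------------------------------------------------------------------------
# Sankoff dynamic programme
# ---------------------------------------------------------------------------


def _linear_cost_transform(m: np.ndarray) -> np.ndarray:
    """min-plus convolution of per-state costs with |i-j| (distance transform).

    m has shape (n_chars, S); returns M with M[:, s] = min_j m[:, j] + |s-j|.
    """
    S = m.shape[1]
    idx = np.arange(S)
    fwd = np.minimum.accumulate(m - idx, axis=1) + idx
    bwd = np.minimum.accumulate((m + idx)[:, ::-1], axis=1)[:, ::-1] - idx
    return np.minimum(fwd, bwd)


def _leaf_message(states: np.ndarray, n_states: int) -> np.ndarray:
    """Message a leaf sends its parent: |s - observed| per character."""
    return np.abs(np.arange(n_states)[None, :] - states[:, None]).astype(float)


def sankoff_length(tree: UnrootedTree, m: CharacterMatrix, leaf_states: Optional[np.ndarray] = None) -> float:
    """Total Wagner-parsimony length of ``tree`` under the character matrix.

    Leaves of the tree must be the rows of ``m`` (by position); the DP is
    run from an arbitrary internal node and is rooting-independent because
    the cost |i-j| is symmetric.
    """
    states = m.row_states() if leaf_states is None else leaf_states
    if states.shape[0] != tree.n_leaves:
        raise ValueError(f"{tree.n_leaves} leaves but {states.shape[0]} matrix rows")
    S = m.n_states
    if tree.n_leaves == 2:
        return float(np.abs(states[0] - states[1]).sum())
    root = next(x for x in tree.adj if not tree.is_leaf(x))
    # iterative postorder over the rooted orientation
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        x = stack.pop()
        for y in tree.adj[x]:
            if y != parent[x]:
                parent[y] = x
                order.append(y)
                stack.append(y)
    cost: Dict[int, np.ndarray] = {}
    for x in reversed(order):
        if tree.is_leaf(x):
            continue
        acc = None
        for y in tree.adj[x]:
            if y == parent[x]:
                continue
            msg = _leaf_message(states[y], S) if tree.is_leaf(y) else _linear_cost_transform(cost.pop(y))
            acc = msg if acc is None else acc + msg
        cost[x] = acc
    return float(cost[root].min(axis=1).sum())


def brute_force_length(tree: UnrootedTree, m: CharacterMatrix, leaf_states: Optional[np.ndarray] = None) -> float:
    """Exhaustive minimisation over all internal-node state assignments.

    Independent oracle for :func:`sankoff_length`: every combination of
    internal states is enumerated explicitly (no dynamic programming), so
    it is exponential in the number of internal nodes and usable only on
    small trees.
    """
    states = m.row_states() if leaf_states is None else leaf_states
    S = m.n_states
    internals = sorted(x for x in tree.adj if not tree.is_leaf(x))
    if not internals:
        return float(np.abs(states[0] - states[1]).sum())
    edges = tree.edges()
    pos = {x: i for i, x in enumerate(internals)}
    # (n_internals, S^n_internals) grid of candidate assignments
    grid = np.indices((S,) * len(internals)).reshape(len(internals), -1)
    total = 0.0
    for c in range(states.shape[1]):
        length = np.zeros(grid.shape[1], dtype=np.int64)
        for u, v in edges:
            su = states[u, c] if tree.is_leaf(u) else grid[pos[u]]
            sv = states[v, c] if tree.is_leaf(v) else grid[pos[v]]
            length += np.abs(su - sv)
        total += int(length.min())
    return float(total)


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------


def _all_topologies(n_leaves: int, leaf_names: Sequence[str]):
    """Yield every unrooted binary topology by recursive leaf insertion."""
    tree = UnrootedTree.initial_triplet(leaf_names, [0, 1, 2])
    yield from _extend(tree, 3, n_leaves)


def _extend(tree: UnrootedTree, next_leaf: int, n_leaves: int):
    if next_leaf == n_leaves:
        yield tree.copy()
        return
    for edge in tree.edges():
        tree.insert_leaf(next_leaf, edge)
        yield from _extend(tree, next_leaf + 1, n_leaves)
        tree.remove_leaf(next_leaf)


def exhaustive_search(m: CharacterMatrix, max_leaves: int = 9) -> Tuple[List[UnrootedTree], float]:
    """Score every unrooted topology; return all optima and the optimal length."""
    n = m.states.shape[0]
    if n > max_leaves:
        raise ValueError(f"{n} leaves exceeds exhaustive limit {max_leaves}")
    if n < 3:
        raise ValueError("need at least 3 leaves")
    names = [str(t) for t in m.states.index]
    states = m.row_states()
    best: List[UnrootedTree] = []
    best_len = np.inf
    for tree in _all_topologies(n, names):
        length = sankoff_length(tree, m, states)
        if length < best_len - 1e-9:
            best, best_len = [tree], length
        elif abs(length - best_len) <= 1e-9:
            best.append(tree)
    return best, float(best_len)


def _nni_neighbors(tree: UnrootedTree, edge: Tuple[int, int]):
    """The two NNI rearrangements around an internal edge, applied in place.

    Yields the tree after each swap and restores the original topology on
    exhaustion (or after the caller stops consuming and resumes).
    """
    u, v = edge
    a = [x for x in tree.adj[u] if x != v]
    b = [x for x in tree.adj[v] if x != u]
    for bx in b:
        _swap_subtrees(tree, u, a[1], v, bx)
        yield tree
        _swap_subtrees(tree, u, bx, v, a[1])


def _swap_subtrees(tree: UnrootedTree, u: int, au: int, v: int, bv: int) -> None:
    tree.adj[u][tree.adj[u].index(au)] = bv
    tree.adj[v][tree.adj[v].index(bv)] = au
    tree.adj[au][tree.adj[au].index(u)] = v
    tree.adj[bv][tree.adj[bv].index(v)] = u


def _random_addition_tree(m: CharacterMatrix, states: np.ndarray, rng: np.random.Generator) -> UnrootedTree:
    """Greedy stepwise addition in a random leaf order (PAUP-style start)."""
    n = states.shape[0]
    names = [str(t) for t in m.states.index]
    order = list(rng.permutation(n))
    tree = UnrootedTree.initial_triplet(names, order[:3])
    for leaf in order[3:]:
        best_edge, best_len = None, np.inf
        for edge in tree.edges():
            tree.insert_leaf(leaf, edge)
            length = sankoff_length(tree, m, states)
            tree.remove_leaf(leaf)
            if length < best_len:
                best_edge, best_len = edge, length
        tree.insert_leaf(leaf, best_edge)
    return tree


def nni_search(m: CharacterMatrix, n_starts: int = 4, seed: int = 0) -> Tuple[UnrootedTree, float]:
    """Hill-climbing parsimony search: random-addition starts + NNI.

    First-improvement over a deterministic enumeration of internal edges;
    restarts are driven by a single seeded generator, so results are
    reproducible.  Returns the best tree found and its length.
    """
    n = m.states.shape[0]
    if n < 4:
        raise ValueError("need at least 4 leaves for a heuristic search")
    states = m.row_states()
    rng = np.random.default_rng(seed)
    best_tree, best_len = None, np.inf
    for _ in range(n_starts):
        tree = _random_addition_tree(m, states, rng)
        length = sankoff_length(tree, m, states)
        improved = True
        while improved:
            improved = False
            for edge in tree.internal_edges():
                if edge[0] not in tree.adj or edge[1] not in tree.adj.get(edge[0], []):
                    continue  # stale after an accepted swap
                for cand in _nni_neighbors(tree, edge):
                    cl = sankoff_length(cand, m, states)
                    if cl < length - 1e-9:
                        length = cl
                        improved = True
                        break
                else:
                    continue
                break
        if length < best_len:
            best_tree, best_len = tree.copy(), length
    return best_tree, float(best_len)


# ---------------------------------------------------------------------------
# Rooting and node distances
# ---------------------------------------------------------------------------


def lundberg_root(
    tree: UnrootedTree,
    m: CharacterMatrix,
    ancestor: str | Sequence[int] = "max",
) -> RootedTree:
    """Root by most-parsimonious attachment of a hypothetical ancestor.

    ``ancestor`` is "max" (all states S-1; the abundance generality
    criterion: the oldest structures are the most abundant and widespread),
    "min" (all zeros), or an explicit per-character state vector.  Ties are
    broken by the first branch in the deterministic edge enumeration and
    logged.
    """
    S = m.n_states
    n_chars = m.states.shape[1]
    if isinstance(ancestor, str):
        if ancestor == "max":
            anc_states = np.full(n_chars, S - 1, dtype=np.int64)
        elif ancestor == "min":
            anc_states = np.zeros(n_chars, dtype=np.int64)
        else:
            raise ValueError(f"unknown ancestor {ancestor!r}")
    else:
        anc_states = np.asarray(ancestor, dtype=np.int64)
        if anc_states.shape != (n_chars,):
            raise ValueError("explicit ancestor length != number of characters")

    scores = root_placement_scores(tree, m, anc_states)
    best_len = min(s for _, s in scores)
    best_edge = next(e for e, s in scores if abs(s - best_len) <= 1e-9)
    ties = sum(1 for _, s in scores if abs(s - best_len) <= 1e-9)
    if ties > 1:
        logger.info("lundberg_root: %d tied root placements; keeping the first", ties)
    aug, anc_leaf = _attach_ancestor(tree, best_edge)
    hub = aug.adj[anc_leaf][0]
    rooted = root_at_node(aug, hub, skip=(anc_leaf,))
    rooted.leaf_names = list(tree.leaf_names)
    return rooted


def root_placement_scores(
    tree: UnrootedTree,
    m: CharacterMatrix,
    ancestor_states: np.ndarray,
    scorer=sankoff_length,
) -> List[Tuple[Tuple[int, int], float]]:
    """Tree length with the ancestor attached to each branch in turn.

    Branches come in the deterministic :meth:`UnrootedTree.edges` order;
    ``scorer`` can be swapped for an independent length oracle.
    """
    states = m.row_states()
    aug_states = np.vstack([states, ancestor_states])  # ancestor becomes leaf id n
    out = []
    for edge in tree.edges():
        aug, _ = _attach_ancestor(tree, edge)
        out.append((edge, float(scorer(aug, m, aug_states))))
    return out


def _attach_ancestor(tree: UnrootedTree, edge: Tuple[int, int]) -> Tuple[UnrootedTree, int]:
    """Copy of ``tree`` with an extra ancestor leaf subdividing ``edge``."""
    n = tree.n_leaves
    aug = UnrootedTree({k + 1 if k >= n else k: [x + 1 if x >= n else x for x in v] for k, v in tree.adj.items()},
                       list(tree.leaf_names) + ["_ANC_"])
    # ancestor must take leaf id n; shift prior internal ids up by one (done above)
    u, v = (x + 1 if x >= n else x for x in edge)
    w = aug.next_node_id()
    aug.adj[u][aug.adj[u].index(v)] = w
    aug.adj[v][aug.adj[v].index(u)] = w
    aug.adj[w] = [u, v, n]
    aug.adj[n] = [w]
    return aug, n


def node_distances(rooted: RootedTree, normalization: str = "root") -> pd.Series:
    """Relative leaf ages nd in [0, 1] from internal-node counts.

    d(leaf) counts internal nodes on the root->leaf path, root included.
    normalization="root" (default): nd = (d-1)/(d_max-1); "minmax":
    nd = (d-d_min)/(d_max-d_min).  Degenerate trees (all d equal, or
    d_max=1) give nd=0 everywhere.
    """
    depths = pd.Series(rooted.leaf_depths(), dtype=float)
    d_max = depths.max()
    if normalization == "root":
        lo = 1.0
    elif normalization == "minmax":
        lo = depths.min()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    span = d_max - lo
    if span <= 0:
        return pd.Series(0.0, index=depths.index)
    return (depths - lo) / span


# ---------------------------------------------------------------------------
# Molecular clock and chronology
# ---------------------------------------------------------------------------


@dataclass
class Clock:
    """Linear molecular clock: age_Gya = intercept + slope * nd."""

    intercept: float
    slope: float

    def age(self, nd) -> np.ndarray:
        ages = self.intercept + self.slope * np.asarray(nd, dtype=float)
        if np.any(ages < -1e-9):
            logger.warning("clock produced negative ages; clipping to 0")
        return np.clip(ages, 0.0, None)


def calibrate_clock(anchors: Sequence[Tuple[float, float]] = DEFAULT_CLOCK_ANCHORS) -> Clock:
    """Least-squares line through (nd, Gya) anchor pairs.

    Default anchors (0, 3.8) and (1, 0): the oldest families date to the
    origin of the protein record at 3.8 Gya and the youngest to the present.
    """
    nds = np.array([a[0] for a in anchors], dtype=float)
    ages = np.array([a[1] for a in anchors], dtype=float)
    if len(anchors) < 2 or np.ptp(nds) == 0:
        raise ValueError("need >= 2 anchors with distinct nd")
    slope, intercept = np.polyfit(nds, ages, 1)
    return Clock(intercept=float(intercept), slope=float(slope))


@dataclass
class Chronology:
    """Rooted tree of families with per-leaf nd and calibrated age in Gya."""

    tree: Optional[RootedTree]
    nd: pd.Series  # index: family IDs
    clock: Clock
    meta: Dict = field(default_factory=dict)

    @property
    def ages(self) -> pd.Series:
        return pd.Series(self.clock.age(self.nd.values), index=self.nd.index, name="age_Gya")

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"nd": self.nd, "age_Gya": self.ages})
        df.index.name = "family"
        return df.sort_values(["nd", "family"], kind="stable")

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "Chronology":
        df = pd.read_csv(path, sep="\t", index_col=0)
        clock = calibrate_clock()
        return cls(tree=None, nd=df["nd"], clock=clock)

    @classmethod
    def from_ages(cls, birth_times: pd.Series, clock: Optional[Clock] = None) -> "Chronology":
        """Chronology directly from known relative birth times (rank-rescaled)."""
        ranks = birth_times.rank(method="dense") - 1
        nd = ranks / max(ranks.max(), 1)
        return cls(tree=None, nd=nd, clock=clock or calibrate_clock())


def build_chronology(
    m: CharacterMatrix,
    n_starts: int = 4,
    seed: int = 0,
    ancestor: str = "max",
    anchors: Sequence[Tuple[float, float]] = DEFAULT_CLOCK_ANCHORS,
    normalization: str = "root",
    transpose: bool = True,
) -> Chronology:
    """Full pipeline: parsimony search -> ancestor rooting -> nd -> clock.

    ``m`` is the proteome x family matrix from :func:`encode_census`; it is
    transposed so tree leaves are families and characters are proteomes
    (set ``transpose=False`` if rows are already families).
    """
    fam_matrix = m.transpose() if transpose else m
    # canonical leaf order: the result then depends only on the data, not on
    # the incoming family/column order
    fam_matrix = CharacterMatrix(
        fam_matrix.states.sort_index(), fam_matrix.n_states, fam_matrix.scope,
        dict(fam_matrix.meta),
    )
    tree, length = nni_search(fam_matrix, n_starts=n_starts, seed=seed)
    rooted = lundberg_root(tree, fam_matrix, ancestor=ancestor)
    nd = node_distances(rooted, normalization=normalization)
    clock = calibrate_clock(anchors)
    nd = nd.reindex(sorted(nd.index))
    return Chronology(tree=rooted, nd=nd, clock=clock,
                      meta={"tree_length": length, "seed": seed, "n_starts": n_starts,
                            "ancestor": ancestor})
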