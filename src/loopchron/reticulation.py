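"""Vertical vs reticulate signal among the supergroup taxa.

The 15 Venn groups become binary characters for five network taxa — A, B,
E, V and a hypothetical all-absent ancestor ANC — weighted by the number
of prototypes (or families) in each group.  From the weighted
uncorrected-P distances we compute quartet delta scores (0 = perfectly
tree-like, 1 = fully reticulate), Q-residuals, a neighbor-joining tree
and bootstrap split support obtained by resampling the item-level units.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .vennphases import VENN_LABELS

DEFAULT_TAXA = ("A", "B", "E", "V", "ANC")


@dataclass
class GroupCharacterMatrix:
    """Binary taxa x Venn-label matrix with per-column item-count weights."""

    taxa: Tuple[str, ...]
    cells: np.ndarray  # (n_taxa, 15) in {0, 1}
    weights: np.ndarray  # (15,) non-negative

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.taxa), len(VENN_LABELS)):
            raise ValueError("cells must be taxa x 15 Venn labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")
        if (self.weights < 0).any() or self.weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")


def build_group_matrix(
    weights: Mapping[str, float],
    taxa: Sequence[str] = DEFAULT_TAXA,
) -> GroupCharacterMatrix:
    """Character matrix from Venn-group item counts.

    ``weights`` maps Venn labels to counts; a taxon scores 1 on a column
    when its letter is in the label (the ANC pseudo-taxon scores 0
    everywhere).
    """
    w = np.array([float(weights.get(lbl, 0.0)) for lbl in VENN_LABELS])
    cells = np.array(
        [[1 if t in lbl else 0 for lbl in VENN_LABELS] for t in taxa], dtype=int
    )
    return GroupCharacterMatrix(taxa=tuple(taxa), cells=cells, weights=w)


def weighted_p_distance(m: GroupCharacterMatrix) -> pd.DataFrame:
    """Weighted uncorrected-P distances: d(t,u) = sum w|x_t - x_u| / sum w."""
    diffs = np.abs(m.cells[:, None, :] - m.cells[None, :, :])
    d = (diffs * m.weights[None, None, :]).sum(axis=2) / m.weights.sum()
    return pd.DataFrame(d, index=m.taxa, columns=m.taxa)


@dataclass
class DeltaResult:
    """Quartet-based treelikeness statistics of a distance matrix."""

    delta: float  # mean quartet delta, in [0, 1]
    per_taxon: pd.Series
    q_residual: float


def _quartet_sums(d: np.ndarray, q: Tuple[int, int, int, int]) -> np.ndarray:
    i, j, k, l = q
    sums = np.array([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
    return np.sort(sums)[::-1]  # m1 >= m2 >= m3


def delta_score(d: pd.DataFrame) -> DeltaResult:
    """Mean quartet delta = (m1-m2)/(m1-m3) with m_i the sorted pair-sums.

    0 when the four-point condition holds on every quartet (additive,
    fully bifurcating signal); 1 on a maximally box-like metric.  Per-taxon
    deltas average over the quartets containing each taxon.  Also computes
    the Q-residual: mean over quartets of (m1-m2)^2 after rescaling the
    distances so the mean off-diagonal distance is 1.
    """
    taxa = list(d.index)
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    dm = d.values.astype(float)
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    off = dm[np.triu_indices(n, 1)]
    scale = off.mean()
    dm_scaled = dm / scale if scale > 0 else dm
    deltas, qres = [], []
    taxon_deltas: Dict[int, list] = {i: [] for i in range(n)}
    for q in combinations(range(n), 4):
        m1, m2, m3 = _quartet_sums(dm, q)
        dq = 0.0 if m1 - m3 <= 1e-12 else (m1 - m2) / (m1 - m3)
        deltas.append(dq)
        for i in q:
            taxon_deltas[i].append(dq)
        s1, s2, _ = _quartet_sums(dm_scaled, q)
        qres.append((s1 - s2) ** 2)
    per_taxon = pd.Series({taxa[i]: float(np.mean(v)) for i, v in taxon_deltas.items()})
    return DeltaResult(
        delta=float(np.mean(deltas)), per_taxon=per_taxon, q_residual=float(np.mean(qres))
    )


def q_residual(d: pd.DataFrame) -> float:
    """Mean squared quartet residual on mean-rescaled distances (see delta_score)."""
    return delta_score(d).q_residual


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to 0."""
    if d.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    dm = DistanceMatrix(d.values.astype(float), ids=[str(t) for t in d.index])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def tree_splits(tree: TreeNode, min_length: float = 0.0) -> Dict[FrozenSet[str], float]:
    """Non-trivial splits of an unrooted tree, as the leaf set on one side.

    Each split is canonicalised as the side *not* containing the
    alphabetically first taxon; the value is the supporting internal
    branch length.  Splits on branches of length <= ``min_length`` can be
    filtered by the caller (zero-length splits are unresolved).
    """
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    out: Dict[FrozenSet[str], float] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if anchor in side:
            side = frozenset(tips) - side
        length = node.length if node.length is not None else 0.0
        out[side] = max(out.get(side, 0.0), float(length))
    return out


def bootstrap_support(
    m: GroupCharacterMatrix,
    replicates: int = 2000,
    seed: int = 0,
    min_length: float = 1e-12,
) -> pd.DataFrame:
    """Bootstrap split support by resampling prototypes (items).

    Column weights are item counts, so a replicate redraws sum(w) items
    over the 15 Venn groups (multinomial with the observed proportions),
    rebuilds the distance matrix and NJ tree, and records its splits.
    Support is the percentage of replicates containing each split of the
    original tree; original splits on zero-length branches are reported as
    unresolved (support NaN).
    """
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    base = nj_tree(weighted_p_distance(m))
    base_splits = tree_splits(base)
    n_items = int(round(m.weights.sum()))
    probs = m.weights / m.weights.sum()
    hits = {s: 0 for s in base_splits}
    for _ in range(replicates):
        w = rng.multinomial(n_items, probs).astype(float)
        if w.sum() == 0:
            continue
        rep = GroupCharacterMatrix(m.taxa, m.cells, w)
        rep_splits = tree_splits(nj_tree(weighted_p_distance(rep)), min_length)
        resolved = {s for s, ln in rep_splits.items() if ln > min_length}
        for s in hits:
            if s in resolved:
                hits[s] += 1
    rows = []
    for s, ln in sorted(base_splits.items(), key=lambda kv: sorted(kv[0])):
        resolved = ln > min_length
        rows.append(
            {
                "split": "|".join(sorted(s)),
                "branch_length": ln,
                "support_pct": 100.0 * hits[s] / replicates if resolved else np.nan,
                "resolved": resolved,
            }
        )
    return pd.DataFrame(rows)


def cumulative_group_weights(
    items: pd.DataFrame,
    through_phase: int,
    phase_col: str = "phase",
    venn_col: str = "venn",
) -> Dict[str, int]:
    """Venn-group item counts accumulated through a phase endpoint."""
    sel = items[items[phase_col] <= through_phase]
    return sel[venn_col].value_counts().to_dict()
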