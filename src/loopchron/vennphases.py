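"""Four-set Venn groups, evolutionary phases, accretion tables and urancestors.

Families and loop prototypes are classified by where they occur among the
supergroups Archaea (A), Bacteria (B), Eukarya (E) and Viruses (V): one of
the 15 non-empty subsets, written with letters in A,B,E,V order (ABEV, ABE,
..., V).  The chronology is segmented into six phases, Phase 0 (communal
world, 3.8-3.6 Gya) through Phase V (rise of Eukarya, 0.9 Gya to the
present); per-phase counts of prototypes and families, and their ratio,
form the accretion table.  The LUCA repertoire is everything dated to
Phase 0; LUCellA additionally includes Phase I.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .census import CensusMatrix, _round_half_away

_LETTERS = ("A", "B", "E", "V")

#: the 15 canonical labels, broadest first
VENN_LABELS = tuple(
    "".join(c)
    for k in (4, 3, 2, 1)
    for c in combinations(_LETTERS, k)
)

PHASE_NAMES = (
    "0: Communal world",
    "I: Rise of viral ancestors",
    "II: Birth of ancestors of Archaea",
    "III: Diversified Bacteria",
    "IV: Rise of diversified superkingdoms and viruses",
    "V: Rise of Eukarya",
)


def venn_group(presence: Iterable[str]) -> str:
    """Canonical Venn label for a non-empty subset of {A, B, E, V}."""
    members = set(presence)
    if not members:
        raise ValueError("empty presence set: item occurs nowhere")
    bad = members - set(_LETTERS)
    if bad:
        raise ValueError(f"unknown supergroup letters: {bad}")
    return "".join(c for c in _LETTERS if c in members)


def presence_from_census(census: CensusMatrix, family: str, min_proteomes: int = 1) -> Set[str]:
    """Supergroups with at least ``min_proteomes`` proteomes carrying the family."""
    if family not in census.abundance.columns:
        raise KeyError(f"unknown family {family!r}")
    col = census.abundance[family]
    hits = census.supergroup[col > 0].value_counts()
    return {g for g in _LETTERS if hits.get(g, 0) >= min_proteomes}


@dataclass
class PhaseConfig:
    """Phase boundaries in Gya, oldest first; phase i spans (b[i+1], b[i]].

    Intervals are closed at the older bound and open at the younger, so an
    age exactly on an internal boundary (e.g. 2.5 Gya) belongs to the
    younger phase; age 0 belongs to the last phase.
    """

    boundaries: Sequence[float] = (3.8, 3.6, 3.2, 2.5, 2.0, 0.9, 0.0)
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2 or not np.all(np.diff(b) < 0):
            raise ValueError("boundaries must strictly decrease")

    @property
    def n_phases(self) -> int:
        return len(self.boundaries) - 1

    @property
    def oldest(self) -> float:
        return float(self.boundaries[0])


def assign_phase(age_gya: float, cfg: Optional[PhaseConfig] = None) -> int:
    """Phase index (0 = most ancient) for an age in Gya."""
    cfg = cfg or PhaseConfig()
    b = cfg.boundaries
    if age_gya < b[-1] - cfg.tolerance or age_gya > b[0] + cfg.tolerance:
        raise ValueError(f"age {age_gya} Gya outside [{b[-1]}, {b[0]}]")
    age = min(max(age_gya, b[-1]), b[0])
    for i in range(cfg.n_phases):
        if age > b[i + 1] or (i == cfg.n_phases - 1):
            return i
    raise AssertionError("unreachable")


@dataclass
class VennPhaseTable:
    """Machine form of the accretion analysis: counts per (phase, Venn group)."""

    prototypes: pd.DataFrame  # index: phase, columns: VENN_LABELS
    families: pd.DataFrame
    summary: pd.DataFrame  # per-phase totals and prototype/family ratio
    config: PhaseConfig = field(default_factory=PhaseConfig)

    def to_tsv(self, path_prefix) -> None:
        self.prototypes.to_csv(f"{path_prefix}_prototypes.tsv", sep="\t")
        self.families.to_csv(f"{path_prefix}_families.tsv", sep="\t")
        self.summary.to_csv(f"{path_prefix}_summary.tsv", sep="\t")


def _phase_venn_counts(items: pd.DataFrame, cfg: PhaseConfig) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=range(cfg.n_phases), columns=list(VENN_LABELS))
    for _, row in items.iterrows():
        counts.loc[assign_phase(float(row["age_gya"]), cfg), row["venn"]] += 1
    counts.index.name = "phase"
    return counts


def phase_ratio(n_prototypes: int, n_families: int) -> Optional[float]:
    """Prototype/family ratio to 2 decimals (half-away); None when undefined."""
    if n_families == 0:
        return None
    return _round_half_away(n_prototypes / n_families * 100) / 100


def phase_table(
    prototypes: pd.DataFrame,
    families: pd.DataFrame,
    cfg: Optional[PhaseConfig] = None,
) -> VennPhaseTable:
    """Build the per-phase accretion table.

    Both inputs need columns ``age_gya`` and ``venn`` (one row per dated,
    labelled item).  Per-phase ratios are prototype count / family count,
    reported to two decimals; phases without families get a flagged
    undefined ratio (NaN).
    """
    cfg = cfg or PhaseConfig()
    p = _phase_venn_counts(prototypes, cfg)
    f = _phase_venn_counts(families, cfg)
    ptot = p.sum(axis=1)
    ftot = f.sum(axis=1)
    ratios = [phase_ratio(int(pc), int(fc)) for pc, fc in zip(ptot, ftot)]
    summary = pd.DataFrame(
        {
            "prototypes": ptot,
            "families": ftot,
            "ratio": [np.nan if r is None else r for r in ratios],
            "ratio_undefined": [r is None for r in ratios],
        }
    )
    summary.index.name = "phase"
    return VennPhaseTable(prototypes=p, families=f, summary=summary, config=cfg)


def urancestor_repertoire(
    prototypes: pd.DataFrame,
    cfg: Optional[PhaseConfig] = None,
    which: str = "LUCA",
) -> Set[str]:
    """Prototype IDs in an urancestral repertoire.

    LUCA (last universal common ancestor of cells and viruses) closes
    Phase 0; LUCellA (last universal cellular ancestor) closes Phase I, so
    its repertoire is everything from Phases 0 and I.  ``prototypes`` needs
    columns ``prototype`` and ``age_gya``.
    """
    cfg = cfg or PhaseConfig()
    cutoff = {"LUCA": 0, "LUCellA": 1}.get(which)
    if cutoff is None:
        raise ValueError(f"unknown urancestor {which!r}")
    phases = prototypes["age_gya"].map(lambda a: assign_phase(float(a), cfg))
    return set(prototypes.loc[phases <= cutoff, "prototype"])


def summarize_repertoire(
    repertoire: Set[str],
    annotations: pd.DataFrame,
    by: Sequence[str] = ("loop_type", "disorder", "function_major", "function_minor"),
    unknown: str = "Other/Unknown",
) -> Dict[str, pd.DataFrame]:
    """Contingency tables (counts + proportions) for an urancestral set.

    ``annotations`` is indexed by prototype ID; prototypes missing from it,
    or with missing values, are tallied under "Other/Unknown".
    """
    tables = {}
    ids = sorted(repertoire)
    for col in by:
        if col in annotations.columns:
            vals = annotations[col].reindex(ids).fillna(unknown)
        else:
            vals = pd.Series(unknown, index=ids)
        counts = vals.value_counts().sort_index()
        tab = pd.DataFrame({"count": counts})
        tab["proportion"] = tab["count"] / max(len(ids), 1)
        tab.index.name = col
        tables[col] = tab
    return tables
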