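"""Dating loop prototypes against the chronology of domain families.

Prototypes are ArchDB-style identifiers (method.type.length.class.subclass,
e.g. DS.HE.6.17.1) mapped to domain families with HMM e-values.  After
filtering at e < 0.001, a prototype is *non-modular* when all its mapped
families share one time of origin (one nd value, within a tie tolerance)
and *modular* otherwise; its age is the minimum nd among mapped families
(first appearance), converted to Gya through the chronology's clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .parsimony import Chronology

logger = logging.getLogger(__name__)

E_VALUE_THRESHOLD = 0.001
ND_TIE_TOLERANCE = 1e-12


@dataclass
class PrototypeRecord:
    """One loop prototype with its surviving family mappings and dating."""

    id: str
    mapped_families: List[Tuple[str, float]]  # (family ID, e-value)
    modularity: Optional[str] = None  # "modular" | "non-modular"
    age_nd: Optional[float] = None
    age_gya: Optional[float] = None
    annotations: Dict[str, str] = field(default_factory=dict)

    @property
    def loop_type(self) -> str:
        """Second token of the ArchDB identifier (bracing-structure type)."""
        parts = self.id.split(".")
        return parts[1] if len(parts) >= 2 else ""


def load_and_filter_mappings(
    table: pd.DataFrame,
    e_threshold: float = E_VALUE_THRESHOLD,
) -> List[PrototypeRecord]:
    """Filter mapping rows at e-value strictly below the threshold.

    ``table`` has columns prototype/family/e_value.  Rows at or above the
    threshold are dropped; prototypes left with no rows are excluded and
    counted in the log.  Duplicate (prototype, family) rows keep the best
    e-value.
    """
    t = table.copy()
    t["e_value"] = pd.to_numeric(t["e_value"], errors="raise")
    if (t["e_value"] < 0).any():
        raise ValueError("negative e-values")
    all_ids = t["prototype"].unique()
    kept = t[t["e_value"] < e_threshold]
    kept = kept.sort_values("e_value").drop_duplicates(["prototype", "family"])
    records = []
    for pid, grp in kept.groupby("prototype", sort=True):
        fams = sorted(zip(grp["family"], grp["e_value"]))
        records.append(PrototypeRecord(id=pid, mapped_families=fams))
    dropped = len(all_ids) - len(records)
    if dropped:
        logger.info("load_and_filter_mappings: %d prototypes had no mapping at e < %g",
                    dropped, e_threshold)
    return records


def classify_modularity(
    rec: PrototypeRecord,
    chronology: Chronology,
    tolerance: float = ND_TIE_TOLERANCE,
) -> str:
    """"non-modular" iff every mapped family shares one nd (within tolerance)."""
    if not rec.mapped_families:
        raise ValueError(f"prototype {rec.id} has no mapped families")
    try:
        nds = [float(chronology.nd[f]) for f, _ in rec.mapped_families]
    except KeyError as err:
        raise KeyError(f"family {err} of prototype {rec.id} absent from chronology") from None
    return "non-modular" if max(nds) - min(nds) <= tolerance else "modular"


def assign_prototype_age(rec: PrototypeRecord, chronology: Chronology) -> Tuple[float, float]:
    """(age_nd, age_Gya): minimum nd among mapped families (first appearance)."""
    if not rec.mapped_families:
        raise ValueError(f"prototype {rec.id} has no mapped families")
    age_nd = min(float(chronology.nd[f]) for f, _ in rec.mapped_families)
    age_gya = float(chronology.clock.age(age_nd))
    return age_nd, age_gya


def date_prototypes(
    records: Sequence[PrototypeRecord],
    chronology: Chronology,
    tolerance: float = ND_TIE_TOLERANCE,
) -> List[PrototypeRecord]:
    """Classify and date every record in place; returns the same list."""
    for rec in records:
        rec.modularity = classify_modularity(rec, chronology, tolerance)
        rec.age_nd, rec.age_gya = assign_prototype_age(rec, chronology)
    return list(records)


def prototype_table(records: Sequence[PrototypeRecord]) -> pd.DataFrame:
    """Flat dated-prototype table (one row per prototype)."""
    return pd.DataFrame(
        {
            "prototype": [r.id for r in records],
            "loop_type": [r.loop_type for r in records],
            "modularity": [r.modularity for r in records],
            "age_nd": [r.age_nd for r in records],
            "age_gya": [r.age_gya for r in records],
            "n_families": [len(r.mapped_families) for r in records],
        }
    )


def bipartite_edges(records: Sequence[PrototypeRecord], chronology: Chronology) -> pd.DataFrame:
    """Edge table of the evolving prototype-domain bipartite network.

    One edge per surviving mapping row; ``is_recruitment`` marks edges
    where the family is younger than the prototype (the prototype was
    reused by a later-born family).
    """
    rows = []
    for rec in records:
        if rec.age_nd is None:
            raise ValueError(f"prototype {rec.id} is undated; run date_prototypes first")
        for fam, ev in rec.mapped_families:
            fam_nd = float(chronology.nd[fam])
            rows.append(
                {
                    "prototype": rec.id,
                    "family": fam,
                    "e_value": ev,
                    "prototype_nd": rec.age_nd,
                    "family_nd": fam_nd,
                    "is_recruitment": fam_nd > rec.age_nd,
                }
            )
    return pd.DataFrame(rows)
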