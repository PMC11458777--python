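"""Synthetic censuses, prototype mappings and loop structures with known truth.

The generator emulates the shape of the study inputs — a proteome x
domain-family abundance census over the four supergroups, ArchDB-style
prototype-to-family mappings with e-values, annotation tables, and
Calpha loop structures — while planting a ground truth (birth order, Venn
labels, modularity, loop internal coordinates) that downstream stages
must recover.  The statistical premise mirrors the accretion model:
families born earlier are more abundant (exponential decay of expected
abundance with birth time) and more widely shared among supergroups
(per-phase Venn-label schedule), which is exactly what makes
maximum-state ancestor rooting meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .census import CensusMatrix, SUPERGROUPS
from .geometry import LOOP_TYPES, LoopStructure
from .parsimony import Chronology
from .vennphases import PhaseConfig, VENN_LABELS, assign_phase

#: per-phase Venn-label probabilities mirroring the published per-phase
#: compositions: Phase 0 all-universal; Phase I 196 ABEV : 40 ABE;
#: Phase II 485 ABEV : 370 ABE : 18 BE/BEV; Phase III dominated by
#: ABEV/ABE with the first trickle of AB/ABV/B/BV (45 of 1220);
#: Phase IV broad groups plus the first supergroup-specific structures;
#: Phase V enriched in E/EV/BE with no bacterial-only groups.
DEFAULT_VENN_SCHEDULE: Dict[int, Dict[str, float]] = {
    0: {"ABEV": 1.0},
    1: {"ABEV": 0.83, "ABE": 0.17},
    2: {"ABEV": 0.555, "ABE": 0.424, "BEV": 0.01, "BE": 0.011},
    3: {"ABEV": 0.55, "ABE": 0.413, "AB": 0.02, "ABV": 0.007, "B": 0.009,
        "BV": 0.001},
    4: {"ABEV": 0.30, "ABE": 0.23, "B": 0.12, "AB": 0.08, "E": 0.10,
        "BE": 0.05, "A": 0.03, "V": 0.03, "EV": 0.02, "ABV": 0.01,
        "BV": 0.01, "AE": 0.007, "AEV": 0.004, "BEV": 0.009},
    5: {"E": 0.45, "EV": 0.25, "BE": 0.12, "BEV": 0.08, "ABEV": 0.05,
        "ABE": 0.02, "AE": 0.02, "AEV": 0.01},
}


@dataclass
class AccretionParams:
    """Parameters of the synthetic accretion model (desk-scale defaults)."""

    n_families: int = 60
    group_sizes: Dict[str, int] = field(default_factory=lambda: {g: 8 for g in SUPERGROUPS})
    venn_schedule: Dict[int, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VENN_SCHEDULE.items()}
    )
    abundance_mean0: float = 50.0  # expected abundance of the oldest family
    decay: float = 2.0  # abundance decay rate with birth time
    dropout: float = 0.05  # per-cell zeroing probability
    seed: int = 1
    phase_config: PhaseConfig = field(default_factory=PhaseConfig)

    def __post_init__(self) -> None:
        if self.n_families < 4:
            raise ValueError("need >= 4 families")
        if set(self.group_sizes) != set(SUPERGROUPS) or min(self.group_sizes.values()) < 2:
            raise ValueError("every supergroup needs >= 2 proteomes")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for phase, row in self.venn_schedule.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"venn_schedule row for phase {phase} does not sum to 1")
            unknown = set(row) - set(VENN_LABELS)
            if unknown:
                raise ValueError(f"unknown Venn labels {unknown}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset."""

    birth_time: pd.Series  # in [0, 1], strictly increasing with family index
    venn: pd.Series  # true Venn label per family
    age_gya: pd.Series
    params: AccretionParams

    def true_chronology(self) -> Chronology:
        """Chronology whose nd is the rank-rescaled planted birth time."""
        return Chronology.from_ages(self.birth_time)


def simulate_accretion(params: Optional[AccretionParams] = None) -> Tuple[CensusMatrix, SyntheticTruth]:
    """Simulate a census under the accretion model.

    Family f (birth time t_f, Venn label L_f) has abundance
    Poisson(lambda0 * exp(-k * t_f)) in every proteome whose supergroup is
    in L_f and 0 elsewhere; cells are then zeroed with the dropout
    probability.  If dropout erases a family everywhere, one member-group
    cell is redrawn so the census stays valid.  Deterministic under seed.
    """
    params = params or AccretionParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_families
    t = np.sort(rng.uniform(0.0, 1.0, size=n))
    oldest = params.phase_config.oldest
    ages = oldest * (1.0 - t)
    phases = [assign_phase(a, params.phase_config) for a in ages]
    venn = []
    for ph in phases:
        row = params.venn_schedule.get(ph, {"ABEV": 1.0})
        labels = sorted(row)
        venn.append(rng.choice(labels, p=[row[l] for l in labels]))
    families = [f"{'abcdefg'[i % 7]}.{i + 1}.1.1" for i in range(n)]
    proteomes, groups = [], []
    for g in SUPERGROUPS:
        for j in range(params.group_sizes[g]):
            proteomes.append(f"{g}{j + 1:02d}")
            groups.append(g)
    lam = params.abundance_mean0 * np.exp(-params.decay * t)
    counts = np.zeros((len(proteomes), n), dtype=int)
    for fi in range(n):
        member = np.array([g in venn[fi] for g in groups])
        counts[member, fi] = rng.poisson(lam[fi], size=member.sum())
    if params.dropout > 0:
        keep = rng.uniform(size=counts.shape) >= params.dropout
        counts = counts * keep
    for fi in range(n):  # census invariant: every family observed somewhere
        if counts[:, fi].sum() == 0:
            member = [i for i, g in enumerate(groups) if g in venn[fi]]
            counts[member[0], fi] = max(int(rng.poisson(lam[fi])), 1)
    census = CensusMatrix(
        pd.DataFrame(counts, index=proteomes, columns=families),
        pd.Series(groups, index=proteomes, name="supergroup"),
    )
    truth = SyntheticTruth(
        birth_time=pd.Series(t, index=families, name="birth_time"),
        venn=pd.Series(venn, index=families, name="venn"),
        age_gya=pd.Series(ages, index=families, name="age_gya"),
        params=params,
    )
    return census, truth


def simulate_prototype_mappings(
    truth: SyntheticTruth,
    n_prototypes: int = 40,
    modular_fraction: float = 0.3,
    seed: int = 0,
    decoy_fraction: float = 0.25,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ArchDB-style prototype -> family mappings with planted labels.

    Non-modular prototypes map to a single family (planted birth times are
    all distinct, so one birth time means one family); modular prototypes
    map to 2-3 families with distinct birth times.  True links get
    e-values < 0.001; decoy rows with e >= 0.001 are interleaved and must
    be removed by the downstream filter.

    Returns (mapping table with columns prototype/family/e_value,
    planted table with columns prototype/modularity/loop_type/true_age_nd).
    """
    if not 0.0 <= modular_fraction <= 1.0:
        raise ValueError("modular_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    families = list(truth.birth_time.index)
    if modular_fraction > 0 and len(families) < 2:
        raise ValueError("modular prototypes need >= 2 distinct birth times")
    n_modular = int(round(modular_fraction * n_prototypes))
    is_modular = np.zeros(n_prototypes, dtype=bool)
    is_modular[rng.permutation(n_prototypes)[:n_modular]] = True
    true_nd = truth.true_chronology().nd
    rows, planted = [], []
    for i in range(n_prototypes):
        lt = LOOP_TYPES[rng.integers(len(LOOP_TYPES))]
        pid = f"DS.{lt}.{rng.integers(2, 11)}.{i + 1}.1"
        if is_modular[i]:
            k = int(rng.integers(2, 4))
            fams = list(rng.choice(families, size=k, replace=False))
        else:
            fams = [families[rng.integers(len(families))]]
        for fam in fams:
            rows.append({"prototype": pid, "family": fam,
                         "e_value": 10.0 ** rng.uniform(-10, -3.05)})
        if rng.uniform() < decoy_fraction:
            rows.append({"prototype": pid,
                         "family": families[rng.integers(len(families))],
                         "e_value": 10.0 ** rng.uniform(-2.99, 0)})
        planted.append({"prototype": pid,
                        "modularity": "modular" if is_modular[i] else "non-modular",
                        "loop_type": lt,
                        "true_age_nd": float(min(true_nd[f] for f in fams))})
    return pd.DataFrame(rows), pd.DataFrame(planted)


#: seven major function categories (the 7th absorbs missing annotations)
FUNCTION_MAJOR = (
    "Metabolism",
    "Information",
    "Intracellular processes",
    "Extracellular processes",
    "Regulation",
    "General",
    "Other/Unknown",
)

DISORDER_LEVELS = ("ordered", "moderate", "high")


def simulate_annotations(
    planted: pd.DataFrame,
    families: Sequence[str],
    seed: int = 0,
    disorder_probs: Sequence[float] = (0.7, 0.2, 0.1),
    n_minor_per_major: int = 7,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Annotation tables: prototype loop type + disorder, family function.

    Minor function categories are ``major:i`` strings (7 majors x 7 minors
    plus Other/Unknown itself = 50 minor labels).
    """
    rng = np.random.default_rng(seed)
    proto = planted.set_index("prototype")[["loop_type"]].copy()
    proto["disorder"] = rng.choice(DISORDER_LEVELS, size=len(proto), p=list(disorder_probs))
    majors = rng.choice(FUNCTION_MAJOR[:-1], size=len(families))
    minors = [f"{m}:{rng.integers(1, n_minor_per_major + 1)}" for m in majors]
    fam = pd.DataFrame({"function_major": majors, "function_minor": minors},
                       index=pd.Index(families, name="family"))
    return proto, fam


# ---------------------------------------------------------------------------
# Ideal secondary-structure elements and loop construction
# ---------------------------------------------------------------------------

#: (rise per residue [A], turn per residue [deg], radius [A])
_SS_PARAMS = {"H": (1.5, 100.0, 2.3), "G": (2.0, 120.0, 1.9)}

_TYPE_TO_SS = {
    "HH": ("H", "H"), "HE": ("H", "E"), "EH": ("E", "H"),
    "BN": ("E", "E"), "BK": ("E", "E"),
    "GG": ("G", "G"), "GH": ("G", "H"), "HG": ("H", "G"),
    "GE": ("G", "E"), "EG": ("E", "G"),
}


def ideal_element(label: str, n_res: int) -> np.ndarray:
    """Canonical Calpha trace of an ideal element with its axis along +z."""
    i = np.arange(n_res)
    if label in _SS_PARAMS:
        rise, turn, radius = _SS_PARAMS[label]
        ang = np.radians(turn * i)
        return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
    if label == "E":  # extended zigzag, ~3.3 A per residue along the axis
        return np.column_stack([0.8 * (-1.0) ** i, np.zeros(n_res), 3.3 * i])
    raise ValueError(f"unknown SS label {label!r}")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _oriented_element(label: str, n_res: int, direction: np.ndarray) -> np.ndarray:
    """Ideal element rotated so its *computed* principal axis equals ``direction``."""
    from .geometry import principal_vector

    canon = ideal_element(label, n_res)
    axis = principal_vector(canon)
    return canon @ _rotation_between(axis, direction).T


def _solve_m2(delta: float, theta: float, rho: float) -> np.ndarray:
    """Unit M2 with angle(M1, M2)=theta and meridian rho about u=+z.

    M1 = (sin d, 0, cos d); M2 = (sin b cos r, sin b sin r, cos b) with the
    polar angle b solving cos t = sin d cos r sin b + cos d cos b.  Raises
    ValueError when the (delta, theta, rho) triple is geometrically
    unachievable or puts M2 at a pole (meridian undefined).
    """
    d, t, r = np.radians([delta, theta, rho])
    if np.sin(d) < 1e-9:  # M1 parallel to D: measure rho from +x instead
        sign = 1.0 if np.cos(d) > 0 else -1.0
        return np.array([np.sin(t) * np.cos(r), np.sin(t) * np.sin(r), sign * np.cos(t)])
    A = np.sin(d) * np.cos(r)
    B = np.cos(d)
    R = float(np.hypot(A, B))
    c = np.cos(t) / R
    if abs(c) > 1.0 + 1e-9:
        raise ValueError(f"(delta={delta}, theta={theta}, rho={rho}) is unachievable")
    gamma = float(np.arctan2(A, B))
    off = float(np.arccos(np.clip(c, -1.0, 1.0)))
    for b in (gamma + off, gamma - off):
        if np.sin(b) > 1e-6:
            return np.array([np.sin(b) * np.cos(r), np.sin(b) * np.sin(r), np.cos(b)])
    raise ValueError(
        f"(delta={delta}, theta={theta}, rho={rho}) puts M2 at a pole; meridian undefined"
    )


def simulate_loop_coordinates(
    loop_type: str,
    D: float = 10.0,
    delta: float = 20.0,
    theta: float = 90.0,
    rho: float = 180.0,
    n_res: Tuple[int, int, int] = (8, 6, 8),
    noise_sd: float = 0.0,
    seed: int = 0,
    name: Optional[str] = None,
) -> LoopStructure:
    """Build a Calpha loop structure realising the requested internal coordinates.

    Ideal bracing elements (alpha-helix: 1.5 A rise, 100 deg/residue,
    2.3 A radius; 3_10-helix: 2.0 A rise, 120 deg/residue; beta-strand:
    3.3 A extended zigzag) are rotated so their principal axes hit the
    requested M1/M2 directions exactly, placed with the boundary Calpha
    atoms D apart, and optionally perturbed with isotropic Gaussian noise.
    """
    if loop_type not in _TYPE_TO_SS:
        raise ValueError(f"unknown loop type {loop_type!r}")
    if D <= 0:
        raise ValueError("D must be positive")
    if not (0 <= delta <= 180 and 0 <= theta <= 180 and 0 <= rho < 360):
        raise ValueError("angle out of range: delta/theta in [0,180], rho in [0,360)")
    n1, nl, n2 = n_res
    if n1 < 4 or n2 < 4:
        raise ValueError("bracing elements need >= 4 residues (principal axis unstable)")
    if nl < 1:
        raise ValueError("aperiodic region needs >= 1 residue")
    s1, s2 = _TYPE_TO_SS[loop_type]
    d_rad = np.radians(delta)
    m1 = np.array([np.sin(d_rad), 0.0, np.cos(d_rad)])
    m2 = _solve_m2(delta, theta, rho)
    ss1 = _oriented_element(s1, n1, m1)
    ss1 = ss1 - ss1[-1]  # boundary atom of ss1 at the origin
    ss2 = _oriented_element(s2, n2, m2)
    ss2 = ss2 - ss2[0] + np.array([0.0, 0.0, D])  # boundary atom of ss2 at (0,0,D)
    frac = (np.arange(nl) + 1.0) / (nl + 1.0)
    loop = np.column_stack([2.0 * np.sin(np.pi * frac), np.zeros(nl), D * frac])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ss1 = ss1 + rng.normal(0.0, noise_sd, ss1.shape)
        loop = loop + rng.normal(0.0, noise_sd, loop.shape)
        ss2 = ss2 + rng.normal(0.0, noise_sd, ss2.shape)
    return LoopStructure(
        ss1=ss1, loop=loop, ss2=ss2, ss1_label=s1, ss2_label=s2,
        strands_adjacent=(loop_type != "BK"),
        name=name or f"{loop_type}_D{D:g}_d{delta:g}_t{theta:g}_r{rho:g}",
    )
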