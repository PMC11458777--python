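"""Internal coordinates and classification of supersecondary loop motifs.

A loop motif is two sequential periodic secondary-structure elements
(alpha-helix H, beta-strand E or 3_10-helix G) bracing an aperiodic
region.  Its geometry is summarised by four internal coordinates derived
from the principal axes M1, M2 of the bracing elements:

* D      — Euclidean distance (Angstroms) between the boundary Calpha
           atoms of the aperiodic region (last residue of the first
           element, first residue of the second);
* delta  — hoist angle between M1 and the D-vector, in [0, 180] deg;
* theta  — packing angle between M1 and M2, in [0, 180] deg;
* rho    — meridian angle: right-handed rotation of M2 about the
           D-vector, measured from the (M1, D) plane, in [0, 360) deg.

Only Calpha coordinates are used; secondary-structure labels are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

LOOP_TYPES = ("HH", "HE", "EH", "BN", "BK", "GG", "GH", "HG", "GE", "EG")
SS_LABELS = ("H", "E", "G")


@dataclass
class LoopStructure:
    """Calpha trace of one loop motif, segmented into ss1 / loop / ss2."""

    ss1: np.ndarray  # (n1, 3) ordered N->C
    loop: np.ndarray  # (nl, 3)
    ss2: np.ndarray  # (n2, 3)
    ss1_label: str = "H"
    ss2_label: str = "H"
    strands_adjacent: bool = True  # sequence adjacency of the strands (BN/BK split)
    name: str = "loop"

    def __post_init__(self) -> None:
        for seg, nm in ((self.ss1, "ss1"), (self.ss2, "ss2")):
            if len(seg) < 4:
                raise ValueError(f"{nm} has {len(seg)} residues; need >= 4")
        coords = self.all_coords()
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        for lab in (self.ss1_label, self.ss2_label):
            if lab not in SS_LABELS:
                raise ValueError(f"unknown SS label {lab!r}")

    def all_coords(self) -> np.ndarray:
        parts = [self.ss1]
        if len(self.loop):
            parts.append(self.loop)
        parts.append(self.ss2)
        return np.vstack(parts)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LoopStructure":
        return LoopStructure(
            self.ss1 @ rotation.T + translation,
            self.loop @ rotation.T + translation if len(self.loop) else self.loop,
            self.ss2 @ rotation.T + translation,
            self.ss1_label,
            self.ss2_label,
            self.strands_adjacent,
            self.name,
        )


@dataclass
class LoopGeometry:
    """The four internal coordinates plus the bracing principal vectors."""

    D: float
    delta: float
    theta: float
    rho: float
    M1: np.ndarray
    M2: np.ndarray


def principal_vector(coords: np.ndarray) -> np.ndarray:
    """First principal axis of an ordered Calpha segment, oriented N->C.

    The dominant right singular vector of the centred coordinates; the sign
    is fixed so the dot product with (last - first) is positive.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("need >= 4 points for a stable principal axis")
    centred = coords - coords.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise ValueError("coincident points: principal axis undefined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    span = coords[-1] - coords[0]
    if axis @ span < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def internal_coordinates(loop: LoopStructure) -> LoopGeometry:
    """Compute (D, delta, theta, rho) for a loop motif.

    The meridian rho is the azimuth of M2's projection onto the plane
    normal to the D-vector, measured right-handed about D from M1's
    projection; when either projection degenerates (element parallel to D)
    rho is reported as 0.
    """
    m1 = principal_vector(loop.ss1)
    m2 = principal_vector(loop.ss2)
    a = loop.ss1[-1]
    b = loop.ss2[0]
    dvec = b - a
    D = float(np.linalg.norm(dvec))
    if D < 1e-9:
        raise ValueError("coincident boundary atoms: D = 0")
    u = dvec / D
    delta = _angle_deg(m1, dvec)
    theta = _angle_deg(m1, m2)
    p1 = m1 - (m1 @ u) * u
    p2 = m2 - (m2 @ u) * u
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        rho = 0.0
    else:
        rho = float(np.degrees(np.arctan2(u @ np.cross(p1, p2), p1 @ p2))) % 360.0
    return LoopGeometry(D=D, delta=delta, theta=theta, rho=rho, M1=m1, M2=m2)


def classify_loop_type(loop: LoopStructure, geom: Optional[LoopGeometry] = None) -> str:
    """One of the ten ArchDB loop types from the bracing SS labels.

    All pairs concatenate directly (H+E -> "HE", ...) except strand-strand,
    which splits into the beta-hairpin BN (sequence-adjacent, antiparallel:
    packing angle theta > 90 deg) and the beta-link BK otherwise.
    """
    s1, s2 = loop.ss1_label, loop.ss2_label
    if s1 not in SS_LABELS or s2 not in SS_LABELS:
        raise ValueError(f"unknown SS labels ({s1!r}, {s2!r})")
    if s1 == "E" and s2 == "E":
        geom = geom or internal_coordinates(loop)
        return "BN" if loop.strands_adjacent and geom.theta > 90.0 else "BK"
    return s1 + s2


def element_lengths(loop: LoopStructure) -> Tuple[int, int, int]:
    """Residue counts of (ss1, aperiodic region, ss2)."""
    return len(loop.ss1), len(loop.loop), len(loop.ss2)


def geometry_table(loops: Sequence[LoopStructure]) -> pd.DataFrame:
    """Per-loop geometry table: type, D, delta, theta, rho, segment lengths."""
    rows = []
    for lp in loops:
        g = internal_coordinates(lp)
        n1, nl, n2 = element_lengths(lp)
        rows.append(
            {
                "loop": lp.name,
                "type": classify_loop_type(lp, g),
                "D": g.D,
                "delta": g.delta,
                "theta": g.theta,
                "rho": g.rho,
                "n_ss1": n1,
                "n_loop": nl,
                "n_ss2": n2,
            }
        )
    return pd.DataFrame(rows)


_METRICS = ("D", "delta", "theta", "rho", "n_ss1", "n_loop", "n_ss2")


def _box_stats(x: pd.Series) -> Dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return {"median": med, "q1": q1, "q3": q3, "whisker_lo": lo, "whisker_hi": hi, "n": len(x)}


def geometry_phase_trends(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot summaries of geometry over evolutionary phases.

    ``table`` is a :func:`geometry_table` output with an added ``phase``
    column.  Returns (per-phase summary over all loops, per-loop-type
    medians), both long-form and deterministic.
    """
    if "phase" not in table.columns:
        raise ValueError("table must carry a 'phase' column")
    rows = []
    for (phase, metric), grp in (
        table.melt(id_vars=["phase"], value_vars=list(_METRICS), var_name="metric")
        .groupby(["phase", "metric"], sort=True)
    ):
        rows.append({"phase": phase, "metric": metric, **_box_stats(grp["value"])})
    per_phase = pd.DataFrame(rows)
    med = (
        table.melt(id_vars=["type"], value_vars=list(_METRICS), var_name="metric")
        .groupby(["type", "metric"], sort=True)["value"]
        .median()
        .rename("median")
        .reset_index()
    )
    return per_phase, med


# ---------------------------------------------------------------------------
# Minimal PDB + SS-sidecar I/O
# ---------------------------------------------------------------------------


def write_loop_pdb(loop: LoopStructure, pdb_path, ss_path) -> None:
    """Write the Calpha trace as a minimal PDB plus a per-residue SS TSV."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = loop.all_coords()
    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(pdb_path))

    n1, nl, n2 = element_lengths(loop)
    labels = [loop.ss1_label] * n1 + ["C"] * nl + [loop.ss2_label] * n2
    ss = pd.DataFrame({"res_id": np.arange(1, n + 1), "ss": labels})
    ss["adjacent"] = loop.strands_adjacent
    ss.to_csv(ss_path, sep="\t", index=False)


def read_loop_pdb(pdb_path, ss_path, name: Optional[str] = None) -> LoopStructure:
    """Read a minimal CA-only PDB and its SS sidecar back into a LoopStructure."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(pdb_path)).get_structure(model=1)
    atoms = atoms[atoms.atom_name == "CA"]
    order = np.argsort(atoms.res_id)
    coords = np.asarray(atoms.coord, dtype=float)[order]
    ss = pd.read_csv(ss_path, sep="\t").sort_values("res_id")
    labels = ss["ss"].tolist()
    if len(labels) != len(coords):
        raise ValueError("SS sidecar length does not match PDB residues")
    lab = np.array(labels)
    periodic = lab != "C"
    n1 = int(np.argmax(~periodic)) if (~periodic).any() else len(lab)
    rest = lab[n1:]
    nl = int(np.argmax(rest != "C")) if (rest != "C").any() else len(rest)
    return LoopStructure(
        ss1=coords[:n1],
        loop=coords[n1 : n1 + nl],
        ss2=coords[n1 + nl :],
        ss1_label=str(lab[0]),
        ss2_label=str(lab[-1]),
        strands_adjacent=bool(ss["adjacent"].iloc[0]) if "adjacent" in ss else True,
        name=name or Path(pdb_path).stem,
    )
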