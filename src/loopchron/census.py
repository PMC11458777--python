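"""Genomic-abundance censuses and their encoding as ordered multistate characters.

A census records, for each proteome (labelled with one of the supergroups
Archaea/Bacteria/Eukarya/Viruses), the genomic abundance ``g`` of every
structural domain family.  Abundances are log-rescaled to ``S`` linearly
ordered character states, ``state = round(ln(1+g)/ln(1+g_max) * (S-1))``,
so that absence maps to state 0 and the column maximum to ``S-1``; the
resulting matrix is the input to Wagner-parsimony tree building.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

SUPERGROUPS = ("A", "B", "E", "V")

#: NEXUS symbols for states 0..35 (0-9 then A-Z); S=24 uses "0-9A-N".
_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _round_half_away(x: float) -> int:
    """Round halves away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class CensusMatrix:
    """Proteome x family abundance counts with per-proteome supergroup labels."""

    abundance: pd.DataFrame  # index: proteome IDs, columns: family IDs, int cells
    supergroup: pd.Series  # index: proteome IDs, values in SUPERGROUPS

    def __post_init__(self) -> None:
        a = self.abundance
        if a.empty:
            raise ValueError("empty census")
        if (a.values < 0).any():
            raise ValueError("negative abundance cell")
        if (a.values.sum(axis=0) == 0).any():
            dead = a.columns[a.values.sum(axis=0) == 0].tolist()
            raise ValueError(f"all-zero family columns: {dead}")
        if not a.index.equals(self.supergroup.index):
            self.supergroup = self.supergroup.reindex(a.index)
        bad = set(self.supergroup.unique()) - set(SUPERGROUPS)
        if bad:
            raise ValueError(f"unknown supergroup labels: {bad}")

    @property
    def families(self) -> list:
        return list(self.abundance.columns)

    @property
    def proteomes(self) -> list:
        return list(self.abundance.index)

    def to_tsv(self, path) -> None:
        out = self.abundance.copy()
        out.insert(0, "supergroup", self.supergroup)
        out.index.name = "proteome"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CensusMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sg = df.pop("supergroup")
        return cls(df.astype(int), sg)


@dataclass
class CharacterMatrix:
    """Ordered multistate character matrix (states 0..S-1) on the census axes."""

    states: pd.DataFrame  # int cells in [0, S-1]
    n_states: int = 24
    scope: str = "per-family"
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.states.values
        if v.size == 0:
            raise ValueError("empty character matrix")
        if v.min() < 0 or v.max() > self.n_states - 1:
            raise ValueError("state outside [0, S-1]")

    def transpose(self) -> "CharacterMatrix":
        return CharacterMatrix(self.states.T, self.n_states, self.scope, dict(self.meta))

    def row_states(self) -> np.ndarray:
        return np.ascontiguousarray(self.states.values, dtype=np.int64)


def normalize_abundance(g: int, g_max: int, n_states: int = 24) -> int:
    """Map an abundance count to its ordered character state.

    ``round(ln(1+g) / ln(1+g_max) * (S-1))``, rounding half away from zero;
    g=0 gives state 0 and g=g_max gives state S-1 exactly.
    """
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    if not 0 <= g <= g_max:
        raise ValueError(f"g={g} outside [0, g_max={g_max}]")
    if n_states < 2:
        raise ValueError("need at least 2 states")
    return _round_half_away(math.log1p(g) / math.log1p(g_max) * (n_states - 1))


def encode_census(census: CensusMatrix, n_states: int = 24, scope: str = "per-family") -> CharacterMatrix:
    """Encode a census into character states.

    scope="per-family" (default) scales each family column by its own
    maximum; scope="global" uses the single matrix-wide maximum.
    """
    a = census.abundance.values
    if scope == "per-family":
        gmax = a.max(axis=0)
    elif scope == "global":
        gmax = np.full(a.shape[1], a.max())
    else:
        raise ValueError(f"unknown scope {scope!r}")
    scaled = np.log1p(a) / np.log1p(gmax)[None, :] * (n_states - 1)
    states = np.floor(scaled + 0.5).astype(int)  # cells are >= 0
    df = pd.DataFrame(states, index=census.abundance.index, columns=census.abundance.columns)
    return CharacterMatrix(df, n_states, scope, meta={"g_max_scope": scope, "S": n_states})


# ---------------------------------------------------------------------------
# NEXUS export / import (ordered standard characters)
# ---------------------------------------------------------------------------


def write_character_matrix(m: CharacterMatrix, path) -> None:
    """Write a PAUP*-style NEXUS file (DATA block + ordered-characters ASSUMPTIONS)."""
    if m.n_states > len(_SYMBOLS):
        raise ValueError(f"cannot encode {m.n_states} states alphanumerically")
    symbols = _SYMBOLS[: m.n_states]
    rows = m.states
    namew = max(len(str(t)) for t in rows.index) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={rows.shape[0]} NCHAR={rows.shape[1]};",
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}";',
        "  MATRIX",
    ]
    for taxon, states in rows.iterrows():
        coded = "".join(symbols[s] for s in states.values)
        lines.append(f"    {str(taxon):<{namew}}{coded}")
    lines += [
        "  ;",
        "END;",
        "BEGIN ASSUMPTIONS;",
        "  TYPESET * default = ord: all;",
        "END;",
        "",
    ]
    lines.insert(1, f"[characters: {' '.join(str(c) for c in rows.columns)}]")
    lines.insert(2, f"[nstates: {m.n_states} scope: {m.scope}]")
    Path(path).write_text("\n".join(lines))


def read_character_matrix(path) -> CharacterMatrix:
    """Read a NEXUS file written by :func:`write_character_matrix`."""
    text = Path(path).read_text()
    mchars = re.search(r"\[characters: (.*?)\]", text)
    mmeta = re.search(r"\[nstates: (\d+) scope: (\S+)\]", text)
    msym = re.search(r'SYMBOLS="([^"]+)"', text)
    if not (mchars and mmeta and msym):
        raise ValueError("not a loopchron NEXUS character file")
    columns = mchars.group(1).split()
    n_states = int(mmeta.group(1))
    scope = mmeta.group(2)
    symbols = msym.group(1)
    body = text.split("MATRIX", 1)[1].split(";", 1)[0]
    taxa, data = [], []
    for line in body.strip().splitlines():
        parts = line.split()
        if len(parts) != 2:
            continue
        taxa.append(parts[0])
        data.append([symbols.index(ch) for ch in parts[1]])
    df = pd.DataFrame(data, index=taxa, columns=columns)
    return CharacterMatrix(df, n_states, scope)
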