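"""Loop internal coordinates, type classification and phase trends.

Reads the CA-only loop structures written by 01, measures the four
internal coordinates (D, hoist delta, packing theta, meridian rho) and
segment lengths, classifies the ten ArchDB loop types, joins prototype
phases, and summarises the geometry per evolutionary phase.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import loopchron as lc
from loopchron.geometry import read_loop_pdb

BASE = Path(__file__).resolve().parents[1] / "results"
LOOPS = BASE / "data" / "loops"

loops = [
    read_loop_pdb(pdb, pdb.with_name(pdb.name.replace(".pdb", ".ss.tsv")))
    for pdb in sorted(LOOPS.glob("*.pdb"))
]
table = lc.geometry_table(loops)

# attach each loop's phase by loop type via the dated prototypes from 03
protos = pd.read_csv(BASE / "prototypes.tsv", sep="\t")
protos["phase"] = protos["age_gya"].map(lambda a: lc.assign_phase(float(a)))
type_phase = protos.groupby("loop_type")["phase"].median().round().astype(int)
table["phase"] = table["loop"].str.replace("loop_", "").map(type_phase)
table = table.dropna(subset=["phase"]).astype({"phase": int})
table.to_csv(BASE / "geometry.tsv", sep="\t", index=False)

per_phase, per_type = lc.geometry_phase_trends(table)
per_phase.to_csv(BASE / "geometry_phase_trends.tsv", sep="\t", index=False)
per_type.to_csv(BASE / "geometry_type_medians.tsv", sep="\t", index=False)

print(f"measured {len(table)} loops across types: {sorted(table['type'].unique())}")
print("median geometry per loop type (theta = packing angle):")
med = per_type[per_type.metric == "theta"].set_index("type")["median"]
for t, v in med.items():
    print(f"  {t}: theta median {v:.1f} deg")
print(f"phase trends written for {per_phase.phase.nunique()} phases -> "
      f"{BASE/'geometry_phase_trends.tsv'}")
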