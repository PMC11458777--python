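"""Venn groups, six-phase accretion tables and urancestral repertoires.

Families get Venn labels from their census presence; prototypes inherit
the labels of their oldest mapped family.  Everything is segmented into
the six evolutionary phases (3.8 Gya -> present) to build the per-phase
prototype/family accretion table, and the LUCA (Phase 0) and LUCellA
(Phases 0-I) repertoires are summarised by loop type, disorder and
function.
"""

from pathlib import Path

import pandas as pd

import loopchron as lc

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"
TABLES = BASE / "tables"
TABLES.mkdir(exist_ok=True)

census = lc.CensusMatrix.from_tsv(DATA / "census.tsv")
chron = lc.Chronology.from_tsv(BASE / "chronology.tsv")
protos = pd.read_csv(BASE / "prototypes.tsv", sep="\t")
edges = pd.read_csv(BASE / "bipartite_edges.tsv", sep="\t")

fam_venn = {f: lc.venn_group(lc.presence_from_census(census, f)) for f in census.families}
families = chron.table().reset_index()
families["venn"] = families["family"].map(fam_venn)
families = families.rename(columns={"age_Gya": "age_gya"})

oldest_family = (
    edges.sort_values(["prototype", "family_nd"]).groupby("prototype").first()["family"]
)
protos["venn"] = protos["prototype"].map(oldest_family).map(fam_venn)
protos = protos.rename(columns={"age_gya": "age_gya"})

table = lc.phase_table(protos, families)
table.to_tsv(TABLES / "venn_phase")

print("per-phase accretion (prototypes / families / ratio):")
for ph, row in table.summary.iterrows():
    ratio = "undef" if row.ratio_undefined else f"{row.ratio:.2f}"
    print(f"  phase {ph}: {int(row.prototypes):3d} / {int(row.families):3d} / {ratio}")

ann = pd.read_csv(DATA / "prototype_annotations.tsv", sep="\t", index_col=0)
for which in ("LUCA", "LUCellA"):
    rep = lc.urancestor_repertoire(protos, which=which)
    tabs = lc.summarize_repertoire(rep, ann, by=("loop_type", "disorder"))
    for name, tab in tabs.items():
        tab.to_csv(TABLES / f"{which}_{name}.tsv", sep="\t")
    types = ", ".join(f"{ix}:{int(r['count'])}" for ix, r in tabs["loop_type"].iterrows())
    print(f"{which}: {len(rep)} prototypes ({types or 'empty'})")
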