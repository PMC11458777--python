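"""Encode the census and infer the tree-of-domains chronology.

Census abundances are log-rescaled to 24 ordered states (per-family
maxima), written as a PAUP*-style NEXUS matrix, and the tree of domains
is inferred by Wagner parsimony (random-addition + NNI), rooted with an
all-maximum-state ancestor (generality criterion), and converted to a
node-distance chronology calibrated on the default 3.8 Gya -> present
clock.  Reports how well the chronology recovers the planted birth order.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

import loopchron as lc

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"

census = lc.CensusMatrix.from_tsv(DATA / "census.tsv")
matrix = lc.encode_census(census, n_states=24, scope="per-family")
lc.write_character_matrix(matrix, BASE / "matrix.nex")

chron = lc.build_chronology(matrix)  # defaults: 4 NNI starts, max-state ancestor
chron.to_tsv(BASE / "chronology.tsv")
(BASE / "tree.nwk").write_text(chron.tree.to_newick() + "\n")

truth = pd.read_csv(DATA / "truth_families.tsv", sep="\t", index_col=0)
rho, _ = spearmanr(truth["birth_time"], chron.nd.reindex(truth.index))

print(f"character matrix: {matrix.states.shape[0]} proteomes x "
      f"{matrix.states.shape[1]} families, S=24 -> {BASE/'matrix.nex'}")
print(f"most parsimonious tree found: length {chron.meta['tree_length']:.0f}")
print(f"chronology spans nd {chron.nd.min():.2f}..{chron.nd.max():.2f} "
      f"({chron.ages.max():.2f}..{chron.ages.min():.2f} Gya)")
print(f"Spearman(planted birth order, inferred nd) = {rho:.3f}")
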