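# loopchron

Phylogenomic chronologies of protein structural domains and the loop
prototypes that build them.

## The problem

Protein domains accrete gradually over evolutionary time, and their
genomic abundances carry phylogenetic memory: structures shared by all of
Archaea (A), Bacteria (B), Eukarya (E) and Viruses (V), and abundant in
every proteome, tend to be older than lineage-specific, rare ones.
`loopchron` turns a census of domain-family abundances across proteomes
into a rooted *tree of domains* and a calibrated chronology, then places
supersecondary **loop prototypes** (two periodic secondary-structure
elements bracing an aperiodic region, ArchDB-style `DS.HE.6.17.1`
identifiers) onto that chronology to study how the building blocks of the
protein world accumulated — from the communal world of 3.8 Gya through
LUCA, LUCellA and the rise of the modern supergroups.

## The method

1. **Encoding.** Abundance `g` of family *f* in proteome *p* becomes an
   ordered character state `round(ln(1+g)/ln(1+g_max) · (S−1))` with
   S = 24 states (per-family `g_max` by default).
2. **Tree of domains.** Wagner parsimony (linear cost `|i−j|`, Sankoff
   dynamic programming) with random-addition + NNI search over family
   leaves; rooting by Lundberg's ancestor method — a hypothetical
   all-maximum-state ancestor attached at the most parsimonious branch
   (Weston's generality criterion: oldest = most abundant/widespread).
3. **Chronology.** Each family's relative age is its node distance
   `nd ∈ [0,1]` (internal nodes from root to leaf, rescaled); a linear
   clock maps nd to Gya (default anchors: nd 0 → 3.8 Gya, nd 1 → present).
4. **Prototype dating.** Prototype→family mappings filtered at
   e-value < 0.001; *non-modular* prototypes map to families of a single
   nd, *modular* ones to several ages and mark recruitment; prototype age
   is the minimum mapped nd.
5. **Accretion analysis.** Four-set Venn groups (15 labels over
   {A,B,E,V}), six evolutionary phases (3.8–3.6, 3.6–3.2, 3.2–2.5,
   2.5–2.0, 2.0–0.9, 0.9–0 Gya), per-phase prototype/family accretion
   tables, LUCA/LUCellA repertoires with annotation summaries.
6. **Reticulation statistics.** Venn-weighted uncorrected-P distances over
   the five network taxa (A, B, E, V, hypothetical ancestor), quartet
   delta scores (0 = tree-like, 1 = fully reticulate), Q-residuals, NJ
   trees and item-resampling bootstrap support.
7. **Loop geometry.** ArchDB internal coordinates from Cα traces: span
   D (Å), hoist δ = ∠(M1, D), packing θ = ∠(M1, M2), meridian
   ρ ∈ [0,360) = rotation of M2 about D from the (M1, D) plane, with
   M1/M2 the principal axes of the bracing elements; ten loop types
   (HH … BN/BK) and per-phase geometry trends.

A synthetic-data generator (`loopchron.synthetic`) emulates the study
inputs with a planted ground truth — birth orders, Venn labels,
modularity and loop coordinates — so the whole pipeline is testable
without any external data.

## Worked example

```python
import loopchron as lc
from scipy.stats import spearmanr

census, truth = lc.simulate_accretion()          # 32 proteomes x 60 families
matrix = lc.encode_census(census)                # 24 ordered states
chron  = lc.build_chronology(matrix)             # search + root + nd + clock
rho, _ = spearmanr(truth.birth_time, chron.nd.reindex(truth.birth_time.index))
print(f"tree length {chron.meta['tree_length']:.0f}, recovery rho = {rho:.3f}")
```

prints

```
tree length 3526, recovery rho = 0.853
```

i.e. the most parsimonious tree found has 3526 ordered state changes and
the inferred node-distance chronology recovers the planted family birth
order with Spearman ρ = 0.853.

The full analysis — synthetic inputs, chronology, prototype dating,
accretion tables, reticulation network, loop geometry — runs as numbered
drivers:

```sh
python analysis/01_simulate_data.py
python analysis/02_build_chronology.py
...
python analysis/06_loop_geometry.py
```

each printing its findings and writing tables under `results/`.

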