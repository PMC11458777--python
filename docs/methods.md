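# Methods

## The model

`loopchron` reconstructs the history of protein structural domains and of
the loop prototypes that compose them, under three assumptions:

1. **Memory.** Genomic abundance of a domain family across proteomes is a
   heritable, slowly-changing character. Log-rescaled abundances are
   treated as linearly ordered multistate characters: a change from state
   *i* to *j* costs `|i − j|` (Wagner parsimony).
2. **Generality.** Older structures are more abundant and more widely
   distributed. This licenses rooting with a hypothetical all-maximum
   state ancestor (Lundberg attachment at the most parsimonious branch)
   and makes node distance a proxy for age.
3. **Clock.** Relative node distances map linearly onto geological time.
   The default calibration anchors nd = 0 at 3.8 Gya (origin of the
   protein record) and nd = 1 at the present; any ≥ 2 anchor pairs can be
   regressed instead (e.g. the biomarker pair nd 0.180 → 3.0 Gya,
   nd 0.210 → 2.9 Gya gives intercept 3.6, slope −10/3).

## Pipeline and conventions

**Encoding** (`census`). `state = round(ln(1+g) / ln(1+g_max) · (S−1))`,
S = 24, rounding half away from zero; `g_max` is per-family (default) or
global. Endpoints are exact: absence → 0, column maximum → S−1. Export is
a PAUP*-style NEXUS with symbols `0–9A–N` and an ordered-characters
ASSUMPTIONS block, round-tripping bit-exactly through the module reader.

**Tree inference** (`parsimony`). Sankoff DP scores a tree in
O(nodes · characters · states) using a min-plus distance transform (two
`minimum.accumulate` passes) for the linear cost. The heuristic is
greedy random-addition starting trees followed by first-improvement NNI
over a deterministic edge enumeration, with seeded restarts (default 4,
seed 0); on ≤ 7 leaves it attains the exhaustive optimum (tested), and an
explicit enumeration over all internal-node state assignments serves as
an independent oracle for the DP. Before searching, family rows are
sorted lexicographically, so results are invariant to input column order.
Tie handling: the first optimal root attachment in the deterministic edge
order is kept and the tie count logged.

**Node distances.** `d(leaf)` counts internal nodes on the root→leaf
path (root included); `nd = (d−1)/(d_max−1)` (a min-max variant is
available). Two-leaf and other degenerate trees yield nd = 0 everywhere.
Negative calibrated ages are clipped to 0 with a warning rather than
raised.

**Prototype dating** (`prototypes`). Mappings filtered at strictly
e < 0.001. Non-modular ⇔ all mapped nds within a tie tolerance (default
1e−12, configurable because inferred chronologies jitter genuine ties).
Prototype age = minimum mapped nd for both classes; for non-modular
prototypes all mapped ages are equal anyway. The bipartite edge table
marks `is_recruitment` where the family is younger than the prototype.

**Venn groups and phases** (`vennphases`). Presence = ≥ 1 proteome with
g > 0 (a min-proteome option exists for noise robustness). Phase
intervals are closed at the older bound, open at the younger, so an age
exactly on an internal boundary (2.5 Gya) belongs to the younger phase;
age 0 belongs to the last phase. Ratios are rounded half-away-from-zero
to 2 decimals; phases without families get a flagged undefined ratio.
Missing annotations are tallied as "Other/Unknown" rather than dropped.

**Reticulation** (`reticulation`). Quartet delta = `(m1−m2)/(m1−m3)` on
the descending pairwise sums, defined 0 when all three sums tie; the
Q-residual is `(m1−m2)²` after rescaling distances so the mean
off-diagonal distance is 1 (scale-invariant). The fifth network taxon is
an all-absent hypothetical ancestor (configurable). Bootstrap resamples
item-level units (prototypes) multinomially over the 15 Venn columns,
because column weights are item counts; splits on zero-length branches
are reported unresolved. Neighbor joining is delegated to scikit-bio with
negative branch lengths clamped to 0.

**Loop geometry** (`geometry`). Only Cα atoms are used; principal axes
are dominant singular vectors of centred coordinates, oriented N→C
(positive dot product with last−first). D is measured between the
flanking Cα atoms of the aperiodic region. The meridian ρ is the
right-handed rotation of M2 about the D-vector measured from the (M1, D)
plane, range [0,360); when either projection degenerates (element
parallel to D) ρ is reported as 0. δ = hoist, θ = packing, ρ = meridian —
the pairing consistent with meridian medians above 180°, which only a
[0,360) range permits. The strand–strand type splits into BN (β-hairpin:
sequence-adjacent and θ > 90°) and BK (β-link) — a declared convention.
Secondary-structure labels are inputs (sidecar TSV next to the CA-only
PDB); no DSSP reimplementation.

## The synthetic generator

`simulate_accretion` plants sorted-uniform birth times `t_f ∈ [0,1]`
(age = 3.8·(1−t)), draws each family's Venn label from a per-phase
schedule, and sets abundance `Poisson(λ0·e^{−k·t_f})` in member-group
proteomes (0 elsewhere), then zeroes cells with the dropout probability.
Defaults — 60 families, 8 proteomes per supergroup, λ0 = 50, k = 2,
dropout = 0.05, seed 1 — are the desk-scale study conditions. The
per-phase Venn schedule follows the composition pattern characteristic of
domain-accretion censuses: universal groups (ABEV, ABE) dominate the
early and middle phases almost entirely, the first bacterial-lineage
labels appear as a small trickle mid-timeline, and supergroup-specific
and E/EV-enriched labels appear only late; labels are assigned at birth
and never change. If
dropout erases a family everywhere, one member cell is redrawn so the
census invariant (every family observed somewhere) holds.

`simulate_prototype_mappings` gives non-modular prototypes one mapped
family and modular ones 2–3 families of distinct birth times, with true
links at e < 0.001 and interleaved decoys at e ≥ 0.001.
`simulate_loop_coordinates` builds ideal elements (α-helix 1.5 Å rise,
100°/residue, 2.3 Å radius; 3₁₀ 2.0 Å, 120°/residue; β-strand 3.3 Å
extended zigzag), rotates them so their *computed* principal axes realise
the requested M1/M2 exactly, and optionally adds isotropic Gaussian
noise. Because (δ, θ, ρ) are mutually constrained (M2 has two degrees of
freedom), the generator solves the spherical relation
`cos θ = sin δ cos ρ sin β + cos δ cos β` for M2's polar angle β and
raises `ValueError` for unreachable or pole-degenerate triples.

What the generator does *not* emulate: realistic SCOP abundance
distributions beyond exponential decay, sequence evolution, correlated
dropout, within-proteome paralog structure, or real ArchDB conformational
classes. Passing tests demonstrate internal consistency of the method
under the accretion model, not performance on empirical censuses.

## Problem sizes and test scales

The test and analysis runs use 60 families × 32 proteomes (tree search
seconds-scale), 40–60 prototypes, 2000 bootstrap replicates for the
five-taxon network, and exhaustive-search oracles up to 7 leaves
(945 topologies) with state-enumeration oracles up to 6 leaves. These
sizes resolve every qualitative behaviour of the method while keeping a
full pipeline run around half a minute.

## Known limitations

- **Chronology variance at desk scale.** With only 32 characters the
  Wagner optimum is nearly degenerate; equally or near-equally
  parsimonious trees can differ in where broadly-shared-but-not-universal
  clades (e.g. ABE families, absent from viral proteomes) attach, and a
  pectinate side-clade inflates its node distances. Across heuristic
  search seeds 0–5 at the default preset, recovery of the planted birth
  order spans Spearman ρ ≈ 0.44–0.89 (0.853 at the package defaults);
  notably the shortest tree found is not the best-recovering one. Global
  abundance scaling (`scope="global"`) shows a narrower range
  (≈ 0.77–0.88) because it retains cross-family magnitude information,
  but per-family scaling remains the default as the standard protocol.
- **nd is a coarse clock.** Node counts compress unresolved regions and
  inflate ladders; ties in nd can merge genuinely distinct ages, which is
  why modularity classification exposes a tolerance.
- **ρ convention.** The meridian's sign/reference convention is declared
  (right-handed about D from the (M1, D) plane); the round-trip oracle
  against the generator defines correctness internally.
- **BN/BK rule.** Sequence adjacency + θ > 90° is a declared stand-in for
  ArchDB's exact hairpin criterion.
- The delta score and Q-residual quantify treelikeness of the 5-taxon
  Venn-weighted system only; no split network is constructed.
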