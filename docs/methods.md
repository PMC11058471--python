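# Methods

## Overview

`phylotda` quantifies the phylogenetic signal in protein 3D structures by
comparing topological signatures of atom point clouds with sequence-derived
evolutionary distances. The pipeline per family: structures → point clouds
(with optional confidence and per-pair indel masking) → filtration (alpha
complex or Vietoris–Rips) → persistence barcodes in homological dimensions
1 and 2 → pairwise barcode distances (bottleneck, 2-Wasserstein, landscape
L2), normalized by the average point count → correlation against
p-distances and patristic distances.

## Filtrations and persistence

**Vietoris–Rips.** Simplex value = maximum pairwise Euclidean distance of
its vertices (diameter convention); default threshold = cloud diameter, so
every class in dimensions ≥ 1 dies inside the complex; `max_dim = 3` so H2
is computable. Construction is the incremental lower-neighbour expansion;
clouds above 150 points are refused (combinatorial growth) in favour of the
alpha complex.

**Alpha complex.** Simplices are the 3D Delaunay simplices
(`scipy.spatial.Delaunay`). A simplex whose smallest circumscribing ball is
empty (Gabriel) enters at its squared circumradius; non-Gabriel faces
inherit the minimum value over their cofaces, assigned by the standard
top-down sweep with a final downward clamp to guarantee the filtration
property in floating point. Values are therefore in Å²; alpha-complex and
VR distances are never mixed in one analysis. Degenerate inputs (duplicate
or cospherical points) are retried once after a deterministic 1e-6 Å
jitter.

**Persistence.** Standard left-to-right column reduction of the boundary
matrix over Z/2Z, columns stored as Python integer bitsets; simplices
ordered by (value, dimension, lexicographic vertices) — any tie-break gives
the same barcode, a fixed one makes runs bit-for-bit reproducible.
Zero-persistence pairs are dropped. Dimension 0 is computed only for
internal checks: component lifetimes mostly reflect inter-point spacing,
not fold geometry. An independent persistent-cohomology route (reduction of
the anti-transposed matrix) is implemented and must agree exactly; the test
suite additionally rederives barcodes of small complexes from persistent
Betti numbers obtained by GF(2) rank computations and inclusion–exclusion
over the critical-value grid — a pairing-free oracle.

## Barcode distances

Printed matching formulas quantify over bijections P → Q, which is
ill-posed for |P| ≠ |Q|; both matching distances use the standard diagonal
augmentation (an interval may match its nearest diagonal point), which the
stability theorems require.

* **Bottleneck**: exact; exhaustive search for ≤ 12 intervals in total,
  otherwise binary search over the finite candidate-cost set with a
  bipartite feasibility matching.
* **2-Wasserstein** (q = 2, internal L2): exact optimal assignment on the
  (|P|+|Q|)-square augmented cost matrix; reported as the square root of
  the minimal sum of squared costs. The sum-of-squares form without the
  outer root (`root=False`) is also exposed; see "size normalization"
  below for why it matters.
* **Landscapes**: λ_ℓ(t) = ℓ-th largest tent value
  max(0, min(t − b, d − t)). Breakpoints are placed at all births, deaths
  and pairwise tent crossings (b_i + d_j)/2, between which every level is
  linear, so the representation is exact; the L2 distance integrates the
  squared piecewise-linear difference in closed form on the merged
  breakpoint grid. No sampling grid, hence no resolution knob.

**Normalization.** Distances are divided by (n_A + n_B)/2, the average
number of points actually used after masking, making values comparable
across proteins of different size (the analogue of per-site sequence
distances).

## Masking

* **Confidence**: per-residue confidence (pLDDT-style, 0–100) is read from
  the B-factor of each residue's CA and inherited by all atoms of the
  residue. Masking removes whole residues with confidence below 70 (≥ 70
  retained by default; strictness and threshold are options).
* **Indels**: for each pair, alignment columns gapped in exactly one row
  mark the opposing residue for removal from that protein's cloud. Masking
  is pair-specific, so barcodes are cached by retained-residue set, not by
  structure. Columns gapped in both rows carry no residue on either side
  and are ignored. The two maskings commute (intersection of retained
  sets).

## Evolutionary distances

p-distance = proportion of differing sites among columns ungapped in both
rows (pairwise deletion; gap treatment is a convention choice — pairwise
deletion matches common distance software). Patristic distance = sum of
branch lengths on the leaf-to-leaf path (dendropy), in expected
substitutions per site. Trees are inputs; no inference or trimming is done
here.

## Synthetic families

The generator provides families whose structures diverge in proportion to
sequence divergence — the statistical premise of the correlation analyses —
with all randomness derived from one seed (two runs with equal config are
byte-identical).

* **Tree**: Yule process, n ≥ 7 taxa (families below 7 members are not
  meaningful here), birth rate 3.0 by default, giving median pairwise
  patristic distances around 0.85 substitutions/site — inside the range
  spanned by real prokaryotic protein families (medians roughly 0.02–1.5).
* **Sequences**: 20-state Jukes–Cantor-type kernel; along a branch of
  length t a site changes with probability (19/20)(1 − e^{−(20/19)t}),
  which composes exactly along paths, so the expected p-distance at
  patristic distance d is (19/20)(1 − e^{−(20/19)d}). Indel events are
  Poisson per branch (default 0.05 events per unit branch length),
  geometric lengths (mean 3), uniform positions; insertions create new
  homology columns in a global column order, from which the true alignment
  is assembled.
* **Structures**: the root CA trace is a compact self-avoiding fixed-step
  walk (3.8 Å consecutive spacing, confined to the globular radius of
  gyration ≈ 2.2·L^0.38 Å, soft self-avoidance). Compactness matters:
  globular folds have large-scale cycles and cavities whose spatial scale
  grows with chain length, as in real proteins; an extended curve has only
  turn-scale features and its barcode distances barely respond to protein
  size. Along each branch, coordinates receive a Gaussian displacement
  field of per-coordinate sd `struct_noise_sd·√t` (default 0.5 Å per
  √(substitution/site)), smoothed along the chain (window 9, marginal
  variance preserved): homologs deform coherently — helices shift, domains
  move — rather than by independent per-residue scatter. The expected
  squared CA displacement between two leaves at patristic distance d is
  3·sd²·d. Deleted residues disappear from descendants; inserted residues
  are placed by interpolation between their flanking residues plus noise.
  Defaults put leaf-pair CA RMSD at roughly 0.9–1.7 Å over the sampled
  divergence range, consistent with the accuracy scale of predicted
  structures.
* **Confidence**: a fraction (default 6%, imitating structure sets where
  ~94% of residues have confidence ≥ 70) of *alignment columns* is marked
  low-confidence family-wide — flexible, poorly predicted segments are
  homologous features — and the corresponding residues get confidence
  Uniform(40, 70) plus extra i.i.d. coordinate noise (3× the Brownian
  scale), the rest Uniform(85, 99). Confidence masking therefore removes
  nearly the same residues from every family member; with per-structure
  random placement, masking would remove a different random subset from
  each cloud and degrade rather than improve the comparison.

What the generator does **not** model: side-chain packing and rotamers,
secondary-structure-specific geometry, among-site rate variation,
structure-constrained (neutral-network) sequence evolution,
domain-rearrangement events. Passing tests therefore demonstrate that the
pipeline recovers signal under a coherent-divergence model, not that real
structure prediction noise behaves like the synthetic noise.

## Behaviour of the distances, and choices made where the design was open

* **Saturation.** The topological signal is non-monotone in the Brownian
  scale: once displacements approach the inter-point spacing the cloud
  scrambles, barcode distances saturate and the correlation with
  evolutionary distance decays. Property tests compare noise levels inside
  the monotone regime.
* **Size scaling and normalization.** Between dense barcodes the
  Wasserstein distance behaves like optimal transport between persistence
  measures: matching absorbs the growth in interval count, so the rooted
  distance is sub-extensive in point count (measured family-mean Ws² ~
  n^0.65 under the generator). The sum-of-squares (no-root) form is the
  closest to extensive, and it is the form under which dividing by the
  average point count is closest to exact; the size-correlation analysis
  therefore uses `root=False`. Even so, the normalized-vs-size correlation
  at the 10-family scale has family-level sampling noise of order ±0.3;
  the fixed-seed test pins one realization.
* **Conventions left open upstream** (coefficient field, VR threshold,
  alpha values as radius vs squared radius, the outer root of Ws/Ls):
  resolved to the defaults of the standard computational-topology tooling
  — Z/2Z, threshold = diameter, squared circumradius, rooted distances —
  with the literal sum-of-squares forms exposed via `root=False` flags.
* **PC(All-C)** includes backbone carbons (literal reading of "all
  carbon"); `sidechain_only=True` gives the other reading.
* **p-values.** Distance pairs sharing a protein are not independent, so a
  parametric Pearson p overstates significance; a within-family
  label-permutation (Mantel-style) p-value is computed alongside it and is
  the one quoted in the analyses.

## Numerical notes

Duplicate coordinates are resolved by a deterministic 1e-6 Å jitter before
Delaunay triangulation. All matching distances are exact (no approximation
parameter); landscape integration is exact. Barcode caching is keyed by
(structure, selector, filtration, retained-residue tuple). Problem sizes in
the test suite and acceptance script — families of 7–16 taxa and chains of
45–300 residues, 10-family pooled analyses, 500-pair null samples — were
chosen so a full run completes in minutes on one CPU while keeping every
statistical check at the scale its effect needs to be detectable.

## Known limitations

Bottleneck/Wasserstein exactness relies on O((n+m)³) assignment; barcodes
beyond a few thousand intervals would need approximate solvers. The VR
construction is capped at 150 points by design. mmCIF is not parsed; only
single-chain, first-model PDB text is read. The homolog-null analysis
samples unordered pairs without replacement within the pools it is given,
so very small family sets limit the attainable pair counts.
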