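# Methods

## Assembly-pathway model

A complex is reduced to its chain-by-chain interface-area matrix. The model
assumes association is dominated by interface size: at every step the pair of
current subcomplexes burying the largest total new interface merges, where the
gain of merging subcomplexes *A* and *B* is the sum of the pairwise chain
areas Σ Mᵢⱼ over cross pairs. This pairwise-additive gain stands in for
re-computing buried surface on whole subcomplexes; it is exact whenever no
chain touches two partners through overlapping patches, and the additivity and
pairwise-versus-full-context properties are verified on triple-contact-free
bead fixtures to within 2%.

The relative order of two subunit species is read off the pathway at the
first step uniting chains of both. "Larger subcomplex assembles first" is
measured by chain count; equal counts give SIMULTANEOUS. Chain count (rather
than buried area or mass) is the choice that reproduces the intended
homodimer-then-monomer narrative, and it generalizes the heterodimer case
(1 vs 1 → simultaneous) to equal-size subcomplexes such as two heterodimers
uniting. Ties in merge gain — certain in symmetric synthetic complexes — are
broken toward the lexicographically smallest merged chain-id tuple, making
the pathway and its serialization deterministic.

Because only the *ranking* of interface areas drives the pathway, the model
is invariant to any positive rescaling of the matrix; this is tested.

## Interface areas

SASA uses a Shrake–Rupley scheme with a deterministic spherical Fibonacci
point set (default 960 points/atom; ≥92 enforced) and probe radius 1.4 Å. Per
atom, the accessible fraction is the fraction of points on the expanded
sphere (r + probe) outside every other expanded sphere. Accuracy on analytic
fixtures: isolated spheres and two-sphere lenses agree with closed forms
within 1% at 960 points, and doubling the point count moves totals by <0.5%.
A pre-existing SASA implementation (biotite) serves as an independent
cross-check in the test suite, never as the computation.

Interface area is defined as half the ΔSASA of association,
(SASA(A) + SASA(B) − SASA(A∪B)) / 2, the standard buried-surface convention.
Whether the >200 Å² physical-interaction threshold refers to halved or total
buried area is ambiguous in the field; the threshold is therefore a
configuration value (`interface_threshold`, default 200 Å² under the halved
convention), and every downstream comparison depends only on area ordering,
which the convention does not affect. Matrix entries are computed in
two-chain context, making them independent of the rest of the complex.
Hydrogens are ignored; van der Waals radii follow the Bondi set (C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80 Å; default 1.70 Å). Bead fixtures, whose
"atoms" are not chemical elements, supply their radius through an explicit
element→radius override rather than abusing B-factor columns.

## Structure handling

PDB and mmCIF files are read with gemmi; only the first model is used (the
intended inputs are X-ray/EM structures), and non-polymer content (waters,
ligands, ions) is excluded. Chains are grouped into entities (distinct
subunit species) by single-linkage clustering at ≥0.95 global sequence
identity — a self-contained substitute for mapping chains to reference
sequence databases; the threshold is configurable. Sequence identity is
matches / alignment columns of a global alignment with match +1, mismatch 0,
gap −1 (no aligner is canonical for this task; the scoring is pinned and an
exhaustive-alignment oracle checks it on short sequences). Inclusion filters:
chains shorter than 30 residues (inclusive bound) are removed first, then
complexes with more than 24 chains or fewer than two entities are dropped,
with enumerated reasons.

## Operon mapping

Operon tables are DOOR-style TSVs. Genes are ordered in expression (5′→3′)
order: ascending genomic start on the + strand, descending on −, positions
1..n. Duplicated genes take the position of their first copy read 5′→3′.
Distance is the positional index difference (1 = adjacent); intervening genes
count whether or not they encode subunits of the same complex, since the
distance axis of the analysis counts genes, not base pairs. Identical ordered
gene lists are collapsed to the lexicographically smallest operon id
(idempotent); a gene appearing in several operons resolves to the first
operon by id with a warning. Pair-level redundancy removal is greedy in input
order and requires *both* members to exceed the identity threshold (default
0.50) against a retained pair, in either member correspondence.

## Statistics

* Fisher's exact test (two-sided): sum of hypergeometric probabilities of
  tables at the observed margins with probability ≤ the observed table's —
  the convention matters because two-sided Fisher definitions vary; it is
  validated against full enumeration for all tables with total ≤ 12.
* Binomial test (two-sided): ≤-likelihood convention; at p₀ = 0.5 this is
  2·min(P(X≤k), P(X≥k)) capped at 1; validated against 2ⁿ sequence
  enumeration for n ≤ 10.
* Wilcoxon rank-sum: midrank ties; exact enumeration up to n = 25 per group
  without ties, otherwise normal approximation with continuity and tie
  correction. Identical pooled samples return p = 1.
* Spearman's ρ: Pearson correlation of midranks; undefined (error) for
  constant ranks.
* Group-shuffle correlation test: observed ρ₁ − ρ₂; null reassigns the
  pooled (x, y) pairs to groups of the original sizes; two-sided,
  p = (#{|null| ≥ |obs|} + 1)/(n + 1). The add-one estimator avoids p = 0,
  matching how a permutation p-value at finite shuffles should be reported.
* Wilson score intervals use the exact central-mass quantile (68% → z ≈
  0.9945, not 1); boundaries at k = 0 and k = n are exact.
* Gene-order randomization null: observed statistic is the mean positional
  distance of physically interacting co-operonic pairs; the null permutes
  gene order uniformly within each operon (pairs in one operon share the
  permutation), one-sided toward small distances, add-one corrected. The
  mean-distance statistic is this package's choice of closeness summary.
* Predictor comparison: gene order predicts the upstream subunit first;
  abundance order predicts the more abundant subunit first (ties never
  match). The two are compared by an exact binomial test restricted to
  records where exactly one predictor is right (McNemar-style).

The concordance binomial test runs where the analysis design calls for it:
conserved-order, order-resolved (non-simultaneous), adjacent pairs.

## Synthetic data

Bead complexes place one sphere per chain (optionally small bead clusters
for reader tests) by embedding the planned-contact tree with deterministic
direction search; unplanned pairs keep a clearance of 2(r + probe) plus a
margin, and infeasible plans (e.g. contact cycles a tree embedding cannot
realize) raise with the offending chains named. Ground-truth pair areas come
from the two-sphere spherical-cap formula, giving closed-form oracles for
the numerical geometry; realism (protein shape, sequence) is deliberately
absent.

Cohorts emulate the statistical structure of the real dataset: the default
marginals are the study's frequencies (368/1079 co-operonic, 220/368
adjacent, interaction 208/220 adjacent and 77/148 non-adjacent, 101/220
order-resolved, 72/101 conserved, concordance 57/72 conserved and 10/29
otherwise), log-normal interface areas truncated at the interaction
threshold, and log-normal ppm abundances that are lower and more correlated
for co-operonic pairs (log-means 3.0 vs 4.0, σ 1.5, correlation 0.7 vs 0.3)
and lower again (−0.7 in log) for concordant pairs. Values the source
analysis does not pin (different-TU interaction rate 0.6, operon lengths
2 + Poisson(3.6) capped at 12, geometric non-adjacent distances) are chosen
as field-plausible and documented here. Each pair is backed by a 2- or
3-chain interface matrix whose greedy pathway *realizes* the drawn order
class (duplicated early entity homodimerizes first), so recovery tests run
the actual predictor rather than reading generator labels. What passing
these tests does not show: behaviour on real structures with irregular
interface geometry, triple contacts, mis-assigned biological assemblies, or
operon tables with annotation noise.

## Problem sizes and determinism

Tests and the acceptance script use cohorts of 72–1079 pairs, 200-replicate
recovery runs, permutation tests at 10²–10⁴ shuffles, and oracle sweeps over
all 2×2 tables with total ≤ 12, all binomial settings with n ≤ 10, and 1000
random matrices over ≤ 6 chains — sizes at which the enumeration oracles are
exact and the whole suite runs in well under a minute. All randomness flows
through explicit integer seeds (numpy `default_rng`); identical seeds give
byte-identical cohort TSVs, reports and pathway serializations.

## Known limitations

* Pairwise-additive merge gains ignore interface remodelling and steric
  occlusion in subcomplexes; the pairwise convention is validated only on
  triple-contact-free geometry.
* Chain-count "larger subcomplex" ordering has no kinetic content; no
  chaperones, co-translational assembly, or concentration effects are
  modelled.
* Entity grouping by sequence identity can split chimeric constructs or
  merge near-identical paralogs; a user-supplied entity→gene table overrides
  it in the pipeline inputs.
* Gene-order conservation and fusion status are consumed as boolean
  annotation columns; the package does not recompute them from comparative
  genomics.
* The synthetic cohort draws pairs independently; real complexes contribute
  several correlated pairs and real operons host several pairs sharing
  genes.
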