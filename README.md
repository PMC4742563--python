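# operon-assembly

Structure-based prediction of protein-complex assembly pathways, joined with
prokaryotic operon gene order to ask: **is the order of genes in an operon
optimized for the order in which the encoded subunits assemble?**

Heteromeric complexes assemble through ordered pathways that can be predicted
from structure: the pair of subunits or subcomplexes burying the largest
interface associates first. Because operon genes are translated 5′→3′ from one
polycistronic mRNA, upstream subunits appear before downstream ones; if gene
order matches assembly order, newly made subunits can find their partners
quickly. This package implements the whole analysis for structural
bioinformaticians and microbial genomics researchers: structure ingestion and
filtering, interface-area computation, greedy pathway prediction, operon
mapping, and the exact/permutation statistics that quantify the concordance.

## The model

For a complex with chains indexed by its interface matrix *M* (Mᵢⱼ = buried
surface area in Å² between chains *i* and *j*, computed as half the ΔSASA of
association with a 1.4 Å probe):

1. Start from free chains. At each step merge the two current subcomplexes
   *A*, *B* maximizing the interface gain Σ_{i∈A, j∈B} Mᵢⱼ, until one
   subcomplex remains (n − 1 binary steps).
2. For two subunit species *x*, *y*, find the first step whose merged
   subcomplex contains chains of both. The species contributed by the larger
   pre-merge subcomplex (by chain count) *assembles first*; equal sizes — the
   plain heterodimerization case — mean *simultaneous* assembly.
3. Map subunit pairs onto operons (genes ordered 5′→3′ by locus and strand,
   1-based positions, first-copy rule for duplicated genes). A pair is
   *concordant* when the upstream gene's subunit assembles first.

Concordance is tested with an exact two-sided binomial test against 0.5;
adjacency × physical interaction (interface > 200 Å²) and conservation ×
concordance with Fisher's exact test; abundance effects with Wilcoxon
rank-sum tests and a seeded group-shuffle test for the difference of Spearman
correlations; proportions carry 68% Wilson score intervals.

## Worked example

Generate a three-subunit bead complex with designed contacts, then predict
its pathway:

```sh
$ operon-assembly generate-complex --spec cspec.json --out toy.pdb
$ operon-assembly predict-assembly --structure toy.pdb --element-radius C=15.0
((A,B):246.4474716986074,C):144.34780485204146
```

A and B bury ≈246 Å² and associate first; C joins the AB subcomplex through a
≈144 Å² interface. In a complex where A's gene sits upstream of B's in their
operon, that pair would be counted as gene order *matching* assembly order
(A and B here assemble simultaneously — a heterodimerization first step).

Run the full analysis on a synthetic cohort (1079 subunit pairs, tables plus
one interface matrix per complex):

```sh
$ operon-assembly generate-cohort --seed 3 --out cohort
$ operon-assembly run --config run.yaml   # points at the cohort tables
```

`out/report.json` from that run contains, among others:

* 344 of 1079 pairs co-operonic, 202 of those (58.7%) encoded by adjacent
  genes;
* adjacent pairs physically interact in 185/202 versus 71/142 of non-adjacent
  pairs (Fisher p ≈ 2.8 × 10⁻¹⁸);
* among conserved-order, order-resolved adjacent pairs, gene order matches
  predicted assembly order in 49/64 (76.6%, binomial p ≈ 2.4 × 10⁻⁵);
* co-operonic subunits are lower in abundance (Wilcoxon) and more correlated
  in abundance (Spearman-difference shuffle test, p ≈ 0.005 at 200 shuffles).

Every count in the report can be recomputed from the emitted
`pairs_annotated.tsv`, and reruns with the same seed are byte-identical.

## Layout

* `structure_model` — PDB/mmCIF reading (gemmi), entity assignment by
  sequence identity, inclusion filters (≥30 residues, ≥2 entities, ≤24
  chains).
* `interface_calc` — deterministic Shrake–Rupley SASA and the chain-pair
  interface matrix (TSV/JSON round trip).
* `assembly` — greedy pathway prediction, pair-order classification,
  newick-like pathway serialization.
* `operon_map` — operon tables, 5′→3′ ordering, distances, pair mapping,
  redundancy filters.
* `stats_suite` — exact, rank, interval and permutation statistics.
* `synthetic_data` — bead complexes with closed-form contact areas; cohort
  generator with tunable marginals.
* `pipeline` / `cli` — orchestration and the `operon-assembly` command.
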