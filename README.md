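# planctostrat

Depth-stratified 16S rRNA amplicon analysis of marine *Planctomycetota*,
packaged as a tested, reusable pipeline. It covers the bespoke computations
of a vertical-distribution survey of this phylum in the open ocean:

- **In silico PCR** of IUPAC-degenerate primer pairs against reference
  genomes: site finding on both strands, amplicon prediction within a length
  window, and per-pair match percentages.
- **Rank-novelty delineation**: each query 16S sequence is compared against a
  type-strain database with a deterministic end-gap-free global aligner, and
  the best-hit percent identity is mapped through the Yarza thresholds
  (98.7 / 94.5 / 86.5 / 82.0 / 78.5 % identity for species / genus / family /
  order / class) to a novelty level, from *known species* to *novel class*.
- **Diversity**: observed ASVs and Shannon index (bits), Bray–Curtis
  dissimilarity BC(u, v) = Σ|uᵢ − vᵢ| / Σ(uᵢ + vᵢ), single-linkage (nearest
  point) dendrograms with Newick export, and exact hypergeometric rarefaction
  E[S_d] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)].
- **Statistics**: paired Wilcoxon signed-rank tests (exact sign-enumeration
  null up to n = 15, normal approximation beyond) and one-way PERMANOVA on
  Bray–Curtis matrices with seeded label permutations.
- **Composition**: target-phylum filtering, per-rank ASV composition tables
  (percentages to one decimal, half-away-from-zero) and per-sample relative
  abundances over whole-sample read totals.
- **Synthetic data** with known ground truth standing in for the cruise's
  sequencing data: primer-planted genomes, substitution-only identity
  ladders, and a 15-sample four-layer community whose *Planctomycetota*
  richness grows below the deep chlorophyll maximum (DCM).

## Worked example

Run the end-to-end synthetic demonstration (simulate → primers → classify →
diversity → stats → compose):

```bash
planctostrat demo --outdir run --seed 7
```

Selected outputs from this exact command:

`primer_report.tsv` — 130 planted genomes, 60 % built amplifiable, and the
in silico PCR recovers exactly that fraction:

```
pair_name        n_genomes  n_matched  pct_matched  n_with_both_sites
515YF/Y926R-jed  130        78         60.00        78
```

`novelty_calls.tsv` — identity-ladder queries at 100/96/90/84/80/75 %
planted identity come back at the planted novelty rank:

```
query_id        best_hit_id  identity  shared_rank  novelty
query_000_t100  ref          100.0000  species      known_species
query_001_t96   ref           96.0000  genus        novel_species
query_002_t90   ref           89.8148  family       novel_genus
query_003_t84   ref           84.0000  order        novel_family
query_004_t80   ref           80.1712  class        novel_order
query_005_t75   ref           74.7199  none         novel_class
```

`stats.tsv` — the four depth layers separate in Bray–Curtis space
(PERMANOVA on 15 samples, 999 permutations), and the deeper-pool community
is richer than its shallow-pool counterpart in the paired Wilcoxon test on
observed ASVs:

```
permanova_layers                 pseudo_F  3.622226
permanova_layers                 p_value   0.001
wilcoxon_observed_asvs_greater   W         0
wilcoxon_observed_asvs_greater   p_value   3.05176e-05
```

A PERMANOVA p-value of 0.001 is the smallest attainable with 999
permutations: no permuted labelling produced a pseudo-F as large as the
observed one. The single-linkage dendrogram (`dendrogram.nwk`) groups the
below-DCM and mesopelagic samples apart from the surface and DCM samples,
the survey's depth-stratification pattern.

The same stages are available individually (`planctostrat simulate`,
`primers`, `classify`, `diversity`, `stats wilcoxon`, `stats permanova`,
`compose`); see `planctostrat --help`.

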