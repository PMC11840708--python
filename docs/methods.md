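# Methods

This note documents the models, conventions and design choices behind
planctostrat, in the spirit of a methods appendix: what each stage computes,
what the synthetic data does and does not emulate, and where the design was
genuinely open.

## In silico PCR

A primer position is *compatible* with a template base when their IUPAC base
sets intersect (Y = {C,T} matches C or T; N matches anything). A primer
*site* is a template window, on either strand, with at most `max_mismatches`
incompatible positions; the default is 0 mismatches — degeneracy only — the
strictest reading of a primer "match" and what TestPrime-style tools report
at their defaults. The tolerance is exposed as a flag, and increasing it can
only add sites (tested as a monotonicity property).

An *amplicon* is a forward site and a downstream reverse-primer site on the
opposite strand whose product length (forward start to reverse end,
coordinates 0-based half-open on the plus strand) lies in the pair's length
window; products initiated on the minus strand are handled symmetrically and
hits are deduplicated by coordinates. When a pair is given only an expected
product size, the window defaults to ±30 % around it, which suppresses
spurious giant products on random sequence. No 3'-end weighting or
thermodynamic model is applied: there is no evidence the original ad-hoc
screen used one, and exact degeneracy-aware matching keeps the planted-truth
property exact. A genome counts once per pair regardless of how many
amplicons it yields; the per-pair report additionally carries the number of
genomes where both primers have a site regardless of productive pairing,
since "matches" can be read either way.

The built-in catalog holds the two pairs whose sequences the emulated survey
prints (the V4–V5 pair 515YF/Y926R-jed and the near-full-length pair
27F/1492R, expected sizes 411 and 1465 bases from the E. coli positions in
their names); other pairs are supplied via the primer TSV.

## Alignment and rank-novelty delineation

Queries are compared to type strains with a three-state affine-gap
Needleman–Wunsch with free terminal gaps (numba-compiled). Scoring defaults
are the classic DNA set: match +5, mismatch −4, gap open −10, gap extend
−0.5, where the first column of a gap run costs the open penalty. Percent
identity is 100 × matched columns / alignment columns, with terminal-gap
columns excluded and internal gap columns counted as non-matches. This
convention approximates BLAST identity on near-full-length 16S comparisons
while being self-contained and deterministic — a deliberate divergence from
the web-BLAST step it replaces. Determinism is pinned down completely: the
alignment end cell is chosen by a fixed scan order (corner, then last row
right-to-left, then last column bottom-up; strictly better scores win) and
traceback prefers diagonal, then up, then left at every tie ("high road").
The test suite holds this contract against an exhaustive path-enumeration
oracle on short sequences with linear gap costs.

One property of this identity convention worth knowing: because terminal
gaps are free and extension is cheap, the optimal alignment may trim or gap
out mismatch-dense stretches, so the aligned identity of a substitution-only
mutant sits slightly *above* its ungapped identity (measured: at most +0.27
points at 90 % identity, +0.89 at 75 %, over 50 replicates). The thresholds
sit far enough from the ladder targets that novelty-rank recovery is
unaffected (100 % of 300 cases in the acceptance run).

Best hits maximize identity with ties broken by the lexicographically
smallest subject id. Delineation maps identity through the Yarza thresholds
(species 98.7, genus 94.5, family 86.5, order 82.0, class 78.5 % — stated as
minimum similarities for rank membership, hence boundaries are inclusive) to
the deepest shared rank, whose complement is the novelty level: sharing only
a genus makes the query a novel species, sharing nothing below domain makes
it a novel class. The per-rank summary reports the count and share of
queries not classifiable at each rank ("unknown at genus level"). How the
original manual curation resolved multi-hit ties or borderline identities is
not recorded anywhere; the rules above are explicit substitutes, not
reconstructions.

The minimum sequence length for alignment defaults to 100 bases (16S
fragments below that are not meaningfully delineable) but is a keyword so
that small-sequence oracle tests remain possible.

## Diversity

Shannon diversity is reported in bits (base 2, the convention of the Python
ecology stack; the base is switchable), observed features is the count of
positive entries. Bray–Curtis is Σ|u−v|/Σ(u+v): symmetric, in [0,1], not a
metric — no triangle property is asserted anywhere. Samples with zero reads
after phylum filtering have no defined dissimilarity and are dropped from
beta diversity with a logged warning.

Single-linkage clustering merges the two clusters with minimal inter-cluster
minimum distance; merge heights are the merging distances and are
non-decreasing (a property of single linkage, tested on random matrices and
against scipy and a brute-force O(n³) agglomeration oracle). Ties are broken
by the lexicographically smallest pair of cluster representative ids (each
cluster represented by its smallest member id), making topologies
platform-independent. Dendrograms serialize to ultrametric Newick: each leaf
at height 0, each internal node at its merge height, so root-to-leaf path
lengths equal merge heights.

Rarefaction is analytic — the hypergeometric expectation of richness at each
depth, computed with log-gamma to avoid overflow — rather than Monte Carlo,
so curves are deterministic; a seeded resampling mode exists and is used as
a parity check in the tests. Alpha diversity is computed on unrarefied
counts, with rarefaction reported separately; whether the emulated survey
rarefied first is unstated, and unrarefied-plus-curves is the more
conservative default.

## Statistics

The paired Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
and uses W = min(W⁺, W⁻) two-sided or W = W⁻ for the one-sided "greater"
alternative. Up to 15 effective pairs the p-value is exact, by enumerating
all 2ⁿ sign assignments; beyond that a tie-corrected normal approximation
with continuity correction is used. The emulated study design (15 samples)
sits exactly at the switch, so at n = 15 both p-values are reported, with
the exact one authoritative. No multiple-testing correction is applied
across the platform-comparison tests, matching the original analysis.

PERMANOVA uses squared distances: SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within from
within-group pairs scaled by group size, pseudo-F = (SS_between/(a−1)) /
(SS_within/(N−a)). Labels are permuted freely (one-way, unstratified);
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations), so p is never 0 and its
floor is 1/(n_permutations+1). An exhaustive mode enumerates every distinct
label arrangement for small designs and is used to assert relabelling and
sample-order invariance. Calibration is checked empirically: on 500
exchangeable null communities the rejection rate at α = 0.05 stays within
[0.03, 0.07].

## Composition

Composition tables count ASVs (not reads). At class level and below the
denominator is the number of target-phylum ASVs; the phylum row is out of
all ASVs — the convention recovered from the printed table's arithmetic
(78/251 = 31.1 %; 251/6379 = 3.9 %). Percentages are printed to one decimal,
rounded half away from zero, which reproduces every printed cell except the
short-read phylum row (printed 4.8 %/95.2 % where 154/3252 = 4.7 %/95.3 %;
the original denominator for that cell is unclear, and it is deliberately
not reproduced). "Unknown" is a reserved label: an ASV unknown at rank r is
pooled under it at every rank ≥ r, and a real taxon named "Unknown" is
rejected at ingest. Relative abundance divides reads assigned to each
target-phylum taxon by the sample's total reads (unfiltered table) × 100, so
the per-sample sum over target taxa equals the phylum's total relative
abundance; a minimal stacked-bar rendering is provided without styling.

## Synthetic data

The community generator encodes the emulated study design: 15 samples in
four depth layers (4 surface at 5 m, 4 DCM at 108–130 m, 3 below-DCM at
175–200 m, 4 mesopelagic at 500 m). Target-phylum ASV pools are nested
prefixes of a global list and grow with depth (defaults 10/10/40/40), so
deeper layers contain every shallow ASV plus extras; the layer effect is
thus a richness effect, matching the survey's observed-features framing, not
a mean-abundance shift. Target ASVs cycle through the four observed classes
(Planctomycetia, Phycisphaerae, 'Candidatus Brocadiia', OM190) with
genus/species left unknown — as in the survey, where essentially no ASV was
classifiable at genus level. A shared background pool (default 200 ASVs
across eight other phyla) dilutes the target phylum. Per sample, relative
abundances over the layer pool plus background are i.i.d. log-normal
(σ = 1.0, a typical microbial-community dispersion) and counts are
multinomial at 20 000 reads per sample, the order of the survey's long-read
per-sample depth; row sums are exactly the read depth. The survey reports no
effect sizes for the layer differences, so the pool sizes above are
documented stand-ins, exposed in the config. Everything is a pure function
of the config including its seed; exports are byte-identical across calls.

What the generator does *not* emulate: read-level errors, chimeras,
denoising behaviour, compositional correlations between taxa, or
overdispersion beyond the log-normal. Passing tests therefore demonstrate
correctness of the computations under a clean abundance model, not
robustness to sequencing artefacts.

Planted genomes are i.i.d. uniform ACGT with a realized forward site and,
at the configured insert length, the reverse complement of a realized
reverse site; degenerate positions are filled with uniformly chosen
compatible bases. Exactly round(n × fraction) genomes are amplifiable.
Non-amplifiable genomes follow the mismatch mode: `missing_site` omits the
reverse site, `broken_site` corrupts three of its positions with
incompatible bases, `degenerate_compatible` corrupts three degenerate
positions specifically (falling back to arbitrary positions when the primer
has fewer than three). Identity ladders are substitution-only (no indels),
so the realized ungapped identity is exact to within 0.05 points of the
target for references ≥ 1000 bases; aligner robustness to indels is a
separate concern tested with slice/overlap fixtures.

## Pipeline and reproducibility

The demo pipeline runs simulate → primers → classify → diversity → stats →
compose on synthetic data and writes a manifest of sha256 hashes; identical
configurations give identical manifests. Stage seeds are derived as
sha256(global_seed:stage_name) truncated below 2³¹, so adding a stage never
shifts existing random streams. The platform contrast in the stats stage
pairs the main community with a second one whose pools are scaled to 75 %,
emulating a platform that recovers less of the target diversity. Problem
sizes throughout (130 genomes, 300 ladder queries, 500 calibration nulls,
20 stratification seeds, 99–999 permutations) were chosen as the package's
own test conditions: large enough for stable rates, small enough to run on
a laptop in well under a minute per stage.

## Known limitations

- The aligner is global (end-gap-free); it does not reproduce BLAST's local
  HSP semantics, e-values, or word seeding, and identity can sit slightly
  above the ungapped value (see above).
- The in silico PCR has no thermodynamics; primer "matching" is purely
  combinatorial.
- PERMANOVA is one-way and unstratified; no dispersion (PERMDISP) test is
  provided, so a significant result can reflect location or spread.
- The published genome-screen match rates (59.69 %/57.36 %) depend on a
  curated 130-genome set that was never published; the package demonstrates
  the computation on planted genomes with known truth instead.
- Published per-sample alpha values are likewise unavailable, so the printed
  Wilcoxon p-values cannot be recomputed; the implementation is validated
  against full sign-enumeration and scipy instead.
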