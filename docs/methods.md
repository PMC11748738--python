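# Methods

This note documents the models, parameter choices and numerical conventions
behind `strepclades`, and what the synthetic cohort does and does not
establish about real data.

## Clade assignment from pairwise ANI

Genomes are clustered agglomeratively with **average linkage** on the
distance d = 1 − ANI/100 and the tree is cut at d = 0.05, i.e. the
conventional ≥95% ANI species boundary (`threshold_ani` is exposed; raising
it can only refine the partition, never merge clusters). Average linkage is
the natural choice for ANI dendrograms produced by genome-dereplication
workflows; the threshold is the community-standard species delimitation.
Determinism: genomes are processed in lexicographic id order, so equal-height
merges always resolve the same way and input order never changes a label.

Clade labels propagate from named reference species to every genome in the
same species cluster. A cluster containing references from two different
clades is a hard error by default (silent mislabeling would corrupt every
downstream proportion); `on_conflict="majority"` downgrades it to a majority
vote with a warning.

Unnamed clusters are classified by dendrogram position. We first find the
smallest subtree spanning **all** named genomes. Clusters inside that
subtree sit among the named clades and become **Other**; clusters outside it
are basal to every named clade and become **Unknown**. For a single
unplaced outgroup this is identical to asking whether the cluster's lowest
common ancestor with the named genomes is the tree root; the spanning-subtree
form is preferred because several independent basal outgroups chain onto the
tree one at a time under average linkage, so only the last of them joins at
the literal root, while all of them lie outside the named span.

## Abundance layers and dominance

All proportions are computed on **species-level read assignments only**;
genus-level reads that were never resolved to a species enter no numerator
or denominator. Per sample:

1. clade share of genus = clade reads / focal-genus reads;
2. genus share = focal-genus reads / all species-level reads;
3. clade share of species = clade reads / all species-level reads,

so layer 3 summed over clades equals layer 2, and layer 1 sums to 1 whenever
the sample has any focal reads. All three are invariant to per-sample read
depth. Samples with no species-level reads are NA throughout and receive
dominance "none".

The dominant clade is the **plurality** (argmax) of layer 1 — no numeric
cutoff, since bimodal cohorts make any threshold arbitrary. Ties break by a
fixed precedence (Sanguinis, Mitis, Anginosus, Salivarius, Mutans, Bovis,
Pyogenic, Downei, Other, Unknown) so calls are reproducible. The heatmap
transform is log10(x + 1) applied to **percent** values (0 → 0, 99 → 2).
Per-clade top-species tallies are restricted, by default, to samples where
that clade is dominant; the unrestricted mode is exposed because cohort
reports can be read either way.

## Compositional statistics

Read counts are compositional, so all association measures run on the
centred log-ratio transform y_i = ln((x_i + pc)/g(x + pc)) with a default
pseudocount of 1 read (exposed; pc = 0 is allowed on strictly positive
data). On CLR columns we compute Pearson correlation (two-sided t-test
p-value; BH correction in all-pairs mode) and the proportionality
coefficient ρ = 1 − var(y_i − y_j)/(var(y_i)+var(y_j)), algebraically equal
to 2·cov/(var+var); the implementation uses the covariance form and the
tests verify both forms agree to 1e-12.

The FDR cutoff for |ρ| uses a permutation null built by independently
shuffling every feature column across samples (seeded), a grid of cutoffs in
steps of 0.05, and FDR(c) = mean null count of |ρ| ≥ c divided by the
observed count (floored at 1). A cutoff only counts as attained if it
retains at least one observed pair: without that condition, small null
datasets "attain" any FDR at high cutoffs where the observed count is zero
and the denominator floor takes over, which inverts the intended meaning of
the control.

CLR-PCA first drops species whose mean relative abundance across samples is
below 0.001% (spurious low-abundance hits), then column-centres the CLR
table and decomposes it by SVD. Component signs follow a fixed convention
(largest-magnitude loading positive) so scores are reproducible.

Metadata screening uses the first canonical correlation between each
variable (categoricals expanded to indicators, reference level dropped) and
the clade-share block, with a seeded permutation p-value, and flags a
variable only when cc ≥ 0.4 **and** p ≤ 0.01 — a deliberately conservative
double rule.

## Group tests

Features present in fewer than 30% of samples are removed before testing.
The two-group comparison is the two-sided Wilcoxon rank-sum test: the exact
null distribution when n₁+n₂ ≤ 12 and there are no ties, otherwise the
tie-corrected normal approximation with continuity correction. The effect
size is r = |Z|/√N from that Z. A feature is *enriched* only when the BH
q-value is below 0.05 **and** r ≥ 0.4. Both thresholds are parameters and
the rule is applied uniformly to taxa and gene tables; gene tables are first
normalised to reads per kilobase (reads/(length/1000)).

## Preservation QC

For each sample, taxa are ranked by decreasing abundance (ties broken
lexicographically; zero-abundance taxa dropped) and the curve value at rank
k is the percentage of the top-k taxa belonging to an oral-reference set. A
sample passes if the curve stays at or above a minimum percentage at every
rank from a burn-in rank on. Defaults: burn-in rank 10 (the first few ranks
are dominated by a handful of taxa and are uninformative), 50% for ancient
and 65% for modern groups — per-group thresholds are configuration, not
constants, since preservation baselines differ by sample type. This is the
simple-threshold variant of cumulative-decay QC; it reproduces the
filtering role of the full published rule set, not its exact cutoffs.

## The synthetic cohort generator

The generator emits what the analysis consumes — an mpa-style species table
with genus aggregate rows, metadata, and block-structured ANI matrices —
from a hierarchical model per sample: dominance state → genus share → clade
composition → within-clade species split → background-genus composition →
optional contaminant admixture → log-normal depth → one multinomial draw.
Identical seeds give bit-identical cohorts, and every group uses its own
seed stream, so a group generated alone equals the same group inside the
full cohort.

Default group conditions (sizes, means ± SDs) are the study conditions the
analyses assume:

* **ancient_calculus**, n = 483: a stratified two-component mixture —
  round(0.147·n) = 71 samples are Anginosus-dominant with suppressed
  Sanguinis and a reduced genus share (2% ± 1.5% vs 5% ± 3%). Stratification
  (rather than a binomial draw) makes the cohort composition itself the
  configured 14.7%. Clade Dirichlet concentration 30; base profiles chosen
  so the mixture yields a mean Mitis share of 13% and a CLR-scale
  Sanguinis–Anginosus correlation near −0.67 under both association
  measures. Within Sanguinis, *S. sinensis* carries the largest weight
  (0.55) and within Anginosus *S. constellatus* (0.62), so those species
  top their clades in dominance-restricted tallies.
* **plaque_industrial** (n = 152, genus 7% ± 6%, Mitis base 43%) vs
  **plaque_nonindustrial** (n = 68, genus 4% ± 3%, Mitis 27%): the Sanguinis
  clade is *S. sanguinis*-led in the industrial group (with *S. sinensis* at
  0.43% of the genus) and *S. sinensis*-led in the non-industrial group
  (11% of the genus) — the VANISH-taxon contrast.
* **buccal_industrial** (n = 28, genus 39% ± 19%) vs
  **buccal_nonindustrial** (n = 28, genus 16% ± 8%), both Mitis-heavy.
* **saliva** groups 14% ± 3% / 19% ± 7%; **modern_calculus** n = 18;
  **vervet_swab** 59% ± 20%; **chimp_calculus** 0.33% ± 0.23%;
  baboon (human-like clade profile) and gorilla round out the non-human
  primates, which otherwise draw from a distinct clade profile dominated by
  Other/Unknown.

Genus shares are **range-bounded logit-normals**: a logit-normal scaled to
[lo, hi] with (μ, σ) moment-matched numerically (Gauss–Hermite quadrature
inside a least-squares solve) to the target mean and SD. The bounds default
to [0, 1]; for the buccal groups they are [0.25, 1] (industrial) and
[0, 0.29] (non-industrial). Rationale: a two-parameter family is pinned down
by mean and SD, but the buccal contrast is characterised by three facts —
both moments *and* a rank separation (Wilcoxon effect size ≈ 0.76), and an
unbounded logit-normal at those moments overlaps too much (expected
r ≈ 0.66). The bounds encode the observation that the two groups occupy
characteristic, barely overlapping ranges; with them the expected effect
size across seeds is 0.76 (SD ≈ 0.055 at n = 28 + 28).

Sequencing depth is log-normal with median 1e5 species-assigned reads
(σ = 0.5, floor 1000) — desk scale, large enough that multinomial noise is
negligible next to the compositional draws. Contamination is off by default
(the calibrated cohort represents the post-QC dataset); QC tests and the
QC driver switch it on per group, replacing 60–90% of a flagged sample's
reads with a 12-taxon soil profile.

Planted ANI matrices draw within-species pairs from U(96.5, 99.9),
within-clade between-species from U(85, 94), between-clade from U(75, 84)
and basal genomes from U(70, 74) against everything; the four ranges must be
disjoint or generation refuses. At these separations the 95% cut recovers
the planted species partition exactly and label propagation recovers every
planted clade, including Unknown for the basal genomes.

**What the generator does not emulate:** taxonomic misassignment noise,
database incompleteness, ancient-DNA damage or fragment-length effects,
within-species strain structure, covariance between genus share and clade
composition beyond the dominance mixture, and real metadata confounding.
Passing calibration here shows the pipeline measures what the generator
planted at realistic sizes and noise levels — it does not validate the
biological claims on real cohorts.

## Orchestration and determinism

`run_all` executes the stages in a fixed order with one master seed;
per-stage seeds derive from it by mixing a CRC32 of the stage name into a
`SeedSequence` (all seeds < 2³¹). Logging goes to stderr, results to files.
Long-format outputs are written with sorted row order and 17-significant-
digit floats, and matrix readers parse floats in round-trip mode, so reruns
with the same configuration and seed are byte-identical and write→read is
the identity (counts exact, floats to 1e-12). The run manifest records the
configuration hash, seeds, per-stage outputs and record counts.

Problem sizes used in the test suite and the calibration report (n = 483
ancient samples, 20-seed group means, 500-replicate type-I checks, ANI
matrices of a few dozen genomes) were chosen as the smallest sizes at which
the calibrated quantities are measured with useful precision; everything is
regenerated programmatically at run time.

## Known limitations

* The Other/Unknown rule depends on the dendrogram topology; with very
  noisy ANI matrices near-threshold clusters can flip between the two
  labels. The partition itself is stable under permutation and threshold
  monotone.
* The permutation FDR cutoff assumes exchangeable samples; group structure
  in the data makes it conservative or anticonservative depending on the
  direction of the structure.
* The exact Wilcoxon path requires tie-free data; with ties at small n the
  normal approximation is used, which is slightly conservative there.
* `cancor_pairs` reports only the first canonical correlation, which is the
  screening statistic of interest but not a full association decomposition.
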