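# Methods

This note documents the statistical procedure `mlgkit` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Problem setting

A clonal germplasm collection holds accessions that are supposed to be
distinct genotypes but, after decades of propagation and acquisition,
contains copies of the same clone under different accession numbers.
Given genome-wide marker data for every accession, the task is to
partition accessions into *multilocus genotypes* (MLGs): groups whose
pairwise genetic distances are small enough to be explained by
measurement error rather than genuine genetic difference. Everything
hinges on one number — the distinctness threshold — and the package's
central idea is that this threshold can be *calibrated empirically* from
technical and biological replicates, which are known a priori to be the
same genotype.

## Distances

Two marker chemistries, two distances, both in [0, 1]:

* **IBS distance** (codominant SNP dosages 0/1/2): at locus *l* with
  dosages `g_a, g_b`, the number of shared alleles is `2 − |g_a − g_b|`;
  the distance is `1 − Σ_l (2 − |g_a − g_b|) / (2·L)` over the `L` loci
  called in both samples. It is invariant to allele labelling
  (`g → 2 − g`), so no reference/alternate resolution is needed.
* **Jaccard distance** (dominant presence/absence): with `a` joint
  presences and `b`, `c` one-sided presences over co-called loci,
  `(b + c)/(a + b + c)`. Joint absences are excluded by definition — an
  absent restriction-fragment tag in both samples carries no evidence of
  similarity for a dominant marker.

Missing data are handled pairwise-complete. A pair with *no* usable loci
gets a flagged sentinel (1.0 for IBS, 0.0 for Jaccard) instead of an
exception, so a single catastrophic sample cannot abort a collection-
scale run; flagged pairs are excluded from merging and reported.

## Quality control

**Markers** pass an *ordered* cascade of inclusive threshold filters.
Defaults for SNPs: maf ≥ 0.001, call rate ≥ 0.8, mean sequence-tag count
≥ 12, its coefficient of variation ≤ 0.6, technical-replicate
reproducibility ≥ 0.98, and mapped-to-reference = true. For dominant
markers: call rate ≥ 0.95, one-ratio ≥ 0.05, mean read depth ≥ 12, CV
≤ 0.7, reproducibility ≥ 0.98. The final survivor set equals the
intersection of single-filter survivor sets; the order matters only for
the per-stage bookkeeping (F0, F1, …) that shows which filter does the
work. Matrix-derived statistics (maf, call rate, one-ratio) are
recomputed whenever the sample set changes; depth and reproducibility
statistics are fixed metadata.

**Samples** are screened by keep-interval rules, strict on both sides:
total tag count > 1.5M, unique tag count > 230k, SNP call rate > 0.73,
observed heterozygosity Ho in (0.05, 0.16), dominant one-ratio > 0.2.
Low values of any of these indicate degraded or under-sequenced DNA;
*high* Ho or one-ratio indicates unintended mixing of two DNA samples,
which inflates heterozygous calls. A sample failing ≥ 1 rule (count
configurable) is excluded. The library-quality category (good /
downshifted / weak) is reported but never auto-excludes.

A deliberate gap: no default rule on the individual dominant-marker call
rate. The keep-direction published for that statistic is internally
inconsistent with the cohort it describes (a keep-rule > 0.996 against a
cohort mean of 0.97 would discard nearly every sample), so the rule
ships disabled and must be configured explicitly.

## Threshold calibration

Replicates come in three classes with increasing error exposure: DNA
replicates (same DNA assayed twice — sequencing/calling error only),
extraction replicates (adds DNA-extraction variation), and individual
replicates (distinct plants of one accession — adds any biological or
tracking divergence). All within-group pairs are enumerated (a trio
yields 3 pairs) and their distance statistics reported per class.

The proposed threshold is the smallest multiple of the grid step
(default 0.005) *strictly greater* than the pooled maximum replicate-pair
distance. This grid-round-up rule is an inference from how such
thresholds are chosen in practice (a pooled maximum of 0.0576 yields
0.06; 0.0127 yields 0.015); it is deliberately simple, and the result
object always carries the per-class statistics so a curator can
override. `validate_replicate_collapse` then checks, accession by
accession, that all replicate samples landed in one MLG, reporting any
split (e.g. "1+6") — the signature of a bad sample — separately from
cross-accession merges, which are genuine redundancy candidates.

The rule uses the *maximum*, not the mean: the threshold must clear every
replicate pair or the validation fails by construction. Alternatives
(mixture models, FDR-style calibration) are out of scope.

## MLG collapsing

Agglomerative merging: repeatedly merge the pair of clusters with the
smallest linkage distance while that distance is strictly below the
threshold. Equality does not merge — so byte-identical samples (distance
exactly 0) do not merge at threshold 0 but merge at any positive
threshold. Linkage options:

* **nearest** (default): cluster distance = minimum cross-pair distance;
  equivalent to connected components of the graph with edges `d < t`.
* **farthest**: maximum cross-pair distance; equivalent to cutting a
  complete-linkage dendrogram at the threshold height.
* **average**: cross-pair mean (size-weighted Lance–Williams update).

The default is nearest-neighbour chaining, and the choice is recorded on
every partition and report. Rationale: in real collections, large
redundancy groups (dozens of accessions) routinely contain accession
pairs whose distance *exceeds* the threshold — their published
within-MLG distance dispersions reach above the cut line — which is
impossible under farthest linkage (every within-cluster pair is below
the cut height by construction) and is exactly the behaviour of
chaining. Farthest linkage is the conservative alternative for users who
want every reported pair below the threshold, and is what the
complete-linkage validation dendrograms display; on tight, well-measured
groups (such as replicate validation sets) the two coincide.

Determinism: tied merges resolve by the lexicographically smallest
member sample ids, and each MLG is named after its smallest member, so
outputs are stable across runs and platforms.

Summaries report #MLGs, #units, #redundant = units − MLGs, percent
distinct/redundant (half-up, 2 decimals, both from the same unrounded
ratio) and the size distribution (C1, C2, …). Regional summaries bin MLG
sizes into C1 / C2 / C3–C5 / C6+ with 1-decimal percentages; the
denominator is the category sum unless an external total is supplied
(accepted with a warning when the two disagree, since published totals
sometimes do).

## Concordance and descriptor review

Two partitions (e.g. SNP-based vs dominant-marker-based) are compared on
their common accessions: each accession is single (its own MLG) or multi
(inside a redundancy group); the report counts the Venn cells, the two
mismatch directions, and both-multi accessions whose MLG sizes differ
(exact sizes, not categories — configurable). Total discrepancy =
mismatches + differing-size both-multi.

Descriptor review scores passport and historical characterization
variables (biological status, country, common names, collection date,
and five morphological descriptors) within selected MLGs: a variable
"scores one" for a case when exactly one class is present among
accessions with data; `ND` (no data) never counts as a class, and common
names are compared as sets of individual names. Per-variable counts
across cases exclude cases where only one accession had data (a single
record cannot show agreement); per-case counts across the nine variables
include them by default, matching how such tables are usually tallied —
both rules are configurable, and no claim is made that either variant
reproduces every cell of historically tallied tables, whose printed
counts are internally inconsistent under any single rule.

## Trees

`hierarchical_cluster` wraps scipy's agglomerative clustering: complete
linkage for threshold validation, ward.D2 (Lance–Williams on squared
distances, heights reported on the distance scale) for structure
display. Samples are clustered in lexicographic order so ties resolve
toward the smallest label. Newick output is ultrametric: leaves at
height 0, branch length = parent merge height − child merge height,
labels quoted when they contain reserved characters. Cutting the
complete-linkage tree strictly below a height reproduces
farthest-linkage collapsing at that threshold (asserted in tests).

## The synthetic generator

`simulate_collection` emulates the data a genotyping campaign produces
for a clonal collection. Defaults (the study conditions used throughout
the tests; all configurable):

| parameter | default | meaning |
|---|---|---|
| n_genotypes | 40 | distinct founder genotypes |
| clones_per_genotype | 2–4 | accessions per founder (true redundancy) |
| n_snp_markers / n_silico_markers | 2000 / 2000 | marker counts |
| allele_freq_law | U(0.01, 0.3) | founder SNP allele frequencies |
| founder_inbreeding | 0.5 | probability a founder's two allele copies are identical by descent |
| presence_freq_law | U(0.02, 0.5) | dominant-marker presence frequencies |
| err_dna / err_extract / err_ind | 0.001 / 0.002 / 0.0025 | per-allele miscall by replicate class |
| missing_rate | 0.02 | per-cell missingness (5% of markers at 0.25) |
| depth_law | lognormal(2.5, 0.5) | per-marker depth statistics |
| replicate groups | 10 DNA pairs, 9 extraction pairs, 7 individual trios | scaled-down replicate hierarchy, one group per founder |
| n_lowq_samples | 3 | injected failures (low depth, contaminated, predigested) |

Design notes:

* **Miscall model.** A miscall flips one allele copy with probability ε:
  SNP dosages move ±1 within bounds (heterozygotes read as homozygotes
  and vice versa); dominant scores bit-flip. Ordinary collection samples
  behave like individual replicates (err_ind). Error-rate defaults are
  set so post-filter DNA-replicate distances average ≈ 0.002, with the
  class ordering err_dna ≤ err_extract ≤ err_ind enforced by a warning.
* **Depth-dependent error.** Per-marker miscall is multiplied by
  clip(12/depth, 0.5, 2): markers below the depth-12 filter line carry
  up to twice the nominal error, and their reproducibility statistic is
  correspondingly depressed. This is what makes the marker cascade
  *measurably* shrink replicate distances rather than merely discard
  markers.
* **Inbreeding and contamination.** Founders are drawn with inbreeding
  coefficient F = 0.5 (clonal landraces carry correlated allele copies,
  below Hardy–Weinberg heterozygosity). This matters for the
  contamination failure mode: a contaminated cell reads one allele from
  each of two mixed founders — a Hardy–Weinberg draw — so contamination
  raises Ho above the (1 − F)-deflated baseline. With F = 0 a mixture
  would be statistically indistinguishable from a clean individual in
  Ho, and the Ho screen would have nothing to detect.
* **Failure modes.** Low-depth samples get tag counts below the QC
  thresholds, 4× error and +0.30 missingness; predigested samples are
  downshifted libraries with the same error/missingness penalty;
  contaminated samples mix two founders cellwise with weight 0.5.
  Injected failures are drawn from ordinary (non-replicate) samples and
  recorded in the ground truth.
* **Descriptors** are generated per founder and copied to its
  accessions, with configurable historical-record error (5%) and
  missing-data (30%) rates.

Everything derives from one `numpy` Generator seeded by `SimConfig.seed`;
identical configurations produce byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: linkage disequilibrium between markers
(markers are independent); population structure among founders (founders
are exchangeable draws); continuous per-sample quality variation (sample
quality is discrete: clean vs injected failure modes, whereas real
replicate-distance distributions are strongly overdispersed by
continuously varying DNA quality); allele-calling artefacts upstream of
the genotype matrix; and tracking errors that place a sample under the
wrong accession (supported in the truth schema, rate zero by default).

## Problem sizes and numerical choices

The test suite and the acceptance script run at simulation sizes chosen
for seconds-scale feedback: 2,000 markers and ~150 samples per
collection, 40 seeds for the recovery study, 20 seeds for replicate-
structure properties, 200 random instances for the linkage-oracle
equivalences. Distance computations are exact integer-count ratios in
double precision (vectorized via dosage-indicator cross-products,
verified against naive per-pair loops to 1e-12); symmetry is enforced to
1e-12; grid round-up uses an epsilon of 1e-9 grid units so a maximum
sitting numerically on a grid line still proposes the next multiple;
percentages round half-up at the stated decimals. Degenerate inputs
(zero called samples for a marker, zero co-called loci for a pair,
single-member replicate groups, empty partitions) are flagged or
rejected explicitly rather than propagating NaNs.

## Known limitations

* The grid-round-up threshold rule is one consistent reading of
  empirical practice; with few replicate pairs the pooled maximum is a
  noisy estimator, and the margin it leaves shrinks with marker count.
  The per-class statistics are always reported so the proposal can be
  overridden.
* Nearest-neighbour chaining can in principle connect genuinely distinct
  genotypes through intermediate samples; at the calibrated thresholds
  and realistic founder separations this does not occur in the tested
  regimes, but users screening collections with continuous genetic
  gradients (e.g. self-compatible crops with pedigree structure) should
  compare linkages.
* No imputation, LD pruning, kinship weighting or population-structure
  modelling: the package screens for redundancy, it does not analyse
  diversity.
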