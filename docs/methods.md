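# Methods

This note documents the statistical procedures implemented in `lungnet`,
the model behind the synthetic-data generator, the defaults and why they
were chosen, and the numerical conventions that make runs reproducible.

## Pipeline

The analysis path from an OTU count table to results is fixed:

1. contamination screen → 2. depth filter → 3. rarefaction →
4. genus aggregation → 5. rare-genus filter → 6. transforms →
7. diversity / ordination / tests / network.

The order is enforced through table state: genus tables carry a declared
transform (`counts`, `relative`, `hellinger`) and each operation checks the
state it requires, so calling stages out of order raises an error rather
than silently producing a wrong answer.

### Contamination screen

Reagent contaminants in low-biomass samples make up a share of reads that
shrinks as the amount of real template grows. The screen therefore
correlates each OTU's relative abundance with the amplicon concentration
of each of the three library amplification runs (Spearman, average ranks)
and removes all reads of any OTU with ρ < 0 and two-sided *P* < α (default
0.05) in at least one run. *P*-values use the exact permutation null for
n ≤ 10 samples (the full n! distribution, cached per n) and the Student-t
approximation otherwise; ties in either vector force the approximation.
A run whose concentration vector is constant is skipped with a warning
(ρ undefined). The screen runs at OTU level, before rarefaction, on
relative abundances; the report records ρ and *P* per run and the total
read mass removed.

### Depth control and rarefaction

Samples under `min_reads` (default 700) total reads are discarded, and all
libraries are rarefied without replacement (multivariate hypergeometric) to
`rarefy_depth` (default 722) reads. A sample cannot be rarefied to more
reads than it has, so the effective discard threshold is
`max(min_reads, rarefy_depth)`; with the defaults that is 722, and the
discrepancy between the two constants is logged. Rows that become all-zero
are retained so OTU ids stay stable.

### Genus aggregation and rare-genus filter

Counts of OTUs classified at genus level are summed per genus; OTUs without
a genus rank contribute to no genus and their total mass is logged. A genus
is then dropped when its share of the grand total read count across all
samples falls below `rare_genus_fraction` (default 10⁻⁴, i.e. 0.01 %). The
alternative reading of that rule — mean per-sample relative abundance —
is available as `mode="mean_relative"`; the total-fraction reading is the
default because it is the stricter interpretation for unevenly deep
samples.

### Transforms and season correction

Relative abundance divides each column by its sum; the Hellinger transform
is the square root of relative abundance, giving unit-norm columns so that
Euclidean-geometry methods (PCoA on Bray-Curtis, here) behave sensibly on
compositional data. Samples processed in winter and summer show a batch
shift, removed by subtracting the per-season median from whatever
per-sample scalar is being tested — a genus's transformed abundance, a
diversity index, or a principal coordinate. The correction applies to the
tested scalar, never to the distance matrix: PERMANOVA runs on uncorrected
distances.

### Diversity and ordination

Pielou's evenness is Shannon entropy (natural log) over `ln S_obs`,
defined as 0 for a single-taxon community. Chao1 is
`S_obs + F₁²/(2 F₂)` with the bias-corrected `S_obs + F₁(F₁−1)/2` branch
when no doubletons exist (Chao1 requires integer counts and rejects
anything else). Rarefaction curves average observed richness over repeated
without-replacement subsamples. PCoA is classical scaling: double-centre
the squared distances, eigendecompose, scale eigenvectors by √λ. Negative
eigenvalues (Bray-Curtis is non-Euclidean) are reported but excluded from
coordinates and from the explained-variance denominator. Eigenvector sign
is arbitrary, so each axis is flipped to make its largest-magnitude
coordinate positive — a pure reproducibility convention.

### Hypothesis tests

Two-group comparisons use the two-sided Wilcoxon-Mann-Whitney test: exact
enumeration when the combined sample size is ≤ 20 without ties, the
tie-corrected normal approximation otherwise, and *P* = 1 when all values
are identical (no evidence either way). PERMANOVA partitions squared
distances into between- and within-group sums and compares the pseudo-F to
its label-permutation distribution; the *P*-value is the add-one estimator
`(#{F_perm ≥ F_obs} + 1)/(n_perm + 1)`, which can never return zero. An
exhaustive mode enumerates all distinct label assignments for small
designs. Benjamini-Hochberg correction is applied per screening family:
all genera of one grouping form one family, and the reported PCoA-axis
tests (PC1, PC2) form another. Group tests run on Hellinger-transformed,
season-corrected abundances.

### Co-occurrence network

Relative abundances of genera present in ≥ `min_prevalence` (default 5)
samples enter pairwise Spearman correlation. Significance comes from a
compositionality-aware permutation null: in each of `n_perm` (default
1000) rounds every genus is permuted independently across samples and each
sample's composition is re-closed to sum one before ranking, so the null
carries the same closure-induced dependence as the data; the two-sided
*P* is the add-one tail of |ρ|. This follows the renormalization-permutation
idea of compositionality-corrected association testing, simplified to the
permutation tail probability (the original method's bootstrap-vs-permutation
comparison step is not reproduced). An edge requires ρ ≥ `rho_threshold`
(default 0.5) and *P* < α; the threshold applies to signed ρ by default
because the communities of interest are positively co-occurring taxa, with
an |ρ| mode available. Every candidate edge is then re-tested on
season-median-corrected abundances (correlation and permutation *P*
recomputed; the null here permutes without re-closing, because corrected
values can be negative and a composition of negative values is undefined)
and edges failing either criterion are dropped; a *P*-only robustness mode
is available. Communities are connected components of the surviving graph,
numbered by decreasing size; components smaller than
`min_community_size_report` (default 3) stay in the data but are flagged
unreported. Heatmap ordering groups genera by community and sorts within
community by degree, descending. A constant genus has undefined ρ and can
never form an edge.

## Synthetic-data generator

The generator emulates the statistical features of a small bronchial-brush
16S cohort on which the pipeline's behaviour can be verified against known
truth. On the log scale, genus abundance is

    baseline(g) + block factor(b(g), s) + group effect + season shift + noise,

closed to a composition per sample (softmax), split across a fixed number
of OTUs per genus with Dirichlet weights, augmented with contaminant OTUs,
and sampled as one multinomial per sample at a depth drawn uniformly from
`depth_range`. Columns therefore sum exactly to the drawn depth — the
closure property a rarefied real table has.

Defaults describe the study conditions: 25 samples in groups of 12 severe,
4 mild and 9 controls; 30 genera of which 22 form four blocks (6/6/5/5);
raw library sizes 900-4800 reads (the observed post-cleanup range of
722-4789 refers to libraries after contaminant removal, so raw depths sit
slightly higher); two OTUs per genus; ten contaminant OTUs; a seasonal
shift of 1.2 log units on four genera; block-level group effects of +1.2
(block 0, severe-enriched) and −1.2 (blocks 1-3, enriched in mild and
control) log units applied to severe samples.

Three modelling choices matter and deserve their rationale:

* **Centred block factors.** The four per-sample block factors are drawn
  i.i.d. Gaussian (sd `within_block_latent_sd`, default 2.0) and then
  centred across blocks within each sample, so communities trade off
  rather than jointly inflating total load. This reproduces the
  co-exclusion between disease-associated communities that co-occurrence
  heatmaps of real cohorts show, and it prevents an artifact of closure:
  un-centred factors make the compositional denominator swing with total
  block mass, which induces spurious positive correlation among all
  *other* genera strong enough to wire them into one false community.
* **A stable core.** Four "core" genera with high baseline (+3 log units)
  and ordinary noise emulate the dominant families that make up more than
  half the reads of most real lung samples. Their collective mass pins the
  compositional denominator, again limiting closure-induced correlation.
  Giving the core *lower* noise than other genera would backfire: a
  too-quiet core simply mirrors the denominator and becomes a false
  community itself.
* **Contaminant model.** Contaminant OTU intensity is
  `exp(c₀ − strength·log c_s + noise)` with per-sample amplicon
  concentration `c_s` log-normal; `c₀` places each contaminant near 0.5 %
  of reads at the median concentration, so low-concentration samples are
  heavily contaminated and occasionally drop under the rarefaction depth
  after cleanup — as happens in real low-biomass studies. One concentration
  value is drawn per sample and reused for all three library-run columns,
  since no mapping of runs to samples is modelled.

Season-affected genera are drawn from the non-block, non-core pool when
possible so the planted batch structure is disjoint from the planted
co-occurrence structure, and the ground truth (block membership,
contaminant ids, differential genera, season-affected genera) is returned
and JSON-serializable.

What the generator does **not** emulate: sequencing error, chimeras,
phylogenetic relatedness between genera, overdispersion beyond the
log-normal latent layer, or any mapping of samples to library runs.
Passing recovery tests therefore demonstrates that the pipeline's
statistics behave as designed under a faithful compositional count model —
not that any particular biological conclusion from real data is correct.

## Numerical conventions

* All randomness flows from explicit `numpy.random.Generator` objects; the
  pipeline derives named per-stage substreams from its single config seed,
  so stage re-runs are stable regardless of execution order and a fixed
  seed gives bit-identical artifacts.
* Permutation *P*-values always use the add-one estimator.
* Spearman ties take average ranks everywhere.
* Comparisons against permutation statistics use a 10⁻¹² tolerance so that
  exact ties count as "at least as extreme".
* All-zero columns stay zero under relative/Hellinger transforms instead
  of raising division errors; the all-zero count vector is rejected by the
  diversity indices.
* A relative-abundance table may have column sums below one after row
  subsetting (e.g. the prevalence filter); closure is never silently
  re-applied, matching the convention that correlations are computed on
  relative abundances taken from the full community.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate calibration and
recovery at desk scale, chosen to keep the whole suite in the
tens-of-seconds range while leaving Monte-Carlo error well inside the
asserted bands: 500 null datasets for PERMANOVA type-I error (199
permutations each), 200 replicate tables of 50 independent genera (200
permutations each) for pair-level calibration, 10-20 synthetic cohorts per
recovery property at the full default 1000 network permutations, and
exhaustive enumeration for the small-design oracles.

## Known limitations

* The edge criteria (ρ ≥ 0.5, *P* < 0.05 at n ≈ 25) admit occasional
  chance edges; isolated spurious dyads are suppressed by the ≥ 3 reporting
  rule, but a chance edge can attach a peripheral genus to a genuine
  community. This is a property of the method at small n, reproduced
  faithfully rather than patched.
* BIOM input is not supported; count tables are TSV.
* The season correction removes location shifts only; a batch effect that
  changes variance survives it, and strongly season-shifted abundant taxa
  can retain correlation after correction through the compositional
  denominator.
* Exact Spearman *P*-values are enumerated up to n = 10; the first call at
  n = 10 computes a 3.6-million-permutation null once and caches it.
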