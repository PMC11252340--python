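# Methods

This note documents the models, rules and numerical choices behind
`rejuvenome`, and what the synthetic study does and does not emulate.

## Study design and contrasts

The pipeline assumes a two-factor bulk design: age ∈ {young, old} × housing
environment ∈ {control, enriched}, giving four cells YC, YE, OC, OE with
`n_reps_per_group` biological replicates each (default 3). Six contrasts
are run per molecular layer, always with the coefficient of interest in
column 1 of the model matrix:

| contrast            | samples      | model                      |
|---------------------|--------------|----------------------------|
| `ee_young`          | young only   | ~ env                      |
| `ee_old`            | old only     | ~ env                      |
| `ee_all_adj_age`    | all          | ~ env + age                |
| `aging_ctrl`        | control only | ~ age                      |
| `aging_all_adj_env` | all          | ~ age + env                |
| `oc_vs_rest`        | all          | ~ 1(old ∧ control)         |

Signs: positive log2FC means higher in old, higher under enrichment, or
higher in old-control, respectively. `oc_vs_rest` is the rejuvenation
contrast: a feature that is restored by enrichment in the old looks like an
OC-specific excursion with YC ≈ YE ≈ OE.

## Count-layer differential testing

Counts are modelled as negative binomial, `var = mu + alpha mu^2`, with a
log link and `log(size factor)` offsets (median-of-ratios size factors over
features nonzero in every sample). The engine is deliberately transparent
rather than a re-implementation of DESeq2's internals:

* **Dispersion** — per-feature method-of-moments
  `alpha_raw = max(0, (s^2 - mu) / mu^2)` pooled across design cells with
  df weights, a mean trend `alpha(mu) = a0 + a1/mu` fitted by least squares
  on features with positive raw estimates (predictions clipped at 0), and a
  fixed 50/50 raw/trend blend floored at 1e-8. Cook's-distance filtering,
  independent filtering and LFC shrinkage are intentionally not reproduced.
* **Fitting** — IRLS batched across features, Fisher-scoring weights
  `mu/(1 + alpha mu)`, convergence at max |Δβ| < 1e-8 (≤100 iterations;
  non-converged features keep their estimate but get missing p-values and
  are excluded from BH). Linear predictors are clipped to ±30 to guard
  exp overflow; a 1e-10 ridge stabilizes the normal equations.
* **Inference** — Wald `z = beta / SE` with SE from the *observed* Fisher
  information at the estimate (`w = mu (1 + alpha y) / (1 + alpha mu)^2`),
  two-sided normal reference, BH within contrast.

The low-expression filter keeps features whose CPM exceeds
`10 / (median library size in millions)` in at least as many samples as the
smallest design cell — a concrete re-specification of the usual
`filterByExpr`-style screen, since that function's realized thresholds
depend on the data. Visual/summary transforms use `log2(count/sf + 1)`;
differential testing never uses a variance-stabilizing transform.

## Proteomics

Technical replicates are averaged on the log2 scale first. Per-protein OLS
for the contrast, then empirical-Bayes variance moderation: the prior
`(d0, s0^2)` is moment-matched on `log s^2` (digamma/trigamma inversion;
Newton on `trigamma(d0/2) = excess spread`, with `d0 = ∞` when the observed
spread of log-variances does not exceed the chi-square sampling spread),
posterior `s~^2 = (d0 s0^2 + d s^2)/(d0 + d)`, moderated t on `d0 + d` df.
Half-life normalization divides the log2 matrix row-wise by the protein
half-life, dropping missing/non-positive entries. Missing abundance values
are not supported (the generator never produces them).

## Methylation

CpG counts are consumed at the pooled-per-CpG level (one measurement per
site). Coverage filters: total ≥ 10 and total ≤ the per-sample 99.9th
percentile, where the percentile is the smallest observed coverage with
cumulative fraction ≥ 0.999 so only sites strictly above it are removed.
Beta = methylated/total. Region summaries are unweighted means of covered
CpG betas; regions with no covered CpG are flagged and excluded downstream.
No DMR segmentation or per-CpG testing is performed.

## Interval engine and domains

Coordinates are 0-based half-open everywhere (BED semantics); the overlap
predicate is ≥1 shared base, with no minimum-fraction rule. Promoters are
−1000/+100 bp around the strand-aware TSS (distal promoters 1000–3000 bp
upstream); CpG shores and shelves are the 0–2000 and 2000–4000 bp island
flanks, with island > shore > shelf precedence so the classes never
overlap; the genomic background is the blacklist-masked genome tiled into
≤200 bp bins. Region annotation uses promoter > distal promoter > gene
body > intergenic precedence and nearest-gene by TSS distance (ties break
to the lexicographically smaller gene id).

Bivalent domains are merged intersections of H3K4me3 and H3K27me3
consensus peaks (consensus = merged union across groups). Switch domains
are merged intersections of H3K27me3 aging up-DERs with H3K9me3 aging
down-DERs, reported with contributing DER ids; count and mean length refer
to the merged intersections, not DER pairs. Because the intersections are
peak-sized while the underlying H3K9me3 blocks are tens of kb, recovery
against planted blocks is scored as "blocks hit by ≥1 detected domain"
(plus a stricter 50% reciprocal-overlap count reported alongside); at real
data scale, where both DER classes are broad, the merged domains themselves
are tens of kb.

## Enrichment machinery

Empirical p-values use the +1 correction, `p = (1 + #{null ≥ obs}) /
(1 + n_perm)`, so the attainable minimum is `1/(n_perm+1)`; fold enrichment
is `obs / mean(null)` with the denominator floored at `1/n_perm` to keep an
empty null defined. Region randomization preserves each region's length
and places it uniformly over all valid start positions across background
segments (segment chosen with probability proportional to its count of
valid starts); placed regions may overlap each other. Resampling draws
equal-size subsets of a region or gene universe without replacement. All
permutation tests are one-sided for over-enrichment; depletion is out of
scope. Fisher tests report the upper hypergeometric tail and the sample
odds ratio with Haldane's 0.5 correction only when a cell is zero.
Default `n_perm` is 1000 (200 in `--fast` mode). Wilcoxon statistics use
exact enumeration for tie-free samples of ≤25 per side and the
tie-corrected normal approximation otherwise.

## Curation rules

* **Reversed**: aging padj < 0.05 and |aging log2FC| > 0.25, and in *both*
  `ee_young` and `ee_old` a log2FC of sign opposite to aging with
  magnitude > 0.25 (no p-value requirement on the EE side). The
  "opposite in both ages" reading is the primary definition; the
  all-samples EE contrast is reported but not used for curation.
* **Old-rejuvenated (genes/proteins)**: `oc_vs_rest` padj < 0.05,
  |log2FC| > 0.25, `ee_young` p ≥ 0.05, minus the reversed set. The
  magnitude threshold is read as |log2FC| > 0.25 (the "< 0.25" variant
  would contradict selecting significant changes).
* **Old-rejuvenated (regions)**: `oc_vs_rest` padj < 0.05, |`ee_old`
  log2FC| > 0.25, `ee_young` p ≥ 0.05.
* **Multi-omic consistency**: aging p < 0.05 in both RNA and protein with
  equal sign, and EE sign opposite to aging in both layers (sign-only on
  the EE side, since the rule specifies direction, not magnitude).

A structural property worth knowing: the gene-level rejuvenation rule
carries no OC-vs-OE requirement, so a feature altered by aging but
untouched by enrichment (OC ≈ OE, both shifted) still shows an OC-vs-rest
excursion of about two-thirds of its aging effect and, having a null young
EE response, satisfies the rule. Under the default generator roughly half
of the curated rejuvenation set consists of such aging-only features; its
*sensitivity* for truly OC-specific features is the meaningful recovery
metric, and is what the tests assert. The region rule does not share this
property because its magnitude test is on the OC-vs-OE change.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 4 × 10 Mb | chromosomes |
| `n_genes` / `n_peaks_per_mark` / `n_cpgs` | 2000 / 1500 / 50,000 | features per layer |
| `n_reps_per_group` | 3 | biological replicates per cell |
| `nb_dispersion` | 0.05 | NB alpha for all count layers |
| `base_mean_log2_range` | (3, 12) | log2-uniform feature means |
| `sf_sigma` | 0.15 | log-normal library size factors |
| `frac_aging_de` / `aging_lfc` | 0.15 / 1.5 | planted aging effects, signs balanced |
| `frac_reversed` / `frac_old_rejuvenated` | 0.6 / 0.2 | fractions of aging features |
| `ee_scale_young` = `ee_scale_old` | 0.8 | EE effect = 0.8 × aging effect, opposite sign (partial reversal) |
| `n_switch_domains` / `switch_block_length` | 10 / 40 kb | H3K9me3-loss blocks with 2–4 planted H3K27me3-gain peaks |
| `n_bivalent_domains` | 20 | co-located H3K4me3/H3K27me3 peaks, both losing signal |
| `global_meth` / `methyl_depth` | 0.76 / 30 | beta baseline and Poisson coverage |
| `switch_meth_frac` / `switch_meth_shift` | 0.78 / 0.05 | fraction of switch domains with an old-age beta up-shift |

Feature means are log2-uniform because no generative model for real
abundances is assumed; size-factor heterogeneity is included specifically
so the median-of-ratios estimator is exercised non-trivially. Aging-only
features shift both old groups; reversed features add an opposite-sign EE
shift in both ages; rejuvenated features shift OC only; an independent 5%
of null features receive an EE-only effect. The H3K9me3 layer carries an
equal number of decoy loss-blocks without H3K27me3 gain, and ordinary
H3K27me3/H3K9me3 peaks are placed without cross-overlap so the planted
blocks are the only K27-up/K9-down co-occurrences — false switch domains
can then arise only from false-positive DER calls. Switch domains carry a
CpG density of ~4/kb so the per-domain trend is measurable over short DER
intersections; the `1 - switch_meth_frac` complement of domains receives an
equal-magnitude *negative* shift, which makes the planted up-trend fraction
the identifiable expectation of the trend statistic (with no-shift
complements the expectation would be `frac + (1-frac)/2`). Proteins are a
600-gene high-expression subset with per-protein offsets (sd 2), Gaussian
noise (sd 0.25), two technical replicates (sd 0.1), log-normal half-lives,
and a 10% protein-specific effect fraction absent from the RNA truth.

Per-layer RNG streams are split from the master seed via stable CRC-based
keys, so adding or regenerating one layer never perturbs another, and
identical configs produce byte-identical datasets on disk.

**What is not emulated:** read-level artefacts (alignment, duplication,
peak calling), bisulfite/enzymatic conversion and strand pooling
(methylation is generated post-pooling), batch effects, missing protein
values, correlated features, isoform structure, and single-cell data.
Passing recovery tests therefore demonstrates correctness of the analysis
logic under the assumed generative model, not robustness to upstream
artefacts in real data.

## Numerical and scale choices

Default test and acceptance runs use the scale above (full pipeline ≈ 10 s
on one core); calibration studies use 500 repetitions at 200 permutations
and 2000-feature null matrices, sizes chosen so the discrete permutation
p-values have fine enough tail granularity for rejection-rate checks.
Degenerate inputs are defined errors: all-zero count matrices for size
factors, empty filtered matrices, zero residual df for moderated tests,
regions longer than every background segment, non-subset resampling
inputs, all-zero Fisher tables, undefined-strand promoters. Ties: the
methylation trend counts exact zero differences as "not increased";
nearest-gene ties break lexicographically; BH enforces monotone adjusted
p-values.

## Known limitations

* The dispersion estimator is intentionally simpler than shrinkage-based
  packages; at very small replicate numbers the Wald test runs slightly
  anticonservative (measured type-I ≈ 0.06 at 6+6 samples), within the
  calibration band asserted by the tests but worth remembering at n=2.
* Switch-domain count and mean length are merged-intersection semantics;
  per-pair counting would give different (larger) counts.
* The gene-level rejuvenation rule admits aging-only features by
  construction (see above); interpret that set's precision accordingly.
* Region randomization allows placed regions to overlap each other,
  matching the conventional default; non-overlapping placement is not
  implemented.
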