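# rejuvenome

Aging remodels the transcriptome, proteome and epigenome of brain tissue,
and lifestyle stimulation (environmental enrichment, EE) can push many of
those changes back toward a youthful state. Quantifying that reversal from
a four-group bulk multi-omic design — young/old × control/enriched
(YC/YE/OC/OE) — takes a fairly long chain of analysis steps: per-layer
differential testing, chromatin-domain definitions, permutation-based
intersection enrichment, and rule-based curation of "reversed" and
"rejuvenated" features. `rejuvenome` implements that chain as a tested,
deterministic pipeline, together with a synthetic multi-omic generator with
planted ground truth, so every step can be validated by recovery scoring
rather than by eye.

It is aimed at computational biologists who want a transparent, desk-scale
re-implementation of this class of aging-reversal analysis: every statistic
is recomputable, every rule is a pure function of the differential tables,
and every claim about the pipeline is checked against planted truth.

## What it computes

**Differential layers.** Count omics (RNA-seq, ATAC-seq, ChIP-seq on
consensus peaks) are tested with a negative-binomial GLM with log link and
library-size offsets: counts `K_is ~ NB(mu_is, alpha_i)` with
`log mu_is = log s_s + x_s' beta_i`, median-of-ratios size factors `s_s`,
method-of-moments dispersion `alpha_i` (`var = mu + alpha mu^2`) shrunk
50/50 toward a `a0 + a1/mu` trend, and two-sided Wald tests
(`z = beta_hat / SE`, SE from the observed Fisher information). Proteomics
(log2 abundances, technical replicates averaged) uses empirical-Bayes
moderated t-tests: posterior variance
`s~_i^2 = (d0 s0^2 + d_i s_i^2) / (d0 + d_i)` with the prior `(d0, s0^2)`
moment-matched on `log s^2`. Six contrasts run per layer: EE in young, old
or all samples (age-adjusted), aging in control or all samples
(environment-adjusted), and old-control vs everything else (OC vs
YC+YE+OE). BH control at FDR < 0.05 within each contrast.

**Chromatin domains.** Bivalent domains are intersections of H3K4me3 and
H3K27me3 consensus peaks. Heterochromatin-switch domains are merged
intersections of H3K27me3 aging *up*-DERs with H3K9me3 aging *down*-DERs —
regions where constitutive heterochromatin loss is met by facultative
heterochromatin gain — and the per-domain DNA-methylation trend
(old − young mean beta) is summarized as the fraction of domains gaining
methylation with age.

**Enrichment.** One-sided permutation tests (free randomization over a
masked genome, or resampling from a region/gene universe) with
`p = (1 + #{null >= obs}) / (1 + n_perm)` and fold enrichment
`obs / mean(null)`, plus one-sided Fisher exact tests; BH within each
comparison family.

**Curation.** *Reversed* features: aging FDR < 0.05, |log2FC| > 0.25, and
sign-opposite EE log2FC (> 0.25 in magnitude) in **both** age groups.
*Old-rejuvenated* features: OC-vs-rest FDR < 0.05, |log2FC| > 0.25, and no
EE evidence in the young (p ≥ 0.05); disjoint from the reversed set.
Direction labels follow the convention that "down" means rejuvenation
brings the level back down.

**Synthetic truth.** The generator plants every one of these effects — NB
counts with feature-wise dispersion, bidirectional aging effects (default
log2FC 1.5), a reversed fraction (EE effect 0.8× the aging effect, opposite
sign, both ages), an OC-only rejuvenated fraction, bivalent domains with
paired mark loss, 40 kb H3K9me3-loss blocks containing H3K27me3-gain peaks,
and a methylation up-trend in 78% of switch domains on a 76% global
methylation baseline — and writes a TruthTable so the pipeline's output can
be scored (sensitivity, precision, FDR, Jaccard).

## Worked example

```python
from rejuvenome import SimConfig, PipelineConfig, run_pipeline

config = PipelineConfig(sim=SimConfig(seed=1), n_perm=1000, seed=1,
                        out_dir="demo_out")
report = run_pipeline(config)
```

This simulates the default study (2000 genes, six histone marks × 1500
peaks, 50,000 CpGs, 3 replicates per group), runs all six contrasts per
layer, detects domains, runs the enrichment battery and curation, and
scores recovery. Printing the headline recovery numbers gives:

```
aging DEGs:    311 called, sensitivity 0.96, FDR 0.071
EE-reversed:   196 genes, Jaccard vs truth 0.91
rejuvenated:   118 genes, sensitivity 0.75
switch blocks: 10/10 recovered, 0 false domains
methylation:   global 76.11%, switch-domain up-trend 78% (planted 78%)
```

Read: of 300 planted aging genes, 96% are recalled at FDR 0.05 with an
empirical false-discovery rate of 7%; the curated reversal list matches the
planted reversed set with Jaccard 0.91; all ten planted heterochromatin-
switch blocks are found with no false domains; and the methylation up-trend
over switch domains reproduces the planted 78% fraction. The rejuvenated
list recalls 75% of planted OC-only features; its precision is limited by
design, because the OC-vs-rest rule also admits aging features that EE
never touched (see `docs/methods.md`).

The same run is available from the shell:

```sh
rejuvenome run-all --out demo_out --seed 1        # writes report.json
rejuvenome evaluate --out demo_out                # prints recovery metrics
```

`rejuvenome simulate/diff/domains/curate/enrich` expose the individual
stages; `--fast` switches permutation tests from 1000 to 200 permutations.

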