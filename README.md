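# agespec

Age-specific analysis of naive CD4 T-cell activation methylomes.

Naive CD4 (nCD4) T cells reshape their DNA methylome when activated
(anti-CD3/CD28 stimulation vs. culture in media alone), and the response
differs between developmental windows such as infancy and adolescence.
`agespec` is a library and command-line pipeline for dissecting that
difference from Illumina EPIC-style beta-value matrices of two paired,
independently assayed cohorts, and for integrating the methylation
signals with chromatin accessibility, gene expression and cytokine
output. It is aimed at epigenomics analysts who have per-cohort
beta matrices, a probe manifest, and optional ATAC peak and cytokine
tables — or who want to validate the whole analysis on simulated data
with known planted truth.

## What it computes

**Per-probe differential methylation.** Testing is on M-values,
M = log2(β/(1−β)); effect sizes on the β scale, Δβ = mean(β_activated) −
mean(β_quiescent). Each probe is fit by OLS on condition plus covariates;
residual variances are shrunk by empirical-Bayes moderation toward a
scaled-F prior (d₀, s₀²) estimated by moment-matching of log s²
(digamma/trigamma inversion):

    s²_post = (d₀·s₀² + d·s²) / (d₀ + d),   t_mod = β̂ / (se·s_post),

with p-values from a t distribution on d₀ + d degrees of freedom and
Benjamini–Hochberg adjustment. A probe is a DMP when q < 0.01 and
|Δβ| > 0.05.

**Dual-threshold age classification.** Combining the two cohorts' DMP
calls, each probe is *shared* (DMP in both, same direction), *opposing*
(DMP in both, opposite directions — reported separately, never merged
into shared), *infant-* or *adolescent-specific* (DMP in exactly one
cohort and truly unresponsive, |Δβ| < 0.02, in the other),
*indeterminate* (DMP in one, 0.02 ≤ |Δβ| < 0.05 in the other) or
*nonresponsive*.

**DMR calling.** Probes are clustered by genomic gap (≤ 1 kb by
default); each candidate of ≥ 4 probes gets an equal-weight Stouffer
statistic over signed probe z-scores, z = Σ zᵢ/√n, BH-adjusted across
candidates; a DMR requires q < 0.01 and mean |Δβ| > 0.05. Regions are
then classified with the same 5%/2% dual cutoffs.

**Multi-omic integration.** Direction concordance between DMPs and
overlapping ATAC peaks (Pearson χ², df = 1, no continuity correction);
per-donor cytokine log2 activation fold changes compared between cohorts
by Wilcoxon rank-sum; a Pearson correlation scan of DMPs within 1 Mb of
cytokine gene TSSs against activated-state cytokine output; 2³ tri-omic
pathway gene categorization; and hypergeometric gene-set enrichment with
an optional probe-count bias-aware (Wallenius) mode.

**Synthetic cohorts.** `agespec.synthetic` generates EPIC-like paired
two-cohort datasets with planted shared / age-specific / opposing
probes, DMR blocks, direction-biased accessibility peaks and
probe-coupled cytokine outputs, so every stage is verifiable by
parameter recovery. See `docs/methods.md` for the generative model.

## Worked example

```python
from agespec.synthetic import SimulationConfig, simulate_cohorts
from agespec.differential import dmp_pipeline
from agespec.classify import classify_probes, summarize_classes

cfg = SimulationConfig(seed=1)          # 20,000 probes, 18 + 15 donors
beta, sheet, manifest, truth = simulate_cohorts(cfg)

stats_inf, sum_inf = dmp_pipeline(beta, sheet, "infant", covariates=("sex",))
stats_adol, sum_adol = dmp_pipeline(beta, sheet, "adolescent", covariates=("sex",))
print("infant DMPs:", sum_inf)
print("adolescent DMPs:", sum_adol)

classes = classify_probes(stats_inf, stats_adol)
print(summarize_classes(classes).to_string(index=False))
```

prints

```
infant DMPs: {'total': 1420, 'hyper': 310, 'hypo': 1110}
adolescent DMPs: {'total': 1220, 'hyper': 450, 'hypo': 770}
              class     n  n_hyper  n_hypo
             shared  1000      260     740
    infant_specific   379       38     341
adolescent_specific   189      169      20
           opposing    20       10      10
      indeterminate    32       13      19
      nonresponsive 18380     9293    9087
```

This run plants 1,000 shared, 400 infant-specific, 200
adolescent-specific and 20 opposing probes at |Δβ| = 0.10. The DMP
totals decompose exactly into the planted responsive sets (1000 + 400 +
20 = 1420 in infants); the classifier recovers the shared and opposing
sets completely and ~95% of the cohort-specific sets, with the planted
hypomethylation asymmetry (90% of infant-specific probes lose
methylation, 90% of adolescent-specific probes gain it) visible in the
direction split.

The same analysis runs from the shell:

```
agespec simulate --outdir data --seed 1
agespec dmp --beta data/beta.tsv --sheet data/samples.csv \
        --cohort infant --covariates sex --out infant.tsv
agespec classify --stats-a infant.tsv --stats-b adolescent.tsv --out classes.tsv
agespec run --outdir run1 --seed 1        # full pipeline, summary.json
```

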