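# Methods

## Statistical model

### Scales

Methylation arrives as beta values, β = M/(M+U) ∈ [0,1]. Hypothesis
testing uses M-values, M = log2(β′/(1−β′)) with β′ = clip(β, ε, 1−ε) and
ε = 1e−6; M-values are closer to homoskedastic Gaussian across the
β range, while β-scale variance shrinks near 0 and 1. All *effect sizes
and calling thresholds* are on the β scale (Δβ = mean activated − mean
quiescent, raw β), because a 5% methylation difference is the
interpretable unit of the field. The modeling scale is a genuine choice
— β-scale fits are also common — and the package fixes M for tests,
β for effects.

### Per-probe model and moderation

Within one cohort, every probe is fit by ordinary least squares on a
design of intercept, condition (activated = 1) and covariates
(categorical covariates reference-coded against the lexicographically
first level, for determinism). Donor pairing is *not* in the default
design; `pair_by_donor=True` adds donor indicators. Both options exist
because paired and unpaired analyses of paired stimulation designs are
both defensible; the default is the plain covariate model, and the
simulator's donor random intercept makes the choice consequential and
testable (pairing roughly halves the residual variance there).

Residual variances s² with d degrees of freedom are moderated by the
standard empirical-Bayes hierarchy: s² | σ² ~ σ²·χ²_d/d and
σ² ~ s₀²·d₀/χ²_{d₀}, so marginally s² ~ s₀²·F(d, d₀). The prior is
estimated by moment-matching log s²: with
e = log s² − ψ(d/2) + log(d/2),

    trigamma(d₀/2) = Var(e) − trigamma(d/2)   →   d₀ (Newton inversion),
    s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).

The posterior variance is s²_post = (d₀ s₀² + d s²)/(d₀ + d), and
t_mod = β̂/(se·s_post) is referred to a t distribution on d₀ + d df.
Numerical choices: the trigamma inversion starts at x₀ = 0.5 + 1/y and
runs Newton steps to relative tolerance 1e−10; if the observed log
variances are *under*-dispersed relative to pure χ² sampling noise
(Var(e) ≤ trigamma(d/2)), d₀ is infinite — complete pooling — and the
prior is then the geometric mean of the observed variances, so that
with exactly equal variances s²_post = s² and the moderated t reduces
*exactly* to the ordinary t (this no-shrinkage identity is asserted in
the tests to 1e−10). An infinite d₀ is capped at 1e8 wherever it enters
arithmetic; p-values then use the large-df t, indistinguishable from
the normal.

Multiple testing is Benjamini–Hochberg step-up with enforced
monotonicity, input order preserved. A probe is a DMP when q < 0.01
and |Δβ| > 0.05 (both strict inequalities).

### Age classification

With per-cohort DMP calls the taxonomy is: shared (DMP in both, same
Δβ sign); opposing (DMP in both, opposite signs — kept out of the
shared set); cohort-specific (DMP in exactly one cohort and
|Δβ| < 0.02 in the other, the "truly unresponsive" rule);
indeterminate (DMP in one, 0.02 ≤ |Δβ| < 0.05 in the other);
nonresponsive (DMP in neither). The 2% rule is interpreted as an
absolute value — a probe moving −3% in the other cohort is not
"unresponsive" regardless of sign. The DMP overlap can be formed with
the disjunctive rule (q < α **or** |Δβ| > 5%) via `venn_mode=True` for
Venn-style reproduction; the conjunction is the default and the
documented semantics. Direction summaries use the discovery cohort's
sign (shared probes have equal signs by construction).

### DMR calling

Candidate regions are maximal runs of probes with successive genomic
gaps ≤ `maxgap` (default 1000 bp, inclusive), never crossing a
chromosome. Candidates with ≥ 4 probes are scored by equal-weight
Stouffer combination of signed probe z-scores,
zᵢ = Φ⁻¹(1 − pᵢ/2)·sign(Δβᵢ), z = Σzᵢ/√n, with a two-sided normal
region p and BH across candidates; a DMR requires q < 0.01 and mean
|Δβ| > 0.05. This deliberately replaces kernel-smoothed region
statistics with a transparent combination that honors the same
reporting gates (probe count, mean effect, region FDR); it is a method
difference, not a reimplementation, and region counts are not expected
to match kernel-based callers probe for probe. Underflowed probe
p-values are clipped to the smallest positive float with a log note.
Region spans are 1-based inclusive internally (min to max probe
position) and widen to 0-based half-open on BED export. Region classes
reuse the 5%/2% dual cutoffs: shared requires overlapping spans and the
same direction in both cohorts; cohort-specific requires mean |Δβ| of
the *same probes* < 0.02 in the other cohort.

### Integration

Probe positions are 1-based (manifest convention); peaks are 0-based
half-open; the conversion happens exactly once, at the overlap boundary:
probe p overlaps [start, end) iff start ≤ p−1 < end. A probe under
several peaks takes the nearest peak midpoint, ties to the lower start.
Direction concordance is a plain Pearson χ² on the 2×2 table
(hyper/hypo × loss/gain), df = 1, no continuity correction by default
(a Yates flag exists). Cytokine activation fold changes are per donor,
log2(activated / max(quiescent, floor)), floor defaulting to the
smallest positive observed concentration per cytokine; cohorts are
compared by two-sided Wilcoxon rank-sum, exact for combined n ≤ 20,
normal approximation with tie correction otherwise — a nonparametric
choice that is robust at n = 18/15. The correlation scan takes DMPs
within 1 Mb of a cytokine gene TSS and computes Pearson r between
activated-state β and activated-state concentration, donor-matched;
the Δβ-vs-log2FC pairing is a defensible alternative and is available
unfiltered via `keep_all`. Enrichment is a one-sided hypergeometric
upper tail; with per-gene probe counts supplied it switches to
Wallenius' noncentral hypergeometric with set odds equal to the ratio
of mean probe counts inside vs outside the set — a single-odds
approximation to probe-number bias correction (genes carrying more
probes are easier to hit by chance); equal weights reduce it exactly to
the hypergeometric.

## Synthetic data generator

The generator emulates a two-cohort paired stimulation study: 18 infant
and 15 adolescent donors, one quiescent and one activated sample each,
assayed as two separate datasets.

Generative model per probe i, donor j, condition c:

    logit(β) = logit(b₀ᵢ) + batch·1[adolescent] + covariate effects
               + uᵢⱼ + δᵢ,cohort·1[activated] + εᵢⱼc

with εᵢⱼc ~ N(0, noise_sd_logit²) independent and uᵢⱼ ~ N(0,
donor_sd_logit²) a per-(probe, donor) intercept shared by the donor's
two conditions (this is what makes pairing decisions consequential).
Baselines b₀ come from a three-component Beta mixture (low 0.10 /
intermediate 0.50 / high 0.85, weights 0.35/0.25/0.40), mimicking the
bimodal marginal of Infinium arrays; planted probes draw from the
intermediate component, clipped so b₀ ± Δβ stays inside (0,1). Effects
are planted on the logit scale, δ = logit(b₀ + Δβ) − logit(b₀), so the
noiseless β-scale difference equals the target exactly; under logit
noise the realized mean Δβ is verified to land within ±0.01 of the
0.10 target. Class labels and hypo/hyper splits are assigned
deterministically at exact rounded counts — not sampled — so truth
counts are reproducible; DMR blocks carry one sign per block, with the
remainder of a class's hypo budget absorbed by non-block probes.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_probes | 20,000 | desk-scale stand-in for the ~7.2×10⁵ common probes of a real two-dataset intersection; full scale is supported, not default |
| donors | 18 / 15 | the two-cohort study design |
| effect_delta_beta | 0.10 | a clearly biological activation effect, twice the 5% calling threshold |
| class fractions | 5% / 2% / 1% / 0.1% | shared response dominates; infant-specific > adolescent-specific; opposing probes are rare |
| hypo fractions | shared 0.74, infant-specific 0.90, adolescent-specific 0.10 | activation is predominantly demethylating overall; the cohort-specific sets are planted with strongly asymmetric direction so the direction summaries are informative |
| noise_sd_logit | 0.12 | ≈ 0.025–0.03 β-scale replicate SD at intermediate methylation, typical array variability |
| donor_sd_logit | 0.08 | inter-donor biological variation, smaller than residual noise |
| batch_shift_logit | 0.4 | a large, visible dataset offset (dominates PC1 before scaling) |
| DMR blocks | 25 blocks × 6 probes / 3 kb | regions comfortably above the ≥4-probe gate |
| atac concordance odds | 1.5 | a weak but detectable direction association, the magnitude seen in real activation data |
| cytokine fold changes | IL2 4→9, IL10 3→7, IFN-γ 5→12 (infant→adolescent); IL6, TNF equal | adolescents respond with higher IL2/IL10/IFN-γ output; IL6 and TNF are age-invariant |
| planted correlations | 4 probe–cytokine pairs at r = 0.9 | recoverable at n = 15 with high probability |

No published estimate exists for the inter-donor variance or the batch
magnitude; those defaults are documented choices, not inferred values.

Layout: probes sit on 22 chromosomes at 5 kb spacing (600 bp inside DMR
blocks), so unplanted probes form only singleton clusters at the 1 kb
default gap; genes sit on a 200 kb TSS grid, and each cytokine gene's
TSS is placed next to its coupled probes so the 1 Mb scan window is
meaningful. A single master seed splits into named substreams (probes,
donors, atac, cytokines, expression, pathway, genesets); adding one
component never perturbs the others, and identical config + seed is
bit-identical.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: probe-specific technical
artifacts (cross-reactivity, SNPs under probes, dye bias, detection
failures beyond a uniform toggle), spatially correlated noise,
cell-composition heterogeneity, realistic linkage between CpG density
and effect size, genuine expression dynamics (expression calls are
Bernoulli sketches around the planted truth), and raw intensity-level
preprocessing (normalization and batch-probe discovery are consumed
upstream as exclusion lists). Recovery rates on synthetic data
demonstrate the pipeline's internal correctness and calibration, not
field performance on arbitrary cohorts.

## Degenerate inputs and tie-breaks

Zero-variance probe rows scale to all-zero; all-zero residual variances
are a hard error; Δβ = 0 is labeled "hypo" by the strict sign
convention (direction = hyper iff Δβ > 0); PCA signs are fixed by
positive loading sums; a zero marginal makes the concordance χ²
undefined — the table is still returned with the error recorded.
Readers reject rather than coerce: out-of-range β, duplicate ids,
ragged rows, start ≥ end intervals and inconsistent peak
direction/fold-change all raise with the offender named. Probes with
any missing β are dropped at read time with a logged count.

## Problem sizes used by the test suite

Unit and property tests run on 4,000-probe simulations with full donor
counts; calibration and recovery checks use the default 20,000-probe
scale (5–10 seeds); the full-resolution 7.2×10⁵-probe setting is
supported through the same configuration but is not exercised by
default. These sizes were chosen as the smallest at which the
asymptotic calibration properties (FDR control, χ² and KS null
uniformity) are expected to hold.

## Known limitations

The Stouffer region statistic treats probe p-values as independent;
correlated neighboring probes make region p-values anti-conservative,
which the planted-block tests do not penalize because blocks are truly
coordinated. The Wallenius mode collapses per-gene weights to a single
odds ratio. The classifier's indeterminate band is sensitive to the Δβ
sampling error of the *other* cohort (≈ 0.01 SE at these sample sizes),
which bounds achievable specificity of the "truly unresponsive" rule.
Cytokine couplings attenuate to r/√k when k probes share one
concentration vector.
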