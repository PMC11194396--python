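# Methods

This note documents the statistical model behind `drugtarget-mr`, the
choices made where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate about real data.

## Two-sample summary-data MR

The package works entirely in the two-sample summary-statistics regime:
per-variant marginal effect sizes, standard errors, allele frequencies and
sample sizes from an eQTL study (exposure) and a disease GWAS (outcome),
with no individual-level data and no sample overlap assumed. The causal
quantity is the log odds ratio of disease per SD of gene expression.

Identification rests on the usual instrumental-variable assumptions:
instruments associate with expression (enforced by p < 5×10⁻⁸ and F > 10),
are independent of confounders, and affect disease only through expression.
The last assumption is untestable; the Egger intercept, Steiger filtering,
reverse MR and colocalization each probe a different failure mode rather
than proving validity.

### Estimators and p-values

Per-instrument ratios use the first-order delta method,
SE(rᵢ) = SE_out,i/|β_exp,i|, ignoring exposure-side uncertainty. With
F > 10 enforced, the neglected term is O(1/F) of the retained one; a
second-order SE is available via `second_order=True`. All p-values are
two-sided standard normal (no t-corrections: summary-data effect sizes come
from very large samples), floored at 10⁻³⁰⁰ so that extreme signals remain
representable. 95% intervals use the 1.959964 quantile throughout.

The IVW default is multiplicative random effects (SE inflated by
√max(1, Q/(k−1))), which absorbs between-instrument heterogeneity without
changing the point estimate; fixed-effect IVW is selectable. The Egger
intercept is weighted least squares (weights 1/SE_out²) of outcome on
exposure effects, instruments oriented to positive exposure effect, with
its conventional over-dispersion scale estimate; it needs ≥ 3 instruments
and is flagged not-computable below that rather than failing.

### Steiger directionality

An instrument is kept when it explains strictly more variance in the
exposure than in the outcome: R²_exp = z²_exp/(z²_exp+n_exp) versus
R²_out = z²_out/(z²_out+n_out). For binary outcomes this is an
observed-scale approximation — adequate for ordering two correlations, not
for estimating liability-scale variance. The reported Steiger p is a
Fisher-z test for the difference of the two correlations with independent
studies, SE = √(1/(n_exp−3) + 1/(n_out−3)).

### Reverse MR

Reverse MR selects instruments from the disease GWAS under the same
cascade, harmonizes against the gene's eQTLs as outcome, and estimates with
IVW/Wald; significance of a reverse path is declared at p < 0.05. Disease
instruments are Steiger-filtered in the reverse orientation by default.
This step matters: at any truly forward-causal locus the mediated disease
association is itself genome-wide significant, and without the
directionality filter every prioritized gene would trivially appear
"bidirectional". With it, a gene is flagged only when the disease has an
association that explains more variance in disease than in expression yet
still moves expression — the signature of a genuine feedback path.

### Colocalization

Single-causal-variant-per-trait colocalization from approximate Bayes
factors, log ABF = ½(log(1−r) + r z²), r = W/(SE²+W). Priors are the
conventional p1 = p2 = 10⁻⁴ (a variant is causal for one trait) and
p12 = 10⁻⁵ (shared); prior effect SDs are 0.15 for quantitative traits and
0.2 for binary log-odds. None of these are estimated from the data; all are
configurable. Hypothesis weights accumulate in log space with log-sum-exp
(H3 via a guarded log-difference), so z-scores of any magnitude cannot
overflow; posteriors are renormalized and checked to sum to one within
10⁻¹⁰. Genes instrumented by trans variants skip colocalization entirely —
the single-causal-variant regional model is a cis concept.

### Harmonization

Outcome records are aligned to the exposure's effect allele: matching
pairs kept, swapped pairs negated and frequency-reflected, strand flips
complemented first. Palindromic (A/T, G/C) variants are aligned by allele
frequency only when the exposure EAF is outside (0.42, 0.58); inside the
band, or with a missing frequency, they are rejected as ambiguous. The
band is the conventional conservative choice and configurable. Variants
are matched by identifier (rsID-keyed sources), not position.

## The prioritization cascade

A gene is *prioritized* when (i) its post-Steiger discovery estimate passes
0.05/m, with m the number of genes that had at least one usable instrument
(recomputed per run, never hard-coded); (ii) at least one instrument
survives Steiger filtering; and (iii) the colocalization decision
PPH3+PPH4 ≥ 0.8 is positive (waived for trans-instrumented genes, where
colocalization is not attempted). Replication verdicts in a validation
family use 0.05/(family's prioritized-gene count) and additionally require
the validation estimate to share the discovery sign; the two replication
strategies — re-using the discovery instruments ("same-variant") versus
re-selecting instruments ("significant-variant") — are both implemented and
recorded in the run manifest, as is the directional-consistency rule. The
biomarker scan is deliberately unadjusted (p < 0.05), with a Bonferroni
option behind a flag.

Discovery tables report both the all-instrument estimate and the
post-Steiger re-estimate; the cascade's verdicts use the latter.

## The synthetic generator

Summary statistics are simulated directly in z-score space from the
multivariate normal implied by regional LD: z ~ MVN(√n_eff·Σλ, Σ), with
AR(1) LD Σᵢⱼ = ρ^|i−j| and sparse joint standardized effects λ. Binary
traits use the logistic regime n_eff = n·φ(1−φ). Defaults mirror the real
study conditions being emulated: an eQTL meta-analysis of n = 31,684 with
per-variant sample-size jitter, a discovery GWAS of 659,316 (case fraction
0.0954), 50 variants per region at ρ = 0.5, MAF uniform on (0.05, 0.5),
per-allele eQTL effect 0.15 (F ≈ 70–360 across the MAF range), and causal
effect θ = 0.4. Scenario-specific parameters: the reverse scenario uses a
strong disease locus (per-allele log-OR 0.3, an HLA-class effect size) with
a modest feedback of 0.2 SD expression per liability unit; the pleiotropic
scenario adds direct effects of 0.05 at three variants. Each gene draws
from an RNG stream keyed by (seed, gene index), making bundles
byte-reproducible and per-gene output independent of iteration order.

What the generator does **not** emulate: realistic human LD (block
structure, long-range hitchhiking), allele-frequency–dependent effect-size
architecture, sample overlap between studies, population stratification,
liability-scale non-collapsibility (binary effects are generated directly
on the log-odds scale), multi-causal-variant regions, and missingness or
strand errors beyond random allele-representation swaps. Passing the
evaluation battery therefore demonstrates internal statistical correctness
and calibration under the stated model — not robustness to every pathology
of real GWAS data.

## Evaluation battery and problem sizes

The suite and `scripts/acceptance.py` measure, at these sizes (chosen to
hold Monte-Carlo error well below each decision band while keeping a
single-CPU run in tens of seconds):

- **Type-I error**: 2,000 null regions; Wald/IVW rejection at α = 0.05
  expected in [0.03, 0.07].
- **Recovery**: 500 causal regions per θ ∈ {−0.4, 0.2, 0.5}; mean estimate
  within 2 MC-SE of θ. This runs under a strong-instrument condition
  (common causal variants, per-allele effect 0.2, F ≈ 230–630): the Wald
  ratio carries the standard O(1/F) Jensen bias (≈ θ/F), which weaker
  instruments would push past 2 MC-SE at this replicate count — a known
  property of ratio estimators, not a defect the recovery check targets.
- **Colocalization discrimination**: 200 shared-variant and 200
  distinct-variant regions; PPH4 > 0.8 (resp. PPH3 > PPH4) in ≥ 90%.
- **Steiger**: 500 reverse-causation regions at n = 50,000 per study;
  > 95% of selected instruments removed.
- **End to end**: 100 genes (10 causal at θ = ±0.4, 90 null), a three-member
  validation family regenerated with fresh noise at half the discovery
  sample size, and 13 biomarkers; expected ≥ 8/10 causal genes prioritized,
  ≤ 1 null gene, ≥ 80% replication.

Oracle-equivalence tests pin the estimators to independent
implementations: IVW against the closed-form weighted mean (10⁻¹²), Egger
against a direct normal-equations solve (10⁻¹⁰), greedy clumping against
brute-force priority retention on ≤ 12-variant regions, and colocalization
against exhaustive enumeration of single-causal configurations on ≤ 4
variants (10⁻⁹).

## Numerical and degenerate-input conventions

Clumping ties on identical p-values break by position, then variant id, so
output order is deterministic. Empty instrument sets are not errors — the
gene is skipped downstream and the selection log records where candidates
died. Tables reject duplicated variant ids, non-positive SEs, p-values
outside (0, 1], and allele codes outside {A,C,G,T} at read time, counting
dropped rows. LD matrices are validated for symmetry, unit diagonal and
[0,1] range, with a 10⁻¹² jitter on the Cholesky used for simulation.

## Limitations

Single-causal-variant colocalization cannot represent allelic series;
weighted-median/mode and MR-PRESSO-style outlier estimators are out of
scope; the cis window (±1 Mb) and all priors are conventions, not estimates;
and the synthetic calibration results transfer to real data only insofar as
the generating model above approximates it.
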