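# Methods

This note documents the statistical model implemented by `medmr`, the
assumptions it rests on, the default parameter choices and why they were
made, what the synthetic-data generator does and does not emulate, the
numerical conventions, and known limitations. All quantitative statements
here are either closed-form derivations or properties computed by the test
suite and `scripts/acceptance.py`; no external empirical claims are made.

## 1. Model

### 1.1 Two-sample MR

For a variant *i* with harmonized exposure effect βˣᵢ (SE σˣᵢ) and outcome
effect βʸᵢ (SE σʸᵢ), the per-variant causal estimate is the Wald ratio
βʸᵢ/βˣᵢ with first-order SE σʸᵢ/|βˣᵢ|. With weights wᵢ = 1/σʸᵢ², the
inverse-variance-weighted (IVW) estimate is

  β̂ = Σ wᵢ βˣᵢ βʸᵢ / Σ wᵢ (βˣᵢ)²,  se(β̂) = (Σ wᵢ (βˣᵢ)²)^(−1/2),

equivalent to a zero-intercept weighted regression of βʸ on βˣ. The default
is the **multiplicative random-effects** variant: the SE is inflated by
√max(1, Q/(n−1)) where Q is Cochran's statistic at β̂, so heterogeneity
widens the interval and the reported uncertainty is never smaller than the
fixed-effect model's. For binary outcomes the effects are log-odds ratios
and estimates exponentiate to odds ratios per unit of exposure.

Sensitivity estimators:

- **MR-Egger** — weighted regression with a free intercept, variants
  oriented to βˣᵢ ≥ 0. A nonzero intercept estimates directional
  pleiotropy; "no directional pleiotropy" is declared at intercept p ≥ 0.05.
  Valid under InSIDE (instrument strength independent of direct effects).
- **Weighted median** — per-variant ratios ordered and weighted by
  (βˣᵢ)²/σʸᵢ², the estimate interpolated at cumulative weight 0.5;
  consistent when ≥ 50% of the weight comes from valid instruments. The SE
  has no closed form and comes from a seeded parametric bootstrap
  resampling (βˣ, βʸ) from their sampling distributions.
- **Cochran's Q** — Σ wᵢ(βʸᵢ − β·βˣᵢ)² on n−1 df for an IVW slope, n−2 for
  an Egger fit; upper-tail χ² p-value.
- **Leave-one-out** — IVW refit with each variant omitted; a variant is
  flagged influential when its omission changes the estimate's sign or
  leaves the full-sample estimate outside the fixed-effect 95% CI of the
  reduced fit. The fixed-effect CI is used as the reference (a deliberate
  choice: the random-effects CI widens with the very heterogeneity an
  outlier causes, masking its own influence).
- **MR-PRESSO** — the observed statistic is the weighted leave-one-out
  residual sum of squares; its null distribution is simulated by drawing
  (βˣ*, βʸ*) from normal sampling distributions centred on the observed βˣ
  and on each variant's leave-one-out IVW prediction. Per-variant outlier
  p-values are simulated tail probabilities, Bonferroni-adjusted. Outliers
  are removed **only when the global test is significant** (p < 0.05) — on
  a clean instrument set nothing is removed even though every variant's
  adjusted p-value falls below the (deliberately permissive) per-variant
  threshold of 1. A distortion test compares the estimate shift after
  removal against removals of random same-size subsets. Simulated p-values
  use the (1 + #{sim ≥ obs})/(K + 1) convention, so they are never zero.

### 1.2 Instrument selection

Candidate instruments pass three stages, each fully logged:

1. **p-value screen** — p < 5·10⁻⁵ for molecular traits (lipids,
   metabolites: smaller GWAS, larger per-variant effects), p < 5·10⁻⁸ when
   the disease outcome is the exposure (reverse direction).
2. **Greedy LD clumping** — repeatedly take the remaining variant with the
   smallest p-value as index and discard same-chromosome variants within
   10,000 kb with r² ≥ 0.001. Ties in p are broken by (chrom, pos,
   variant_id), so results do not depend on input row order. LD is supplied
   by the caller as a lookup (explicit pair table, all-zero for independent
   panels, or distance-only as a conservative fallback).
3. **Strength filter** — per-variant F = [R²/(1−R²)]·(N−K−1)/K with K = 1;
   keep F > 10. By default R² = t²/(t² + N − 2) from the reported effect
   and SE (needs no allele frequency and makes F ≈ t²); an allele-frequency
   based R² = 2·eaf·(1−eaf)·β² is available for standardized continuous
   traits.

### 1.3 Harmonization

Outcome effects are aligned to the exposure's effect allele. Non-palindromic
variants align from the allele letters (a swap negates the effect and
complements the frequency). Palindromic variants (A/T, C/G) are
strand-ambiguous: they are aligned by effect-allele-frequency agreement
(flip iff the two frequencies sit on opposite sides of 0.5) and **excluded
as ambiguous** when the exposure frequency lies in [0.42, 0.58] or either
frequency is missing. Allele sets that match neither directly nor by swap
are excluded as incompatible. A strict mode drops every palindromic
variant. Retained + excluded always equals the variant-ID intersection.

### 1.4 Two-step mediation

Phase 1 screens each exposure bidirectionally: keep X when the forward MR
(X→Y) has p < 0.05 **and** the reverse MR (Y→X) has p ≥ 0.05. Phase 2, for
each surviving X and each mediator M:

- a from X→M and b from M→Y by univariable MR, each through the full
  selection/harmonization funnel; the b-run excludes X's instruments from
  M's instrument set (two-step rather than multivariable adjustment — see
  §2.3);
- gates: a and b must each have p < α (default 0.05); failures are recorded
  with a machine-readable rejection stage and the pipeline continues with
  the next pathway;
- mediated effect a·b with delta-method SE √(a²·se_b² + b²·se_a²) (a
  Monte-Carlo percentile interval is available); direct effect c′ = c − a·b;
  mediated proportion (a·b)/c, **withheld** (reported as NaN with an
  `inconsistent_sign` flag) when a·b and c disagree in sign, since a
  "proportion" outside [0, 1] by sign is not interpretable;
- optional batch-level multiplicity adjustment of the a- and b-gates
  (Bonferroni or Benjamini–Hochberg FDR).

### 1.5 Assumptions

Instrument relevance (enforced by the F filter), exchangeability (no
instrument–confounder association) and exclusion restriction (no horizontal
pleiotropy) are assumed for point identification; the Egger intercept,
weighted median, Q, leave-one-out and MR-PRESSO probe violations of the
third. The two cohort samples are assumed non-overlapping (overlap biases
two-sample MR toward the confounded estimate). Mediation additionally
assumes no unmeasured mediator–outcome confounding and linearity of the
decomposition c = c′ + a·b on the log-odds scale, which is first-order
(see §4).

## 2. Default parameters and rationale

| Parameter | Default | Rationale |
|---|---|---|
| molecular selection p | 5·10⁻⁵ | molecular GWAS are modest-sized with oligogenic large effects; genome-wide 5·10⁻⁸ would leave too few instruments |
| outcome-as-exposure p | 5·10⁻⁸ | reverse direction instruments a disease from a large GWAS; genome-wide significance is the standard bar |
| clump window / r² | 10,000 kb / 0.001 | long-range, near-independence clumping: keeps instruments effectively uncorrelated so IVW's independence assumption holds |
| F threshold | 10 | conventional weak-instrument bound; with the t-statistic R², F ≈ t², so F > 10 ≈ |t| > 3.2 |
| palindromic eaf window | [0.42, 0.58] | inside this window frequency cannot distinguish strands with realistic sampling noise |
| IVW variant | multiplicative random effects | never anti-conservative relative to fixed effects; reduces to it when Q ≤ n−1 |
| PRESSO per-variant threshold | 1 (all flagged) | outlier removal is gated on the global test instead, so clean sets lose nothing while contaminated sets drop every implicated variant |
| α (gates) | 0.05 | headline screening level; multiplicity adjustment available per batch |
| mediated CI | delta method | accurate when a and b are individually well separated from zero — guaranteed here because both must pass their significance gates first; Monte Carlo alternative for small samples |

## 3. The synthetic-data generator

### 3.1 Structural model

A panel of biallelic variants G with MAF uniform on [0.1, 0.5] drives three
disjoint cohorts (no sample overlap, matching the two-sample assumption):

- X = Σ γᵢGᵢ + ε, observed in the exposure cohort;
- M = a·X + Σ αᵢGᵢ + ε, observed in the mediator cohort;
- logit P(Y=1) = β₀ + b·M + c′·X + Σ δᵢGᵢ, observed in the outcome cohort,
  with β₀ solved by root-finding so the marginal prevalence hits its target
  (default 0.10).

Disjoint instrument sets carry γ (exposure), α (mediator) and δ (outcome)
effects; the remaining variants are null. The true marginal per-variant
effects are γ for X, aγ + α for M, and b(aγ + α) + c′γ + δ for Y (on the
linear predictor scale). Optional pleiotropy attaches α and δ directly to
the exposure instruments — balanced (zero-mean, violating exclusion but
preserving InSIDE) or directional (nonzero-mean, which the Egger intercept
targets).

Two modes: **individual-level** simulates genotypes (Hardy–Weinberg
binomial; optional block LD through a Gaussian copula), phenotypes, and
per-variant GWAS (vectorized OLS for continuous traits, per-variant Newton
logistic regression for the binary outcome), returning realized LD;
**summary-level** draws β̂ ~ N(true marginal effect, asymptotic SE) directly
— exact for OLS, first-order for the logistic score — which makes
thousand-replicate calibration studies cheap. Allele representation is
scrambled for a configurable fraction of mediator/outcome rows (effect
stored on the other allele: negated β, complemented frequency) so
harmonization is always exercised end to end.

### 3.2 Instrument-effect distribution and cohort sizes (bias budget)

Instrument effect magnitudes are uniform on [0.5, 1.5]×scale (default scale
0.6) with random sign — **bounded away from zero**. Two reasons. First,
realism: an instrument panel is the product of genome-wide selection, so
its effect-size distribution is bounded away from zero, unlike a normal
with most mass near the origin. Second, statistical hygiene of the default
scenarios: effects near the selection threshold create winner's curse
(variants enter only when their effect is overestimated), which inflates
Σw(β̂ˣ)² and attenuates IVW beyond the classical dilution term.

The classical term itself — E[β̂] ≈ β·(1 − mean(se_x²/γ²)) — sets the cohort
sizes. A recovery study with R replicates can only detect bias down to its
Monte Carlo SE, so the design requirement is dilution ≲ 0.5·MCSE at
R = 500. With magnitudes in [0.3, 0.9], 12 instruments per trait, and
var(X) ≈ 2.8, the closed-form budget gives relative dilution
var(X)·E[1/2p(1−p)]·E[1/γ²]/n ≈ 29/n — hence the default molecular cohort
sizes n_exposure = 50,000 and n_mediator = 30,000 (bias on a ≈ 0.0002
against MCSE ≈ 0.0004), while the binary outcome cohort stays at
disease-study scale (6,000, prevalence 0.10). These values were fixed from
this calculation and then verified, not iterated against the test outcomes
(the decision history records one redesign, driven by exactly this
analysis).

### 3.3 What the generator does not emulate

- LD is block-local with a Gaussian-copula target; realized genotype r² is
  attenuated relative to the copula parameter (discretized margins) and
  there is no population stratification, relatedness or assortative mating.
- No confounding of X–M–Y beyond what pleiotropy induces: the generator
  tests estimator behaviour under the MR assumptions and controlled
  violations of exclusion, not under arbitrary confounding.
- Effect sizes, allele frequencies and architectures are stylized; the
  scenario emulates the *shape* of a molecular-QTL study (few strong
  instruments, modest binary-outcome GWAS), not any specific dataset.
- The logistic outcome model means marginal per-variant log-odds effects
  are non-collapsible; summary-level mode sidesteps this by drawing around
  the linear-predictor marginals, individual-level mode inherits the small
  attenuation a real GWAS would show.

## 4. Numerical conventions

- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; derived child seeds are drawn below 2³¹. Reruns are byte-identical
  (verified by the determinism acceptance check); outputs contain no
  timestamps, and manifests carry a SHA-256 configuration hash.
- Normal-approximation p-values are two-sided and floored at the smallest
  positive double rather than zero. 95% intervals use
  z = 1.959963984540054.
- Egger is solved by closed-form weighted normal equations; degeneracy
  (constant βˣ) is detected by a *relative* variance test, since floating
  point leaves O(ε²) residual variance where the exact value is zero.
- Simulated p-values (PRESSO) use (1 + #{≥})/(K + 1).
- TSVs are written with `%.17g`, so floats round-trip exactly.
- The delta-method decomposition c′ = c − a·b holds exactly in code
  (asserted to 10⁻¹² in tests); its *interpretation* as a causal
  decomposition on the log-odds scale is first-order, see below.

## 5. Limitations

- The product-of-coefficients decomposition on the log-odds scale is
  approximate under non-collapsibility of the odds ratio; for rare outcomes
  (prevalence ≈ 0.1 here) the distortion is second-order but not zero.
- The delta-method CI for a·b is symmetric and can undercover when a or b
  is weakly identified; the pipeline mitigates this by gating on both
  coefficients' significance before reporting a mediated effect, and a
  Monte Carlo interval is available.
- The bidirectional screen is a hard threshold pair (forward p < 0.05,
  reverse p ≥ 0.05); it controls neither direction's error rate jointly and
  inherits the usual perils of screening on significance.
- Excluding the exposure's instruments from the b-step removes first-order
  contamination but is not a multivariable-MR adjustment; residual overlap
  through LD between X- and M-instruments is only handled by clumping.
- MR-PRESSO's distortion test resamples subsets of the observed variants;
  with very few instruments (< ~6) its null is coarse.
- The leave-one-out influence flag uses the fixed-effect CI and is a
  diagnostic, not a test with a controlled error rate.
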