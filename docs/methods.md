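# Methods

`targetmr` implements a drug-target Mendelian randomization (MR) and
colocalization pipeline over GWAS summary statistics, together with a
generator of synthetic summary statistics with known ground truth so every
stage can be validated without external data. This note records the models,
the defaults and why they were chosen, the numerical policies, and what the
synthetic validation does and does not establish.

## The analysis model

**Design.** Genetic variants in (or near) the gene encoding a drug's protein
target that associate with the drug's indication trait — here, systolic
blood pressure (SBP) — proxy pharmacological perturbation of that target.
Their effects on an outcome, taken from an independent GWAS (two-sample
design), identify the causal effect of target-mediated SBP change under the
instrumental-variable assumptions (relevance, independence, exclusion
restriction).

**Instrument selection.** Per gene region (1-based inclusive GRCh37
coordinates, symmetric flank of 10,000 bp, boundaries inclusive), variants
with p < 5×10⁻⁸ (strict) are clumped greedily in p-value rank order to
pairwise r² < 0.1: the most significant remaining variant is retained and
all remaining variants in LD with it at or above the threshold are
discarded. Ties in p break by position, then lexicographic id, so output is
reproducible. The greedy p-ranked rule is the de-facto standard; the
packaged default region table lists the beta-blocker (ADRB1) and
calcium-channel-blocker genes with their published coordinates, transcribed
verbatim (including chromosome annotations that look odd against standard
gene maps — regions are user-configurable precisely because of this). A
genome-wide mode skips region extraction and clumps all significant hits.
Multi-gene targets pool candidates across regions and clump jointly with
cross-region LD taken as zero (regions sit on different chromosomes or far
apart). LD is always *consumed* as a user-supplied r² matrix, never
computed from genotypes.

**Instrument strength.** Per-SNP variance explained is R² = F/(N−2+F) with
F = (β/SE(β))²; the joint R² is the sum of per-SNP R² (appropriate for
near-independent post-clump variants), and the joint
F = ((n−k−1)/k)·R²/(1−R²). Sets with F < 10 are flagged weak (the usual
rule of thumb). Note that evaluating the joint-F formula at published
*rounded* R² inputs (e.g. R² = 0.00028, n = 757,601, k = 2) gives ≈106.1;
tables computed from unrounded inputs can print slightly different values
(105.49 for that case). The package asserts the formula, not any one
printed rounding.

**Harmonization.** Outcome effects are aligned to the exposure's effect
allele: swapped alleles flip the outcome beta's sign and complement its
frequency; opposite-strand reports (A↔T, C↔G complements) are aligned the
same way. Palindromic (A/T, G/C) variants cannot be strand-resolved from
alleles; they are kept only when both effect-allele frequencies are present,
both fall outside 0.5 ± w (default w = 0.08), and they agree in side after
alignment — otherwise dropped with reason `palindromic_ambiguous`. The
window rule is a documented, conservative convention for two-sample MR, not
an inference about any upstream tool's behaviour. Indels and multi-allelic
rows are rejected at read time; missing frequency is allowed for
non-palindromic variants.

## Estimators

With instrument–outcome pairs (βx_i, βy_i) and outcome SEs σ_i, weights
w_i = 1/σ_i²:

- **Wald ratio** (k = 1): β = βy/βx, SE = σ/|βx| (first-order delta
  method).
- **IVW** (k ≥ 2): weighted regression through the origin,
  β = Σwβxβy / Σwβx², with heterogeneity Q = Σw(βy − βÂ·βx)² and
  multiplicative dispersion φ = Q/(k−1) **floored at 1**:
  SE = √(φ/Σwβx²). The floor is the "standard error correction for
  underdispersion": it prevents the random-effects SE from dropping below
  the fixed-effect SE when Q < k−1, and is the only reading of that phrase
  that *corrects* anything. The unfloored variant is available for oracle
  comparisons.
- **MR-Egger** (k ≥ 3): records are oriented so βx ≥ 0 (flipping both
  betas, an allele relabelling), then βy is regressed on βx *with* an
  intercept. The intercept estimates constant directional pleiotropy and
  its p-value is the pleiotropy test; the slope is the pleiotropy-adjusted
  effect. SEs carry φ = Q/(k−2) floored at 1; p-values use a t reference
  with k−2 df (configurable to normal). Whether the original analyses
  floored Egger SEs is not documented anywhere we could check; flooring is
  our package-wide policy and is recorded in every estimate's φ field.
- **Weighted median** (k ≥ 3): per-SNP ratios weighted by the inverse
  delta-method ratio variance; estimate by cumulative-weight interpolation
  at 0.5. The SE comes from a parametric bootstrap (default 1,000 draws,
  seeded): βx and βy are redrawn from their normal sampling distributions
  and the weighted median recomputed. The bootstrap SE choice is ours; no
  standard exists that we would call canonical for summary-level input.
- **MR-PRESSO** (k ≥ 4): the observed statistic is the weighted RSS of each
  outcome beta around its leave-one-out IVW prediction. Its null
  distribution comes from parametric simulation (default 1,000 draws,
  seeded): outcome betas are redrawn around the leave-one-out fitted means
  with their reported SEs and the leave-one-out fit is *recomputed per
  draw*, so the observed and simulated statistics are exchangeable — this
  is what makes the global p approximately uniform under the null. Exposure
  betas are held fixed in the simulation (a simplification relative to
  redrawing both sides; with the strong instruments this pipeline selects,
  exposure noise contributes negligibly to the residual). Per-variant
  outlier p-values are tail fractions of each variant's contribution,
  compared against 0.05/k (Bonferroni); the corrected estimate is IVW on
  the non-outliers.

**Reporting scale.** Estimates are multiplied by a scale factor (default
−10: per 10-unit — 10 mmHg — *reduction* of the exposure, which flips
direction), and case-control outcomes are exponentiated to odds ratios with
CI endpoints exp(scaled β ∓ 1.96·scaled SE). The CI multiplier is fixed at
1.959964 everywhere. With m outcomes the significance threshold is α/m
(0.05/3 → 0.017 printed at 3 dp). The outcome count is read from the
configuration, never hard-coded.

## Colocalization

Single-causal-variant Bayesian colocalization over all region variants (the
significance filter applies to MR instruments only, never here). Per
variant, the Wakefield log approximate Bayes factor is
0.5·log(1−r) + r·z²/2 with z = β/SE, r = W/(SE²+W), and prior effect SD
√W = 0.15 for continuous traits or 0.2 (log-odds) for case-control traits —
the published defaults of the method this follows, since only "default
priors" were specified for p1/p2/p12. Hypothesis posteriors combine the
per-variant ABFs with per-variant priors p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵:

- H1/H2 terms: logsumexp of single-trait ABFs + log p;
- H4: logsumexp of per-variant ABF sums + log p12;
- H3 (distinct causal variants): the off-diagonal double sum, computed as
  exp(l1+l2) − exp(l4) in log space via log1p with the largest term
  factored out; with one variant the H3 term is −∞ exactly.

All arithmetic is in log space, so |log ABF| up to 10⁴ (z ≈ 140) cannot
overflow; posteriors are renormalized softmax outputs and sum to 1 within
10⁻¹⁰. PP(H4) > 0.5 sets a `shared_variant` *flag* — all five posteriors
are always reported, the flag never gates anything. Prior sensitivity
recomputes posteriors over a p12 grid from cached ABFs (ABFs do not depend
on p12); PP(H4) is non-decreasing in p12. A brute-force enumeration over
all (n+1)² per-variant causal configurations is shipped alongside as an
independent oracle for small n.

## The synthetic generator

The generator emulates the statistical structure of summary data the
analysis consumes, not individual-level genetics:

- **LD** is AR(1): corr(i,j) = ρ^|i−j| (default ρ = 0.9 within a region),
  chosen for analytic transparency; block structures come from
  concatenation, and real-panel LD is out of scope by design.
- **Marginal effects** propagate a sparse causal vector γ through the
  correlation matrix C: exposure marginals Cγ; outcome marginals
  θ·Cγ + Cη, where η ~ N(δ, τ²) per SNP models directional (δ) and
  balanced (τ) pleiotropy.
- **Sampling noise** is multivariate normal with covariance σ²C/n per
  trait, drawn independently for exposure and outcome (two-sample
  assumption; cross-trait noise correlation verified < 0.05 empirically).
  Effects sit on the standardized-genotype scale, so SEs are σ/√n
  (continuous; σ = 19 mmHg for the SBP-like exposure) and
  1/√(n·cf·(1−cf)) on the log-odds scale for case-control traits with case
  fraction cf. Allele frequencies are drawn uniform in (0.05, 0.5) and
  matter only for harmonization bookkeeping; simulated alleles are
  non-palindromic so harmonization drops nothing by construction
  (palindromic cases are built explicitly in tests).
- **Defaults** mirror the study conditions being emulated: exposure GWAS of
  5×10⁵–7.6×10⁵ samples, binary pregnancy outcomes with case fractions of
  a few percent on ~1.4×10⁵ samples, cis regions of 30–50 variants, causal
  effects ~0.5 mmHg per allele (marginal z ≈ 20 at the causal variant),
  true θ chosen per analysis (e.g. 0.13 log-odds/mmHg reproduces an OR of
  0.27 per 10 mmHg reduction). Colocalization scenarios set causal effects
  so the causal variant's expected z is 8 per trait, with shared or
  distinct (mutual r² < 0.05) causal indices.

**What passing tests show — and do not.** The simulations verify internal
statistical correctness: estimator formulas against independent oracles,
type-I calibration, CI coverage, pleiotropy-intercept recovery, and
H3-vs-H4 discrimination under the generator's assumptions (AR(1) LD, normal
sampling noise, correct SEs, no sample overlap, no winner's curse). They do
not establish robustness to real-data pathologies outside that model:
mis-specified SEs, population stratification, overlapping samples, or LD
mismatch between the reference panel and the GWAS population.

## Problem sizes and numerical choices

Simulation-based checks use 1,000 replicates for calibration/coverage/
recovery, 500 for colocalization discrimination and enumeration oracles,
and 200 for clumping oracles — sizes at which the binomial noise on every
asserted rate is several times smaller than the asserted margin, while the
whole suite stays fast. MR-PRESSO uses 1,000 null simulations per fit;
empirical p-values use the (1+exceedances)/(1+draws) form, so they are
never exactly zero. All random streams derive from explicit seeds via
`numpy` `SeedSequence` spawning; identical configuration + seed reproduces
results byte-identically (JSON bundles are dumped with sorted keys).

Degenerate inputs are contracts, not surprises: a single variant routes to
the Wald ratio and zeroes the H3 term; βx = 0 excludes a variant from
ratio-based estimators (with a warning) and errors the Wald ratio; empty
post-clump sets raise a named "no instruments" error that the orchestrator
records per target without aborting the run; Cholesky factorization of the
AR(1) correlation adds a 10⁻¹⁰ jitter only on numerical failure.

## Known limitations

- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  extension, no credible sets.
- Uncorrelated-instrument IVW only — appropriate because clumping enforces
  near-independence; no correlated-weights variant, no multivariable MR.
- No proxy-variant lookup when an instrument is absent from the outcome
  GWAS; the variant is simply not in the intersection.
- The p+MAF route into the ABF is not implemented; betas and SEs are
  required (the beta/varbeta route of the underlying method).
- LD input is trusted as given; no consistency check against the summary
  statistics beyond variant-id matching.
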