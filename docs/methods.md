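# Methods

## Data model and assumptions

The observed data are a dominant-coded carrier matrix (M rare variants × N
individuals; an entry is 1 when at least one haplotype carries a mutant
allele) and a dichotomous phenotype. Variants are treated as conditionally
independent given their causal states — linkage disequilibrium between rare
variants is assumed negligible, so all cross-variant structure lives in the
latent fields, not in the genotype likelihood. "MAF" throughout means the
carrier (dominant-coded) frequency per group, not the allelic frequency.

Two binary latent fields are estimated jointly: the causal status `X` and
the region status `R`. Elevated regions (`R = 1`) are contiguous stretches
of the variant axis with a higher prior causal rate ξ than the background
rate ζ; they play the role of a flexible, data-driven alternative to fixed
sliding windows.

## Probability components

**Emissions.** For a causal site, case and control carrier frequencies are
distinct, each with a Beta prior; integrating them out gives the marginal
likelihood of the observed counts as a product of two Beta-function ratios
`B(α+c, β+n−c) / B(α, β)`. For a null site both groups share one pooled
frequency. Binomial coefficients are omitted consistently in both branches,
so the difference of the two log-marginals is a well-defined per-site log
Bayes factor. A useful consequence of the coefficient-free convention: when
all hyperparameters are flat the Bayes factor behaves like a conservative
independence test — negative for balanced case/control splits, positive for
imbalanced ones.

**Hyperparameters.** The Beta hyperparameters for θ (case), ρ (control) and
the pooled null frequency are refit each cycle by the Beta-Binomial method
of moments on the raw per-site proportions: the observed variance is first
reduced by the expected binomial sampling variance `m(1−m)/n`. Two guards
keep the empirical-Bayes fit honest:

* *resolution guard* — if the implied prior strength exceeds the per-site
  sample size, the across-site dispersion is below what the data can
  resolve and the fit reverts to the flat prior;
* *symmetry guard* — if any of the three fits reverts to flat, all three
  do, because a Bayes factor comparing an adaptive prior on one side with a
  flat prior on the other is biased toward the adaptive side.

The fits deliberately use the raw proportions rather than the MAP-shrunken
estimates of the previous cycle: refitting on shrunken values collapses the
prior variance geometrically and with it the Occam penalty of the marginal
likelihood.

**Causal field.** The local conditional of `X_s` combines an own term — the
region-conditional prior `P(X_s = x | R_s)` raised to a tempering weight γ
— with a pairwise term `η Σ ω(s,s′) P(X_s′|R_s′) X_s′` over the
collapsing-weight neighborhood. The pairwise term is shared by both states
of `X_s`, so the normalized conditional is logistic in `γ·logit(ξ or ζ)`;
ω and η define the joint potential but do not move the per-site contrast.
At the self-consistent fit γ ≈ 1 and the field is exactly the Bayesian
classifier prior: a site is selected when its emission log Bayes factor
beats the prior log-odds of its region class. Elevated regions therefore
act as a pooled, window-level relaxation of the selection threshold, which
is what lets weak causal sites inside a recovered block be kept while
isolated background noise is rejected.

**Region field.** `R` lives on the genomic variant order with an
Ising-style smoothing potential (`τ` base-rate term plus `υ` times the
signed sum of the 2h flanking labels, h = `region_window`/2, default 5).
Its data coupling is the Bernoulli likelihood of the current `X̂_s` under ξ
versus ζ. ξ and ζ carry a fixed weakly-informative Beta(2, 2) prior: a
single pair of counts has no replicate structure to fit hyperparameters
from, and a flat prior's MAP saturates at 0 or 1 whenever a region class
contains no causal site, which would make the region evidence infinite.
Because the model is symmetric under swapping the two region labels,
"elevated" is pinned to the class with the higher causal rate; labels are
flipped whenever the estimates invert.

## Estimation cycle

Each cycle: (1) hyperparameter fits and MAP updates of θ̂, ρ̂; (2) counts
`c_X⁺/c_E`, `c_X⁻/c_B` and MAP updates of ξ̂, ζ̂ (with relabeling);
(3) bounded maximum pseudo-likelihood fits of γ and (τ, υ); (4) an ICM
sweep — all `X_s` by vectorized argmax of emission + field (order-free,
since the contrast involves no other site's causal state), then the region
field relaxed by sequential sweeps (ascending site order, ≤ 20 inner
passes) until stable, so blocks consolidate or dissolve fully before the
next parameter update. Iteration stops when neither field changes
(Euclidean distance on `X̂` below 1, `R̂` identical), when the selection
becomes empty (terminal: collapsing an empty set is p = 1 and the prior
weight is then unidentified — continuing can only oscillate), or at
`max_iter` (default 20, flagged non-converged).

Initialization: `X₀` flags sites with |z| ≥ 1; `R₀` thresholds a centered
moving average of `X₀` (window 10) at 0.5. Optional per-variant prior
scores in [0, 1] (e.g. from functional predictors) override either seed.

**Final test.** The selected set is split by the sign of the per-site z
into risk and protective subsets; each non-empty subset is collapsed to a
per-individual indicator of carrying ≥ 1 mutant across the subset and
tested with the pooled two-proportion z (two-sided normal p). With both
subsets present, p = min(1, 2·min(p⁺, p⁻)). The default significance
threshold 2.5 × 10⁻⁶ is the Bonferroni level for 20,000 genes. Because the
subsets are data-selected, this p-value is a screening statistic rather
than an exactly calibrated tail probability; the all-null simulations in
the test suite bound its practical behavior at the benchmark sample sizes.

## Numerical choices

Probabilities are floored at 1e-300 before logs; MAP rates are clamped to
[1e-6, 1−1e-6]; γ is fitted on [0, 30], τ and υ on [−12, 12] × (0, 12]
(bounds act as separation guards for the logistic fits; the fitted values
sit well inside them in non-degenerate data). Exact ties in any argmax keep
the previous state. z is defined as 0 whenever the two proportions are
equal, including the degenerate pooled 0/1 cases; ω(0, 0) = 0 (a
monomorphic pair carries no collapsing information). If an optimizer fails
or would return a lower pseudo-likelihood than the incoming parameters, the
incoming values are kept.

## Simulators

* **Fixed causal count** — control frequencies from Wright's stationary
  distribution under purifying selection, density ∝
  ρ^(βS−1)(1−ρ)^(βN−1)e^(σ(1−ρ)) truncated to [1e-5, 0.01] (the density is
  improper at 0 for βS < 1; the truncation keeps draws in the rare range),
  sampled by inverse CDF on a 4096-point log grid. Defaults σ = 12,
  βS = 0.001, βN = 0.00033. Each of K causal sites gets the marginal
  attributable risk δ = Δ/K, relative risk RR = δ/((1−δ)ρ) + 1 and case
  frequency θ = RR·ρ/((RR−1)ρ+1) (equivalently θ = δ + ρ(1−δ)); genotypes
  are independent Bernoulli draws per group. The causal sites form one
  contiguous block at a seeded random offset, recorded as the elevated
  region so region recovery can be scored on every framework.
* **PAR-driven causal set** — causal frequencies drawn from Wright's
  distribution under strong selection (σ = 30, βS = 0.2, βN = 0.002) and
  appended while ∏(1−θ_s·Pr/P_D) > 1−Δ; the draw that breaks the
  inequality is the last member. Non-causal sites use the coalescent null
  frequency 5/N.
* **Region-structured** — elevated/background labels preset (equal chunks,
  one elevated block of the stated length per chunk) or generated by a
  two-state Markov chain (stay 0.8 / switch 0.2); causal status Bernoulli
  per class (0.1 elevated, 0.001 background); causal frequencies from the
  strong-selection Wright's distribution, null sites at 5/N.

For the mechanistic frameworks the phenotype model is: a carrier of ≥ 1
causal variant is affected with penetrance Pr (default 0.1), a non-carrier
with the baseline rate solving marginal prevalence P_D (default 0.01);
cases and controls are rejection-sampled to quota (1000/1000 by default).
Only the causal-site genotypes are drawn for rejected individuals; accepted
individuals then receive full genotype vectors — distributionally identical
to simulating everyone and much faster. These generators reproduce the
benchmark designs' frequency spectra and ascertainment, but not features of
real resequencing data such as linkage disequilibrium, genotyping error,
population stratification or variable per-site missingness, so passing
benchmarks here does not certify behavior under those artifacts.

## Problem sizes and observed behavior

The packaged experiments use 20 replicates per setting (M up to 2000,
N = 2000), 10 seeds for the recovery check and 100 seeds for the all-null
calibration check — sizes chosen so the whole suite re-runs in well under a
minute on one core while keeping Monte-Carlo error on a 20-replicate power
estimate at about ±5 percentage points.

Known limitations, measured at the benchmark conditions:

* With 50 weak causal sites (δ = 0.001 each) in 100, roughly a quarter of
  causal sites show no case excess at all in a given sample; sensitivity of
  the selection plateaus near 0.75, and 2–3 of 20 replicates carry too
  little aggregate signal for *any* selection of true causal sites to reach
  2.5 × 10⁻⁶ (the oracle that collapses exactly the causal risk-direction
  sites attains ~94% power). Measured power is ~85% at M = 100 and ~95-100%
  at M = 2000.
* Under the region-structured design's stated causal rates, some replicates
  realize only 1–3 causal sites at carrier frequencies near 10⁻⁴ and are
  undetectable in principle; measured power is ~85% with region-recovery
  accuracy ~95%.
* Under the global null, no dataset in 100 seeds reaches the threshold, and
  the per-site type-I rate of the selection stays below 0.1 under strong
  signal — but see the caveat above on the screening nature of the final
  p-value.
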