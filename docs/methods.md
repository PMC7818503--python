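# Methods

## The model

`sparsemeta` pools k two-arm randomised trials with a binary outcome using
an arm-level binomial–normal hierarchical model. For trial i and arm
j ∈ {T, C}:

    r_ij ~ Binomial(π_ij, n_ij)
    logit(π_iT) = μ_i + ½ δ_i
    logit(π_iC) = μ_i − ½ δ_i
    δ_i ~ N(δ, τ²)

δ is the overall treatment effect on the log odds ratio (logOR) scale,
τ the between-study SD of the trial-specific effects, and μ_i the trial
baseline on the logit scale. Because the likelihood is binomial at the arm
level, zero-event arms — including double-zero trials — contribute
information directly and no continuity correction is ever applied to the
likelihood. The only place a correction (0.5 added to all four cells of
trials containing a zero cell) appears is in the within-study variances
s_i² = 1/a + 1/b + 1/c + 1/d used to set the scale of the empirical
priors.

Priors: δ ~ N(0, 100) (95% range ±19.6 on the logOR scale) and
μ_i ~ N(μ₀, 100). The centring parameter μ₀ is given a vague N(0, 10⁶)
hyperprior and sampled; describing the baselines as centred on their own
mean is self-referential, and the hierarchical hyperparameter reproduces
that behaviour without circularity. Sensitivity checks during development
(μ₀ ~ N(0,100), μ₀ fixed at the pooled empirical logit, μ_i ~ N(0,100))
moved the case-study posterior medians by under 0.03, so the choice is
immaterial here.

## Heterogeneity priors

Twelve priors are specified on five transformed scales of τ (registry ids
in parentheses):

| id | g(τ) | distribution | label |
|----|------|--------------|-------|
| AG, ag | 1/τ² | Gamma(0.001, 0.001), Gamma(0.1, 0.1) | less / more restrictive |
| AU, du | log τ² | Uniform(−10, 10), Uniform(−10, 1.386) | less / more |
| B, b | τ² | Uniform(0, 1000), Uniform(0, 4) | less / more |
| C, c | τ | Uniform(0, 100), Uniform(0, 2) | less / more |
| DN, dn | τ | Half-normal(0, 100), Half-normal(0, 1) | less / more |
| E | s₀/(s₀+τ) | Uniform(0, 1) | empirical (DuMouchel) |
| e | τ² | Half-normal(0, z₀.₇₅/s₀) | empirical |

Conventions that matter:

* **Half-normal second argument is a variance** (SD = √arg). This is the
  reading under which Half-normal(0, 100) on τ has median 10 × 0.6745 =
  6.75 and 97.5% point 22.4; parameterising by SD would give 67.4 and
  224 instead.
* **Gamma is shape/rate** (the BUGS/JAGS convention).
* **s₀ = √(k / Σ s_i⁻²)**, the square root of the harmonic mean of the
  within-study variances, so s₀ lives on the τ (SD) scale, the shrinkage
  ratio s₀/(s₀+τ) is dimensionless, and the DuMouchel prior median of τ
  is exactly s₀.
* **Prior e**: "Φ[0.75]/s₀" is read as z₀.₇₅ = Φ⁻¹(0.75) ≈ 0.6745 divided
  by s₀ and used as the *variance* of the half-normal on τ². The notation
  is ambiguous (quantile vs CDF value; variance vs SD); this reading is a
  documented choice and nothing in the test suite asserts printed values
  for this prior.

Each prior exposes the density pushed forward to the τ scale (with the
Jacobian of g), the CDF, quantiles (closed-form where available, e.g.
τ_p = s₀(1−u_p)/u_p for DuMouchel) and an i.i.d. sampler. A numerical
caveat: the Gamma(0.001, 0.001) prior on the precision is so heavy-tailed
on τ that its median is ~10¹⁴⁹ and roughly a quarter of its mass lies
beyond the largest IEEE double (~1.8 × 10³⁰⁸). Its normalisation is
therefore verified as density/CDF consistency over the representable
window, and quantile round-trips are only asserted where the quantile is
representable. This is the quantitative content behind printing that
prior's 95% range as unbounded.

## MCMC engine

Inference uses adaptive random-walk Metropolis-within-Gibbs, implemented
as numba kernels. Design choices:

* **τ is sampled on each prior's native scale** g(τ), through an
  unconstrained coordinate (log for positive supports, logit for bounded
  ones) with the Jacobian folded into the target. This avoids τ-scale
  Jacobian bookkeeping per prior and keeps heavy tails (AG) and hard
  bounds (c, du, B) well behaved without gradients.
* Every scalar (δ, μ₀, z, each μ_i, each δ_i) gets a Gaussian random-walk
  proposal whose log-SD is adapted toward a 0.44 acceptance rate by a
  Robbins–Monro step (t^−0.6) **during burn-in only**; the post-burn-in
  kernel is fixed, preserving detailed balance for the retained draws.
* Initialisation: μ_i at the pooled empirical logit with a 0.5 correction
  (finite even for double-zero trials), δ = δ_i = 0, τ at the prior median
  clipped to [0.01, 5], μ₀ at the mean of the μ_i; chains are jittered
  deterministically from the chain seed.
* Chains are bit-reproducible given the configuration seed; per-chain
  seeds derive from it below 2³¹.
* Defaults are 3 chains × 30 000 iterations, burn-in 4500, thinning 3
  (`McmcConfig.fast()`, the simulation-grade setting); the packaged case
  studies use 3 × 850 000, burn-in 150 000, thinning 35
  (`McmcConfig.case_study()`).

Summaries are posterior medians with equal-tailed 2.5–97.5% credible
intervals (matching standard BUGS-style output, not HPD), tail
probabilities P(δ>0)/P(δ<0), and a "beneficial side" probability defined
as the posterior mass on the side of zero containing the median — a
direction-free restatement of the efficacy probability that is robust to
which arm is coded as treatment. Monte-Carlo SEs of medians use the
quantile MCSE estimator (arviz). Diagnostics are split-R̂ and bulk ESS
(arviz) plus lag-1 autocorrelation; a fit is flagged non-converged when
R̂ > 1.05 or ESS < 400 on δ or τ. Non-converged results are returned and
reported, never discarded; the evaluation pipeline includes them in
aggregates (with a `converged_only` switch for sensitivity analysis),
because excluding hard replicates would bias coverage estimates. Note the
ESS < 400 rule is deliberately strict: in very sparse scenarios with short
chains it fires frequently while the aggregate estimates remain usable,
and the per-scenario `n_converged` column makes that visible.

## Simulator

The generator implements independent per-arm study-specific logits:
n_iC = n_iT drawn integer-uniform on [n_low, n_high],
θ_iC ~ N(logit(π_c), (τ/2)²), θ_iT ~ N(logit(π_c) + δ, (τ/2)²)
independently, and binomial event counts with probabilities expit(θ_ij).
Datasets with zero-event arms — or entirely zero events — are retained;
they are the study object.

A consequence worth stating precisely: with independent arms at per-arm SD
τ/2, the SD of the trial-level logOR θ_iT − θ_iC is τ/√2, not τ. The
mechanism is implemented literally as specified, and the τ labelling
follows the scenario grid; but any comparison of "estimated τ" with "true
τ" under this generator should use the effective value τ/√2. One visible
effect at desk scale: at nominal τ = 1 (effective 0.71), the Half-normal(0,1)
prior — whose prior median is 0.674 — produces average posterior medians of
τ closer to the effective truth than the log-uniform prior does, simply
because the truth lands on its prior median. For this reason no test
asserts a generic "least τ bias" ordering; the orderings that are asserted
(overestimation of δ by wide priors, coverage robustness of the
log-uniform prior) are invariant to this labelling subtlety.

Scenario presets: `paper_full_factors` crosses k ∈ {2,4,6}, per-arm n
ranges {[5,10], [40,50]}, π_c ∈ {0.05, 0.1, 0.3}, τ ∈ {0.01, 0.5, 1} and
δ ∈ {0, 0.5, 3} (162 cells, 1000 replicates each); `desk_small` is a
12-cell workstation subset (k ∈ {2,6} × both n ranges × π_c = 0.05 ×
(τ,δ) ∈ {(0.01,0), (0.5,0.5), (1,3)}) at 200 replicates. Replicates use
independent, parallel-safe RNG substreams derived from (scenario seed,
replicate index).

What the generator does *not* emulate: unequal arm sizes, correlated arm
effects, non-normal random effects, selection or publication bias, and
trial-level covariates. Passing tests therefore demonstrate correctness of
the machinery under the stated mechanism, not robustness of the model to
real-world violations of it.

## Evaluation measures

Per scenario × prior: average posterior median of δ, coverage of the
equal-tailed 95% CrI (share of replicates whose interval contains the true
δ), MSE of the posterior median of δ, and average posterior median of τ —
each with an MC standard error (binomial formula for coverage, sample
SD/√reps for means). `comparison_table` flattens results to a tidy long
format (scenario factors × prior × measure × value × mc_se) so any
cross-scenario averaging is explicit in downstream code.

## Case studies and reference values

Two datasets ship as fixtures, transcribed events/non-events per arm:

* **mmn** — multifocal motor neuropathy, intravenous immunoglobulin vs
  placebo, improvement in disability; 3 trials (0/5 vs 0/5, 3/6 vs 0/6,
  4/7 vs 2/7), one double-zero trial.
* **gbs** — Guillain-Barré syndrome, intravenous immunoglobulin vs plasma
  exchange, treatment discontinuation; 4 trials (0/74 vs 12/73,
  0/26 vs 0/24, 3/130 vs 18/121, 1/23 vs 1/24), one double-zero trial.
  These arm totals match the original trials (74 vs 73, 26 vs 24,
  130 vs 121, 23 vs 24).

At long-chain settings the package obtains, under the log-uniform (AU)
prior: posterior median logOR ≈ 2.35 with P(δ>0) ≈ 93% for mmn, and
≈ −2.34 with ≈ 96% beneficial-direction probability for gbs; under the
Half-normal(0,1) (dn) prior: ≈ 2.32 / 97% and ≈ −2.33 / 99%. Across all
twelve priors the mmn posterior median spans roughly (2.24, 3.20) — wide
priors on τ (B, C, DN) push the estimate up by nearly a full log-odds
unit, the central sensitivity this package exists to expose. These values
were cross-checked during development against an independent JAGS
implementation of the same model, which agrees within Monte-Carlo error.

## Problem sizes and tolerances

The test suite runs the case studies at 3 chains × 0.6–2M iterations
(MCSE of the posterior median < 0.02, tolerances ±0.05 on medians and
±1.5 percentage points on tail probabilities), the twelve-prior sweep at
3 × 850k, and the simulation properties at 200 replicates with 3 × 8–20k
chains and 3-MCSE tolerances. The acceptance script fits both case
studies at 3 × 2M in about half a minute. Quadrature tolerances: prior
normalisation to 1e−6; CDF/quantile round-trips to 1e−8.

## Known limitations

* The sampler is single-site random walk; for very diffuse priors (AU,
  AG) the τ chain mixes slowly and long chains are needed for small MC
  error (ESS/draw ≈ 0.01–0.05). Gradient-based samplers would mix better
  but cannot handle the bounded/heavy-tailed priors uniformly.
* Equal arm variances are assumed (the ½δ_i split); alternatives that
  allocate more variance to the treatment arm are out of scope.
* Effect measures other than the log odds ratio (risk ratio, risk
  difference) are not implemented.
* The full 162-cell × 1000-replicate × 12-prior evaluation is
  computationally out of desk range by design; the shipped presets and
  properties cover the crossed factors and the qualitative orderings.
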