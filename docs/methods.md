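# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `coxcal`, in the spirit of the methods
documentation of mature statistical packages. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and residuals

We observe right-censored survival data `(x_i, δ_i, z_i)`, `i = 1..n`,
with `x_i = min(T_i, C_i)`, `δ_i = I(T_i ≤ C_i)` and a fixed `p`-vector
of covariates per subject. The working model is the Cox proportional
hazards intensity

    h_i(t; z_i) = h_0(t) exp(β'z_i) Y_i(t),

with `Y_i(t)` the at-risk indicator. `β` is estimated by Newton–Raphson
on the log partial likelihood; the baseline cumulative hazard by the
Breslow estimator `Λ̂₀(t) = Σ_{t_j ≤ t} d_j / Σ_{l∈R(t_j)} exp(β̂'z_l)`.
Martingale residuals at `t = ∞` are `M̂_i = δ_i − exp(β̂'z_i) Λ̂₀(x_i)`;
the subtracted term is the Cox–Snell residual, the model-expected number
of events for subject `i`. With the Breslow baseline, martingale
residuals sum to zero (at any `β`, not only `β̂`) and Cox–Snell residuals
sum to the total event count — both identities are asserted in the tests
at `1e-8 · n`.

## Grouped sums and their covariance

Subjects are ranked by risk score `r̂_i = β̂'z_i` and cut into `D`
contiguous groups of near-equal size (stable sort; ties broken by
original row order, which matters for heavily tied genotype scores and
makes the grouping a deterministic function of the input). `H_d` sums
the martingale residuals of group `d`; all `D` sums total zero, so one
reference group must be omitted.

Rather than refitting anything, the covariance of the retained `H` is
evaluated analytically: augment the design with the `D−1` indicator
columns `K`, evaluate the score and observed information of the extended
model at `(β̂, γ=0)`, and take the Schur complement
`Σ̂ = J̃_γγ − J̃_γβ J̃_ββ⁻¹ J̃_βγ`. The γ-score at that point equals `H`
exactly (score-test identity), which the tests verify to `1e-8` against
direct summation, and `Σ̂` is verified against (a) a finite-difference
Hessian of the extended log partial likelihood (`≤ 1e-5` relative,
central differences with step `3e-4` — chosen to balance `O(h²)`
truncation against `eps·|ℓ|/h²` roundoff), (b) the freeze-coefficients
recipe in the R `survival` package (values frozen into the test from a
one-off run of survival 3.8-3 on a synthetic fixture), and (c) the
empirical covariance of `H` over repeated null simulations.

Implementation notes:

* The information is assembled without per-event-time loops via
  `Σ_j d_j S₂_j/S₀_j = W' diag(w · Λ₀(x)) W`, reducing the dominant cost
  to two BLAS products; a full `n = 5000` fit takes single-digit
  milliseconds, which is what makes 10,000-replicate studies cheap.
* Internally covariates are centered (the partial likelihood is
  shift-invariant); estimates and the baseline are reported on the
  original scale. The linear predictor is max-shifted before
  exponentiation.
* The extended information is computed once over all `D` indicator
  columns; because every block entry at `γ = 0` is a pairwise functional
  of columns, the blocks for any choice of reference group are exact
  sub-blocks. The global and extreme-risk tests therefore share a single
  information pass in the simulation harness.
* Ties: Breslow and Efron handling are both implemented. Breslow is the
  default because it is exactly internally consistent with the Breslow
  baseline and the Schur-complement algebra above (the score identity is
  exact); Efron (the default of some other survival software) is provided
  for real, tied data and is cross-checked against `lifelines`.
  Simulated event times are continuous, so ties arise with probability
  zero there; tied event/censoring times sort events first.
* Columns with exactly zero variance carry no partial-likelihood
  information; they are pinned at coefficient 0 rather than rejected,
  so degenerate-but-harmless designs (e.g., an all-zero covariate)
  still fit. Collinearity among varying columns raises an error.

## The two tests

**Global (GB) test.** Reference group `D` omitted;
`T = H'Σ̂⁻¹H ~ χ²_{D−1}` under the null. A simulation-based p-value
(same Gaussian engine as below) is available as an option; the
asymptotic χ² is the default. A numerically singular `Σ̂` falls back to
the pseudo-inverse with a warning.

**Extreme-risk (ER) test.** Reference = median group (hence `D` odd;
even `D` is rejected rather than choosing one of the two middle groups
arbitrarily). Scale `H̃_d = H_d/√Σ̂_dd`, `Σ̃ = D_σ^{-1/2} Σ̂ D_σ^{-1/2}`.
The nested symmetric tail sets over the retained groups are
`R_c = {1..c} ∪ {D−c+1..D}`, `c = 1..(D−1)/2`; for `D = 11` that is
{1,11}, {1,2,10,11}, …, up to all ten non-median groups (the full set is
included in the maximization). The statistic is
`T^max = max_c Σ_{d∈R_c} H̃_d² / n_c` with `n_c = 2c`; `T̃_c` squares the
*scaled* sums, the natural reading of "constructed from `H̃`".

The p-value simulates `R` draws from `N(0, Σ̃)` (spectral square root;
negative eigenvalues clipped at zero, since the constraint `Σ_d H_d = 0`
can leave `Σ̃` numerically semidefinite) and counts exceedances. Two
small deliberate deviations from the plain proportion-greater estimator,
both recorded in the result object: add-one smoothing `(1+k)/(R+1)` so
`p` is never exactly zero, and `≥` rather than `>` in the count
(conservative; ties have measure zero under the continuous draws).
Identical seed and inputs give a bit-identical result.

**Group collapsing (`GB_adj`/`ER_adj`).** Opt-in "no fewer than 5
expected events" rule, expected events measured by group sums of
Cox–Snell residuals. Policy (the literature leaves direction
unspecified; this one is ours and deterministic): repeatedly take the
deficient group with the smallest expected count and merge it *toward
the center* — edge groups merge inward, interior groups merge with the
smaller-expected neighbor, ties toward the median — preserving the
identity of the extreme groups as long as possible, since they carry the
ER signal. Collapsing below three groups is an error. The default is
**no collapsing**: at the sample sizes studied (`n ≥ 1500`) collapsing
rarely changes type-I error and can cost power, so it is exposed as a
flag rather than applied silently.

## Simulator

Cohorts are generated from the Weibull intensity
`h_i(t) = λ α t^{α−1} exp(g_i)` so that
`T_i = (−log U_i / (λ e^{g_i}))^{1/α}` by inverse-CDF (validated against
the closed-form CDF by Kolmogorov–Smirnov at `n = 10⁵`). The predictor
families `g01/g02/gA1/g03/gA3/gA4` cover: correctly specified SNP main
effects; an omitted environmental exposure; omitted single or per-SNP
gene–environment interactions; omitted Gaussian-covariate interaction;
and additive (non-multiplicative) genotype effects
`g = log(1 + Σ β_j G_j)` with a positivity guard.

Default study conditions follow the simulation design the tests were
characterized under: SNP genotypes `Binomial(2, MAF=0.3)` (Hardy–
Weinberg), per-SNP log hazard ratio `log(1.2)` for `p = 5` and
`log(1.15)` for `p = 10`, exposure `Bernoulli(0.3)` with main effect
equal to the SNP effect, `α ∈ {0.3, 1, 3}` for decreasing/constant/
increasing baseline hazards, ten-year administrative horizon, `D = 11`
groups, `R = 1000` inner draws. For the additive family the coefficient
is specified directly; a helper maps it to the marginal fitted hazard
ratio via a pilot simulation (coefficients 0.3–1.2 correspond to
marginal HRs ≈ 1.16–1.29 at `p = 5`, inside the intended 1–1.4 band).

**Event-rate calibration.** `λ` solves
`E_g[1 − exp(−λ·10^α·e^g)] = target` by bracketed root-finding to
`|rate error| < 1e-6`. The expectation is exact for the finite
genotype/exposure covariate spaces — the distribution of `g` is built by
sequential convolution of per-SNP three-point distributions (with equal
per-SNP effects this collapses to a Binomial(2p, MAF) allele count) —
and uses a deterministic scrambled-Sobol quasi-Monte Carlo grid of
`2^17` points for Gaussian covariates.

**Censoring.** Administrative censoring truncates at 10 years. Lost to
follow-up is modelled as an independent `C_i ~ Uniform(0, τ_c)` per
subject, with `τ_c` calibrated so the expected fraction of subjects
censored before `min(T_i, 10)` equals the target;
`f(τ) = E[min(T, 10, τ)]/τ` is strictly decreasing from 1 toward 0, so
any target rate in (0, 1) has a unique solution (a 50% target at a 20%
event rate gives `τ_c ≈ 17.9` years — draws beyond the horizon simply
act as administrative censoring). Fixing the upper support at the
10-year horizon instead would bound the achievable rate *below* by
`E[min(T,10)]/10 ≈ 0.9` under these event rates, so an unbounded support
is the only uniform mechanism that can realize moderate loss rates; the
calibration round-trips to `0.50 ± 0.01` at `n = 10⁵` in the tests.

All randomness descends from one seed through three named substreams
(covariates, event times, censoring), so scenarios differing in one
mechanism share the other draws; identical seeds reproduce datasets
byte-for-byte.

**What the simulator does not emulate.** Linkage disequilibrium between
SNPs, covariate measurement error, informative censoring, competing
risks, calendar-time effects, and real-cohort covariate correlation
structures. Passing tests therefore demonstrate correctness of the
statistics and their null calibration under clean, independent
covariates — not robustness on messy clinical data.

## Study sizes used in the checked experiments

Type-I error is verified with 2,000 replicates per cell in the test
suite (binomial 3·SE band ≈ ±0.015 around the tabulated rates) and
10,000 replicates per cell in `scripts/acceptance.py`; power orderings
use 500 replicates per effect-size grid point with 500 inner ER draws
(recorded in the outputs), at grid points chosen where the tail tests'
power is intermediate rather than saturated. The null-distribution
checks (mean of the global statistic vs `D−1`; Kolmogorov–Smirnov
uniformity of ER p-values) reuse the 2,000-replicate primary-cell study.

## Known limitations

* Fixed covariates and right censoring only; no left truncation,
  stratification, time-varying effects or penalized estimation.
* The tests evaluate the linear predictor's calibration in the training
  sample; they are insensitive to bias in a baseline hazard transported
  to an external cohort.
* Asymptotic behaviour of `Σ̂` requires enough events per group; with
  very few events (`≪ 5` per group) use the collapsing variants, accept
  conservatism, or more data.
* The grouped statistics are conditional on the estimated grouping; the
  group boundaries themselves are treated as fixed, as is standard for
  this family of tests.
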