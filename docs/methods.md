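# Methods

## Model and estimation

The package treats exactly one design: two groups (control x = 0,
experimental x = 1), right-censored responses, proportional hazards
λ(t | x) = λ₀(t) e^{xβ}.  The baseline hazard is never estimated — it
cancels out of the partial likelihood, so the whole analysis is a function
of the time *ranks*, the event indicators and the group labels.  Two
consequences are load-bearing and tested: multiplying all times by any
positive constant changes nothing (scale invariance), and with only
rank-based target statistics the reconstruction's t_max bound is
inconsequential.

Ties are handled with Efron's approximation: for a distinct event time with
d tied events, the denominator at tie position l ∈ {0..d−1} subtracts the
fraction l/d of the tied subjects' risk contributions.  With a single
binary covariate every risk-set sum reduces to four counts per event time
(at-risk and tied-event counts per group), which are precomputed once per
dataset; each likelihood, score or information evaluation is then a few
vectorised operations over one array entry per event.  This is what makes
the particle-swarm loop (thousands of Cox fits per reconstruction)
affordable.  Subjects censored at an event time remain in that risk set
(events precede censorings), and tie grouping uses exact floating-point
equality — the reconstruction machinery manipulates times continuously and
must control ties explicitly, so readers never round input times.

β̂ is found by Newton–Raphson with analytic score and observed information,
started at 0, with step-halving as a guard (the scalar log partial
likelihood is concave, so halving rarely triggers).  Convergence:
|score| < 1e−9 or step < 1e−10, hard cap 50 iterations.  |β̂| > 20 is
declared a monotone-likelihood divergence — e^{±20} is far outside any
interpretable hazard ratio, and the classic separation geometry (all events
in one group preceding the other group's times) drives β̂ to ±∞.  SE(β̂) is
the inverse root of the observed information at β̂; the HR interval is Wald,
exp(β̂ ± z·SE).

Kaplan–Meier summaries use the product-limit estimator with Greenwood's
variance on the log-survival scale.  The median is the first time S(t) ≤ 0.5;
its interval is the Brookmeyer–Crowley construction — the set of times whose
pointwise log-scale CI for S(t) straddles 0.5 — with bounds reported as
undefined (None) when a confidence curve never crosses 0.5.  The variance
transformation is a package default, chosen to match the dominant
survival-analysis convention; it is deliberately kept in one function so an
alternative transformation is a local change.

## Bayes factors

BF₁₀ = ∫_{Ω₁} e^{ℓ(β)} f(β) dβ / e^{ℓ(β₀)}, with f a Normal(μ, σ²) prior on
β truncated to Ω₁ and renormalised for one-sided hypotheses.  Defaults
μ = 0, σ = 1 (unit-information scale on the log hazard ratio: HR values
between roughly 1/7 and 7 within ±2σ), β₀ = 0.

Numerics: the integrand is recentred by ℓ evaluated at β̂ clipped to Ω₁, so
it peaks near 1; adaptive Gauss–Kronrod quadrature (scipy's QUADPACK,
relative tolerance 1e−10, β̂ passed as a known peak) runs on the finite
interval Ω₁ ∩ [min(μ−10σ, β̂−12SE), max(μ+10σ, β̂+12SE)], which contains all
but ~e^{−50} of both prior and likelihood mass.  If the adaptive error
estimate is unreliable (non-positive value or estimated relative error
above 1e−6), a fixed 61-node Gauss–Legendre rule on β̂ ± 12SE ∩ Ω₁ is used
instead and flagged in the result's diagnostics.  All arithmetic is in log
space; bf10 is exponentiated only on output.  A dataset with zero events
has a constant partial likelihood, so the prior integrates to 1 and the
function returns BF₁₀ = 1 exactly rather than raising — the "no
information" reading of a flat likelihood.

The Savage–Dickey route approximates the likelihood by Normal(β̂, SE²).
With the conjugate Normal prior the posterior is Normal with
v = (SE⁻² + σ⁻²)⁻¹ and m = v(β̂/SE² + μ/σ²), and BF₁₀ is the
prior-over-posterior ordinate ratio at β₀; two-sided, this is the closed
form quoted in the module docstring.  One-sided priors are handled by the
same ordinate ratio with *truncated* prior and posterior densities — a
package extension of the two-sided formula, exact under the same Normal
approximation, and cross-checked numerically in the tests.

A regime note that the test suite encodes: the approximation error
|log BF_exact − log BF_SD| shrinks with n only while β₀ remains inside the
likelihood's bulk.  Under a fixed nonzero effect, (β̂ − β₀)/SE grows like
√n, the null ordinate recedes into the tail, and the cubic term of the
Laplace expansion — of order n·(β₀ − β̂)³ — makes the gap *grow*.  The
convergence property is therefore asserted under a true null, where the
skewness error is O(n^{−1/2}); under strong effects the Savage–Dickey value
should be treated as an order-of-magnitude statement only.

Evidence labels (Jeffreys, Lee–Wagenmakers, Kass–Raftery schemes) are
half-open-interval lookups with BF < 1 classified via 1/BF and flagged
toward H0; they are rules of thumb, not calibrated quantities.

## Reconstruction from summary statistics

Inputs: per-group sample sizes n_c, n_e and event counts v_c, v_e (these
are matched *exactly* by construction, never optimised), plus target
statistics E — by default the hazard ratio and its CI bounds; optionally
Kaplan–Meier medians with CIs, which require a t_max.  Starting times are
Uniform(1, t_max) — the shape is arbitrary since the multiplicative
adjustment can reach any configuration in [1, t_max]ⁿ — with the event and
group vectors laid out in blocks.  The loss is

  φ(ξ) = log[ mean_r ( ((O_r − E_r)/E_r) · w_r )² ],

with the weight inside the square (the formula, not the looser prose
reading), O recomputed from the candidate times e^{ξ}∘Y at every
evaluation, and perfect matches floored at log(1e−300) to keep swarm
arithmetic finite.  An undefined KM median in a candidate dataset is scored
as a huge deviation rather than an error, steering the swarm away without
killing the run.  Default weights (2, 1, 1) on (HR, CI_lb, CI_ub) with KM
excluded: matching β̂ and its SE (equivalently HR and its CI) is what pins
the likelihood's location and curvature, hence the Bayes factor; KM targets
add noise to that objective.

The optimiser is a self-contained SPSO-2007: swarm size ⌊10 + 2√d⌋ with
d = n_c + n_e, inertia 1/(2 ln 2), cognitive = social = 0.5 + ln 2, K = 3
random informants per particle re-randomised after any non-improving
iteration, reflecting bound handling (clip to the bound, damp and reverse
the velocity component).  ξ = 0 — the raw uniform draw — is seeded as
particle 0, so the returned optimum is never worse than the evaluated
start.  Bounds are the static per-coordinate [log(1/Y⁰_i), log(t_max/Y⁰_i)]
of the initial times; re-bounding every iteration reaches the same set, so
the static form is used for its simpler interface.  Stopping: max_iter
iterations (default 300; 100–300 is the sensible band, and HR-only targets
converge in well under 100) or ⌈max_iter/5⌉ consecutive iterations without
improvement of the swarm best.

Replicate r uses master_seed + r; the initial-times draw uses
default_rng(seed) and the swarm uses default_rng([seed, 1]), making every
replicate independently reproducible from the recorded master seed.
Replicates whose Cox fit diverges at the optimum are flagged, counted and
excluded from the Bayes-factor distribution rather than aborting the batch.

`weight_sweep` reruns the reconstruction under several loss configurations
against one source dataset and tabulates the bias and variance of the
reconstructed log Bayes factors around the full-data value, with a shared
master seed so the comparison is paired on the starting draws.

## Synthetic data

`simulate_survival` draws exponential event times with control hazard
`baseline_rate` and experimental hazard `baseline_rate · e^{β_true}` —
proportional hazards holds by construction, and since Cox inference is
baseline-agnostic the exponential shape costs no generality for what the
package tests.  Censoring is independent exponential (expected censoring
fraction ≈ λ_c/(λ_c + λ_event) per group) plus an optional administrative
cutoff.  `rescale_min_time` multiplies all times so the minimum is 1,
putting simulated data on the [1, t_max] scale the reconstruction assumes
without touching the partial likelihood.

What the generator does *not* emulate: covariate-dependent or informative
censoring, non-proportional hazards, discrete/rounded times as recorded in
real registries (beyond the tie-handling tests, which induce ties by
rounding), and staggered accrual.  Passing tests therefore demonstrate
correctness of the machinery and internal consistency of the two Bayes
factor routes under proportional hazards with independent censoring — not
robustness of the Cox model itself to violations of those assumptions.

`make_fixture` provides three synthetic stand-in datasets whose *total*
sample sizes (76, 228, 929) match three classic survival datasets widely
used to exercise survival software; the group splits, effect sizes and
~30–60% censoring fractions are package choices, since the originals'
censoring patterns are not reproduced here.

## Problem sizes and defaults used in validation

The shipped validation runs use: a 60 + 60 source trial with β = 0.4 and
~30% censoring for end-to-end reconstruction recovery (20 replicates,
max_iter 300); 20-replicate HR-only runs at t_max ∈ {100, 10000} for the
t_max-irrelevance check (max_iter 100, ample for a one-statistic target);
200 replicates at 200 per group for parameter recovery; 50 replicates at
n ∈ {200, 1000} under the null for the Savage–Dickey convergence check.
These sizes were chosen so each property is measured with comfortable
statistical margin while a full validation pass stays in the
few-minutes range on a single core; recovery margins observed are
order-of-magnitude clear of the asserted bounds (median |Δ log BF| from
reconstruction ≈ 0.004 against a bound of 0.05).

## Known limitations

* One binary covariate only: no stratification, no additional covariates,
  no Breslow or exact-tie partial likelihoods.
* The one-sided Savage–Dickey ordinate ratio is an extension defined by
  this package (exact under the Normal-likelihood approximation), not a
  standard printed formula.
* Reconstruction quality is only as good as the published statistics: with
  HR but no CI the curvature of the likelihood is weakly constrained, and
  the Bayes-factor spread across replicates widens accordingly; the spread
  is the diagnostic, not a nuisance.
* PSO is stochastic and derivative-free; the loss reached, not the
  iteration count, is the meaningful convergence indicator.  Extremely
  large studies (thousands of subjects) make each loss evaluation and the
  search space proportionally larger.
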