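# coxbf

Bayes factors for two-group Cox proportional hazards regression — from full
time-to-event data, or from nothing more than the summary statistics a
published article reports.

## Who this is for

Clinical and biomedical researchers analysing time-to-event outcomes
(survival, time to recovery, time to relapse) who want to quantify evidence
*for or against* a treatment effect rather than only reject a null
hypothesis, and meta-researchers reanalysing published trials whose raw data
are not available.

## The model and the statistic

For subject *i* we observe a response time *Y<sub>i</sub>*, an event
indicator *δ<sub>i</sub>* (1 = event, 0 = right-censored) and a group
indicator *x<sub>i</sub>* (0 = control, 1 = experimental).  The Cox model

&nbsp;&nbsp;&nbsp;&nbsp;λ(t | x) = λ₀(t) e<sup>xβ</sup>

leaves the baseline hazard λ₀(t) unspecified; the hazard ratio is
HR = e<sup>β</sup>.  Inference uses Efron's approximation to the partial
likelihood, which handles tied event times and reduces to the exact Cox
partial likelihood when all event times are distinct.

The evidence for H1 (an effect, β restricted to Ω₁) against H0 (β = β₀,
usually 0) is the Bayes factor

&nbsp;&nbsp;&nbsp;&nbsp;BF₁₀ = ∫<sub>Ω₁</sub> f(D | β) f(β) dβ / f(D | β₀),

where f(D | β) = exp(ℓ(β)) is the Efron partial likelihood and f(β) is a
Normal(μ, σ²) prior on the log hazard ratio, truncated to Ω₁ and
renormalised for one-sided hypotheses.  The integral is evaluated by
adaptive Gauss–Kronrod quadrature after recentring at the likelihood
maximum.

Three workflows:

* **Full data** — `bayes_factor_full(data, prior)` computes BF₁₀ exactly.
* **Summary statistics only** — `reconstruct(stats, ...)` reverse-engineers
  pseudo-raw datasets whose fitted statistics match the published per-group
  sample sizes and event counts, hazard ratio and CI (optionally
  Kaplan–Meier medians): times start Uniform(1, t_max), are adjusted
  multiplicatively Y′ = e<sup>ξ</sup>Y, and ξ is chosen by particle swarm
  optimisation to minimise the log mean squared weighted relative deviation
  between observed and published statistics.  Each reconstructed dataset
  yields one Bayes factor; their spread shows how strongly the published
  numbers constrain the answer.
* **Closed-form approximation** — `savage_dickey_bf(beta_hat, se, prior)`
  approximates the likelihood by Normal(β̂, SE²) and returns the
  Savage–Dickey ordinate-ratio Bayes factor; fast, and accurate when β₀ lies
  within the likelihood's bulk.

## Worked example

```python
import numpy as np
from coxbf import (PriorSpec, SimulationSpec, simulate_survival, fit_cox,
                   bayes_factor_full, summary_stats_from_data, reconstruct,
                   rescale_min_time, classify_evidence)

# a synthetic trial: 60 + 60 subjects, true log HR = 0.4, ~30% censoring
data = rescale_min_time(simulate_survival(SimulationSpec(
    n_control=60, n_experimental=60, beta_true=0.4,
    baseline_rate=1.0, censor_rate=0.6, seed=314)))

fit = fit_cox(data)
print(f"HR = {fit.hr:.3f}, 95% CI [{fit.ci_lower:.3f}, {fit.ci_upper:.3f}]")

prior = PriorSpec(mu=0.0, sigma=1.0, side="greater")   # superiority H1
full = bayes_factor_full(data, prior)
print(f"BF10 = {full.bf10:.3f}  ({classify_evidence(full.bf10)})")

# now pretend only the summary statistics were published
stats = summary_stats_from_data(data)
recon = reconstruct(stats, n_datasets=20, max_iter=300, prior=prior,
                    rng_seed=2024)
log_bf = recon.log_bf_values
print(f"reconstructed BF10 range [{np.exp(log_bf.min()):.3f}, "
      f"{np.exp(log_bf.max()):.3f}]")
```

prints

```
HR = 1.745, 95% CI [1.121, 2.717]
BF10 = 8.370  (substantial evidence for H1)
reconstructed BF10 range [8.342, 8.522]
```

The full-data Bayes factor of 8.37 means the data are about 8 times more
likely under the superiority hypothesis than under HR = 1.  The twenty
Bayes factors recomputed from the hazard ratio and its CI alone span
[8.34, 8.52]: the published summary statistics pin the evidence down almost
exactly, which is the point of the reconstruction route.

The same analyses are available from a shell:

```sh
coxbf simulate --nc 60 --ne 60 --beta 0.4 --censor-rate 0.6 --seed 314 --out trial.csv
coxbf bf --input trial.csv --has-header --alternative greater
coxbf reconstruct --nc 60 --ne 60 --vc 34 --ve 49 --hr 1.745 \
    --ci-lower 1.121 --ci-upper 2.717 --n-datasets 20 --seed 2024 \
    --alternative greater --out recon.csv
coxbf sd-approx --beta-hat 0.557 --se 0.226 --alternative greater
```

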