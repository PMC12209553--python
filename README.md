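# cfrail

Recurrent-event survival analysis for cluster randomised trials.

Many trial outcomes are events that can happen to the same participant
repeatedly — medical contacts, asthma exacerbations, prescription
collections.  Standard analyses (a negative-binomial count model, a Cox
model of the first event) discard the timing or the recurrence
structure.  `cfrail` implements the counting-process toolbox for
analysing such outcomes when randomisation is by intact cluster (e.g.
GP practice), so that within-cluster correlation, within-participant
event dependence, and an increasing risk of subsequent events are all
modelled rather than ignored.

## The models

Events are described by their intensity — the instantaneous event rate
conditional on history.  The family of multiplicative intensity models
fitted by the package, for participant *i*, event number *k* and
covariates *Z*:

| model | intensity | clustering |
|---|---|---|
| Andersen–Gill (AG) | λ₀(t) exp(βᵀZ) | robust SE |
| PWP total-time | λ₀ₖ(t) exp(βᵀZ) | robust SE |
| PWP gap-time | λ₀ₖ(t − t_{k−1}) exp(βᵀZ) | robust SE |
| conditional frailty (CF) | λ₀ₖ(t − t_{k−1}) exp(βᵀZ + w_g) | frailty w_g |

The centrepiece is the **conditional frailty model**: the
Prentice–Williams–Peterson gap-time model (event-number-specific
baseline hazards λ₀ₖ, conditional risk sets — nobody is at risk of
event *k* before experiencing event *k−1*) extended with a shared
random effect at **cluster** level.  The frailty u_g = exp(w_g) has
mean 1 and variance θ (gamma by default; log-normal as a sensitivity
analysis).  Treatment effects are reported as intensity ratios
IR = exp(β_arm), globally or per event number, with Wald 95% intervals.

Around the core model the package provides:

* counting-process data preparation from raw event histories
  ((start, stop] rows, gap or total clock, event-number strata,
  zero-event and practice-drop-out censoring);
* Firth's penalised partial likelihood for rare recurrent events and
  monotone-likelihood (separation) problems, with events-per-variable
  advisories;
* truncation of sparse later-event risk sets, with the standard
  5% / 2% / 1% / 0.5% / 0.25% population thresholds;
* diagnostics: per-event-number cumulative hazard curves (event
  dependence), and likelihood-ratio / Wald tests of the frailty
  variance (clustering), with the boundary-corrected χ²₀:χ²₁ mixture
  reference available;
* the Nelson–Aalen mean cumulative function (MCF) by treatment group;
* a synthetic cluster-trial generator with exactly the structure the CF
  model assumes, for testing and power exploration.

## Worked example

```python
import numpy as np
from cfrail import (SimulationConfig, simulate_trial, build_counting_process,
                    max_stratum_for_threshold, truncate_events, ModelSpec,
                    fit_conditional_frailty, fit_cox, frailty_lrt, global_effect)

cfg = SimulationConfig(seed=42)          # 50 practices x 40 subjects, 122 days,
histories, truth = simulate_trial(cfg)   # gamma frailty theta=0.5, true IR 0.8

table = build_counting_process(histories, window_end=122, clock="gap")
table = truncate_events(table, max_stratum_for_threshold(table, 10))

spec = ModelSpec(clock="gap", stratified=True, frailty="gamma",
                 covariates=("age", "sex", "prior_count"))
fit = fit_conditional_frailty(table, spec)
lrt = frailty_lrt(fit, fit_cox(table, spec.with_(frailty="none")))
est = global_effect(fit)
print(f"IR {est.ir:.3f} (95% CI {est.ci_lower:.3f}, {est.ci_upper:.3f})")
print(f"frailty variance {fit.theta:.3f}, LRT p = {lrt.pvalue:.2g}")
```

Output:

```
IR 0.724 (95% CI 0.494, 1.061)
frailty variance 0.467, LRT p = 7.4e-287
```

The fitted intensity ratio 0.724 estimates the generating IR of 0.8 for
this single replicate (cluster-level randomisation with θ = 0.5 makes
single-trial arm estimates noisy — the CI is wide because only 25
clusters sit in each arm, which is exactly what the frailty term is
there to reflect).  The frailty variance 0.467 estimates the generating
θ = 0.5, and the LRT correctly finds strong evidence of clustering.

The same pipeline is scriptable from the shell:

```
cfrail simulate trial.csv --seed 42
cfrail prepare trial.csv table.csv --window-end 122 --clock gap
cfrail fit table.csv --covariates age,sex,prior_count --frailty gamma
cfrail run --config analysis.yaml     # full workflow with reports
```

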