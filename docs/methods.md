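# Methods

This note records the statistical procedures implemented in `cfrail`,
the modelling assumptions behind them, the numerical choices made where
the design was genuinely open, and what the synthetic-data checks do
and do not establish.

## Counting-process representation

Raw data are per-participant event histories: cluster, arm, baseline
covariates, an ordered list of event times (days from the
analysis-period start) and a follow-up end (the minimum of the analysis
window and the cluster's data cut-off).  `build_counting_process` turns
these into (start, stop] risk intervals stratified by cumulative event
number *k*:

* every event inside the window yields a status-1 row in stratum *k*;
* observation continuing past the last event yields one terminal
  status-0 row, emitted only when its interval has positive length;
* zero-event participants contribute a single censored stratum-1 row —
  no participant is ever dropped;
* under the **gap clock** every row starts at 0 and stops at the time
  since the previous event; under the **total clock** rows carry
  delayed entry on study time.

The framework assumes no two events are simultaneous, so same-day
duplicates are collapsed to one event by default; the alternative
`spread` policy distributes *d* same-day events at equal sub-day
increments.  Neither policy is asserted to be what any particular study
did — day-resolution sources rarely document it.

Risk-set tabulation defines the number at risk for stratum *k* as the
number of participants with at least *k−1* events (the conditional
risk-set rule), reports zero-event participants as censored at 0 days
within stratum 1, and counts cumulative events on each stratum's own
clock.

Truncation caps events per participant: thresholds are
floor(fraction × population), a stratum is retained only when its risk
set *strictly* exceeds the threshold, and retained rows are unchanged.
The shipped sensitivity fractions are 5%, 2%, 1%, 0.5% and 0.25%.

## Partial likelihood engine

The engine maximises the stratified Cox partial likelihood on
counting-process data by Newton–Raphson with step-halving,
initialised at β = 0.  Risk-set sums S₀, S₁ at each event time are
computed as differences of suffix sums over stop-sorted and
start-sorted rows, which is exact for delayed entry, costs
O(n log n + n p²) per stratum independent of the number of distinct
event times, and avoids cancellation against the stratum total (the
entry-side term vanishes identically under the gap clock).  A linear
predictor is always centred by its stratum maximum before
exponentiation; candidate steps whose exponentials still underflow an
entire risk set evaluate to −∞ and are rejected by the line search.
Structurally empty risk sets (a data error) are reported with the
stratum and time.

Numerical policy:

* **Ties.** Efron's correction is the default, Breslow available; the
  two coincide exactly on tie-free data.  Efron gradients, Hessians and
  score residuals are derived through the pseudo-risk-set
  decomposition, so the residuals sum exactly to the score.
* **Convergence.** Relative log-likelihood change < 1e−9 and gradient
  max-norm < 1e−6, at most 50 iterations.
* **Separation.** A coefficient beyond ±10 with the score still
  pushing outward flags monotone likelihood; the fit stops and
  recommends Firth penalisation instead of wandering to a
  pseudo-optimum.
* **Rank deficiency** is detected on the correlation-scaled information
  at β = 0 and reported with the implicated columns.

**Firth penalisation** maximises log Lp(β) + ½ log det I(β).  The
penalty gradient is computed by central finite differences of the
log-determinant (2p extra Hessian evaluations per iteration), which
avoids assembling third-derivative tensors; p is small in all intended
uses.  On the canonical two-subject separation problem the penalised
estimate is log 3, which the implementation reproduces to 1e−6.

**Robust (cluster sandwich) covariance** aggregates score residuals
within cluster: I⁻¹ (Σ_g s_g s_gᵀ) I⁻¹.  With one subject per cluster
it reduces to the subject-level sandwich.

**Baseline hazards** are Breslow-type per stratum (jump = events at t
divided by the risk-set sum of exp(βᵀZ)), reducing to Nelson–Aalen at
β = 0 in a single stratum.

## Conditional frailty model

The conditional frailty model adds a cluster-shared log-frailty w_g to
the PWP gap-time linear predictor.  Estimation follows the penalised
partial likelihood scheme: cluster indicators enter the design as
additional columns whose coefficients w are penalised by

* gamma (default, shape = rate = 1/θ): (1/θ) Σ_g (w_g − e^{w_g}),
  whose stationary points coincide with the EM solution of the marginal
  gamma-frailty likelihood at fixed θ;
* log-normal: ridge −Σ_g w_g²/(2s²) with s² = log(1+θ), so that the
  frailty-scale variance is θ and θ is comparable across the two
  distributions.

The inner Newton iteration solves (β, w) jointly at fixed θ.  The outer
profile maximises the **integrated** likelihood over θ ∈ [0, 10]
(coarse log-spaced grid, then bounded refinement; estimates pinned at
the cap raise a warning; estimates below 2e−3 that do not beat the
boundary collapse to θ = 0, reproducing the no-frailty fit exactly).
For the gamma distribution the integrated likelihood has the closed
form

  Σ_events (η_e + log λ₀(t_e)) + Σ_g [ν log ν − log Γ(ν)
    + log Γ(ν + d_g) − (ν + d_g) log(ν + A_g)],  ν = 1/θ,

with d_g the cluster's event count and A_g its accumulated baseline
hazard scaled by exp(η); for the log-normal a Laplace approximation
around the penalised solution is used.  Both reduce analytically to the
no-frailty full likelihood as θ → 0, which makes likelihood-ratio
comparisons across θ well defined; on shared data the implementation
agrees with R `survival::coxph(frailty.gamma(..., sparse=FALSE))` to
six decimals in both the integrated likelihood and the coefficients
(asserted in the test suite).  Baseline jumps inside the integrated
likelihood are Breslow-form regardless of the fixed-effect ties
correction — a documented convention, as tie corrections for the
integrated likelihood are not standardised.

Fitted gamma frailties are centred to mean 1 (the multiplicative shift
is absorbed by the baseline, leaving β unchanged).  Fixed-effect
covariances come from the inverse penalised information, so they
account for frailty-estimation uncertainty at fixed θ.

### Testing the frailty term

* **LRT**: 2 × (integrated log-likelihood at θ̂ − no-frailty
  log-likelihood), clamped at 0.  Because θ = 0 lies on the boundary of
  the parameter space, the asymptotic null is the 50:50 mixture of χ²₀
  and χ²₁ rather than plain χ²₁; the plain χ²₁ p-value is the default
  report (the conservative, conventional choice) and the mixture
  p-value is always reported alongside and used when
  `boundary_correction=True`.
* **Wald**: (θ̂/SE)² against χ²₁, with SE from a central second
  difference of the profile integrated log-likelihood at θ̂.  This is a
  documented stand-in — Wald constructions for variance components are
  not standardised — and θ̂ = 0 is reported as degenerate (p = 1), not
  an error.
* The effective degrees of freedom of the frailty term use the trace
  identity tr(I_pen⁻¹ I_unpen) over the frailty block.

## Headline outputs

Intensity ratios are exp of the arm coefficient with Wald 95% intervals
on the log scale (the robust SE when the fit carries one).
Event-specific effects come from **one joint fit** with an
arm-by-stratum interaction and all other covariates shared across event
numbers — not separate per-stratum fits — preserving the common frailty
and covariate structure; on frailty-free data with no shared covariates
the joint fit decouples into the per-stratum fits (asserted).  Strata
with zero events in either arm are excluded from the interaction and
flagged non-estimable rather than silently dropped; strata whose
interaction coefficient walks past ±10 are flagged as quasi-separated.
No multiplicity correction is applied to event-specific p-values by
default (they are planned, limited comparisons); the Bonferroni level
is computed on request.

The rare-events advisory recommends Firth penalisation when fewer than
1% of participants have recurrent (≥2) events or fewer than 20 per
predictor, and reports the 10-per-variable and 6-per-variable EPV
minima for context.  The sensitivity suite refits the global effect
over the truncation-fraction grid and both frailty distributions,
recording per-variant failures without aborting.

## Mean cumulative function

The MCF (expected cumulative events per participant) is estimated by
the Nelson–Aalen estimator applied to the recurrent-event counting
process: jumps dN·(t)/Y·(t) at observed event times, ties contributing
one pooled jump, with the J(t) guard skipping times with an empty risk
set.  Participants stay in Y·(t) through their follow-up end however
many events they have had — the MCF counts recurrences, unlike the
conditional risk sets of the PWP table.  The at-risk definition is
follow-up-based (practice drop-out removes a subject from Y at its
cut-off), a documented choice.  The merged-population curve equals the
at-risk-weighted combination of group increments at every jump time
(exact identity, asserted).

## Synthetic trial generator

The generator draws from exactly the process the CF model assumes:
clusters randomised 1:1; one mean-1 frailty per cluster (gamma, or
log-normal matched to variance θ); sequential gap times by inverse
transform from stratum-specific Weibull hazards (shape 1 = constant
rates), scaled by exp(βᵀZ + w_g); censoring by the window end and by
cluster drop-out.  Times are continuous in day units: whole-day
rounding is available but off by default, because rounding plus
same-day collapsing aliases the generative intensity and would entangle
discretisation with estimator behaviour in recovery checks.

Reference scenario (the package default): 50 clusters × 40 subjects,
122-day window, gamma θ = 0.5, arm log-IR = log 0.8, stratum-1 gap rate
1/60 per day rising to 1/30 by event 6 (later events reuse the last
rate, emulating increasing risk of subsequent events), covariates age ~
U(5, 16) years (log-intensity +0.01/yr), sex ~ Bernoulli(½) (−0.10),
prior-period event count ~ Poisson(2) (+0.08), 5% cluster drop-out
uniform over the final three quarters of the window.  These produce
roughly three events per participant with ~15% zero-event participants
— the regime of a school-age asthma contact outcome.

What the generator does *not* emulate: seasonal/holiday hazard shapes,
informative (outcome-dependent) drop-out, covariate measurement error,
and participant-level frailty nested within cluster.  Passing recovery
tests therefore show the estimator is correct under its own model, not
that the model is correct for any particular dataset.

## Verification studies and problem sizes

* **Parameter recovery** (test suite): 20 seeded replicates of the
  reference scenario; the means of β̂_arm and θ̂ must fall within 2
  Monte-Carlo SEs of the generating values.  Runs in about a minute.
* **LRT size** (test suite): 500 seeded replicates with θ = 0, 200
  clusters × 6 subjects.  The boundary-mixture reference is asymptotic
  in the *number of clusters*, and the approach is slow: in pilot scans
  the empirical size under the mixture reference was roughly 2% with
  30–100 clusters and only reached the nominal 5% around 200 clusters
  (cluster counts of this order are typical of large
  practice-randomised studies).  The check therefore uses 200 clusters,
  where the reference applies, and asserts the empirical size sits in
  the 99% binomial band around 5%; the finite-cluster conservatism at
  smaller G is a property of the test itself, worth remembering when
  interpreting non-significant frailty LRTs in trials with few
  clusters.
* **Oracles**: brute-force risk-set enumeration, central finite
  differences, 1-D grid search, closed-form toys, R `survival` and
  `lifelines` cross-checks, all on small fixtures.

`scripts/acceptance.py` repeats the deterministic rules and toys
exactly and runs reduced replicate counts (20 recovery, 200 size) to
stay within a few minutes; the test suite carries the full-size
studies.

## Known limitations

* Time-varying covariates are out of scope (internal covariates would
  require joint modelling of the covariate process).
* The Firth-with-frailty composition penalises the fixed-effect
  information block only, with the frailty handled by its own penalty —
  a minimal composition; the interaction between the two penalties is
  not standardised in the literature.
* The log-normal integrated likelihood is a Laplace approximation; its
  LRT is therefore approximate.
* Profile-likelihood unimodality in θ is checked on shipped scenarios,
  not guaranteed globally.
* The Wald test for θ relies on local quadratic behaviour of the
  profile likelihood, which is doubtful near θ = 0.
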