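# Methods

## Natural-history model

The disease process is a continuous-time, age-inhomogeneous Markov chain
over nine health states (normal, small adenoma, large adenoma, preclinical
early CRC, preclinical late CRC, clinical early CRC, clinical late CRC,
CRC death, other-cause death; the last two absorbing). Non-zero
transition intensities:

| transition | rate | default (generative) value |
| --- | --- | --- |
| normal → small adenoma | λ₁(a) = l·γ·a^(γ−1) | l = 2.86e−6, γ = 2.78 |
| small → large adenoma | λ₂ | 0.0346 /yr |
| large adenoma → preclin. early | λ₃ | 0.0215 /yr |
| preclin. early → preclin. late | λ₄ | 0.3697 /yr |
| preclin. early → clinical early | λ₅ | 0.2382 /yr |
| preclin. late → clinical late | λ₆ | 0.4582 /yr |
| clinical early → CRC death | λ₇ | 0.0302 /yr (external) |
| clinical late → CRC death | λ₈ | 0.2099 /yr (external) |
| any alive state → other death | μ(a) | life table |

The age-50 cohort starts with adenoma prevalence p_adeno = 0.25 split
p_small = 0.71 small / 0.29 large, plus fixed preclinical early/late CRC
prevalences of 0.12% and 0.08%; the remainder is normal.

Assumptions worth stating explicitly:

* Intensities are frozen within each one-year cycle at their value for the
  current integer age; the annual transition matrix is P(a) = expm(Q(a)),
  which permits multi-state jumps within a year. A person whose year ends
  in a clinical state having started it at risk is an incident case;
  passages *through* a clinical state that end elsewhere (e.g. a direct
  draw to CRC death) are not observed and not counted — identically so in
  the deterministic trace and the stochastic engine, which is what lets
  the two agree exactly in expectation.
* Clinical early CRC does not progress to clinical late: stage at
  diagnosis is fixed, treatment implicit in stage-specific mortality.
* The horizon is age 50–100, women only, no half-cycle correction.
* Incidence denominators are person-years alive without clinical CRC
  (registry at-risk convention), reported per 100,000 person-years.

## Background mortality

`mu(a) = c + b·exp(θa)` (Gompertz–Makeham) with c = 3.0e−4, b = 3.5e−5,
θ = 0.0875 per year of age — a deliberately smooth stand-in (synthetic,
labelled as such) for 2014-era US female all-cause mortality. Its implied
remaining life expectancy at 50 is 34.6 years, inside the 30–36-year
plausibility band for that population; rates are monotone above age 60.
Any `age,mortality_rate` CSV can replace it; probabilities qₓ should be
converted to rates as −ln(1−qₓ).

## Synthetic calibration targets

Targets are generated by the model at the generative values: 100
replications, each simulating one 500-person cohort (adenoma prevalence
and proportion-small at ages 55/60/65/70 — the scale of endoscopy studies)
and one 100,000-person cohort (stage-specific clinical incidence in
5-year bins 52–56 … 82–86 — registry scale). A target's mean is the
across-replication average; its standard error is the across-replication
**standard deviation** (not SD/√reps): each replication is one study of
the stated size, and the likelihood needs the sampling error of a single
observed dataset. A 1e−6 floor keeps degenerate zero-variance cells
finite; cells undefined in every replication are dropped with a warning.
The age bins are a design choice (the reference analysis does not state
its bins) and are configurable.

What the generator does *not* emulate: real targets would come from
independent studies — here all four target types share replications, so
cells are correlated across ages and types while the likelihood treats
them as independent, exactly as in the reference procedure. Passing
recovery tests therefore demonstrates internal consistency of the
calibration machinery, not robustness to real-data misspecification.

## Likelihood

Each target cell contributes log N(y | φ(θ), σ_eff); φ comes from the
deterministic cohort trace — the exact expectation of the
microsimulation — so the surface is noise-free and a desk-scale
calibration is feasible. By default σ_eff² = σ²·(1 + n_t/100 000):
the reference procedure *estimates* φ by microsimulating a 100,000-person
cohort, and importance sampling with that unbiased noisy normal likelihood
targets precisely the posterior with the evaluation noise marginalized
into the variance (σ scales as 1/√cohort, so the evaluation-noise variance
is σ²·n_t/N_eval). Using the closed form keeps the likelihood
deterministic while targeting the same posterior; `phi_eval_size=None`
gives the pure-expectation likelihood. For incidence cells (n_t = N_eval =
100,000) the correction doubles the variance; for the 500-person adenoma
cells it is negligible.

## Priors and the sampler

Priors: p_adeno ~ Beta(3,8), p_small ~ Beta(6,3), and lognormals for the
positive parameters — l: LN(−11.97, 0.59), γ: LN(1.04, 0.18),
λ₂: LN(−3.45, 0.59), λ₃: LN(−3.91, 0.35), λ₄: LN(−1.15, 0.23),
λ₅: LN(−1.41, 0.10), λ₆: LN(−0.78, 0.22).

IMIS runs on transformed coordinates (logit for proportions, log for
positive parameters) with Jacobian-corrected densities so Gaussian
proposal components respect the supports. Stages:

1. **Prior stage** — n₀ draws from the prior.
2. **Optimization stage** (n_opt = 2 starts) — quasi-Newton search
   (Nelder–Mead then BFGS) from the most promising, mutually distant prior
   draws; each located mode contributes a Gaussian component with
   numerically-differenced inverse-Hessian (Laplace) covariance inflated
   by 1.2. Without this stage the desk-scale sampler stalls (ESS ≈ 300
   after 100 iterations); with it the ESS target is met in ~40.
3. **Incremental stage** — each iteration adds a component centred at the
   current highest-weight draw, covariance from its b nearest neighbours
   (Mahalanobis distance under the prior covariance; weights = importance
   weights + 1/N floor), draws b points, recomputes mixture weights.
4. **Stop** at ESS ≥ target or max_iters (the reference analysis itself
   stopped short of its ESS goal, so the iteration cap is a first-class
   stopping rule); then resample 5,000 draws with replacement.

Numerical choices: covariances are ridge-regularised starting at
1e−8·trace/d and escalating ×10 until Cholesky succeeds; all-zero-weight
runs abort with a diagnostic; likelihood evaluations within a batch are
order-independent (optional joblib parallelism yields results identical
to serial). Desk profile: n₀ = 1000, b = 100, ESS target 1000; full
profile n₀ = 5000, b = 500, ESS target 5000.

The MAP estimate is the evaluated draw with the highest log prior +
log likelihood (first occurrence on ties). Summaries (means, SDs,
equal-tailed 95% CrIs, Pearson correlations) are computed on the
resampled draws. Internal validation evaluates the deterministic outputs
per posterior draw (duplicates computed once) and checks target means
against the 2.5–97.5 percentile envelope.

A caution on reading correlations: the summary carries two matrices —
Pearson on the natural parameter scale and Pearson on the estimation
(logit/log) scale. The l–γ onset ridge is nearly deterministic but curved
in l, whose marginal spans an order of magnitude; its natural-scale
Pearson coefficient is ≈ −0.90 while the estimation-scale (equivalently,
rank) coefficient is ≈ −0.96. Correlation coefficients reported from
transformed-scale samplers correspond to the second matrix. Correlation
magnitudes also depend on the age-bin scheme.

## Screening strategy and accrual

10-yearly colonoscopy from 50 to 85. At a due exam: small adenomas are
detected with sensitivity 0.773, large adenomas and CRC with 0.950
(specificity 0.868; false positives cost nothing beyond the scope, which
is always billed). Detected adenomas are removed (back to normal) and the
person enters surveillance — 5-yearly after a small finding (low-risk,
onset hazard ratio 2), 3-yearly after a large one (high-risk, HR 3); risk
classes only escalate, and a negative exam reverts the person to the
10-year routine clock. Detected preclinical CRC becomes clinical CRC of
the same stage. Cycle order: test → relocation → transition draw →
accrual on the post-test state; a person dead at the end of a cycle
accrues neither that cycle's utility nor its annual cost.

Economics (point values; PSA ranges in `crcuq/data/cea.yaml`): colonoscopy
$10,000; annual clinical-stage costs $21,524 (early) / $37,000 (late);
utilities 1 for states without clinical CRC (1.000 preclinical), 0.855
early, 0.300 late. The discount rate is **not stated in the reference
analysis**; the default is 3%/year for both costs and QALYs and is
configurable to 0 — absolute EVPI magnitudes depend on it. Both strategy
arms share initial-state and transition random numbers (common random
numbers), so incremental outcomes isolate the screening effect.

## PSA and value of information

External-parameter PSA distributions are fitted from the printed value
(anchored as the distribution mean) and 95% equal-tailed range
(least-squares on the 2.5/97.5 percentiles): betas for test
characteristics, lognormals for hazard ratios, costs and utilities.
Sampled utilities are capped at 1 and post-polypectomy hazard ratios
floored at 1 to respect their supports.

The four uncertainty characterizations of the calibrated parameters: (A1)
joint posterior + external draws; (A2) MAP + external draws; (A3) joint
posterior + external means; (A4) independent beta/lognormal marginals
moment-matched to the posterior means/SDs (all nine parameters, including
l and γ) + external draws — A4 deliberately discards the posterior
correlations. Each PSA draw simulates an independent cohort per strategy
pair with common random numbers across strategies; desk profile 500 draws
× 2,000-person cohorts.

EVPI(λ) = E[maxₛ (λ·Eₛ − Cₛ)] − maxₛ E[λ·Eₛ − Cₛ] per patient, on a
$0–150,000 grid in $1,000 steps (covering the $66k/$71k/$81k thresholds
relevant to the reference analysis). Finite per-draw cohorts add nested
Monte-Carlo noise that **inflates** EVPI — desk-scale EVPI levels are
upper-biased and should be read comparatively (ordering across
approaches), not as absolute dollar values; before quoting levels,
check that EVPI stabilises as n_micro doubles.

## Known limitations

* One lesion state per person (state-level, not lesion-level, model);
  "location-specific" test sensitivity is applied at person level.
* No colonoscopy complications, adherence, or competing screening
  modalities; a single strategy vs none.
* Desk-scale IMIS (ESS target 1000) yields correlation estimates with
  Monte-Carlo error of a few hundredths; the full profile tightens them.
* The life table is a smooth parametric stand-in, not an official table;
  absolute survival-linked quantities (e.g. discounted life expectancy)
  shift slightly if a real table is substituted.
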