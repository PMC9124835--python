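# Generative ("true") values and priors for the nine-state CRC natural-history
# model. The `truth` block is the parameter set used to generate synthetic
# calibration targets; `priors` are the calibration prior distributions.
truth:
  padeno: 0.25        # adenoma prevalence at age 50
  psmall: 0.71        # proportion of prevalent adenomas that are small
  l: 2.86e-06         # Weibull scale, adenoma onset hazard
  gamma: 2.78         # Weibull shape, adenoma onset hazard
  lambda2: 0.0346     # small adenoma -> large adenoma (1/yr)
  lambda3: 0.0215     # large adenoma -> preclinical early CRC (1/yr)
  lambda4: 0.3697     # preclinical early -> preclinical late (1/yr)
  lambda5: 0.2382     # preclinical early -> clinical early (1/yr)
  lambda6: 0.4582     # preclinical late -> clinical late (1/yr)
fixed:
  lambda7: 0.0302     # CRC mortality, early stage (1/yr)
  lambda8: 0.2099     # CRC mortality, late stage (1/yr)
  p_preclin_early_50: 0.0012   # prevalence of preclinical early CRC at 50
  p_preclin_late_50: 0.0008    # prevalence of preclinical late CRC at 50
priors:
  padeno:  {family: beta, a: 3.0, b: 8.0}
  psmall:  {family: beta, a: 6.0, b: 3.0}
  l:       {family: lognormal, m: -11.97, s: 0.59}
  gamma:   {family: lognormal, m: 1.04, s: 0.18}
  lambda2: {family: lognormal, m: -3.45, s: 0.59}
  lambda3: {family: lognormal, m: -3.91, s: 0.35}
  lambda4: {family: lognormal, m: -1.15, s: 0.23}
  lambda5: {family: lognormal, m: -1.41, s: 0.10}
  lambda6: {family: lognormal, m: -0.78, s: 0.22}
# Gompertz-Makeham approximation to US female all-cause mortality (2014-era
# level): mu(a) = c + b * exp(theta * a). Gives e50 of roughly 33-34 years.
life_table:
  makeham_c: 3.0e-04
  makeham_b: 3.5e-05
  makeham_theta: 0.0875
  age_max: 100
  label: "synthetic US females 2014 (Gompertz-Makeham approximation)"
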