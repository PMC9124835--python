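# Cost-effectiveness parameters for 10-yearly colonoscopy screening vs no
# screening. `value` is the point estimate; `lo`/`hi` the 95% equal-tailed
# interval used to fit the PSA distribution of the external parameters.
external:
  sens_small:        {value: 0.773, lo: 0.734, hi: 0.808, family: beta}
  sens_large_crc:    {value: 0.950, lo: 0.920, hi: 0.990, family: beta}
  spec:              {value: 0.868, lo: 0.855, hi: 0.880, family: beta}
  hr_low_risk:       {value: 2.0,   lo: 1.0,   hi: 3.0,   family: lognormal}
  hr_high_risk:      {value: 3.0,   lo: 2.0,   hi: 4.0,   family: lognormal}
  cost_colonoscopy:  {value: 10000, lo: 9000,  hi: 11000, family: lognormal}
  cost_early_annual: {value: 21524, lo: 20000, hi: 23000, family: lognormal}
  cost_late_annual:  {value: 37000, lo: 35000, hi: 39000, family: lognormal}
  util_preclin:      {value: 1.000, lo: 0.980, hi: 1.000, family: lognormal}
  util_early:        {value: 0.855, lo: 0.700, hi: 0.900, family: lognormal}
  util_late:         {value: 0.300, lo: 0.200, hi: 0.400, family: lognormal}
schedule:
  screen_start: 50
  screen_stop: 85
  screen_interval: 10
  surveil_small: 5      # surveillance interval after small-adenoma polypectomy
  surveil_large: 3      # surveillance interval after large-adenoma polypectomy
discount_rate: 0.03
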