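# Final population-PK estimates of rilpivirine (oral + long-acting IM),
# as printed: fractions dimensionless, rate constants 1/h, volumes L,
# clearances L/h, zero-order oral input duration h.  Variability terms are
# given on the published CV% scale and converted to SDs at load time.
typical:
  CL: 6.74        # L/h
  V3: 277.0       # L, central
  Q: 4.08         # L/h
  V4: 839.0       # L, peripheral
  ka_fast: 0.00214    # 1/h
  ka_slow: 0.000229   # 1/h
  F_im_fast: 0.276    # fraction via fast IM depot pathway
  F_oral: 0.654       # oral bioavailability relative to IM
  D_oral: 4.0         # h, fixed
variability_cv_percent:
  F_oral: 37.1
  ka_slow: 82.7
  CL: 25.9
  F_im_fast: 16.8     # delta-method CV of the logistic transform
  IOV_CL: 13.0
residual:
  sigma_add_oral: 18.0   # ng/mL, additive (oral records)
  sigma_prop_im: 0.18    # proportional SD (IM records)
covariates:
  theta_female: -0.456   # fractional change of F_im_fast for females
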