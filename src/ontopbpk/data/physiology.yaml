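# Age-dependent system (anatomical/physiological) parameters.
#
# These parametric growth functions are the package defaults; they are
# smooth, monotone approximations calibrated to typical published values
# (WHO/CDC-style weight-for-age, allometric liver weight, cubic-in-age
# log10 MPPGL, hepatic blood flow as a fixed fraction of a BSA-scaled
# cardiac output).  To replicate a specific whole-body PBPK platform,
# swap this file for the platform's own coefficient sets so that the
# reduced and whole-body models share consistent assumptions.
adult:
  age: 35.0          # years, adult reference age
  body_weight: 70.0  # kg
  hepatic_blood_flow: 90.0  # L/h at the reference body weight
  fu: 1.0            # default unbound fraction (drug configs override)
  blood_plasma_ratio: 1.0

weight_for_age:
  # WT(a) = w0 + w1*a/(a+w2) + w3*(1-exp(-a/w4)) + w5*a^w6/(a^w6+w7^w6)
  # w5 is derived at load time so that WT(adult reference age) equals the
  # adult reference body weight exactly.
  w0: 3.5    # kg, birth weight
  w1: 7.7    # kg, infant growth amplitude
  w2: 0.43   # years, infant growth half-time
  w3: 22.8   # kg, childhood growth amplitude
  w4: 12.0   # years, childhood growth time constant
  w6: 5.5    # pubertal Hill coefficient
  w7: 13.5   # years, pubertal half-age

liver_weight:
  # LW(g) = k * BW(kg)^exponent; k derived so LW(adult) = adult_liver_weight
  exponent: 0.85
  adult_liver_weight: 1800.0  # g

mppgl:
  # log10 MPPGL (mg microsomal protein / g liver) = c0 + c1*a + c2*a^2 + c3*a^3
  c0: 1.407
  c1: 0.0158
  c2: -0.00038
  c3: 0.0000024

hepatic_blood_flow:
  # Q_H = adult flow * (BW / adult BW)^exponent  (BSA-like scaling)
  exponent: 0.6667

gfr_maturation:
  # sigmoid fraction-of-adult GFR; shared with the GFR_maturation fixed
  # ontogeny profile (postnatal-age approximation of the published
  # postmenstrual-age Hill curve)
  F_birth: 0.35
  Age_up50: 0.4
  gamma_u: 1.1

demographics:
  weight_cv: 0.2   # lognormal CV around the weight-for-age curve
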