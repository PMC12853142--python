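# Frozen ontogeny profiles used as system inputs (not estimands).
#
# The hepatic CYP3A profiles are representative approximations of the two
# published in-vivo maturation functions commonly used in pediatric PBPK
# platforms (a fast-maturing sigmoid, profile 1, and a slower-maturing
# sigmoid, profile 2).  The GFR profile is a postnatal-age sigmoid
# approximation of the published postmenstrual-age Hill maturation curve.
# Edit this file (or point the loaders at an alternative) to swap in the
# exact coefficient sets used by a specific whole-body PBPK platform.
profiles:
  CYP3A_profile1:
    family: eq1_sigmoid_up
    parameters: {F_birth: 0.08, F_max: 1.0, Age_up50: 0.64, gamma_u: 1.2}
  CYP3A_profile2:
    family: eq1_sigmoid_up
    parameters: {F_birth: 0.05, F_max: 1.0, Age_up50: 1.5, gamma_u: 1.0}
  GFR_maturation:
    family: eq1_sigmoid_up
    parameters: {F_birth: 0.35, F_max: 1.0, Age_up50: 0.4, gamma_u: 1.1}

# Example/demonstration parameter sets.
# risdiplam_case: bell-shaped hepatic FMO3 ontogeny calibrated so the
# normalized curve peaks near age 2 years at ~3x the adult activity.
examples:
  risdiplam_case:
    family: eq4a
    parameters:
      F_birth: 0.1
      Age_up50: 0.5
      gamma_u: 2.0
      FRD: 0.7
      Age_down50: 6.0
      gamma_d: 2.5
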