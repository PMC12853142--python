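# Bundled example drug: an orally dosed, low-hepatic-extraction compound
# eliminated by hepatic FMO3 (75%) and CYP3A (20%) metabolism and renal
# excretion (5%), with high bioavailability and age-independent plasma
# protein binding.  This is a representative "risdiplam-like" compound:
# per-mg intrinsic clearances are back-calculated from the adult
# elimination partition and total clearance at load time.
name: risdiplam_like
FaFg: 0.99
ka: 1.0              # 1/h
V_ref: 210.0         # L at 70 kg
vol_allometric_exponent: 1.0
fu: 0.11
BP: 1.0
adult_CL_total: 2.6  # L/h
adult_fm:
  FMO3: 0.75
  CYP3A: 0.20
adult_fe_renal: 0.05
ontogeny:
  FMO3: {example: risdiplam_case}   # bell-shaped, ~3x adult near 2 years
  CYP3A: {profile: CYP3A_profile1}  # fixed, well-established maturation
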