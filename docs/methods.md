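# Methods

This note documents the modeling choices behind `ontopbpk`: the
structural model and its assumptions, the numerical machinery, the
synthetic-trial generator and what passing tests on it do and do not
demonstrate, and the places where the design was genuinely open.

## Structural model and assumptions

The package targets one setting: an orally dosed, low-hepatic-extraction
drug eliminated by competing hepatic metabolic pathways plus renal
excretion, with sparse concentration data spanning children and adults.
Only the clearance arm is physiological; everything irrelevant to
ontogeny estimation is deliberately empirical:

* **Hepatic clearance** — well-stirred liver model. Whole-liver unbound
  intrinsic clearance per pathway scales as
  `CLint_per_mg [µL/min/mg] × MPPGL [mg/g] × liver weight [g] ×
  F_activity(age)`, converted to L/h. Competing pathways see the same
  unbound liver exposure, so the hepatic clearance is apportioned by
  intrinsic-clearance shares. The fraction metabolized per pathway is
  defined at the level of systemic clearance,
  `fm_p = CL_H·s_p / (CL_H + CL_R)`; first-pass extraction is carried by
  `F = FaFg·F_H` and excluded from the mass-balance bookkeeping. For a
  low-extraction drug (extraction ratio ≈ 0.03 for the bundled example)
  the distinction is below half a percent.
* **Renal clearance** — adult value scaled by a GFR maturation fraction.
* **Absorption/distribution** — first-order absorption into one
  compartment; volume allometric in body weight with exponent 1.0.
  Plasma protein binding is age-independent by default (a property of
  the motivating drug); an age-dependent binding hook would be a
  constants-file change. Intestinal metabolism is folded into `FaFg`
  and treated as age-independent, justified by high oral
  bioavailability; drugs with substantial gut-wall extraction would
  need a physiological intestine, which is out of scope.
* **Linearity** — no saturable elimination; AUC = Dose·F/CL applies at
  steady state and as AUC(0–∞).

Units throughout: mg doses, hours, ng/mL concentrations, litres, L/h,
years of postnatal age (no gestational-age adjustment; the motivating
data start at 2 months).

## Ontogeny families

Fractional activity is always normalized: curves are evaluated as
`raw(age)/raw(reference age)` with the adult reference at 35 years, and
families that declare an `AGECAP` are normalized at the cap and pinned
to exactly 1 beyond it (which also makes the pin continuous). The
normalization is the substantive definition of ontogeny — activity
*relative to adult* — and guarantees the adult fixed point for every
admissible parameter set rather than only asymptotically.

Building blocks: a rising Hill term
`U(a) = F_birth + (F_max − F_birth)·a^γu/(Age_up50^γu + a^γu)`, a rising
Gompertz `G(a) = F_max·exp(ln(F_birth/F_max)·e^(−K·a))` (requires
F_birth > 0), a declining Hill `D(a) = 1 − FRD·a^γd/(Age_down50^γd +
a^γd)` and a declining Gompertz sigmoid with rate γd. The six
bell-shaped families are the products {Hill, Gompertz} × {Hill down,
Gompertz down}, a capped Hill×Hill variant, and an additive
up-minus-down variant; in all of them the adult asymptote constraint
`F_max·(1 − FRD) = 1` makes F_max a derived parameter, leaving 6–7 free
parameters. The flexible double sigmoid keeps F_max free (9 free
parameters) and relies on its cap for the adult anchor. `Age_down50` is
interpreted as the midpoint of the decline (the age at which half of
the down-slope contribution has accrued); the alternative reading —
age at 50% of the minimum activity — was rejected as
parameterization-dependent.

Fixed (non-estimable) profiles for hepatic CYP3A (two published-style
curves that disagree in infancy) and GFR maturation ship in an editable
YAML constants file. They are representative approximations, not
transcriptions of the original coefficient sets; anyone replicating a
specific whole-body PBPK platform should replace the file so both
models share assumptions.

## Physiology

The constants file provides: a smooth three-term weight-for-age curve
(infant saturating rise, childhood exponential approach, pubertal
sigmoid) whose pubertal amplitude is solved at load time so the
35-year-old reproduces the 70-kg adult reference exactly; liver weight
allometric in body weight (exponent 0.85, anchored at 1800 g);
log10 MPPGL cubic in age (≈25 mg/g at birth to ≈40 mg/g in adults);
hepatic blood flow as the adult 90 L/h scaled by (BW/70)^(2/3), a body
surface-area-like scaling of the cardiac-output fraction; and a sigmoid
GFR maturation (35% of adult at birth). These are calibrated to typical
published values but are package defaults, not literature
transcriptions — the file exists precisely so they can be swapped.

## Estimation

* **Likelihood.** Per subject, minus log joint of observations and
  log-normal random effects; the marginal is approximated by Laplace:
  `−2 log L_i ≈ 2 l_i(η*) + log det H_i − k log 2π`. Residual model:
  proportional CV plus additive SD with a 1e-6 ng/mL variance floor.
  When all random-effect variances are zero the OFV reduces exactly to
  the fixed-effect weighted deviance.
* **Inner problem.** All subjects' modes are found simultaneously by
  damped Newton iterations vectorized across subjects. Gradients use
  small-step central differences (1e-4) so the mode is located
  precisely and the OFV is reproducible to ~1e-9 regardless of the
  starting point; Hessians use a wider step (1e-2) for stable
  curvature. Mode Hessians with non-positive eigenvalues (flat
  directions, numerically indefinite cases) are eigenvalue-floored
  rather than failing the likelihood; the count of affected subjects is
  exposed as a diagnostic.
* **Outer problem.** Positive fixed effects are estimated on the log
  scale, fractions (FRD, FaFg) on a logit scale, Hill coefficients on a
  bounded logit over [0.1, 15]; variance components as log-SDs. L-BFGS-B
  with successive restarts (the restart rebuilds the Hessian
  approximation and recovers from premature line-search termination);
  warm-started inner modes (sanitized against excursions into guarded
  parameter regions) cut the inner cost roughly in half. Multi-start
  with seed-controlled jitter is available (`multi_start`), default 1:
  the documented family inits converge reliably at the bundled problem
  sizes, and scans/bootstraps run many fits.
* **Standard errors** from the central-difference Hessian of the OFV at
  the optimum (delta method back to the natural scale); the condition
  number is reported as an identifiability heuristic.
* **Random effects** default to intrinsic clearance and volume. An
  absorption-rate eta is supported but off by default: with 2–4 samples
  per subject at steady state it is practically unidentifiable and
  doubles the inner dimension.
* **Default estimable ontogeny subsets.** Hill coefficients are fixed at
  family defaults (γu = 2, γd = 2.5), standard for sparse designs. For
  the bell families the birth intercept `F_birth` is also fixed by
  default: with enrollment starting months after birth the likelihood
  is flat in it, which is the same reason estimated trajectories
  diverge below ~4 months of age. Both remain estimable on request.
* **Below-quantification handling**: rows with MDV=1 are excluded; no
  censored-likelihood (M3) treatment.
* **Quadrature cross-check.** `agq_ofv` integrates the same joint
  density by adaptive Gauss–Hermite quadrature (nodes centered at the
  mode, scaled by the inverse Cholesky factor of the Hessian; tensor
  grid for two effects). On small sparse datasets Laplace agrees with
  the 21-node quadrature within 0.1 OFV units, and reproduces the
  closed-form linear-Gaussian marginal to ~1e-10.

## Diagnostics

* **Post hoc age scan** fits the model with the target pathway's
  ontogeny forced to 1, then examines `log exp(η_CL)` against age: a
  lowess trend on log-age plus a Spearman rank correlation with a
  Fisher-z CI. Classification: a prominent interior lowess maximum is a
  bell; otherwise a monotone label requires both a lowess span above
  0.2 (log scale) *and* a rank-correlation CI excluding zero — the
  lowess ends rest on few points, and edge variance alone must not read
  as a trend; everything else is flat.
* **GOF** reports population predictions, empirical-Bayes individual
  predictions, FOCE-linearized conditional residuals (CWRES, zero
  mean/unit variance under the true model) and population residuals
  (PWRES). The residual-vs-age flag uses a Kruskal–Wallis test of PWRES
  across age bands: EBE shrinkage hides structural misfit from CWRES,
  and a bell-shaped misfit defeats monotone tests.
* **VPC** simulates replicates under the observed design (same
  subjects, doses, times), bins by time-after-dose quantiles within age
  strata and separately by age, and compares observed 5/50/95th
  percentiles with the 95% prediction band of each percentile. Bands
  need enough replicates to resolve their tails: 200 simulations
  under-cover by a few percent, 500 restore the nominal 95% per-bin
  coverage (measured by self-simulation), so the bundled experiments
  use 500. Per-bin coverage events are correlated (age bins share
  subjects with time bins), so pooled coverage estimates carry more
  variance than a binomial count suggests.
* **Bootstrap** resamples subjects with replacement within age bands
  (default <2, 2–12, 12–18, ≥18 years) so pediatric representation
  survives resampling, refits, and reports percentile CIs plus the
  refit failure rate.
* **Family scan** fits every requested family from its default inits,
  ranks by AIC, retains families within ΔAIC ≤ 2 (configurable — the
  retention rule is a reporting default, not a claim that AIC is the
  right qualification criterion), and flags the ages at which the
  fitted curves agree within 20% relative spread. With a design sparse
  below 4 months, families agree above that age and diverge below —
  curve recovery in the observed range, not family identity, is the
  meaningful contract, since the bell families are nearly degenerate
  reparameterizations of one another.

## Synthetic trials: what they do and do not show

The generator emulates the case design: 525 subjects (120 aged
2 months–2 years, log-uniform to enrich infants; 162 aged 2–12; 100
aged 12–18; 143 adults), mg/kg dosing capped at the 5-mg adult dose,
2–4 samples per subject drawn within a 0.5–24 h post-dose window at
steady state, 30% CV log-normal between-subject variability on
intrinsic clearance and volume, 15% proportional residual error. The
true FMO3 ontogeny is the bundled `risdiplam_case` bell (peak ≈2.9×
adult near 2 years). Steady-state dose records (SS/II columns) stand in
for months of daily dosing; the closed-form periodic solution replaces
superposition over hundreds of doses.

Passing tests on these trials shows the estimator recovers the
generating mechanism at realistic sparsity, noise and imbalance — it
does **not** show robustness to model misspecification the generator
cannot produce: nonlinear elimination, absorption delays or transit
compartments, multi-compartment disposition, adherence gaps, disease
progression, assay censoring, or physiology functions different from
the fitting model's own. The generator and fitting model share the
physiology file by construction; with real data that consistency is an
assumption to be defended, not a given.

Two honest limits of the bundled calibration: the recovery experiment
measures bias only for the estimated fixed effects (the fixed Hill
coefficients and birth intercept are supplied at their generating
values, as in any self-consistent recovery study); and the 16-day-old
neonate extrapolation at 0.15 mg/kg lands at or above the 95th
percentile of the simulated 2–12-month reference exposure band — in
the motivating program that dose was chosen by exposure matching
against the sponsor's model, and this package's synthetic drug is not
that model, so the package reports the fraction of retained models
inside the band rather than asserting containment.

## Extrapolation

Static DDI: the inhibited pathway's intrinsic clearance is divided by
the inhibition factor and the well-stirred model rebuilt, so hepatic
availability moves consistently; under linearity
`AUCR = (F'/CL')/(F/CL)`. The textbook shortcut `1/(1 − fm + fm/IR)` is
retained as a cross-check and agrees within ~0.04% for the bundled
low-extraction drug. Elevated FMO3 activity in infancy shrinks the
CYP3A-metabolized fraction (≈0.20 adult → ≈0.07 at 3 months), hence a
lower DDI AUC ratio in infants (≈1.07 vs 1.25) — the qualitative
pediatric-DDI conclusion the model family supports.

Neonate exposure uses typical-subject AUC per retained ontogeny model
(population simulation with BSV is a flag), summarized as
min/median/max against a reference band, by default the 5th–95th
percentile of simulated exposure in the adjacent studied age group
(2–12 months) at its approved dose.

## Numerical conventions and degenerate inputs

`ka = ke` uses the exact limit formula in the transient solution and a
1e-6 relative nudge in the steady-state path. Padded observation/dose
arrays carry zero amounts, so ragged subjects vectorize without
branching. Curve evaluation guards non-finite normalization references
and rejects inadmissible parameters with a per-violation report. All
randomness flows through `numpy.random.default_rng` seeds passed
explicitly; simulator, VPC, bootstrap and workflow reruns with the same
seed are byte-identical.

## Known limitations

One-compartment disposition only (multi-compartment kinetics are
empirical territory this reduced model does not cover); diagonal
random-effect covariance only (no correlated etas); no
covariate-search machinery; no Bayesian estimation; no
time-dependent/mechanistic DDI; single-analyte, parent drug only;
quadrature checker limited to two random effects; age bins of the VPC
and bootstrap strata are fixed defaults rather than data-adaptive.
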