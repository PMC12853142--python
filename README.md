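# ontopbpk

Population-PBPK estimation of drug-metabolizing-enzyme ontogeny from
sparse pediatric pharmacokinetic data.

## The problem

Predicting drug exposure in children requires knowing how the activity
of each drug-metabolizing enzyme (DME) matures with age — its
*ontogeny*, expressed as the fraction of adult activity,
`F_activity(age)`. For many enzymes the published in vitro ontogeny
data disagree, and applying the wrong maturation function can mis-predict
pediatric clearance several-fold. When sparse concentration data have
been collected in the target pediatric population, the ontogeny can
instead be **estimated in vivo**: embed a reduced, physiologically
based clearance model inside a nonlinear mixed-effects (NLME)
framework, fix what is well known (physiology, the ontogeny of
well-studied pathways, renal maturation), and estimate the structural
maturation function of the uncertain pathway directly from the data.

`ontopbpk` implements that approach end to end for an orally dosed,
low-hepatic-extraction drug cleared by competing hepatic pathways and
renal excretion — the setting of a pediatric rare-disease program in
which a flavin-containing monooxygenase 3 (FMO3)–cleared drug was dosed
in patients from 2 months to adulthood. It is aimed at pharmacometricians
and clinical-pharmacology modelers.

## The model

Hepatic clearance uses the well-stirred liver model with
ontogeny-scaled, pathway-partitioned intrinsic clearance:

    CL_int,p(age) = CLint_per_mg[p] · MPPGL(age) · LW(age) · F_activity_p(age)
    CL_H  = Q_H · fu_B · CL_int / (Q_H + fu_B · CL_int)
    F_H   = Q_H / (Q_H + fu_B · CL_int),      F = Fa·Fg · F_H
    CL_R  = CL_R,adult · GFR_frac(age)

with MPPGL the microsomal protein per gram liver, LW the liver weight,
Q_H the hepatic blood flow and fu_B the unbound fraction in blood.
Absorption and distribution are empirical (first-order absorption, one
compartment, volume allometric in body weight with exponent 1).
Between-subject variability is log-normal on intrinsic clearance and
volume; residual error is proportional (+ optional additive).

Ontogeny functions come from a registry of structural families —
sigmoid Emax (Hill) and Gompertz rises, Hill/exponential declines, six
bell-shaped rise×decline combinations (6–7 free parameters each) for
enzymes more active in children than adults, and a 9-parameter capped
double sigmoid. All are normalized so `F_activity = 1` at the adult
reference age (35 y).

Estimation maximizes the Laplace-approximated marginal likelihood
(−2 log L, "OFV"), with per-subject random-effect modes found by
vectorized Newton iterations; an adaptive Gauss–Hermite quadrature
routine provides an independent check of the approximation.
Qualification follows standard pharmacometric practice: age-stratified
bootstrap, goodness-of-fit with FOCE-linearized residuals, and visual
predictive checks (VPC). A synthetic-trial simulator reproduces the
sparse case-study design (525 subjects aged 2 months–61 years, 382 of
them pediatric, mg/kg steady-state dosing) so the whole pipeline is
testable without proprietary data.

## Worked example

```python
import numpy as np
import ontopbpk as op
from ontopbpk.model import OntogenyNlme

drug = op.load_example_drug()            # adult fm: FMO3 75%, CYP3A 20%, renal 5%
data = op.simulate_trial(op.risdiplam_like_design(), drug, seed=42)
print(data.n_subjects, data.n_observations)

est = OntogenyNlme(drug=drug, target_pathway="FMO3", ontogeny_family="eq4a",
                   theta_init={"F_birth": 0.1, "gamma_u": 2.0, "gamma_d": 2.5},
                   seed=1)
est.fit(data.df)
print(f"converged={est.converged_}  OFV={est.ofv_:.1f}")
curve = est.ontogeny_curve(np.linspace(0, 18, 500))
print(f"peak FMO3 activity {curve.max():.2f}x adult "
      f"at {np.linspace(0, 18, 500)[curve.argmax()]:.1f} y")
```

Output:

```
525 2100
converged=True  OFV=19149.8
peak FMO3 activity 3.21x adult at 2.0 y
```

The estimator recovers the generating bell-shaped FMO3 ontogeny (truth
peaks near 2 years at ≈2.9× the adult activity; this replicate
estimates 3.2× at 2.0 years) from sparse steady-state
samples. Downstream, the fitted curves drive the extrapolations:

```python
from ontopbpk.extrapolate import DDIScenario, ddi_auc_ratio
print(ddi_auc_ratio(drug, 35.0, DDIScenario()))   # 1.2505 — adult, complete CYP3A inhibition
print(ddi_auc_ratio(drug, 0.25, DDIScenario()))   # 1.0709 — 3-month-old: lower DDI propensity
```

An infant with elevated FMO3 activity has a smaller CYP3A-metabolized
fraction, so complete CYP3A inhibition raises exposure less than in
adults (1.07-fold vs 1.25-fold).

The same stages are available from the shell:

```bash
ontopbpk simulate --seed 42 --out trial.csv
ontopbpk workflow trial.csv --families eq4a,eq4c,eq4f --seed 1 --out run/
```

which writes the full artifact set (adult/pediatric fits, post hoc
CL_int-vs-age scan, multi-family ontogeny scan, bootstrap CIs, GOF,
VPC, fm-vs-age table, DDI ratios) plus a JSON manifest recording seeds.

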