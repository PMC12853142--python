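"""Synthetic sparse-trial simulator.

Generates NONMEM-style datasets that emulate the structure of a
pediatric rare-disease program: mg/kg (capped) oral dosing at steady
state, sparse sampling within visit windows, a wide age range with a
majority of pediatric subjects, log-normal between-subject variability
and proportional (+ optional additive) residual error.  The bundled
default design mirrors the published case structure: 525 subjects aged
2 months to 61 years, 382 of them pediatric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import PKDataset
from .physiology import load_constants, sample_demographics
from .structural import DoseEvent, DrugParameters, individual_parameters, predict_concentration
from .physiology import profile_for_age

__all__ = [
    "TrialArm",
    "TrialDesign",
    "simulate_trial",
    "risdiplam_like_design",
    "neonate_design",
]


@dataclass(frozen=True)
class TrialArm:
    """One age cohort of the design."""

    age_range: tuple[float, float]     # years
    n: int
    dose_mg_per_kg: float | None = None
    dose_mg: float | None = None       # fixed dose alternative
    dose_cap_mg: float | None = None   # cap on mg/kg dosing
    n_samples: int = 4                 # per visit
    sample_window: tuple[float, float] = (0.5, 24.0)  # h after dose
    n_visits: int = 1
    visit_spacing: float = 168.0       # h between visit doses
    age_distribution: str = "uniform"
    pediatric: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("each arm needs n >= 1")
        if (self.dose_mg_per_kg is None) == (self.dose_mg is None):
            raise ValueError("specify exactly one of dose_mg_per_kg / dose_mg")
        lo, hi = self.sample_window
        if not (0 <= lo < hi):
            raise ValueError("invalid sampling window")


@dataclass(frozen=True)
class TrialDesign:
    arms: tuple[TrialArm, ...]
    ii: float = 24.0          # dosing interval, h
    label: str = "trial"

    @property
    def n_subjects(self) -> int:
        return sum(a.n for a in self.arms)


def risdiplam_like_design() -> TrialDesign:
    """Bundled design emulating the case-study structure.

    525 subjects aged 2 months-61 years with 382 pediatric subjects;
    mg/kg dosing capped at the adult dose; sparse steady-state sampling.
    Enrollment is deliberately sparse below 4 months (the infant arm is
    log-uniform over 2 months-2 years), which is what limits how well
    any family's trajectory is determined in early infancy.
    """
    return TrialDesign(
        label="risdiplam_like_case",
        arms=(
            TrialArm((2.0 / 12.0, 2.0), 120, dose_mg_per_kg=0.2,
                     dose_cap_mg=5.0, age_distribution="log-uniform"),
            TrialArm((2.0, 12.0), 162, dose_mg_per_kg=0.25, dose_cap_mg=5.0),
            TrialArm((12.0, 18.0), 100, dose_mg_per_kg=0.25, dose_cap_mg=5.0),
            TrialArm((18.0, 61.0), 143, dose_mg=5.0, pediatric=False),
        ),
    )


def neonate_design(age_days: float, dose_mg_per_kg: float, n: int,
                   n_samples: int = 6) -> TrialDesign:
    """Single-arm extrapolation design at one (young) age."""
    if age_days < 0:
        raise ValueError("age must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    age_y = age_days / 365.25
    return TrialDesign(
        label=f"neonate_{age_days:g}d",
        arms=(TrialArm((age_y, age_y + 1e-6), n,
                       dose_mg_per_kg=dose_mg_per_kg,
                       n_samples=n_samples),),
    )


def simulate_trial(
    design: TrialDesign,
    drug: DrugParameters,
    omega: dict[str, float] | None = None,
    sigma: tuple[float, float] = (0.15, 0.0),
    seed: int = 0,
    constants=None,
) -> PKDataset:
    """Simulate one trial under the design and a true model.

    Demographics come from :func:`sample_demographics`; individual
    parameters from the structural model with ``eta ~ N(0, omega)``
    (log-normal, keys cl/v/ka); observations are steady-state
    concentrations with residual ``DV = pred * (1 + prop*eps) + add*eps'``
    truncated at zero.  Deterministic under ``seed``.
    """
    omega = omega or {"cl": 0.09, "v": 0.09}
    c = constants or load_constants()
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for arm in design.arms:
        demo = sample_demographics(arm.age_range, arm.n, seed=rng,
                                   age_distribution=arm.age_distribution,
                                   constants=c)
        for _, person in demo.iterrows():
            sid += 1
            age, wt = float(person["age"]), float(person["body_weight"])
            if arm.dose_mg is not None:
                amt = arm.dose_mg
            else:
                amt = arm.dose_mg_per_kg * wt
                if arm.dose_cap_mg is not None:
                    amt = min(amt, arm.dose_cap_mg)
            eta = {k: rng.normal(0.0, np.sqrt(v)) if v > 0 else 0.0
                   for k, v in omega.items()}
            physio = profile_for_age(age, body_weight=wt, fu=drug.fu,
                                     BP=drug.BP, constants=c)
            params = individual_parameters(drug, physio, age, eta=eta,
                                           constants=c)
            doses = []
            times = []
            for visit in range(arm.n_visits):
                t_dose = visit * arm.visit_spacing
                doses.append(DoseEvent(amount=amt, time=t_dose, ss=True,
                                       ii=design.ii))
                offs = np.sort(rng.uniform(arm.sample_window[0],
                                           arm.sample_window[1],
                                           size=arm.n_samples))
                times.extend(t_dose + offs)
            times = np.asarray(times)
            pred = predict_concentration(params, doses, times)
            prop, add = sigma
            dv = pred * (1.0 + prop * rng.normal(size=times.size))
            if add > 0:
                dv = dv + add * rng.normal(size=times.size)
            dv = np.maximum(dv, 0.0)
            for d in doses:
                rows.append(dict(ID=sid, TIME=d.time, AMT=d.amount, EVID=1,
                                 MDV=1, DV=np.nan, AGE=age, WT=wt, SS=1,
                                 II=design.ii))
            for t, y in zip(times, dv):
                rows.append(dict(ID=sid, TIME=t, AMT=np.nan, EVID=0, MDV=0,
                                 DV=y, AGE=age, WT=wt, SS=0, II=np.nan))
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        ascending=[True, True, False])
    return PKDataset(df.reset_index(drop=True))
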