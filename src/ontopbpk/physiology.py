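"""Age-dependent system parameters for pediatric clearance scaling.

Provides the anatomical/physiological quantities the reduced PBPK model
needs to scale adult drug parameters to children: body weight, liver
weight, microsomal protein per gram of liver (MPPGL), hepatic blood
flow, and the fraction of adult glomerular filtration rate.  Defaults
live in a packaged, editable YAML constants file so the reduced model
can be kept consistent with whatever whole-body PBPK platform the adult
parameters came from.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

from .ontogeny import OntogenyParameters, evaluate_ontogeny, get_model

__all__ = [
    "PhysiologyProfile",
    "PhysiologyConstants",
    "load_constants",
    "weight_for_age",
    "profile_for_age",
    "sample_demographics",
]


@dataclass(frozen=True)
class PhysiologyProfile:
    """System parameters resolved at one age."""

    age: float               # years
    body_weight: float       # kg
    liver_weight: float      # g
    MPPGL: float             # mg microsomal protein / g liver
    Q_H: float               # hepatic blood flow, L/h
    GFR_frac: float          # fraction of adult GFR
    fu: float                # unbound fraction in plasma
    BP: float                # blood-to-plasma ratio


class PhysiologyConstants:
    """Parsed constants file with derived anchoring coefficients.

    The weight-for-age pubertal amplitude and the liver-weight
    coefficient are derived at load time so that the adult reference age
    reproduces the adult reference constants exactly.
    """

    def __init__(self, raw: dict):
        self.raw = raw
        adult = raw["adult"]
        self.adult_age = float(adult["age"])
        self.adult_weight = float(adult["body_weight"])
        self.adult_qh = float(adult["hepatic_blood_flow"])
        self.adult_fu = float(adult["fu"])
        self.adult_bp = float(adult["blood_plasma_ratio"])
        w = raw["weight_for_age"]
        self._w = {k: float(v) for k, v in w.items()}
        base = self._weight_base(self.adult_age)
        hill = self._pubertal_hill(self.adult_age)
        self._w5 = (self.adult_weight - base) / hill
        lw = raw["liver_weight"]
        self.lw_exponent = float(lw["exponent"])
        self.adult_liver_weight = float(lw["adult_liver_weight"])
        self._lw_k = self.adult_liver_weight / self.adult_weight**self.lw_exponent
        self._mppgl = [float(raw["mppgl"][k]) for k in ("c0", "c1", "c2", "c3")]
        self.qh_exponent = float(raw["hepatic_blood_flow"]["exponent"])
        g = raw["gfr_maturation"]
        self._gfr_params = OntogenyParameters(
            F_birth=float(g["F_birth"]),
            F_max=1.0,
            Age_up50=float(g["Age_up50"]),
            gamma_u=float(g["gamma_u"]),
        )
        self.weight_cv = float(raw["demographics"]["weight_cv"])

    def _weight_base(self, age):
        w = self._w
        age = np.asarray(age, dtype=float)
        return (
            w["w0"]
            + w["w1"] * age / (age + w["w2"])
            + w["w3"] * (1.0 - np.exp(-age / w["w4"]))
        )

    def _pubertal_hill(self, age):
        w = self._w
        age = np.asarray(age, dtype=float)
        return age ** w["w6"] / (age ** w["w6"] + w["w7"] ** w["w6"])

    def weight_for_age(self, age):
        return self._weight_base(age) + self._w5 * self._pubertal_hill(age)

    def liver_weight(self, body_weight):
        return self._lw_k * np.asarray(body_weight, dtype=float) ** self.lw_exponent

    def mppgl(self, age):
        c0, c1, c2, c3 = self._mppgl
        a = np.asarray(age, dtype=float)
        return 10.0 ** (c0 + c1 * a + c2 * a**2 + c3 * a**3)

    def hepatic_blood_flow(self, body_weight):
        bw = np.asarray(body_weight, dtype=float)
        return self.adult_qh * (bw / self.adult_weight) ** self.qh_exponent

    def gfr_frac(self, age):
        f = evaluate_ontogeny(
            get_model("eq1_sigmoid_up"), self._gfr_params, age,
            adult_reference_age=self.adult_age,
        )
        return np.minimum(f, 1.2)


@lru_cache(maxsize=4)
def _load_default() -> PhysiologyConstants:
    ref = importlib.resources.files("ontopbpk.data").joinpath("physiology.yaml")
    with ref.open("r") as fh:
        return PhysiologyConstants(yaml.safe_load(fh))


def load_constants(path: str | None = None) -> PhysiologyConstants:
    """Load the physiology constants file (packaged default if no path)."""
    if path is None:
        return _load_default()
    with open(path) as fh:
        return PhysiologyConstants(yaml.safe_load(fh))


def weight_for_age(age, constants: PhysiologyConstants | None = None):
    """Typical body weight (kg) at a postnatal age (years)."""
    c = constants or _load_default()
    out = c.weight_for_age(np.asarray(age, dtype=float))
    return float(out) if np.ndim(age) == 0 else out


def profile_for_age(
    age: float,
    body_weight: float | None = None,
    fu: float | None = None,
    BP: float | None = None,
    constants: PhysiologyConstants | None = None,
) -> PhysiologyProfile:
    """Deterministic physiology profile at a given age.

    ``body_weight`` overrides the typical weight-for-age value; liver
    weight and hepatic blood flow then scale from the supplied weight.
    ``fu``/``BP`` default to the (age-independent) adult constants and
    are normally supplied from the drug configuration.
    """
    c = constants or _load_default()
    if age < 0:
        raise ValueError("age must be >= 0")
    bw = float(body_weight) if body_weight is not None else float(c.weight_for_age(age))
    if bw <= 0:
        raise ValueError("body_weight must be > 0")
    return PhysiologyProfile(
        age=float(age),
        body_weight=bw,
        liver_weight=float(c.liver_weight(bw)),
        MPPGL=float(c.mppgl(age)),
        Q_H=float(c.hepatic_blood_flow(bw)),
        GFR_frac=float(c.gfr_frac(age)),
        fu=float(fu) if fu is not None else c.adult_fu,
        BP=float(BP) if BP is not None else c.adult_bp,
    )


def sample_demographics(
    age_range: tuple[float, float],
    n: int,
    seed: int | np.random.Generator = 0,
    weight_cv: float | None = None,
    age_distribution: str = "uniform",
    constants: PhysiologyConstants | None = None,
) -> pd.DataFrame:
    """Draw (age, body_weight, sex) for a virtual cohort.

    Ages are uniform over ``age_range`` by default (``"log-uniform"``
    enriches the youngest ages, useful for 0-2 year arms); weights are
    log-normal around the weight-for-age curve with coefficient of
    variation ``weight_cv`` (0 puts every subject exactly on the curve).
    """
    c = constants or _load_default()
    lo, hi = float(age_range[0]), float(age_range[1])
    if not (hi > lo >= 0):
        raise ValueError("age_range must satisfy 0 <= lo < hi")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if age_distribution == "uniform":
        ages = rng.uniform(lo, hi, size=n)
    elif age_distribution == "log-uniform":
        shift = 0.05  # years; keeps age 0 admissible
        ages = np.exp(rng.uniform(np.log(lo + shift), np.log(hi + shift), size=n)) - shift
    else:
        raise ValueError(f"unknown age_distribution {age_distribution!r}")
    cv = c.weight_cv if weight_cv is None else float(weight_cv)
    typical = c.weight_for_age(ages)
    if cv > 0:
        sdlog = np.sqrt(np.log(1.0 + cv**2))
        weights = typical * np.exp(rng.normal(0.0, sdlog, size=n))
    else:
        weights = typical.copy()
    sex = rng.integers(0, 2, size=n)
    return pd.DataFrame({"age": ages, "body_weight": weights, "sex": sex})
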