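"""Structural models of enzyme/transporter ontogeny.

An ontogeny function expresses the activity (or abundance) of a
drug-metabolizing enzyme or transporter at a given postnatal age as a
fraction of the typical adult value, ``F_activity(age)``.  The module
provides a registry of structural families covering the shapes seen in
maturation data:

* monotonic rise to the adult level (sigmoid Emax / Hill, Gompertz),
* monotonic decline from a higher fetal/neonatal level,
* bell-shaped profiles where activity in young children transiently
  exceeds the adult level (products or sums of a rising and a declining
  limb), and
* a flexible capped double-sigmoid.

Every family is normalized so that ``F_activity`` equals 1 at the adult
reference age (default 35 years): curves are evaluated as
``raw(age) / raw(reference)``, and families that declare an ``AGECAP``
are pinned to exactly 1 for ``age >= AGECAP`` (normalized at the cap, so
the pinning is continuous).  Ages are postnatal ages in decimal years.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields, replace

import numpy as np
import yaml

__all__ = [
    "ADULT_REFERENCE_AGE",
    "OntogenyParameters",
    "OntogenyModel",
    "OntogenyError",
    "model_registry",
    "get_model",
    "evaluate_ontogeny",
    "validate_parameters",
    "fixed_profile",
    "example_parameters",
    "to_config",
    "from_config",
]

#: Age (years) at which fractional activity is defined to be 1.
ADULT_REFERENCE_AGE = 35.0


class OntogenyError(ValueError):
    """Invalid ontogeny family or parameter set."""


@dataclass(frozen=True)
class OntogenyParameters:
    """Named parameters of the ontogeny families.

    Each family uses a declared subset (see :class:`OntogenyModel`).

    F_birth : fraction of adult activity at birth (dimensionless).
    F_max : maximum fraction of activity (dimensionless); for the
        bell-shaped product/sum families it is derived from the adult
        asymptote constraint ``F_max * (1 - FRD) = 1``.
    F_min : minimum fraction of activity (dimensionless).
    Age_up50 : age (years) to reach 50% of the maximum rise.
    gamma_u : Hill coefficient of the rising limb.
    Age_down50 : age (years) at the midpoint of the decline.
    gamma_d : Hill coefficient (or Gompertz rate, 1/years) of the
        declining limb.
    FRD : fractional contribution of the down slope, in [0, 1).
    K : development rate (1/years) of Gompertz/exponential limbs.
    AGECAP : age (years) at which fractional activity is pinned to 1.
    """

    F_birth: float | None = None
    F_max: float | None = None
    F_min: float | None = None
    Age_up50: float | None = None
    gamma_u: float | None = None
    Age_down50: float | None = None
    gamma_d: float | None = None
    FRD: float | None = None
    K: float | None = None
    AGECAP: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    def with_updates(self, **kwargs: float) -> "OntogenyParameters":
        return replace(self, **kwargs)


PARAMETER_FIELDS = tuple(f.name for f in fields(OntogenyParameters))


@dataclass(frozen=True)
class OntogenyModel:
    """A structural family: identifier, free-parameter roster, cap flag.

    ``parameter_roster`` lists the free (estimable) parameters;
    ``derived`` lists parameters fixed by the adult-asymptote constraint
    (``F_max = 1 / (1 - FRD)`` for the bell-shaped families).
    """

    family_id: str
    parameter_roster: tuple[str, ...]
    capped: bool = False
    derived: tuple[str, ...] = ()

    @property
    def n_free_parameters(self) -> int:
        return len(self.parameter_roster)


# ---------------------------------------------------------------------------
# building blocks (raw, un-normalized curves)
# ---------------------------------------------------------------------------

def _hill(age, a50, gamma):
    age = np.asarray(age, dtype=float)
    a50 = np.float64(a50)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        s = age**gamma / (a50**gamma + age**gamma)
    return np.where(age <= 0.0, 0.0, s)


def _rise_hill(age, p):
    return p["F_birth"] + (p["F_max"] - p["F_birth"]) * _hill(
        age, p["Age_up50"], p["gamma_u"]
    )


def _rise_gompertz(age, p):
    # F_birth > 0 required; rises from F_birth at age 0 to F_max.
    age = np.asarray(age, dtype=float)
    return p["F_max"] * np.exp(
        np.log(p["F_birth"] / p["F_max"]) * np.exp(-p["K"] * age)
    )


def _down_hill(age, p):
    return 1.0 - p["FRD"] * _hill(age, p["Age_down50"], p["gamma_d"])


def _down_gompertz(age, p):
    # sigmoid decline from ~1 at birth to 1 - FRD; gamma_d is the rate.
    age = np.asarray(age, dtype=float)
    s = np.exp(-np.exp(-p["gamma_d"] * (age - p["Age_down50"])))
    return 1.0 - p["FRD"] * s


def _fmax_from_frd(p):
    return 1.0 / (1.0 - p["FRD"])


def _raw_eq1(age, p):
    return _rise_hill(age, p)


def _raw_eq2(age, p):
    return _rise_gompertz(age, p)


def _raw_eq3a(age, p):
    return p["F_min"] + (p["F_birth"] - p["F_min"]) * (
        1.0 - _hill(age, p["Age_down50"], p["gamma_d"])
    )


def _raw_eq3b(age, p):
    age = np.asarray(age, dtype=float)
    return p["F_min"] + (p["F_birth"] - p["F_min"]) * np.exp(-p["K"] * age)


def _raw_eq4a(age, p):
    p = {**p, "F_max": _fmax_from_frd(p)}
    return _rise_hill(age, p) * _down_hill(age, p)


def _raw_eq4b(age, p):
    p = {**p, "F_max": _fmax_from_frd(p)}
    return _rise_hill(age, p) * _down_gompertz(age, p)


def _raw_eq4c(age, p):
    p = {**p, "F_max": _fmax_from_frd(p)}
    return _rise_gompertz(age, p) * _down_hill(age, p)


def _raw_eq4d(age, p):
    p = {**p, "F_max": _fmax_from_frd(p)}
    return _rise_gompertz(age, p) * _down_gompertz(age, p)


def _raw_eq4e(age, p):
    # capped variant of the Hill x Hill product
    return _raw_eq4a(age, p)


def _raw_eq4f(age, p):
    # additive up-plus-down variant
    fmax = _fmax_from_frd(p)
    up = p["F_birth"] + (fmax - p["F_birth"]) * _hill(age, p["Age_up50"], p["gamma_u"])
    down = p["FRD"] * fmax * _hill(age, p["Age_down50"], p["gamma_d"])
    return up - down


def _raw_eq4g(age, p):
    prod = _rise_hill(age, p) * _down_hill(age, p)
    return np.maximum(prod, p["F_min"])


_RAW = {
    "eq1_sigmoid_up": _raw_eq1,
    "eq2_gompertz_up": _raw_eq2,
    "eq3a_sigmoid_down": _raw_eq3a,
    "eq3b_exp_down": _raw_eq3b,
    "eq4a": _raw_eq4a,
    "eq4b": _raw_eq4b,
    "eq4c": _raw_eq4c,
    "eq4d": _raw_eq4d,
    "eq4e": _raw_eq4e,
    "eq4f": _raw_eq4f,
    "eq4g_double_sigmoid": _raw_eq4g,
}

_BELL_ROSTER = ("F_birth", "Age_up50", "gamma_u", "FRD", "Age_down50", "gamma_d")

_REGISTRY = (
    OntogenyModel("eq1_sigmoid_up", ("F_birth", "F_max", "Age_up50", "gamma_u")),
    OntogenyModel("eq2_gompertz_up", ("F_birth", "F_max", "K")),
    OntogenyModel("eq3a_sigmoid_down", ("F_birth", "F_min", "Age_down50", "gamma_d")),
    OntogenyModel("eq3b_exp_down", ("F_birth", "F_min", "K")),
    OntogenyModel("eq4a", _BELL_ROSTER, derived=("F_max",)),
    OntogenyModel("eq4b", _BELL_ROSTER, derived=("F_max",)),
    OntogenyModel(
        "eq4c",
        ("F_birth", "K", "FRD", "Age_down50", "gamma_d", "AGECAP"),
        capped=True,
        derived=("F_max",),
    ),
    OntogenyModel(
        "eq4d",
        ("F_birth", "K", "FRD", "Age_down50", "gamma_d", "AGECAP"),
        capped=True,
        derived=("F_max",),
    ),
    OntogenyModel(
        "eq4e",
        _BELL_ROSTER + ("AGECAP",),
        capped=True,
        derived=("F_max",),
    ),
    OntogenyModel("eq4f", _BELL_ROSTER, derived=("F_max",)),
    OntogenyModel(
        "eq4g_double_sigmoid",
        (
            "F_birth",
            "F_max",
            "Age_up50",
            "gamma_u",
            "FRD",
            "Age_down50",
            "gamma_d",
            "F_min",
            "AGECAP",
        ),
        capped=True,
    ),
)

_BY_ID = {m.family_id: m for m in _REGISTRY}

BELL_FAMILIES = ("eq4a", "eq4b", "eq4c", "eq4d", "eq4e", "eq4f")


def model_registry() -> list[OntogenyModel]:
    """Return the full registry of structural ontogeny families."""
    return list(_REGISTRY)


def get_model(family_id: str) -> OntogenyModel:
    try:
        return _BY_ID[family_id]
    except KeyError:
        raise OntogenyError(f"unknown ontogeny family {family_id!r}") from None


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_POSITIVE = {"Age_up50", "Age_down50", "AGECAP", "K", "gamma_u", "gamma_d"}
_NONNEGATIVE = {"F_birth", "F_max", "F_min"}


def validate_parameters(model: OntogenyModel, params: OntogenyParameters) -> list[str]:
    """Return a list of invariant violations (empty iff admissible)."""
    report: list[str] = []
    values = params.as_dict()
    needed = set(model.parameter_roster)
    for name in sorted(needed - set(values)):
        report.append(f"missing parameter {name!r} required by {model.family_id}")
    for name, value in values.items():
        if name in _POSITIVE and value <= 0:
            report.append(f"{name} must be > 0 (got {value})")
        if name in _NONNEGATIVE and value < 0:
            report.append(f"{name} must be >= 0 (got {value})")
    frd = values.get("FRD")
    if frd is not None and not (0.0 <= frd < 1.0):
        report.append(f"FRD must lie in [0, 1) (got {frd})")
    if "F_max" in model.derived and "F_max" in values and frd is not None:
        implied = 1.0 / (1.0 - frd)
        if abs(values["F_max"] * (1.0 - frd) - 1.0) > 1e-6:
            report.append(
                f"F_max is derived for {model.family_id}: expected "
                f"{implied:.6g} from FRD, got {values['F_max']}"
            )
    if model.family_id in ("eq2_gompertz_up", "eq4c", "eq4d"):
        fb = values.get("F_birth")
        if fb is not None and fb <= 0:
            report.append("F_birth must be > 0 for Gompertz-rise families")
    return report


def _check(model: OntogenyModel, params: OntogenyParameters) -> dict[str, float]:
    report = validate_parameters(model, params)
    if report:
        raise OntogenyError(
            f"invalid parameters for {model.family_id}: " + "; ".join(report)
        )
    return params.as_dict()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_ontogeny(
    model: OntogenyModel | str,
    params: OntogenyParameters,
    age,
    adult_reference_age: float = ADULT_REFERENCE_AGE,
):
    """Fraction of adult activity at ``age`` (years).

    Normalized so the value at ``adult_reference_age`` is exactly 1;
    capped families return exactly 1 for ``age >= AGECAP``.  Accepts a
    scalar or array age; negative ages are rejected.
    """
    if isinstance(model, str):
        model = get_model(model)
    p = _check(model, params)
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise OntogenyError("age must be >= 0")
    raw = _RAW[model.family_id]
    if model.capped:
        cap = p["AGECAP"]
        ref = float(raw(np.asarray(cap), p))
        if not np.isfinite(ref) or ref <= 0:
            raise OntogenyError("curve is non-positive at AGECAP")
        out = np.where(age_arr >= cap, 1.0, raw(age_arr, p) / ref)
    else:
        ref = float(raw(np.asarray(adult_reference_age), p))
        if not np.isfinite(ref) or ref <= 0:
            raise OntogenyError("curve is non-positive at the adult reference age")
        out = raw(age_arr, p) / ref
    out = np.maximum(out, 0.0)
    if np.isscalar(age) or np.ndim(age) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# packaged fixed profiles and example parameter sets
# ---------------------------------------------------------------------------

def _load_profiles() -> dict:
    ref = importlib.resources.files("ontopbpk.data").joinpath("fixed_profiles.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def fixed_profile(name: str) -> tuple[OntogenyModel, OntogenyParameters]:
    """A frozen (non-estimable) ontogeny profile, loaded from the packaged
    constants file.

    Known names: ``CYP3A_profile1``, ``CYP3A_profile2``, ``GFR_maturation``.
    These are system inputs, not estimands; the packaged constants are
    documented approximations of published maturation curves and may be
    replaced by editing the constants file.
    """
    profiles = _load_profiles()["profiles"]
    if name not in profiles:
        raise OntogenyError(
            f"unknown fixed profile {name!r}; known: {sorted(profiles)}"
        )
    return from_config(profiles[name])


def example_parameters(name: str) -> tuple[OntogenyModel, OntogenyParameters]:
    """Bundled example parameter sets (e.g. ``risdiplam_case``, a bell-shaped
    curve peaking near 2 years at roughly three times the adult activity)."""
    examples = _load_profiles()["examples"]
    if name not in examples:
        raise OntogenyError(f"unknown example {name!r}; known: {sorted(examples)}")
    return from_config(examples[name])


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def to_config(model: OntogenyModel, params: OntogenyParameters) -> dict:
    return {"family": model.family_id, "parameters": dict(params.as_dict())}


def from_config(block: dict) -> tuple[OntogenyModel, OntogenyParameters]:
    model = get_model(block["family"])
    raw = {str(k): float(v) for k, v in block.get("parameters", {}).items()}
    unknown = set(raw) - set(PARAMETER_FIELDS)
    if unknown:
        raise OntogenyError(f"unknown ontogeny parameters: {sorted(unknown)}")
    return model, OntogenyParameters(**raw)
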