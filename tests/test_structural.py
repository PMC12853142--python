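"""Reduced PBPK structural model: clearance scaling, pathway partition,
concentration predictions."""

import numpy as np
import pytest

from ontopbpk import ontogeny as ont
from ontopbpk.physiology import load_constants, profile_for_age
from ontopbpk.structural import (
    UL_PER_MIN_TO_L_PER_H,
    DoseEvent,
    auc,
    fraction_metabolized,
    hepatic_intrinsic_clearance,
    individual_parameters,
    load_drug_config,
    mass_balance_fractions,
    predict_concentration,
    well_stirred,
)


@pytest.fixture(scope="module")
def adult(drug_mod):
    return profile_for_age(35.0, fu=drug_mod.fu, BP=drug_mod.BP)


@pytest.fixture(scope="module")
def drug_mod():
    import ontopbpk as op
    return op.load_example_drug()


# ---------------------------------------------------------------------------
# well-stirred liver
# ---------------------------------------------------------------------------

def test_well_stirred_closed_form():
    assert well_stirred(0.0, 90.0, 1.0) == (0.0, 1.0)
    cl_h, f_h = well_stirred(10.0, 90.0, 1.0)
    assert cl_h == pytest.approx(9.0)
    assert f_h == pytest.approx(0.9)
    cl_hi, f_hi = well_stirred(1e9, 90.0, 1.0)
    assert cl_hi == pytest.approx(90.0, rel=1e-6)
    assert f_hi == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        well_stirred(10.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# intrinsic clearance scaling and fm partition
# ---------------------------------------------------------------------------

def test_adult_clint_hand_unit_conversion(drug_mod, adult):
    total, per = hepatic_intrinsic_clearance(drug_mod, adult, 35.0)
    # hand unit conversion oracle: uL/min/mg * mg protein -> L/h
    expected = sum(
        v * adult.MPPGL * adult.liver_weight * UL_PER_MIN_TO_L_PER_H
        for v in drug_mod.CLint_per_mg.values()
    )
    assert total == pytest.approx(expected, rel=1e-9)
    assert set(per) == {"FMO3", "CYP3A"}


def test_adult_partition_matches_config(drug_mod, adult):
    part = fraction_metabolized(drug_mod, adult, 35.0)
    assert part.fm["FMO3"] == pytest.approx(0.75, abs=1e-9)
    assert part.fm["CYP3A"] == pytest.approx(0.20, abs=1e-9)
    assert part.fe_renal == pytest.approx(0.05, abs=1e-9)


def test_child_partition_hand_arithmetic(drug_mod, adult):
    # FMO3 activity tripled, CYP3A and renal unchanged relative to the
    # hepatic capacity: low-extraction arithmetic gives
    # 0.75*3 / (0.75*3 + 0.20 + 0.05) = 0.90 etc.
    per_mg = dict(drug_mod.CLint_per_mg)
    per_mg["FMO3"] *= 3.0
    from dataclasses import replace
    tripled = replace(drug_mod, CLint_per_mg=per_mg)
    part = fraction_metabolized(tripled, adult, 35.0)
    assert part.fm["FMO3"] == pytest.approx(0.90, abs=0.005)
    assert part.fm["CYP3A"] == pytest.approx(0.08, abs=0.005)
    assert part.fe_renal == pytest.approx(0.02, abs=0.005)


def test_partition_sums_to_one_across_ages(drug_mod):
    for age in (0.1, 0.5, 2.0, 8.0, 18.0, 35.0):
        physio = profile_for_age(age, fu=drug_mod.fu, BP=drug_mod.BP)
        part = fraction_metabolized(drug_mod, physio, age)
        assert sum(part.fm.values()) + part.fe_renal == pytest.approx(1.0)


def test_fm_cyp3a_decreases_as_fmo3_rises(drug_mod, adult):
    from dataclasses import replace
    fm_values = []
    for scale in (1.0, 2.0, 3.0):
        per_mg = dict(drug_mod.CLint_per_mg)
        per_mg["FMO3"] *= scale
        part = fraction_metabolized(replace(drug_mod, CLint_per_mg=per_mg),
                                    adult, 35.0)
        fm_values.append(part.fm["CYP3A"])
    assert fm_values[0] > fm_values[1] > fm_values[2]


def test_low_extraction_at_all_ages(drug_mod):
    for age in np.geomspace(0.05, 35.0, 30):
        physio = profile_for_age(age, fu=drug_mod.fu, BP=drug_mod.BP)
        p = individual_parameters(drug_mod, physio, age)
        assert p.CL_H / physio.Q_H < 0.3


def test_backcalculation_round_trip():
    cfg = {"name": "x", "FaFg": 0.9, "ka": 0.8, "V_ref": 100.0, "fu": 0.2,
           "BP": 1.1, "adult_CL_total": 4.0,
           "adult_fm": {"A": 0.6, "B": 0.3}, "adult_fe_renal": 0.1}
    d = load_drug_config(cfg)
    adult = profile_for_age(35.0, fu=d.fu, BP=d.BP)
    part = fraction_metabolized(d, adult, 35.0)
    assert part.fm["A"] == pytest.approx(0.6, abs=1e-9)
    assert part.fm["B"] == pytest.approx(0.3, abs=1e-9)
    assert part.fe_renal == pytest.approx(0.1, abs=1e-9)


# ---------------------------------------------------------------------------
# individual parameters
# ---------------------------------------------------------------------------

def test_volume_allometry_exponent_one(drug_mod):
    c = load_constants()
    full = individual_parameters(
        drug_mod, profile_for_age(35.0, body_weight=70.0), 35.0, constants=c)
    half = individual_parameters(
        drug_mod, profile_for_age(35.0, body_weight=35.0), 35.0, constants=c)
    assert half.V == pytest.approx(full.V / 2.0)


def test_eta_applies_before_well_stirred(drug_mod, adult):
    base_int, _ = hepatic_intrinsic_clearance(drug_mod, adult, 35.0)
    doubled = individual_parameters(drug_mod, adult, 35.0,
                                    eta={"cl": np.log(2.0)})
    cl_h, _ = well_stirred(2.0 * base_int, adult.Q_H, drug_mod.fu_B)
    assert doubled.CL_H == pytest.approx(cl_h, rel=1e-9)
    # multiplying CL_H itself by 2 would overshoot the saturating transform
    base = individual_parameters(drug_mod, adult, 35.0)
    assert doubled.CL_H < 2.0 * base.CL_H


# ---------------------------------------------------------------------------
# concentration-time predictions
# ---------------------------------------------------------------------------

def test_prediction_zero_at_dose_time(drug_mod, adult):
    p = individual_parameters(drug_mod, adult, 35.0)
    c = predict_concentration(p, [DoseEvent(5.0, 0.0)], [0.0])
    assert c[0] == 0.0


def test_analytic_matches_ode(drug_mod, adult):
    rng = np.random.default_rng(5)
    p0 = individual_parameters(drug_mod, adult, 35.0)
    for _ in range(3):
        from ontopbpk.structural import IndividualPKParams
        p = IndividualPKParams(
            CL_H=p0.CL_H * rng.uniform(0.5, 2.0),
            CL_R=p0.CL_R, F=p0.F,
            V=p0.V * rng.uniform(0.5, 2.0),
            ka=p0.ka * rng.uniform(0.5, 2.0))
        doses = [DoseEvent(5.0, 0.0), DoseEvent(5.0, 24.0)]
        t = np.linspace(0.5, 96.0, 40)
        ca = predict_concentration(p, doses, t)
        co = predict_concentration(p, doses, t, method="ode")
        assert np.max(np.abs(ca - co) / co) < 1e-6


def test_ka_equals_ke_limit(drug_mod, adult):
    from ontopbpk.structural import IndividualPKParams
    v, cl = 100.0, 5.0
    exact = IndividualPKParams(CL_H=cl, CL_R=0.0, F=1.0, V=v, ka=cl / v)
    near = IndividualPKParams(CL_H=cl, CL_R=0.0, F=1.0, V=v,
                              ka=cl / v * (1.0 + 1e-7))
    t = np.linspace(0.5, 100.0, 50)
    c1 = predict_concentration(exact, [DoseEvent(10.0)], t)
    c2 = predict_concentration(near, [DoseEvent(10.0)], t)
    assert np.allclose(c1, c2, rtol=1e-5)
    assert np.all(c1 >= 0)


def test_auc_identities(drug_mod, adult):
    p = individual_parameters(drug_mod, adult, 35.0)
    a = auc(p, 100.0)
    assert a == pytest.approx(100.0 * p.F / p.CL * 1000.0)
    # doubling clearance halves the exposure
    from dataclasses import replace as drep
    from ontopbpk.structural import IndividualPKParams
    p2 = IndividualPKParams(CL_H=2 * p.CL_H, CL_R=2 * p.CL_R, F=p.F,
                            V=p.V, ka=p.ka)
    assert auc(p2, 100.0) == pytest.approx(a / 2.0)
    # trapezoid-to-the-tail agrees with Dose*F/CL under linear PK
    t = np.linspace(0.0, 4000.0, 40000)
    conc = predict_concentration(p, [DoseEvent(100.0)], t)
    a_num = np.trapezoid(conc, t)
    assert abs(a_num / a - 1.0) < 1e-3
    with pytest.raises(ValueError):
        auc(IndividualPKParams(CL_H=0.0, CL_R=0.0, F=1.0, V=10.0, ka=1.0),
            10.0)


def test_steady_state_auc_equals_single_dose(drug_mod, adult):
    p = individual_parameters(drug_mod, adult, 35.0)
    t = np.linspace(0.0, 24.0, 2000)
    conc_ss = predict_concentration(
        p, [DoseEvent(5.0, 0.0, ss=True, ii=24.0)], t)
    a_ss = np.trapezoid(conc_ss, t)
    assert a_ss == pytest.approx(auc(p, 5.0), rel=2e-3)


# ---------------------------------------------------------------------------
# pathway-flux mass balance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("age", [0.5, 2.0, 35.0])
def test_mass_balance_matches_partition(drug_mod, age):
    physio = profile_for_age(age, fu=drug_mod.fu, BP=drug_mod.BP)
    part = fraction_metabolized(drug_mod, physio, age)
    sim = mass_balance_fractions(drug_mod, physio, age)
    for pth in part.fm:
        assert abs(sim.fm[pth] - part.fm[pth]) < 0.005
    assert abs(sim.fe_renal - part.fe_renal) < 0.005
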