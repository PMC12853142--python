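"""Laplace NLME engine: likelihood oracles, degenerate limits,
estimation invariances, estimator interface."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import ontopbpk as op
from ontopbpk.dataio import PKDataset
from ontopbpk.model import OntogenyNlme
from ontopbpk.nlme import (
    LaplaceEngine,
    PopulationModelSpec,
    _FitData,
    agq_ofv,
    empirical_bayes,
    fit,
    laplace_ofv,
)

from _oracles import LinearModelEngine, closed_form_linear_ofv


def _toy_dataset(n_subjects=4, n_obs=3, seed=0):
    """Minimal dataset scaffold (values are overridden by the linear
    oracle engine; the structural columns just have to validate)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(1, n_subjects + 1):
        rows.append(dict(ID=sid, TIME=0.0, AMT=5.0, EVID=1, MDV=1,
                         DV=np.nan, AGE=30.0, WT=70.0, SS=1, II=24.0))
        for t in np.linspace(2, 20, n_obs):
            rows.append(dict(ID=sid, TIME=t, AMT=np.nan, EVID=0, MDV=0,
                             DV=float(rng.uniform(5, 15)), AGE=30.0,
                             WT=70.0, SS=0, II=np.nan))
    return PKDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# oracle 1: closed-form linear-Gaussian marginal likelihood
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,omega_diag,sig", [
    (1, [0.09], 0.5),
    (1, [0.4], 1.5),
    (2, [0.09, 0.04], 0.8),
])
def test_laplace_exact_for_linear_gaussian(drug, k, omega_diag, sig):
    data = _toy_dataset(n_subjects=5, n_obs=4, seed=k)
    eta_names = ("cl", "v")[:k]
    spec = PopulationModelSpec(
        drug=drug, eta_names=eta_names,
        omega={n: w for n, w in zip(eta_names, omega_diag)},
        sigma=(0.0, sig))
    rng = np.random.default_rng(10 + k)
    fd = _FitData(data)
    a = rng.uniform(5.0, 15.0, size=fd.dv.shape)
    b = rng.uniform(-2.0, 2.0, size=fd.dv.shape + (k,))
    engine = LinearModelEngine(spec, fd, a, b)
    got = engine.ofv()
    expected = closed_form_linear_ofv(a, b, fd.dv, fd.mask,
                                      np.diag(omega_diag), sig)
    assert abs(got - expected) < 1e-8


# ---------------------------------------------------------------------------
# oracle 2: adaptive Gauss-Hermite quadrature on nonlinear cases
# ---------------------------------------------------------------------------

AGQ_CASES = [
    dict(eta_names=("cl",), omega={"cl": 0.09}, sigma=(0.15, 0.0)),
    dict(eta_names=("cl",), omega={"cl": 0.5}, sigma=(0.25, 0.0)),
    dict(eta_names=("cl",), omega={"cl": 0.09}, sigma=(0.10, 5.0)),
    dict(eta_names=("cl", "v"), omega={"cl": 0.09, "v": 0.09},
         sigma=(0.15, 0.0)),
    dict(eta_names=("cl", "v"), omega={"cl": 0.3, "v": 0.15},
         sigma=(0.20, 2.0)),
]


@pytest.mark.parametrize("case", AGQ_CASES)
def test_laplace_close_to_quadrature(drug, adult_data, case):
    small = PKDataset(adult_data.df[adult_data.df["ID"] <= 3].copy())
    spec = PopulationModelSpec(drug=drug, **case)
    lap = laplace_ofv(spec, small)
    quad = agq_ofv(spec, small, n_nodes=21)
    assert abs(lap - quad) < 0.1


# ---------------------------------------------------------------------------
# degenerate limits and invariances
# ---------------------------------------------------------------------------

def test_zero_omega_reduces_to_fixed_effect_deviance(drug, adult_data):
    spec = PopulationModelSpec(drug=drug, sigma=(0.15, 0.0))
    got = laplace_ofv(spec, adult_data, omega={"cl": 0.0, "v": 0.0})
    engine = LaplaceEngine(spec, adult_data)
    pred = engine.predict(spec.theta, np.zeros((engine.fd.n, 2)))
    var = (0.15 * pred) ** 2 + 1e-12
    fd = engine.fd
    expected = float(np.sum(((fd.dv - pred) ** 2 / var
                             + np.log(2 * np.pi * var)) * fd.mask))
    assert got == pytest.approx(expected, rel=1e-10)


def test_ofv_invariant_to_subject_order(drug, adult_data):
    spec = PopulationModelSpec(drug=drug)
    base = laplace_ofv(spec, adult_data)
    df = adult_data.df.copy()
    order = df["ID"].unique()[::-1]
    shuffled = pd.concat([df[df["ID"] == i] for i in order],
                         ignore_index=True)
    assert laplace_ofv(spec, PKDataset(shuffled)) == pytest.approx(
        base, abs=1e-6)


def test_dv_rescaling_shifts_ofv_by_jacobian(drug, adult_data):
    # with proportional-only error, DV -> c*DV matched by a purely linear
    # output scale (bioavailability here) leaves the standardized
    # residuals unchanged: OFV shifts by the Jacobian term 2*n*log(c)
    c = 0.5
    spec = PopulationModelSpec(drug=drug, sigma=(0.15, 0.0))
    base = laplace_ofv(spec, adult_data)
    df = adult_data.df.copy()
    df.loc[df["EVID"] == 0, "DV"] *= c
    theta = dict(spec.theta)
    theta["FaFg"] = theta["FaFg"] * c
    shifted = laplace_ofv(spec, PKDataset(df), theta=theta)
    n_obs = int((df["EVID"] == 0).sum())
    assert shifted - base == pytest.approx(2.0 * n_obs * np.log(c), abs=1e-4)


def test_non_psd_omega_rejected(drug, adult_data):
    spec = PopulationModelSpec(drug=drug)
    with pytest.raises(ValueError):
        laplace_ofv(spec, adult_data, omega={"cl": -0.1, "v": 0.09})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_all_fixed_fit_returns_ofv_at_inits(drug, adult_data):
    spec = PopulationModelSpec(drug=drug, estimate=(),
                               estimate_omega=False, estimate_sigma=False)
    res = fit(spec, adult_data)
    assert res.n_iter == 0
    assert res.ofv == pytest.approx(laplace_ofv(spec, adult_data))
    assert res.converged


def test_noise_free_recovery(drug):
    # omega = 0, near-zero residual, rich sampling: thetas come back
    design = op.TrialDesign(arms=(op.TrialArm((18.0, 61.0), 12, dose_mg=5.0,
                                              n_samples=8),))
    truth = drug
    data = op.simulate_trial(design, truth, omega={"cl": 0.0, "v": 0.0},
                             sigma=(1e-4, 0.0), seed=2)
    spec = PopulationModelSpec(
        drug=drug, estimate=("CLint", "V_ref"),
        theta={"CLint": 1.3, "V_ref": 150.0},
        omega={"cl": 0.0, "v": 0.0}, sigma=(1e-4, 0.0),
        estimate_omega=False, estimate_sigma=False)
    res = fit(spec, data, compute_se=False)
    assert abs(res.theta["CLint"] - 1.0) < 0.005
    assert abs(res.theta["V_ref"] / 210.0 - 1.0) < 0.005
    assert res.ofv <= res.ofv_init


def test_superfluous_parameter_never_raises_ofv(drug, adult_data):
    lean = PopulationModelSpec(drug=drug, estimate=("CLint",),
                               estimate_omega=False, estimate_sigma=False)
    rich = replace(lean, estimate=("CLint", "V_ref", "ka"))
    res_lean = fit(lean, adult_data, compute_se=False)
    res_rich = fit(rich, adult_data, compute_se=False)
    assert res_rich.ofv <= res_lean.ofv + 1e-6


def test_fit_reports_standard_errors(drug, adult_data):
    spec = PopulationModelSpec(drug=drug, estimate=("CLint", "V_ref"))
    res = fit(spec, adult_data, compute_se=True)
    assert set(res.theta_se) == {"CLint", "V_ref"}
    assert all(se > 0 for se in res.theta_se.values())
    assert np.isfinite(res.condition_number)


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def test_ebe_prior_mode_without_observations(drug, adult_data):
    df = adult_data.df.copy()
    first = df["ID"].iloc[0]
    extra = df[(df["ID"] == first) & (df["EVID"] == 1)].copy()
    extra["ID"] = 9999  # dose-only subject, no observations
    data = PKDataset(pd.concat([df, extra], ignore_index=True))
    spec = PopulationModelSpec(drug=drug, estimate=(),
                               estimate_omega=False, estimate_sigma=False)
    res = fit(spec, data)
    ebe = empirical_bayes(spec, data, res, subject_id=9999)
    assert ebe["eta_cl"].iloc[0] == pytest.approx(0.0, abs=1e-6)
    assert ebe["eta_v"].iloc[0] == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(KeyError):
        empirical_bayes(spec, data, res, subject_id="nope")


def test_ebe_shrinks_to_zero_as_omega_vanishes(drug, adult_data):
    spec = PopulationModelSpec(drug=drug, estimate=(),
                               estimate_omega=False, estimate_sigma=False,
                               omega={"cl": 1e-6, "v": 1e-6})
    res = fit(spec, adult_data)
    ebe = empirical_bayes(spec, adult_data, res)
    assert np.max(np.abs(ebe[["eta_cl", "eta_v"]].to_numpy())) < 0.01


def test_ebe_recovers_known_eta_with_rich_data(drug):
    design = op.TrialDesign(arms=(op.TrialArm((18.0, 61.0), 6, dose_mg=5.0,
                                              n_samples=10),))
    data = op.simulate_trial(design, drug, omega={"cl": 0.09, "v": 0.09},
                             sigma=(0.005, 0.0), seed=8)
    # regenerate the true etas exactly as the simulator drew them
    rng = np.random.default_rng(8)
    from ontopbpk.physiology import sample_demographics
    demo = sample_demographics((18.0, 61.0), 6, seed=rng)
    true_etas = []
    for _ in range(6):
        true_etas.append({k: rng.normal(0.0, 0.3)
                          for k in ("cl", "v")})
        rng.uniform(0.5, 24.0, size=10)  # consume sampling-time draws
        rng.normal(size=10)              # consume residual draws
    spec = PopulationModelSpec(drug=drug, estimate=(),
                               estimate_omega=False, estimate_sigma=False,
                               sigma=(0.005, 0.0))
    res = fit(spec, data)
    ebe = empirical_bayes(spec, data, res)
    got = ebe["eta_cl"].to_numpy()
    want = np.array([e["cl"] for e in true_etas])
    assert np.max(np.abs(got - want)) < 0.05 * max(1.0, np.abs(want).max())


# ---------------------------------------------------------------------------
# sklearn-style estimator surface
# ---------------------------------------------------------------------------

def test_estimator_interface(drug, adult_data):
    from sklearn.base import clone
    est = OntogenyNlme(drug=drug, target_pathway=None, ontogeny_family=None,
                       estimate=("CLint", "V_ref"), compute_se=False)
    cloned = clone(est)
    assert cloned.get_params()["estimate"] == ("CLint", "V_ref")
    est.fit(adult_data.df)
    assert hasattr(est, "ofv_") and np.isfinite(est.ofv_)
    assert est.theta_["CLint"] > 0
    pred = est.predict(adult_data.df)
    assert pred.shape == (adult_data.n_observations,)
    assert np.all(pred >= 0)
    with pytest.raises(RuntimeError):
        OntogenyNlme(drug=drug).predict(adult_data.df)
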