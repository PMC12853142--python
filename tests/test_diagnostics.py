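"""Qualification diagnostics: post hoc scan, family scan, bootstrap,
VPC, GOF, external comparison."""

import numpy as np
import pandas as pd
import pytest

import ontopbpk as op
from ontopbpk import ontogeny as ont
from ontopbpk.dataio import PKDataset
from ontopbpk.diagnostics import (
    OntogenyScanResult,
    bootstrap,
    compare_external,
    gof,
    ontogeny_scan,
    posthoc_age_scan,
    vpc,
)
from ontopbpk.nlme import PopulationModelSpec


@pytest.fixture(scope="module")
def scan_spec(drug):
    return PopulationModelSpec(drug=drug, target_pathway="FMO3",
                               ontogeny_family=None,
                               estimate=("CLint", "V_ref"))


# ---------------------------------------------------------------------------
# post hoc CL_int-vs-age scan
# ---------------------------------------------------------------------------

def test_posthoc_scan_flat_truth(scan_spec, flat_data):
    res = posthoc_age_scan(scan_spec, flat_data)
    assert res.classification == "flat"
    assert res.spearman_ci[0] <= 0.0 <= res.spearman_ci[1]
    assert len(res.table) == flat_data.n_subjects


def test_posthoc_scan_bell_truth(scan_spec, bell_data):
    res = posthoc_age_scan(scan_spec, bell_data)
    assert res.classification == "bell"
    # elevated post hoc CL_int clusters in the 1-4 y range
    toddlers = res.table[(res.table["age"] >= 1.0) & (res.table["age"] <= 4.0)]
    adults = res.table[res.table["age"] >= 18.0]
    assert toddlers["posthoc_cl_ratio"].median() > \
        2.0 * adults["posthoc_cl_ratio"].median()


# ---------------------------------------------------------------------------
# multi-family scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scan_result(scan_spec, bell_data):
    return ontogeny_scan(scan_spec, bell_data, ("eq4a", "eq4f"))


def test_scan_retains_all_families(scan_result):
    assert set(scan_result.table["family"]) == {"eq4a", "eq4f"}
    assert (scan_result.table["delta_ofv"].min() == 0.0)
    assert (scan_result.table["delta_aic"].min() == 0.0)
    assert scan_result.best_family in ("eq4a", "eq4f")


def test_scan_order_invariant(scan_spec, bell_data, scan_result):
    other = ontogeny_scan(scan_spec, bell_data, ("eq4f", "eq4a"))
    pd.testing.assert_frame_equal(
        other.table.reset_index(drop=True),
        scan_result.table.reset_index(drop=True))
    assert other.best_family == scan_result.best_family


def test_scan_curves_recover_truth(scan_result, drug):
    model, params = ont.example_parameters("risdiplam_case")
    ages = scan_result.curves["age"].to_numpy()
    keep = ages >= 1.0 / 3.0
    truth = ont.evaluate_ontogeny(model, params, ages[keep])
    best = scan_result.curves[scan_result.best_family].to_numpy()[keep]
    mae = np.mean(np.abs(best - truth) / truth)
    assert mae < 0.15


def test_scan_requires_families(scan_spec, bell_data):
    with pytest.raises(ValueError):
        ontogeny_scan(scan_spec, bell_data, ())


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_reproducible(drug, adult_data):
    spec = PopulationModelSpec(drug=drug, estimate=("CLint", "V_ref"))
    ci1 = bootstrap(spec, adult_data, n_resamples=3, seed=7)
    ci2 = bootstrap(spec, adult_data, n_resamples=3, seed=7)
    pd.testing.assert_frame_equal(ci1, ci2)
    assert (ci1["p2.5"] <= ci1["p50"]).all()
    assert (ci1["p50"] <= ci1["p97.5"]).all()


def test_bootstrap_degenerate_design_rejected(drug, adult_data):
    spec = PopulationModelSpec(drug=drug)
    one = adult_data.df[adult_data.df["ID"] == adult_data.df["ID"].iloc[0]]
    with pytest.raises(ValueError, match="degenerate"):
        bootstrap(spec, PKDataset(one.copy()), n_resamples=2, seed=0)
    with pytest.raises(ValueError):
        bootstrap(spec, adult_data, n_resamples=0, seed=0)


# ---------------------------------------------------------------------------
# VPC
# ---------------------------------------------------------------------------

def test_vpc_reproducible(base_spec, bell_data):
    v1 = vpc(base_spec, bell_data, n_sim=50, seed=4)
    v2 = vpc(base_spec, bell_data, n_sim=50, seed=4)
    pd.testing.assert_frame_equal(v1.table, v2.table)


def test_vpc_bands_collapse_without_variability(drug):
    design = op.TrialDesign(arms=(op.TrialArm((18.0, 40.0), 8, dose_mg=5.0),))
    data = op.simulate_trial(design, drug, omega={"cl": 0.0, "v": 0.0},
                             sigma=(1e-12, 0.0), seed=2)
    spec = PopulationModelSpec(drug=drug, omega={"cl": 0.0, "v": 0.0},
                               sigma=(1e-12, 1e-9))
    v = vpc(spec, data, n_sim=30, seed=3)
    t = v.table
    # every simulated band degenerates onto the prediction percentiles
    for tag in ("p5", "p50", "p95"):
        assert np.allclose(t[f"sim_{tag}_lo"], t[f"sim_{tag}_hi"], rtol=1e-5)
        assert np.allclose(t[f"obs_{tag}"], t[f"sim_{tag}_med"], rtol=1e-4)


def test_vpc_percentiles_ordered(base_spec, bell_data):
    v = vpc(base_spec, bell_data, n_sim=50, seed=4)
    t = v.table
    assert (t["obs_p5"] <= t["obs_p50"]).all()
    assert (t["obs_p50"] <= t["obs_p95"]).all()
    assert (t["sim_p50_lo"] <= t["sim_p50_med"]).all()
    assert (t["sim_p50_med"] <= t["sim_p50_hi"]).all()


# ---------------------------------------------------------------------------
# GOF
# ---------------------------------------------------------------------------

def test_gof_residual_contract_under_true_model(base_spec, bell_data, drug):
    from ontopbpk.nlme import fit
    spec = PopulationModelSpec(drug=drug, estimate=(),
                               estimate_omega=False, estimate_sigma=False)
    res = fit(spec, bell_data)
    table = gof(spec, bell_data, res)
    assert len(table) == bell_data.n_observations
    assert abs(table.attrs["residual_mean"]) < 0.1
    assert 0.8 < table.attrs["residual_var"] < 1.2


def test_gof_flags_age_trend_when_ontogeny_omitted(flat_drug, bell_data):
    from ontopbpk.nlme import fit
    spec = PopulationModelSpec(drug=flat_drug, estimate=("CLint", "V_ref"))
    res = fit(spec, bell_data, compute_se=False)
    table = gof(spec, bell_data, res)
    assert table.attrs["residual_age_trend_p"] < 0.01


def test_gof_noise_free_residuals_vanish(drug):
    design = op.TrialDesign(arms=(op.TrialArm((18.0, 40.0), 5, dose_mg=5.0),))
    data = op.simulate_trial(design, drug, omega={"cl": 0.0, "v": 0.0},
                             sigma=(1e-12, 0.0), seed=6)
    from ontopbpk.nlme import fit
    spec = PopulationModelSpec(drug=drug, estimate=(),
                               omega={"cl": 1e-8, "v": 1e-8},
                               sigma=(1e-6, 0.0),
                               estimate_omega=False, estimate_sigma=False)
    res = fit(spec, data)
    table = gof(spec, data, res)
    assert np.max(np.abs(table["DV"] - table["IPRED"]) / table["DV"]) < 1e-3


# ---------------------------------------------------------------------------
# external comparison
# ---------------------------------------------------------------------------

def _toy_scan(curve_params):
    ages = np.geomspace(0.05, 20.0, 50)
    model, params = curve_params
    curves = pd.DataFrame({
        "age": ages,
        "truth": np.asarray(ont.evaluate_ontogeny(model, params, ages)),
    })
    return OntogenyScanResult(
        fits={"truth": None}, table=pd.DataFrame(), curves=curves,
        agreement=pd.DataFrame(), best_family="truth", retained=("truth",))


def test_compare_external_arithmetic():
    scan = _toy_scan(ont.example_parameters("risdiplam_case"))
    ages = scan.curves["age"]
    pred_at_2 = float(np.interp(2.0, ages, scan.curves["truth"]))
    out = compare_external(scan, [(2.0, pred_at_2, "self"),
                                  (2.0, pred_at_2 / 2.0, "half")])
    assert out["fold_difference"].iloc[0] == pytest.approx(1.0)
    assert out["fold_difference"].iloc[1] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        compare_external(scan, [(2.0, -1.0, "bad")])
    with pytest.raises(ValueError):
        compare_external(scan, [])


def test_compare_external_noisy_truth_mostly_within_twofold():
    scan = _toy_scan(ont.example_parameters("risdiplam_case"))
    rng = np.random.default_rng(12)
    model, params = ont.example_parameters("risdiplam_case")
    ages = rng.uniform(0.3, 10.0, size=40)
    truth = np.asarray(ont.evaluate_ontogeny(model, params, ages))
    noisy = truth * (1.0 + 0.3 * rng.standard_normal(40))
    pts = [(a, max(v, 1e-3), "invitro") for a, v in zip(ages, noisy)]
    out = compare_external(scan, pts)
    assert out["within_2fold"].mean() >= 0.8
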