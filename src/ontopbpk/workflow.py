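"""End-to-end workflow: adult check, pediatric adaptation, ontogeny
estimation, qualification, extrapolation.

``run_workflow`` executes the recommended sequence for estimating
enzyme/transporter ontogeny from sparse data and writes every artifact
(CSV tables, a few plots, a JSON manifest recording seeds and versions)
under one output directory.  Stages:

1. adult subset fit (anchors CLint/V in adults),
2. pediatric adaptation with the target ontogeny forced flat, with a
   bias check on absorption/volume,
3. post hoc CL_int-vs-age scan (suggests the maturation shape),
4. multi-family ontogeny scan with AIC ranking,
5. qualification of the best family (bootstrap, GOF, VPC),
6. optional external-plausibility comparison and extrapolation
   (neonate exposure, DDI ratios).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from . import ontogeny as _ont
from .dataio import PKDataset, read_dataset, write_dataset
from .diagnostics import (
    bootstrap,
    compare_external,
    gof,
    ontogeny_scan,
    posthoc_age_scan,
    vpc,
)
from .extrapolate import DDIScenario, ddi_auc_ratio, extrapolate_exposure, fm_vs_age
from .nlme import PopulationModelSpec, fit as _fit
from .structural import DrugParameters, load_drug_config, load_example_drug

__all__ = ["RunConfig", "run_workflow"]


@dataclass
class RunConfig:
    """Configuration of one workflow run."""

    dataset: str | PKDataset
    drug: str | dict | DrugParameters = "risdiplam_like"
    target_pathway: str = "FMO3"
    families: tuple[str, ...] = ("eq4a", "eq4c", "eq4f")
    seed: int = 0
    output_dir: str = "ontopbpk_run"
    overwrite: bool = False
    n_bootstrap: int = 20
    n_vpc: int = 200
    external_points: tuple = ()          # (age, fraction_of_adult, source)
    extrapolate_age_days: float | None = None
    extrapolate_dose_mg_per_kg: float | None = None
    ddi_ages: tuple[float, ...] = ()
    fit_options: dict = field(default_factory=dict)


def _resolve_drug(drug) -> DrugParameters:
    if isinstance(drug, DrugParameters):
        return drug
    if isinstance(drug, dict):
        return load_drug_config(drug)
    if isinstance(drug, str):
        if os.path.exists(drug):
            return load_drug_config(drug)
        return load_example_drug(drug)
    raise TypeError("drug must be DrugParameters, dict, path or bundled name")


def _write(df: pd.DataFrame, path: str, manifest: dict, stage: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["artifacts"].append({"stage": stage, "path": os.path.basename(path)})


def run_workflow(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dict (also written as
    JSON)."""
    out = config.output_dir
    if os.path.exists(out) and os.listdir(out) and not config.overwrite:
        raise FileExistsError(
            f"output directory {out!r} is not empty; pass overwrite=True")
    os.makedirs(out, exist_ok=True)
    for fam in config.families:
        _ont.get_model(fam)  # validate before any fitting

    drug = _resolve_drug(config.drug)
    data = (config.dataset if isinstance(config.dataset, PKDataset)
            else read_dataset(config.dataset))
    manifest = {"package": "ontopbpk", "version": __version__,
                "seed": config.seed, "stages": [], "artifacts": []}
    fit_opts = dict(config.fit_options)
    fit_opts.setdefault("compute_se", False)
    base = PopulationModelSpec(drug=drug, target_pathway=config.target_pathway,
                               ontogeny_family=None,
                               estimate=("CLint", "V_ref"))

    # 1. adult model check ------------------------------------------------
    df = data.df
    adult_ids = df.groupby("ID")["AGE"].first()
    adult_ids = set(adult_ids[adult_ids >= 18.0].index)
    flat_drug = drug.with_ontogeny(config.target_pathway, None)
    flat = replace(base, drug=flat_drug)
    adult_fit = None
    if adult_ids:
        adult_data = PKDataset(df[df["ID"].isin(adult_ids)].copy())
        adult_fit = _fit(flat, adult_data, **fit_opts)
        _write(adult_fit.summary(), os.path.join(out, "01_adult_fit.csv"),
               manifest, "adult_fit")
        manifest["stages"].append({"stage": "adult_fit", "ofv": adult_fit.ofv,
                                   "n_subjects": adult_fit.n_subjects})

    # 2. pediatric adaptation (flat target ontogeny) + bias check ---------
    ped_fit = _fit(replace(flat, estimate=("CLint", "V_ref", "ka")),
                   data, **fit_opts)
    _write(ped_fit.summary(), os.path.join(out, "02_pediatric_flat_fit.csv"),
           manifest, "pediatric_flat_fit")
    bias = {}
    if adult_fit is not None:
        for name in ("V_ref",):
            bias[name] = ped_fit.theta[name] / adult_fit.theta[name] - 1.0
    bias["ka_vs_config"] = ped_fit.theta["ka"] / drug.ka - 1.0
    manifest["stages"].append({"stage": "pediatric_flat_fit",
                               "ofv": ped_fit.ofv,
                               "absorption_volume_bias": bias})

    # 3. post hoc CL_int vs age scan --------------------------------------
    scan_spec = replace(flat, estimate=("CLint", "V_ref"))
    age_scan = posthoc_age_scan(scan_spec, data, **fit_opts)
    _write(age_scan.table, os.path.join(out, "03_posthoc_age_scan.csv"),
           manifest, "posthoc_age_scan")
    _write(age_scan.trend, os.path.join(out, "03_posthoc_trend.csv"),
           manifest, "posthoc_age_scan")
    manifest["stages"].append({
        "stage": "posthoc_age_scan",
        "classification": age_scan.classification,
        "spearman_rho": age_scan.spearman_rho,
        "spearman_ci": list(age_scan.spearman_ci),
    })

    # 4. multi-family ontogeny scan ---------------------------------------
    est_spec = PopulationModelSpec(
        drug=drug, target_pathway=config.target_pathway,
        ontogeny_family=None, estimate=("CLint", "V_ref"))
    scan = ontogeny_scan(est_spec, data, config.families, **fit_opts)
    _write(scan.table, os.path.join(out, "04_ontogeny_scan.csv"),
           manifest, "ontogeny_scan")
    _write(scan.curves, os.path.join(out, "04_ontogeny_curves.csv"),
           manifest, "ontogeny_scan")
    _write(scan.agreement, os.path.join(out, "04_curve_agreement.csv"),
           manifest, "ontogeny_scan")
    manifest["stages"].append({"stage": "ontogeny_scan",
                               "best_family": scan.best_family,
                               "retained": list(scan.retained)})
    best_fit = scan.fits[scan.best_family]
    best_spec = replace(
        est_spec, ontogeny_family=scan.best_family,
        theta=dict(best_fit.theta),
        estimate=tuple(best_fit.spec.estimate))

    # 5. qualification -----------------------------------------------------
    if config.n_bootstrap > 0:
        ci = bootstrap(best_spec, data, n_resamples=config.n_bootstrap,
                       seed=config.seed, **fit_opts)
        ci.insert(0, "parameter", ci.index)
        _write(ci.reset_index(drop=True),
               os.path.join(out, "05_bootstrap_ci.csv"), manifest, "bootstrap")
        manifest["stages"].append({"stage": "bootstrap",
                                   "n_resamples": config.n_bootstrap,
                                   "seed": config.seed})
    gof_df = gof(best_spec, data, best_fit)
    _write(gof_df, os.path.join(out, "05_gof.csv"), manifest, "gof")
    manifest["stages"].append({"stage": "gof",
                               "residual_mean": gof_df.attrs["residual_mean"],
                               "residual_var": gof_df.attrs["residual_var"]})
    vpc_res = vpc(best_spec, data, best_fit, n_sim=config.n_vpc,
                  seed=config.seed)
    _write(vpc_res.table, os.path.join(out, "05_vpc.csv"), manifest, "vpc")
    manifest["stages"].append({"stage": "vpc", "n_sim": config.n_vpc,
                               "seed": config.seed,
                               "median_coverage": vpc_res.coverage("p50")})
    _plots(out, age_scan, scan, vpc_res, gof_df, manifest)

    # 6. external comparison / extrapolation -------------------------------
    if config.external_points:
        ext = compare_external(scan, config.external_points)
        _write(ext, os.path.join(out, "06_external_comparison.csv"),
               manifest, "compare_external")
        manifest["stages"].append({
            "stage": "compare_external",
            "fraction_within_2fold": float(ext["within_2fold"].mean())})
    fm_table = fm_vs_age(drug, np.geomspace(0.05, 35.0, 40))
    _write(fm_table, os.path.join(out, "06_fm_vs_age.csv"), manifest, "fm_vs_age")
    if config.extrapolate_age_days is not None:
        retained = {}
        for fam in scan.retained:
            res = scan.fits[fam]
            params = _ont.OntogenyParameters(**{
                n: res.theta[n]
                for n in _ont.get_model(fam).parameter_roster})
            retained[fam] = (_ont.get_model(fam), params)
        rng_dose = config.extrapolate_dose_mg_per_kg or 0.15
        exp = extrapolate_exposure(
            drug, config.extrapolate_age_days / 365.25, retained,
            target_pathway=config.target_pathway,
            dose_mg_per_kg=rng_dose)
        _write(exp.table, os.path.join(out, "06_extrapolated_exposure.csv"),
               manifest, "extrapolate")
        manifest["stages"].append({"stage": "extrapolate",
                                   "age_days": config.extrapolate_age_days,
                                   "auc_min": exp.minimum,
                                   "auc_median": exp.median,
                                   "auc_max": exp.maximum})
    if config.ddi_ages:
        rows = []
        for age in config.ddi_ages:
            rows.append({"age": age, "aucr_complete_inhibition":
                         ddi_auc_ratio(drug, age, DDIScenario())})
        _write(pd.DataFrame(rows), os.path.join(out, "06_ddi_aucr.csv"),
               manifest, "ddi")

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _plots(out, age_scan, scan, vpc_res, gof_df, manifest) -> None:
    """Diagnostic figures (PNG) alongside the machine-readable tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(age_scan.table["age"], np.log(age_scan.table["posthoc_cl_ratio"]),
                ".", alpha=0.4)
    ax.semilogx(age_scan.trend["age"], age_scan.trend["log_posthoc_ratio"], "-")
    ax.set_xlabel("age (y)"); ax.set_ylabel("log post hoc CL_int ratio")
    ax.set_title(f"post hoc scan: {age_scan.classification}")
    fig.tight_layout(); fig.savefig(os.path.join(out, "03_posthoc_scan.png"))
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for fam in scan.fits:
        ax.semilogx(scan.curves["age"], scan.curves[fam], label=fam)
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("age (y)"); ax.set_ylabel("fraction of adult activity")
    ax.legend(fontsize=7)
    fig.tight_layout(); fig.savefig(os.path.join(out, "04_ontogeny_curves.png"))
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(gof_df["PRED"], gof_df["DV"], ".", alpha=0.3)
    lim = max(gof_df["DV"].max(), gof_df["PRED"].max())
    ax.plot([0, lim], [0, lim], "k-", lw=0.5)
    ax.set_xlabel("population prediction"); ax.set_ylabel("observed")
    fig.tight_layout(); fig.savefig(os.path.join(out, "05_gof_obs_pred.png"))
    plt.close(fig)

    for name in ("03_posthoc_scan.png", "04_ontogeny_curves.png",
                 "05_gof_obs_pred.png"):
        manifest["artifacts"].append({"stage": "plots", "path": name})
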