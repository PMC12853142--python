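"""Model qualification and the ontogeny-estimation workflow diagnostics.

Implements the scan-and-qualify sequence used when estimating enzyme
ontogeny from sparse pediatric data:

* ``posthoc_age_scan`` — fit with the target pathway's ontogeny forced
  flat, then inspect the relationship between age and the post hoc
  (empirical Bayes) intrinsic-clearance deviations; classifies the
  apparent shape (flat / rising / falling / bell).
* ``ontogeny_scan`` — estimate the ontogeny with multiple structural
  families and rank them by OFV/AIC; flags the age strata where the
  fitted curves agree (sparse early-infancy designs typically agree from
  about 4 months of age upward and diverge below).
* ``bootstrap`` — age-stratified nonparametric bootstrap for parameter
  precision.
* ``vpc`` — visual predictive check (observed percentiles vs
  simulation-based prediction bands, binned by time after dose within
  age strata and by age).
* ``gof`` — population/individual predictions and FOCE-linearized
  standardized residuals.
* ``compare_external`` — fold differences against independent ontogeny
  observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import ontogeny as _ont
from .dataio import PKDataset
from .nlme import (
    FitResult,
    LaplaceEngine,
    PopulationModelSpec,
    _FitData,
    default_ontogeny_estimate,
    default_ontogeny_inits,
    empirical_bayes,
    fit as _fit,
)

__all__ = [
    "AgeScanResult",
    "OntogenyScanResult",
    "VPCResult",
    "posthoc_age_scan",
    "ontogeny_scan",
    "bootstrap",
    "vpc",
    "gof",
    "compare_external",
]

DEFAULT_AGE_BANDS = (0.0, 2.0, 12.0, 18.0, np.inf)
DEFAULT_AGE_GRID = np.geomspace(0.05, 20.0, 60)


# ---------------------------------------------------------------------------
# post hoc CL_int vs age scan
# ---------------------------------------------------------------------------

@dataclass
class AgeScanResult:
    table: pd.DataFrame          # ID, age, posthoc CL_int ratio
    classification: str          # flat / rising / falling / bell
    spearman_rho: float
    spearman_ci: tuple[float, float]
    trend: pd.DataFrame          # lowess curve on a log-age grid
    fit: FitResult


def _flat_spec(spec: PopulationModelSpec) -> PopulationModelSpec:
    """The same model with the target pathway's ontogeny forced to 1."""
    drug = spec.drug
    if spec.target_pathway is not None:
        drug = drug.with_ontogeny(spec.target_pathway, None)
    theta = {k: v for k, v in spec.theta.items()}
    est = tuple(e for e in spec.estimate if e in ("CLint", "V_ref", "ka", "FaFg"))
    return replace(spec, drug=drug, ontogeny_family=None, theta=theta,
                   estimate=est or ("CLint", "V_ref"))


def posthoc_age_scan(spec: PopulationModelSpec, data, constants=None,
                     span_threshold: float = 0.2, **fit_kwargs) -> AgeScanResult:
    """Fit without the target ontogeny, then scan post hoc CL_int vs age.

    The post hoc ratio exp(eta_cl) measures how far each subject's
    intrinsic clearance deviates from the ontogeny-free model; a
    systematic age pattern in it reveals the maturation shape that the
    structural model is missing.  Classification uses a lowess trend on
    log age: span below ``span_threshold`` (log scale) is flat, a
    prominent interior maximum is a bell, otherwise the sign of the
    trend decides rising vs falling.
    """
    flat = _flat_spec(spec)
    fit_kwargs.setdefault("compute_se", False)
    result = _fit(flat, data, constants=constants, **fit_kwargs)
    ebe = empirical_bayes(flat, data, result, constants=constants)
    ebe = ebe[ebe["ID"].isin(_subjects_with_obs(data))]
    r = np.log(ebe["posthoc_cl_ratio"].to_numpy())
    age = ebe["age"].to_numpy()
    x = np.log10(np.maximum(age, 1e-3))
    grid = np.linspace(x.min(), x.max(), 60)
    lo = lowess(r, x, frac=0.5, xvals=grid)
    trend = pd.DataFrame({"age": 10.0**grid, "log_posthoc_ratio": lo})
    rho, _ = stats.spearmanr(age, r)
    n = len(age)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    half = 1.959964 / np.sqrt(max(n - 3, 1))
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))

    span = float(lo.max() - lo.min())
    imax = int(np.argmax(lo))
    interior = 3 <= imax <= len(lo) - 4
    prominence = lo[imax] - max(lo[0], lo[-1])
    ci_excludes_zero = not (ci[0] <= 0.0 <= ci[1])
    # monotone labels additionally require a rank correlation whose CI
    # excludes zero: the lowess ends are noisy (few points), and a span
    # driven by edge variance alone must not read as a trend
    if span >= span_threshold and interior and prominence > 0.25 * span:
        label = "bell"
    elif span >= span_threshold and ci_excludes_zero:
        label = "rising" if rho > 0 else "falling"
    else:
        label = "flat"
    table = ebe[["ID", "age", "posthoc_cl_ratio", "posthoc_CL", "typical_CL"]]
    return AgeScanResult(table=table.reset_index(drop=True), classification=label,
                         spearman_rho=float(rho), spearman_ci=ci,
                         trend=trend, fit=result)


def _subjects_with_obs(data) -> set:
    df = data.df if isinstance(data, PKDataset) else data
    return set(df.loc[(df["EVID"] == 0) & (df["MDV"] == 0), "ID"].unique())


# ---------------------------------------------------------------------------
# multi-family ontogeny scan
# ---------------------------------------------------------------------------

@dataclass
class OntogenyScanResult:
    fits: dict[str, FitResult]
    table: pd.DataFrame          # family, ofv, aic, delta_ofv, delta_aic, converged
    curves: pd.DataFrame         # age grid x family F_activity
    agreement: pd.DataFrame      # per age: relative spread and agree flag
    best_family: str
    retained: tuple[str, ...]    # families within the retention window

    def curve(self, family: str) -> np.ndarray:
        return self.curves[family].to_numpy()


def ontogeny_scan(spec: PopulationModelSpec, data, families, constants=None,
                  age_grid=None, agreement_tol: float = 0.2,
                  retain_delta_aic: float = 2.0, **fit_kwargs) -> OntogenyScanResult:
    """Estimate the target ontogeny under several structural families.

    Every family is fitted from its own default inits (estimating its
    default subset plus the spec's PK fixed effects); families that fail
    stay in the table flagged unconverged.  Ranking is by AIC; the
    agreement table flags ages where the converged curves lie within
    ``agreement_tol`` relative spread of their median.  Ranking and
    outputs do not depend on the order families are supplied (fits are
    run in sorted order and re-indexed).
    """
    if not families:
        raise ValueError("at least one family is required")
    families = tuple(sorted(set(families)))
    age_grid = DEFAULT_AGE_GRID if age_grid is None else np.asarray(age_grid)
    fit_kwargs.setdefault("compute_se", False)
    pk_est = tuple(e for e in spec.estimate if e in ("CLint", "V_ref", "ka", "FaFg"))
    fits: dict[str, FitResult] = {}
    rows = []
    curves = {"age": age_grid}
    for fam in families:
        fspec = replace(
            spec, ontogeny_family=fam,
            theta={k: v for k, v in spec.theta.items()
                   if k in ("CLint", "V_ref", "ka", "FaFg")},
            estimate=pk_est + default_ontogeny_estimate(fam),
        )
        try:
            res = _fit(fspec, data, constants=constants, **fit_kwargs)
            ok = res.converged
        except Exception as exc:  # reported, never dropped silently
            res = None
            ok = False
            rows.append({"family": fam, "ofv": np.nan, "n_params": np.nan,
                         "aic": np.nan, "converged": False, "error": str(exc)})
            continue
        fits[fam] = res
        n_par = len(fspec.estimate) + (len(fspec.eta_names)
                                       if fspec.estimate_omega else 0) + 1
        aic = res.ofv + 2.0 * n_par
        params = _ont.OntogenyParameters(**{
            name: res.theta[name]
            for name in _ont.get_model(fam).parameter_roster
        })
        curves[fam] = np.asarray(_ont.evaluate_ontogeny(fam, params, age_grid))
        rows.append({"family": fam, "ofv": res.ofv, "n_params": n_par,
                     "aic": aic, "converged": ok, "error": ""})
    table = pd.DataFrame(rows)
    if table["aic"].notna().sum() == 0:
        raise RuntimeError("no family converged")
    table["delta_ofv"] = table["ofv"] - table["ofv"].min()
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best = table.loc[table["aic"].idxmin(), "family"]
    retained = tuple(table.loc[table["delta_aic"] <= retain_delta_aic, "family"])
    curves_df = pd.DataFrame(curves)
    fitted = [f for f in families if f in fits]
    arr = curves_df[fitted].to_numpy()
    med = np.median(arr, axis=1)
    spread = (arr.max(axis=1) - arr.min(axis=1)) / np.maximum(med, 1e-12)
    agreement = pd.DataFrame({
        "age": age_grid,
        "relative_spread": spread,
        "agree": spread <= agreement_tol,
    })
    return OntogenyScanResult(fits=fits, table=table, curves=curves_df,
                              agreement=agreement, best_family=str(best),
                              retained=retained)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap(spec: PopulationModelSpec, data, n_resamples: int, seed: int = 0,
              age_bands=DEFAULT_AGE_BANDS, constants=None,
              **fit_kwargs) -> pd.DataFrame:
    """Age-stratified nonparametric bootstrap of the fit.

    Subjects are resampled with replacement within age bands (so the
    pediatric strata keep their representation), the model is refitted
    on each resample, and 2.5/50/97.5 percentiles are reported per
    parameter together with the resample failure rate.  Bit-reproducible
    under ``seed``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    df = (data.df if isinstance(data, PKDataset) else data).copy()
    subj = df.groupby("ID")["AGE"].first()
    if len(subj) < 2:
        raise ValueError("degenerate design: bootstrap needs >= 2 subjects")
    bands = np.asarray(age_bands)
    strata = {b: subj.index[(subj >= bands[b]) & (subj < bands[b + 1])].to_numpy()
              for b in range(len(bands) - 1)}
    strata = {b: ids for b, ids in strata.items() if len(ids)}
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("compute_se", False)
    groups = {sid: g for sid, g in df.groupby("ID")}
    draws = []
    failures = 0
    for _ in range(n_resamples):
        picked = []
        for ids in strata.values():
            picked.extend(rng.choice(ids, size=len(ids), replace=True))
        frames = []
        for new_id, sid in enumerate(picked, start=1):
            g = groups[sid].copy()
            g["ID"] = new_id
            frames.append(g)
        boot = pd.concat(frames, ignore_index=True)
        try:
            res = _fit(spec, PKDataset(boot), constants=constants, **fit_kwargs)
            row = {f"theta:{k}": v for k, v in res.theta.items()
                   if k in spec.estimate}
            row.update({f"omega:{k}": v for k, v in res.omega.items()})
            row["sigma:prop"] = res.sigma[0]
            row["sigma:add"] = res.sigma[1]
            row["ofv"] = res.ofv
            draws.append(row)
        except Exception:
            failures += 1
    if not draws:
        raise RuntimeError(f"all {n_resamples} bootstrap refits failed")
    dd = pd.DataFrame(draws)
    out = dd.quantile([0.025, 0.5, 0.975]).T
    out.columns = ["p2.5", "p50", "p97.5"]
    out["n_success"] = len(dd)
    out["failure_rate"] = failures / n_resamples
    return out


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    table: pd.DataFrame   # one row per bin with observed + simulated bands
    n_sim: int
    seed: int
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0)

    def coverage(self, percentile: str = "p50", bin_type: str | None = None) -> float:
        t = self.table if bin_type is None else self.table[
            self.table["bin_type"] == bin_type]
        inside = (t[f"obs_{percentile}"] >= t[f"sim_{percentile}_lo"]) & (
            t[f"obs_{percentile}"] <= t[f"sim_{percentile}_hi"])
        return float(inside.mean())


def vpc(spec: PopulationModelSpec, data, result: FitResult | None = None,
        n_sim: int = 200, seed: int = 0, n_time_bins: int = 4,
        age_bands=DEFAULT_AGE_BANDS, constants=None) -> VPCResult:
    """Visual predictive check under the design of the observed data.

    ``n_sim`` replicate datasets are simulated from the (fitted) model at
    the observed times/doses/covariates; observed 5/50/95th percentiles
    are compared with the 95% prediction band of each simulated
    percentile, binned by time after dose within age strata and,
    separately, by age.
    """
    engine = LaplaceEngine(spec, data, constants=constants)
    theta = result.theta if result is not None else spec.theta
    omega = result.omega if result is not None else spec.omega
    sigma = result.sigma if result is not None else spec.sigma
    fd = engine.fd
    rng = np.random.default_rng(seed)
    k = engine.k
    om_sd = np.sqrt([omega[e] for e in spec.eta_names])
    typ = engine._typical(theta)

    mask = fd.mask
    obs_dv = fd.dv[mask]
    obs_tad = fd.x_ss[mask]
    obs_age = np.repeat(fd.ages, mask.sum(axis=1))

    # bin assignment: quantile bins of time-after-dose within age strata
    bands = np.asarray(age_bands)
    band_idx = np.digitize(obs_age, bands[1:-1])
    bins = []
    bin_id = np.full(obs_dv.shape, -1, dtype=int)
    next_id = 0
    for b in range(len(bands) - 1):
        sel = band_idx == b
        if sel.sum() == 0:
            continue
        edges = np.quantile(obs_tad[sel], np.linspace(0, 1, n_time_bins + 1))
        edges = np.unique(edges)
        which = np.clip(np.digitize(obs_tad[sel], edges[1:-1]), 0,
                        len(edges) - 2)
        for t in range(len(edges) - 1):
            ss = sel.copy()
            ss[sel] = which == t
            if ss.sum() == 0:
                continue
            bins.append(("time_by_age", f"age[{bands[b]:g},{bands[b+1]:g})"
                         f"_tad[{edges[t]:.1f},{edges[t+1]:.1f}]", ss))
    # age bins (finer, for maturation misfit)
    age_edges = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, np.inf])
    which = np.digitize(obs_age, age_edges[1:-1])
    for a in range(len(age_edges) - 1):
        ss = which == a
        if ss.sum():
            bins.append(("age", f"age[{age_edges[a]:g},{age_edges[a+1]:g})", ss))

    pcts = (5.0, 50.0, 95.0)
    sim_stats = np.zeros((n_sim, len(bins), 3))
    for s in range(n_sim):
        etas = rng.normal(size=(fd.n, k)) * om_sd if k else np.zeros((fd.n, 1))
        pred = engine.predict(theta, etas, typ=typ)
        dv = pred * (1.0 + sigma[0] * rng.normal(size=pred.shape))
        if sigma[1] > 0:
            dv = dv + sigma[1] * rng.normal(size=pred.shape)
        dv = np.maximum(dv, 0.0)[mask]
        for ib, (_, _, ss) in enumerate(bins):
            sim_stats[s, ib] = np.percentile(dv[ss], pcts)
    rows = []
    for ib, (btype, label, ss) in enumerate(bins):
        obs_p = np.percentile(obs_dv[ss], pcts)
        row = {"bin_type": btype, "bin": label, "n_obs": int(ss.sum()),
               "obs_p5": obs_p[0], "obs_p50": obs_p[1], "obs_p95": obs_p[2]}
        for ip, tag in enumerate(("p5", "p50", "p95")):
            lo, med, hi = np.percentile(sim_stats[:, ib, ip], (2.5, 50.0, 97.5))
            row[f"sim_{tag}_lo"] = lo
            row[f"sim_{tag}_med"] = med
            row[f"sim_{tag}_hi"] = hi
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def gof(spec: PopulationModelSpec, data, result: FitResult,
        constants=None) -> pd.DataFrame:
    """Observation-level predictions and standardized residuals.

    PRED is the population (eta = 0) prediction, IPRED the empirical
    Bayes individual prediction; the standardized residual uses the
    FOCE linearization around the individual mode, so under the true
    model it has approximately zero mean and unit variance.
    """
    engine = LaplaceEngine(spec, data, constants=constants)
    fd = engine.fd
    k = engine.k
    if k and any(v > 1e-12 for v in result.omega.values()):
        etas, _, _ = engine.inner_modes(
            result.theta, engine._omega_matrix(result.omega), result.sigma)
    else:
        etas = np.zeros((fd.n, k))
    typ = engine._typical(result.theta)
    pred_pop = engine.predict(result.theta, np.zeros_like(etas), typ=typ)
    ipred = engine.predict(result.theta, etas, typ=typ)
    # FD Jacobian of predictions wrt eta at the mode
    h = 1e-4
    jac = np.zeros(ipred.shape + (k,))
    for i in range(k):
        step = np.zeros((1, k)); step[0, i] = h
        jac[..., i] = (engine.predict(result.theta, etas + step, typ=typ)
                       - engine.predict(result.theta, etas - step, typ=typ)
                       ) / (2.0 * h)
    jac0 = np.zeros(ipred.shape + (k,))
    for i in range(k):
        step = np.zeros((1, k)); step[0, i] = h
        jac0[..., i] = (engine.predict(result.theta,
                                       np.zeros_like(etas) + step, typ=typ)
                        - engine.predict(result.theta,
                                         np.zeros_like(etas) - step, typ=typ)
                        ) / (2.0 * h)
    om = engine._omega_matrix(result.omega)
    var_res = engine._residual_var(ipred, result.sigma)
    var_res0 = engine._residual_var(pred_pop, result.sigma)
    rows = []
    for i in range(fd.n):
        m = fd.mask[i]
        if not m.any():
            continue
        y = fd.dv[i][m]
        j = jac[i][m]
        mean_i = ipred[i][m] - j @ etas[i]
        cov = j @ om @ j.T + np.diag(var_res[i][m])
        cwres = np.linalg.solve(np.linalg.cholesky(cov), y - mean_i)
        j0 = jac0[i][m]
        cov0 = j0 @ om @ j0.T + np.diag(var_res0[i][m])
        pwres = np.linalg.solve(np.linalg.cholesky(cov0), y - pred_pop[i][m])
        tad = fd.x_ss[i][m]
        for jj in range(int(m.sum())):
            rows.append({"ID": fd.ids[i], "age": fd.ages[i], "tad": tad[jj],
                         "DV": y[jj], "PRED": pred_pop[i][m][jj],
                         "IPRED": ipred[i][m][jj], "CWRES": cwres[jj],
                         "PWRES": pwres[jj]})
    out = pd.DataFrame(rows)
    # population residuals (not shrunk by the EBEs) carry the age misfit;
    # a rank test across age bands also catches non-monotone (bell) misfit
    rho, _ = stats.spearmanr(out["age"], out["PWRES"])
    bands = np.digitize(out["age"], [0.5, 2.0, 6.0, 18.0])
    groups = [g["PWRES"].to_numpy() for _, g in out.groupby(bands)
              if len(g) >= 3]
    if len(groups) >= 2:
        _, p = stats.kruskal(*groups)
    else:
        p = np.nan
    out.attrs["residual_age_trend_rho"] = float(rho)
    out.attrs["residual_age_trend_p"] = float(p)
    out.attrs["residual_mean"] = float(out["CWRES"].mean())
    out.attrs["residual_var"] = float(out["CWRES"].var())
    return out


# ---------------------------------------------------------------------------
# external plausibility comparison
# ---------------------------------------------------------------------------

def compare_external(scan: OntogenyScanResult, points) -> pd.DataFrame:
    """Fold differences between scanned curves and independent ontogeny
    observations.

    ``points`` is an iterable of (age, fraction_of_adult, source); the
    fold difference is predicted/observed, and ``within_2fold`` flags
    agreement within a factor of two (the usual plausibility window).
    """
    points = list(points)
    if not points:
        raise ValueError("at least one external point is required")
    rows = []
    ages = scan.curves["age"].to_numpy()
    for age, obs, source in points:
        if obs <= 0:
            raise ValueError("external observations must be positive")
        for fam in scan.fits:
            predicted = float(np.interp(age, ages, scan.curves[fam].to_numpy()))
            fold = predicted / obs
            rows.append({"family": fam, "age": age, "observed": obs,
                         "predicted": predicted, "source": source,
                         "fold_difference": fold,
                         "within_2fold": bool(0.5 <= fold <= 2.0)})
    return pd.DataFrame(rows)
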