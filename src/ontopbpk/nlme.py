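"""Nonlinear mixed-effects estimation for the reduced PBPK model.

Marginal likelihood by the Laplace approximation: for each subject the
joint density of observations and log-normal random effects is
optimized over the random effects (vectorized Newton iterations across
subjects) and the integral is approximated at the mode,

    -2 log L_i  ~=  2 l_i(eta*) + log det H_i - k log(2pi),

where ``l_i`` is the negative log joint and ``H_i`` its Hessian at the
mode.  An adaptive Gauss-Hermite quadrature routine (``agq_ofv``, up to
two random effects) provides an independent numerical route to the same
marginal likelihood for verification.

Fixed effects comprise a global intrinsic-clearance multiplier, volume,
absorption and bioavailability terms, and the structural ontogeny
parameters of one target pathway; positive parameters are estimated on
the log scale, fractions on a logit scale, Hill coefficients on a
bounded-logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import ontogeny as _ont
from .dataio import PKDataset
from .physiology import load_constants
from .structural import (
    MG_PER_L_TO_NG_PER_ML,
    UL_PER_MIN_TO_L_PER_H,
    DrugParameters,
)

__all__ = [
    "PopulationModelSpec",
    "FitResult",
    "LaplaceEngine",
    "laplace_ofv",
    "agq_ofv",
    "fit",
    "empirical_bayes",
]

LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-6**2  # additive residual floor (ng/mL)^2


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def _log_tf():
    return (np.log, np.exp, lambda x: np.exp(x))


def _logit_tf(lo, hi):
    def fwd(v):
        z = (v - lo) / (hi - lo)
        return np.log(z / (1.0 - z))

    def inv(x):
        return lo + (hi - lo) / (1.0 + np.exp(-x))

    def dinv(x):
        e = np.exp(-x)
        return (hi - lo) * e / (1.0 + e) ** 2

    return (fwd, inv, dinv)


_TRANSFORMS = {
    "CLint": _log_tf(),
    "V_ref": _log_tf(),
    "ka": _log_tf(),
    "FaFg": _logit_tf(0.0, 1.0),
    "F_birth": _log_tf(),
    "F_max": _log_tf(),
    "F_min": _log_tf(),
    "Age_up50": _log_tf(),
    "Age_down50": _log_tf(),
    "K": _log_tf(),
    "AGECAP": _log_tf(),
    "gamma_u": _logit_tf(0.1, 15.0),
    "gamma_d": _logit_tf(0.1, 15.0),
    "FRD": _logit_tf(0.0, 1.0),
}

_PK_THETA = ("CLint", "V_ref", "ka", "FaFg")

_FAMILY_INITS = {
    "eq1_sigmoid_up": {"F_birth": 0.1, "F_max": 1.0, "Age_up50": 0.5, "gamma_u": 1.5},
    "eq2_gompertz_up": {"F_birth": 0.1, "F_max": 1.0, "K": 2.0},
    "eq3a_sigmoid_down": {"F_birth": 2.0, "F_min": 1.0, "Age_down50": 1.0, "gamma_d": 2.0},
    "eq3b_exp_down": {"F_birth": 2.0, "F_min": 1.0, "K": 1.0},
    "eq4a": {"F_birth": 0.2, "Age_up50": 0.3, "gamma_u": 2.0, "FRD": 0.6,
             "Age_down50": 5.0, "gamma_d": 2.5},
    "eq4b": {"F_birth": 0.2, "Age_up50": 0.3, "gamma_u": 2.0, "FRD": 0.6,
             "Age_down50": 5.0, "gamma_d": 0.5},
    "eq4c": {"F_birth": 0.2, "K": 3.0, "FRD": 0.6, "Age_down50": 5.0,
             "gamma_d": 2.5, "AGECAP": 20.0},
    "eq4d": {"F_birth": 0.2, "K": 3.0, "FRD": 0.6, "Age_down50": 5.0,
             "gamma_d": 0.5, "AGECAP": 20.0},
    "eq4e": {"F_birth": 0.2, "Age_up50": 0.3, "gamma_u": 2.0, "FRD": 0.6,
             "Age_down50": 5.0, "gamma_d": 2.5, "AGECAP": 20.0},
    "eq4f": {"F_birth": 0.2, "Age_up50": 0.3, "gamma_u": 2.0, "FRD": 0.6,
             "Age_down50": 5.0, "gamma_d": 2.5},
    "eq4g_double_sigmoid": {"F_birth": 0.2, "F_max": 3.0, "Age_up50": 0.3,
                            "gamma_u": 2.0, "FRD": 0.67, "Age_down50": 5.0,
                            "gamma_d": 2.5, "F_min": 0.1, "AGECAP": 25.0},
}

# Default estimable subsets: Hill coefficients stay fixed (standard for
# sparse designs), and the birth intercept F_birth stays fixed for the
# bell-shaped families — with enrollment starting months after birth the
# likelihood is flat in F_birth, which is exactly why estimated
# trajectories diverge below ~4 months of age.
_FAMILY_DEFAULT_ESTIMATE = {
    "eq1_sigmoid_up": ("F_birth", "Age_up50"),
    "eq2_gompertz_up": ("F_birth", "K"),
    "eq3a_sigmoid_down": ("F_birth", "Age_down50"),
    "eq3b_exp_down": ("F_birth", "K"),
    "eq4a": ("Age_up50", "FRD", "Age_down50"),
    "eq4b": ("Age_up50", "FRD", "Age_down50"),
    "eq4c": ("K", "FRD", "Age_down50"),
    "eq4d": ("K", "FRD", "Age_down50"),
    "eq4e": ("Age_up50", "FRD", "Age_down50"),
    "eq4f": ("Age_up50", "FRD", "Age_down50"),
    "eq4g_double_sigmoid": ("F_max", "Age_up50", "FRD", "Age_down50"),
}


def default_ontogeny_inits(family: str) -> dict[str, float]:
    """Family-appropriate starting values for ontogeny parameters."""
    return dict(_FAMILY_INITS[family])


def default_ontogeny_estimate(family: str) -> tuple[str, ...]:
    """Default estimated subset (Hill coefficients fixed, standard for
    sparse designs)."""
    return _FAMILY_DEFAULT_ESTIMATE[family]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class PopulationModelSpec:
    """Structural + stochastic model specification for one fit.

    ``theta`` holds fixed effects on the natural scale: a multiplier
    ``CLint`` on all adult per-mg intrinsic clearances, absolute
    ``V_ref``/``ka``/``FaFg``, and (when ``ontogeny_family`` is set) the
    structural ontogeny parameters of ``target_pathway``.  ``estimate``
    names the subset optimized; the rest stay fixed.  Random effects are
    log-normal (``eta_names`` drawn from cl/v/ka with variances
    ``omega``); the residual model is proportional + additive
    (``sigma = (prop_cv, add_sd)``).
    """

    drug: DrugParameters
    target_pathway: str | None = None
    ontogeny_family: str | None = None
    theta: dict[str, float] = field(default_factory=dict)
    estimate: tuple[str, ...] = ("CLint", "V_ref")
    eta_names: tuple[str, ...] = ("cl", "v")
    omega: dict[str, float] = field(default_factory=lambda: {"cl": 0.09, "v": 0.09})
    sigma: tuple[float, float] = (0.15, 0.0)
    estimate_omega: bool = True
    estimate_sigma: bool = True
    adult_reference_age: float | None = None

    def __post_init__(self):
        theta = dict(self.theta)
        theta.setdefault("CLint", 1.0)
        theta.setdefault("V_ref", self.drug.V_ref)
        theta.setdefault("ka", self.drug.ka)
        theta.setdefault("FaFg", self.drug.FaFg)
        if self.ontogeny_family is not None:
            if self.target_pathway is None:
                raise ValueError("ontogeny_family requires target_pathway")
            model = _ont.get_model(self.ontogeny_family)
            inits = default_ontogeny_inits(self.ontogeny_family)
            for name in model.parameter_roster:
                theta.setdefault(name, inits[name])
        self.theta = theta
        if self.target_pathway is not None and self.target_pathway not in self.drug.pathways:
            raise ValueError(f"unknown pathway {self.target_pathway!r}")
        missing = [e for e in self.estimate if e not in self.theta]
        if missing:
            raise ValueError(f"estimate lists unknown theta entries: {missing}")
        bad = [e for e in self.eta_names if e not in ("cl", "v", "ka")]
        if bad:
            raise ValueError(f"unsupported eta names: {bad}")
        om = np.asarray([self.omega[e] for e in self.eta_names], dtype=float)
        if np.any(om < 0):
            raise ValueError("omega variances must be >= 0")
        if self.sigma[0] < 0 or self.sigma[1] < 0 or self.sigma == (0.0, 0.0):
            raise ValueError("sigma components must be >= 0 and not both 0")

    def ontogeny_theta_names(self) -> tuple[str, ...]:
        if self.ontogeny_family is None:
            return ()
        return _ont.get_model(self.ontogeny_family).parameter_roster


@dataclass
class FitResult:
    """Estimates, uncertainty, and empirical Bayes output of one fit."""

    theta: dict[str, float]
    theta_se: dict[str, float]
    omega: dict[str, float]
    sigma: tuple[float, float]
    ofv: float
    eta: pd.DataFrame
    converged: bool
    n_iter: int
    n_subjects: int
    n_obs: int
    condition_number: float
    message: str
    ofv_init: float
    spec: PopulationModelSpec

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, v in self.theta.items():
            rows.append({"parameter": f"theta:{k}", "estimate": v,
                         "se": self.theta_se.get(k, np.nan)})
        for k, v in self.omega.items():
            rows.append({"parameter": f"omega:{k}", "estimate": v, "se": np.nan})
        rows.append({"parameter": "sigma:prop", "estimate": self.sigma[0], "se": np.nan})
        rows.append({"parameter": "sigma:add", "estimate": self.sigma[1], "se": np.nan})
        rows.append({"parameter": "OFV", "estimate": self.ofv, "se": np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# padded data arrays
# ---------------------------------------------------------------------------

class _FitData:
    """Per-subject padded arrays for vectorized prediction."""

    def __init__(self, data: PKDataset | pd.DataFrame, constants=None):
        if isinstance(data, pd.DataFrame):
            data = PKDataset(data)
        self.constants = constants or load_constants()
        df = data.df
        ids, ages, wts = [], [], []
        obs_t, obs_dv = [], []
        ss_x, ss_tau, ss_amt = [], [], []
        tr_dt, tr_amt = [], []
        for sid, grp in df.groupby("ID", sort=False):
            doses = grp[grp["EVID"] == 1]
            obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
            ids.append(sid)
            ages.append(float(grp["AGE"].iloc[0]))
            wts.append(float(grp["WT"].iloc[0]))
            obs_t.append(obs["TIME"].to_numpy(dtype=float))
            obs_dv.append(obs["DV"].to_numpy(dtype=float))
            has_ss = "SS" in grp.columns
            ss_doses = doses[(doses["SS"] == 1)] if has_ss else doses.iloc[0:0]
            tr_doses = doses[(doses["SS"] != 1)] if has_ss else doses
            x_row, tau_row, amt_row = [], [], []
            dt_rows, amt_rows = [], []
            for t in obs_t[-1]:
                prior = ss_doses[ss_doses["TIME"] <= t]
                if len(prior):
                    last = prior.iloc[-1]
                    x_row.append(t - float(last["TIME"]))
                    tau_row.append(float(last["II"]))
                    amt_row.append(float(last["AMT"]))
                else:
                    x_row.append(0.0)
                    tau_row.append(24.0)
                    amt_row.append(0.0)
                tr_prior = tr_doses[tr_doses["TIME"] <= t]
                dt_rows.append(t - tr_prior["TIME"].to_numpy(dtype=float))
                amt_rows.append(tr_prior["AMT"].to_numpy(dtype=float))
            ss_x.append(np.array(x_row))
            ss_tau.append(np.array(tau_row))
            ss_amt.append(np.array(amt_row))
            tr_dt.append(dt_rows)
            tr_amt.append(amt_rows)

        n = len(ids)
        jmax = max((len(t) for t in obs_t), default=0)
        jmax = max(jmax, 1)
        mmax = max(
            (len(d) for rows in tr_dt for d in rows), default=0
        )
        self.ids = np.array(ids)
        self.n = n
        self.ages = np.array(ages)
        self.wts = np.array(wts)
        self.mask = np.zeros((n, jmax), dtype=bool)
        self.dv = np.zeros((n, jmax))
        self.x_ss = np.zeros((n, jmax))
        self.tau = np.full((n, jmax), 24.0)
        self.amt_ss = np.zeros((n, jmax))
        self.dt_tr = np.zeros((n, jmax, mmax)) if mmax else None
        self.amt_tr = np.zeros((n, jmax, mmax)) if mmax else None
        for i in range(n):
            j = len(obs_t[i])
            self.mask[i, :j] = True
            self.dv[i, :j] = obs_dv[i]
            self.x_ss[i, :j] = ss_x[i]
            self.tau[i, :j] = ss_tau[i]
            self.amt_ss[i, :j] = ss_amt[i]
            if mmax:
                for jj in range(j):
                    m = len(tr_dt[i][jj])
                    if m:
                        self.dt_tr[i, jj, :m] = tr_dt[i][jj]
                        self.amt_tr[i, jj, :m] = tr_amt[i][jj]
        self.n_obs_per_subject = self.mask.sum(axis=1)
        self.n_obs = int(self.mask.sum())

        c = self.constants
        self.scaling_mg = c.mppgl(self.ages) * c.liver_weight(self.wts)
        self.q_h = c.hepatic_blood_flow(self.wts)
        self.gfr = np.asarray(c.gfr_frac(self.ages), dtype=float)
        self.wt_ratio = self.wts / c.adult_weight

    def subset(self, indices) -> "_FitData":
        new = object.__new__(_FitData)
        new.constants = self.constants
        for name in ("ids", "ages", "wts", "mask", "dv", "x_ss", "tau", "amt_ss",
                     "scaling_mg", "q_h", "gfr", "wt_ratio", "n_obs_per_subject"):
            setattr(new, name, getattr(self, name)[indices])
        for name in ("dt_tr", "amt_tr"):
            arr = getattr(self, name)
            setattr(new, name, arr[indices] if arr is not None else None)
        new.n = len(new.ids)
        new.n_obs = int(new.mask.sum())
        return new


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class LaplaceEngine:
    """Laplace marginal-likelihood machinery bound to one dataset."""

    def __init__(self, spec: PopulationModelSpec, data, constants=None,
                 inner_tol: float = 1e-7, inner_maxiter: int = 50,
                 fd_step: float = 1e-2):
        self.spec = spec
        self.fd = data if isinstance(data, _FitData) else _FitData(data, constants)
        self.inner_tol = inner_tol
        self.inner_maxiter = inner_maxiter
        self.fd_step = fd_step
        self.k = len(spec.eta_names)
        drug = spec.drug
        self._per_mg = np.array([drug.CLint_per_mg[p] for p in drug.pathways])
        # fixed (non-estimated) pathway activities, precomputed on ages
        self._fixed_act = {}
        for p in drug.pathways:
            if p == spec.target_pathway and spec.ontogeny_family is not None:
                continue
            binding = drug.pathway_ontogeny.get(p)
            if binding is None:
                self._fixed_act[p] = np.ones(self.fd.n)
            else:
                model, params = binding
                self._fixed_act[p] = np.asarray(
                    _ont.evaluate_ontogeny(model, params, self.fd.ages), dtype=float
                )

    # -- structural predictions ------------------------------------------

    def _typical(self, theta: dict[str, float]) -> dict[str, np.ndarray]:
        """Eta-independent per-subject quantities for one theta vector."""
        spec, fd, drug = self.spec, self.fd, self.spec.drug
        act_sum = np.zeros(fd.n)
        for ip, p in enumerate(drug.pathways):
            if p == spec.target_pathway and spec.ontogeny_family is not None:
                params = _ont.OntogenyParameters(**{
                    name: theta[name] for name in self.spec.ontogeny_theta_names()
                })
                ref_age = spec.adult_reference_age or _ont.ADULT_REFERENCE_AGE
                act = np.asarray(_ont.evaluate_ontogeny(
                    spec.ontogeny_family, params, fd.ages,
                    adult_reference_age=ref_age), dtype=float)
            else:
                act = self._fixed_act[p]
            act_sum = act_sum + self._per_mg[ip] * act
        cl_int = theta["CLint"] * act_sum * fd.scaling_mg * UL_PER_MIN_TO_L_PER_H
        return {
            "x_typ": drug.fu_B * cl_int,
            "cl_r": drug.CLR_adult * fd.gfr,
            "v_typ": theta["V_ref"] * fd.wt_ratio ** drug.vol_allometric_exponent,
            "ka_typ": theta["ka"] * np.ones(fd.n),
            "fafg": theta["FaFg"],
        }

    def _individual_arrays(self, theta, eta, typ=None):
        """CL, V, ka, F arrays for eta of shape (m, k); m == n or n == 1."""
        spec, fd = self.spec, self.fd
        if typ is None:
            typ = self._typical(theta)
        eta = np.atleast_2d(eta)
        e = {name: eta[:, i] for i, name in enumerate(spec.eta_names)}
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            x = typ["x_typ"] * np.exp(e.get("cl", 0.0))
            cl_h = fd.q_h * x / (fd.q_h + x)
            f_h = fd.q_h / (fd.q_h + x)
            cl = cl_h + typ["cl_r"]
            v = typ["v_typ"] * np.exp(e.get("v", 0.0))
            ka = typ["ka_typ"] * np.exp(e.get("ka", 0.0))
            f_oral = typ["fafg"] * f_h
        return cl, v, ka, f_oral

    def predict(self, theta, eta, typ=None) -> np.ndarray:
        """Padded concentration predictions (m, J) for eta (m, k)."""
        cl, v, ka, f = self._individual_arrays(theta, eta, typ=typ)
        fd = self.fd
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            ke = cl / v
            ka_s = np.where(np.abs(ka - ke) < 1e-9 * np.maximum(ka, ke),
                            ke * (1.0 + 1e-6), ka)
            keb, kab = ke[:, None], ka_s[:, None]
            conc = (
                f[:, None] * fd.amt_ss * kab / (v[:, None] * (kab - keb))
                * (np.exp(-keb * fd.x_ss) / (1.0 - np.exp(-keb * fd.tau))
                   - np.exp(-kab * fd.x_ss) / (1.0 - np.exp(-kab * fd.tau)))
                * MG_PER_L_TO_NG_PER_ML
            )
            if fd.dt_tr is not None:
                keb3, kab3 = ke[:, None, None], ka_s[:, None, None]
                core = kab3 / (kab3 - keb3) * (
                    np.exp(-keb3 * fd.dt_tr) - np.exp(-kab3 * fd.dt_tr)
                )
                tr = (f[:, None, None] * fd.amt_tr / v[:, None, None]
                      * core * MG_PER_L_TO_NG_PER_ML)
                conc = conc + np.where(fd.dt_tr >= 0, tr, 0.0).sum(axis=2)
        return np.maximum(conc, 0.0)

    # -- likelihood pieces ------------------------------------------------

    def _residual_var(self, pred: np.ndarray, sigma) -> np.ndarray:
        prop, add = sigma
        return (prop * pred) ** 2 + add**2 + _VAR_FLOOR

    def _data_nll(self, theta, eta, sigma, typ=None) -> np.ndarray:
        """0.5 * sum_j [(y-f)^2/v + log(2 pi v)] per subject, (m,)."""
        fd = self.fd
        pred = self.predict(theta, eta, typ=typ)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self._residual_var(pred, sigma)
            ll = ((fd.dv - pred) ** 2 / v + np.log(2.0 * np.pi * v)) * fd.mask
        return 0.5 * ll.sum(axis=1)

    def joint_nll(self, theta, eta, omega_mat, sigma, typ=None) -> np.ndarray:
        """Negative log joint density per subject (prior included)."""
        eta = np.atleast_2d(eta)
        om_inv = np.linalg.inv(omega_mat)
        _, logdet = np.linalg.slogdet(2.0 * np.pi * omega_mat)
        prior = 0.5 * np.einsum("mi,ij,mj->m", eta, om_inv, eta) + 0.5 * logdet
        return self._data_nll(theta, eta, sigma, typ=typ) + prior

    # -- inner optimization (vectorized Newton) ---------------------------

    def _fd_grad(self, obj, eta, h=1e-4):
        """Central-difference gradient (small step: locates the mode
        precisely; roundoff stays ~1e-10 at these objective scales)."""
        m, k = eta.shape
        g = np.zeros((m, k))
        for i in range(k):
            step = np.zeros((1, k))
            step[0, i] = h
            g[:, i] = (obj(eta + step) - obj(eta - step)) / (2.0 * h)
        return g

    def _fd_hess(self, obj, eta, f0=None):
        """Central-difference Hessian (wider step: curvature only)."""
        m, k = eta.shape
        h = self.fd_step
        if f0 is None:
            f0 = obj(eta)
        hess = np.zeros((m, k, k))
        for i in range(k):
            step = np.zeros((1, k))
            step[0, i] = h
            hess[:, i, i] = (obj(eta + step) - 2.0 * f0 + obj(eta - step)) / h**2
        for i in range(k):
            for j in range(i + 1, k):
                si = np.zeros((1, k)); si[0, i] = h
                sj = np.zeros((1, k)); sj[0, j] = h
                hess[:, i, j] = hess[:, j, i] = (
                    obj(eta + si + sj) - obj(eta + si - sj)
                    - obj(eta - si + sj) + obj(eta - si - sj)
                ) / (4.0 * h**2)
        return hess

    def _fd_grad_hess(self, obj, eta):
        f0 = obj(eta)
        return f0, self._fd_grad(obj, eta), self._fd_hess(obj, eta, f0=f0)

    def inner_modes(self, theta, omega_mat, sigma, eta0=None):
        """Per-subject modes of the joint density + Hessians there."""
        n, k = self.fd.n, self.k
        typ = self._typical(theta)
        om_inv = np.linalg.inv(omega_mat)
        _, prior_logdet = np.linalg.slogdet(2.0 * np.pi * omega_mat)

        def obj(e):
            e = np.atleast_2d(e)
            prior = 0.5 * np.einsum("mi,ij,mj->m", e, om_inv, e) + 0.5 * prior_logdet
            out = self._data_nll(theta, e, sigma, typ=typ) + prior
            return np.where(np.isfinite(out), out, 1e10)

        eta = np.zeros((n, k)) if eta0 is None else np.clip(eta0, -4.0, 4.0)
        f = obj(eta)
        # subjects whose warm start landed in the guard region restart at 0
        bad0 = ~np.isfinite(f) | (f >= 1e9)
        if bad0.any():
            eta[bad0] = 0.0
            f = obj(eta)
        eye = np.eye(k)
        for _ in range(self.inner_maxiter):
            f0, g, hess = self._fd_grad_hess(obj, eta)
            if np.max(np.abs(g)) < self.inner_tol:
                break
            # per-subject damping until positive definite
            lam = np.zeros(n)
            for _try in range(12):
                hd = hess + lam[:, None, None] * eye
                ev = np.linalg.eigvalsh(hd)
                bad = ev[:, 0] <= 1e-10
                if not bad.any():
                    break
                lam[bad] = np.maximum(lam[bad] * 10.0, 1e-4)
            step = np.linalg.solve(hd, g[..., None])[..., 0]
            # vectorized backtracking line search
            alpha = np.ones(n)
            for _bt in range(10):
                trial = eta - alpha[:, None] * step
                ft = obj(trial)
                worse = ft > f0 + 1e-12
                if not worse.any():
                    break
                alpha[worse] *= 0.5
            improved = ft <= f0 + 1e-12
            eta = np.where(improved[:, None], eta - alpha[:, None] * step, eta)
            f = np.where(improved, ft, f0)
        f_final = obj(eta)
        hess = self._fd_hess(obj, eta, f0=f_final)
        return eta, f_final, hess

    # -- objective function values ----------------------------------------

    def _omega_matrix(self, omega: dict[str, float]) -> np.ndarray:
        return np.diag([float(omega[e]) for e in self.spec.eta_names])

    def ofv(self, theta=None, omega=None, sigma=None, eta0=None,
            return_etas: bool = False, warm: bool = False):
        """Laplace -2 log marginal likelihood.

        Cold-started (deterministic) by default; ``warm=True`` reuses the
        previous call's modes as the Newton starting point, which speeds
        up repeated evaluations inside an outer optimization (the modes
        are converged to ``inner_tol`` either way).
        """
        spec = self.spec
        theta = dict(spec.theta if theta is None else theta)
        omega = dict(spec.omega if omega is None else omega)
        sigma = tuple(spec.sigma if sigma is None else sigma)
        om = self._omega_matrix(omega)
        if np.any(np.diag(om) < 0) or np.any(np.linalg.eigvalsh(om) < -1e-12):
            raise ValueError("omega must be positive semidefinite")
        if self.k == 0 or np.all(np.diag(om) < 1e-12):
            eta = np.zeros((self.fd.n, max(self.k, 1)))
            nll = self._data_nll(theta, np.zeros((self.fd.n, self.k))
                                 if self.k else np.zeros((self.fd.n, 1)), sigma)
            value = float(2.0 * nll.sum())
            if return_etas:
                return value, np.zeros((self.fd.n, self.k)), None
            return value
        if warm and eta0 is None:
            eta0 = getattr(self, "_eta_warm", None)
        eta, f, hess = self.inner_modes(theta, om, sigma, eta0=eta0)
        if warm and np.all(np.isfinite(eta)) and np.max(np.abs(eta)) < 4.0:
            self._eta_warm = eta.copy()
        # eigenvalue floor: flat/indefinite directions at a mode are
        # regularized instead of failing the whole likelihood
        ev = np.linalg.eigvalsh(hess)
        floor = 1e-8 + 1e-6 * np.max(np.abs(ev), axis=1, keepdims=True)
        self.n_hessian_clipped_ = int(np.sum(np.any(ev < floor, axis=1)))
        logdet = np.sum(np.log(np.maximum(ev, floor)), axis=1)
        comp = 2.0 * f + logdet - self.k * LOG2PI
        value = float(comp.sum())
        if return_etas:
            return value, eta, hess
        return value


# ---------------------------------------------------------------------------
# public functions
# ---------------------------------------------------------------------------

def laplace_ofv(spec: PopulationModelSpec, data, theta=None, omega=None,
                sigma=None, constants=None) -> float:
    """Laplace-approximated -2 log marginal likelihood of the dataset."""
    engine = LaplaceEngine(spec, data, constants=constants)
    return engine.ofv(theta=theta, omega=omega, sigma=sigma)


def agq_ofv(spec: PopulationModelSpec, data, theta=None, omega=None,
            sigma=None, n_nodes: int = 21, constants=None) -> float:
    """Adaptive Gauss-Hermite -2 log marginal likelihood (k <= 2).

    Quadrature is centered per subject at the joint mode and scaled by
    the inverse Cholesky factor of the Hessian; with enough nodes this
    is numerically exact for the small problems it is intended to
    verify.
    """
    engine = LaplaceEngine(spec, data, constants=constants)
    k = engine.k
    if k > 2:
        raise ValueError("quadrature supports at most 2 random effects")
    sp = engine.spec
    theta = dict(sp.theta if theta is None else theta)
    omega = dict(sp.omega if omega is None else omega)
    sigma = tuple(sp.sigma if sigma is None else sigma)
    om = engine._omega_matrix(omega)
    if np.all(np.diag(om) < 1e-12):
        return engine.ofv(theta=theta, omega=omega, sigma=sigma)
    modes, _, hess = engine.inner_modes(theta, om, sigma)
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    if k == 1:
        zgrid = z[:, None]
        logw = np.log(w)
    else:
        z1, z2 = np.meshgrid(z, z, indexing="ij")
        zgrid = np.column_stack([z1.ravel(), z2.ravel()])
        logw = (np.log(w)[:, None] + np.log(w)[None, :]).ravel()
    total = 0.0
    for i in range(engine.fd.n):
        sub = LaplaceEngine(sp, engine.fd.subset([i]),
                            inner_tol=engine.inner_tol)
        h = hess[i]
        low = np.linalg.cholesky(h)
        # eta = mode + sqrt(2) * L^{-T} z
        offs = np.sqrt(2.0) * np.linalg.solve(low.T, zgrid.T).T
        etas = modes[i][None, :] + offs
        nll = sub.joint_nll(theta, etas, om, sigma)
        _, logdet = np.linalg.slogdet(h)
        log_l = (k / 2.0) * np.log(2.0) - 0.5 * logdet + logsumexp(
            logw + np.sum(zgrid**2, axis=1) - nll
        )
        total += -2.0 * log_l
    return float(total)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class _Packer:
    """Pack/unpack (theta, omega, sigma) into an unconstrained vector."""

    def __init__(self, spec: PopulationModelSpec):
        self.spec = spec
        self.theta_names = tuple(spec.estimate)
        self.omega_names = tuple(spec.eta_names) if spec.estimate_omega else ()
        sig = []
        if spec.estimate_sigma:
            if spec.sigma[0] > 0:
                sig.append(0)
            if spec.sigma[1] > 0:
                sig.append(1)
        self.sigma_idx = tuple(sig)
        self.size = len(self.theta_names) + len(self.omega_names) + len(self.sigma_idx)

    def pack(self, theta, omega, sigma) -> np.ndarray:
        x = []
        for name in self.theta_names:
            fwd, _, _ = _TRANSFORMS[name]
            x.append(fwd(theta[name]))
        for name in self.omega_names:
            x.append(0.5 * np.log(max(omega[name], 1e-12)))
        for i in self.sigma_idx:
            x.append(np.log(max(sigma[i], 1e-12)))
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray):
        theta = dict(self.spec.theta)
        omega = dict(self.spec.omega)
        sigma = list(self.spec.sigma)
        pos = 0
        for name in self.theta_names:
            _, inv, _ = _TRANSFORMS[name]
            theta[name] = float(inv(x[pos])); pos += 1
        for name in self.omega_names:
            omega[name] = float(np.exp(2.0 * x[pos])); pos += 1
        for i in self.sigma_idx:
            sigma[i] = float(np.exp(x[pos])); pos += 1
        return theta, omega, tuple(sigma)

    def dnat_dpacked(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        pos = 0
        for name in self.theta_names:
            _, _, dinv = _TRANSFORMS[name]
            out[pos] = dinv(x[pos]); pos += 1
        for name in self.omega_names:
            out[pos] = 2.0 * np.exp(2.0 * x[pos]); pos += 1
        for i in self.sigma_idx:
            out[pos] = np.exp(x[pos]); pos += 1
        return out


def fit(spec: PopulationModelSpec, data, constants=None, multi_start: int = 1,
        seed: int = 0, maxiter: int = 200, tol: float = 1e-6,
        compute_se: bool = True) -> FitResult:
    """Maximize the Laplace marginal likelihood.

    ``multi_start > 1`` adds jittered restarts of the packed initial
    vector (seed-controlled); the best optimum wins.  Standard errors
    come from the finite-difference Hessian of the objective at the
    optimum, transformed to the natural scale by the delta method.
    """
    engine = LaplaceEngine(spec, data, constants=constants)
    packer = _Packer(spec)
    x0 = packer.pack(spec.theta, spec.omega, spec.sigma)
    n_eval = [0]

    def objective(x):
        n_eval[0] += 1
        theta, omega, sigma = packer.unpack(x)
        try:
            val = engine.ofv(theta=theta, omega=omega, sigma=sigma, warm=True)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    ofv0 = objective(x0)
    if packer.size == 0:
        return _build_result(engine, packer, x0, ofv0, ofv0, True, 0,
                             "all parameters fixed", compute_se=False)

    opts = {"maxiter": maxiter, "ftol": tol * 1e-3, "gtol": 1e-6, "eps": 1e-5}

    def _polished(xs):
        # successive restarts rebuild the Hessian approximation and
        # recover from premature line-search termination
        res = minimize(objective, xs, method="L-BFGS-B", options=opts)
        n_iter = res.nit
        for _ in range(6):
            res2 = minimize(objective, res.x, method="L-BFGS-B", options=opts)
            n_iter += res2.nit
            if res2.fun > res.fun - 0.01:
                res = res2 if res2.fun < res.fun else res
                break
            res = res2
        return res, n_iter

    rng = np.random.default_rng(seed)
    best, best_iter = None, 0
    for start in range(max(1, multi_start)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.2, size=packer.size)
        res, n_iter = _polished(xs)
        if best is None or res.fun < best.fun:
            best, best_iter = res, n_iter
    converged = bool(best.success) and best.fun <= ofv0 + 1e-9
    x_hat, ofv_hat = (best.x, float(best.fun)) if best.fun <= ofv0 else (x0, ofv0)
    return _build_result(engine, packer, x_hat, ofv_hat, ofv0, converged,
                         best_iter, str(best.message), compute_se=compute_se)


def _build_result(engine, packer, x_hat, ofv_hat, ofv0, converged, n_iter,
                  message, compute_se=True):
    spec = engine.spec
    theta, omega, sigma = packer.unpack(x_hat)
    if engine.k and any(v > 1e-12 for v in omega.values()):
        try:
            etas, _, _ = engine.inner_modes(
                theta, engine._omega_matrix(omega), sigma)
        except (FloatingPointError, np.linalg.LinAlgError):
            etas = np.zeros((engine.fd.n, engine.k))
    else:
        etas = np.zeros((engine.fd.n, engine.k))
    eta_df = pd.DataFrame(etas, columns=[f"eta_{e}" for e in spec.eta_names])
    eta_df.insert(0, "ID", engine.fd.ids)
    theta_se = {}
    cond = np.nan
    if compute_se and packer.size:
        hess, cond = _ofv_hessian(engine, packer, x_hat)
        try:
            cov = 2.0 * np.linalg.inv(hess)
            se_packed = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se_nat = se_packed * np.abs(packer.dnat_dpacked(x_hat))
            for i, name in enumerate(packer.theta_names):
                theta_se[name] = float(se_nat[i])
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        theta=theta, theta_se=theta_se, omega=omega, sigma=sigma,
        ofv=float(ofv_hat), eta=eta_df, converged=converged, n_iter=n_iter,
        n_subjects=engine.fd.n, n_obs=engine.fd.n_obs,
        condition_number=float(cond), message=message,
        ofv_init=float(ofv0), spec=spec,
    )


def _ofv_hessian(engine, packer, x, step=1e-3):
    d = packer.size

    def f(xv):
        theta, omega, sigma = packer.unpack(xv)
        try:
            return engine.ofv(theta=theta, omega=omega, sigma=sigma)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return np.nan

    f0 = f(x)
    hess = np.zeros((d, d))
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        fp, fm = f(x + ei), f(x - ei)
        hess[i, i] = (fp - 2.0 * f0 + fm) / step**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    with np.errstate(all="ignore"):
        try:
            cond = float(np.linalg.cond(hess))
        except np.linalg.LinAlgError:
            cond = np.nan
    return hess, cond


def empirical_bayes(spec: PopulationModelSpec, data, result: FitResult,
                    subject_id=None, constants=None) -> pd.DataFrame:
    """Per-subject random-effect modes and post hoc parameters.

    Returns one row per subject (or the requested subject) with the eta
    vector, the post hoc total intrinsic clearance, and the ratio of
    that clearance to the typical (eta = 0) value.
    """
    engine = LaplaceEngine(spec, data, constants=constants)
    if engine.k and any(v > 1e-12 for v in result.omega.values()):
        etas, _, _ = engine.inner_modes(
            result.theta, engine._omega_matrix(result.omega), result.sigma
        )
    else:
        etas = np.zeros((engine.fd.n, engine.k))
    cl, v, ka, f = engine._individual_arrays(result.theta, etas)
    cl0, _, _, _ = engine._individual_arrays(result.theta, np.zeros_like(etas))
    out = pd.DataFrame({"ID": engine.fd.ids, "age": engine.fd.ages,
                        "weight": engine.fd.wts})
    for i, name in enumerate(spec.eta_names):
        out[f"eta_{name}"] = etas[:, i]
    idx = list(spec.eta_names).index("cl") if "cl" in spec.eta_names else None
    ratio = np.exp(etas[:, idx]) if idx is not None else np.ones(engine.fd.n)
    out["posthoc_cl_ratio"] = ratio
    out["posthoc_CL"] = cl
    out["typical_CL"] = cl0
    if subject_id is not None:
        sel = out[out["ID"] == subject_id]
        if sel.empty:
            raise KeyError(f"unknown subject ID {subject_id!r}")
        return sel.reset_index(drop=True)
    return out
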