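"""Scikit-learn-style estimator interface to the NLME engine.

:class:`OntogenyNlme` wraps the population-PBPK mixed-effects fit in the
familiar ``fit``/``predict`` shape so it composes with sklearn
pipelines and model selection; the functional API in
:mod:`ontopbpk.nlme` delegates here for nothing — both surfaces sit on
the same :class:`~ontopbpk.nlme.LaplaceEngine`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import ontogeny as _ont
from .dataio import PKDataset
from .nlme import (
    FitResult,
    LaplaceEngine,
    PopulationModelSpec,
    default_ontogeny_estimate,
    default_ontogeny_inits,
    empirical_bayes,
    fit as _fit,
)

__all__ = ["OntogenyNlme"]


class OntogenyNlme(BaseEstimator):
    """Population-PBPK mixed-effects model with estimable enzyme ontogeny.

    Parameters
    ----------
    drug : DrugParameters
        Adult drug configuration (pathways, ontogeny bindings).
    target_pathway : str or None
        Pathway whose ontogeny is estimated (None: all bindings fixed).
    ontogeny_family : str or None
        Structural family for the target pathway; None keeps the drug's
        own binding (or a flat ontogeny if the binding is None).
    estimate : tuple of str or "auto"
        Fixed effects to estimate. "auto" uses CLint, V_ref plus the
        family's default estimable subset.
    theta_init : dict or None
        Natural-scale starting values overriding the defaults.
    eta_names, omega_init, sigma_init
        Random-effect structure (log-normal) and residual model
        (proportional CV, additive SD).
    estimate_omega, estimate_sigma : bool
        Whether variance components are estimated.
    multi_start : int
        Number of jittered restarts (seed-controlled).

    Attributes (after ``fit``)
    --------------------------
    theta_, theta_se_, omega_, sigma_, ofv_, eta_, converged_,
    n_iter_, condition_number_, result_
    """

    def __init__(self, drug=None, target_pathway="FMO3", ontogeny_family="eq4a",
                 estimate="auto", theta_init=None, eta_names=("cl", "v"),
                 omega_init=(0.09, 0.09), sigma_init=(0.15, 0.0),
                 estimate_omega=True, estimate_sigma=True, multi_start=1,
                 seed=0, maxiter=200, tol=1e-6, compute_se=False,
                 constants=None):
        self.drug = drug
        self.target_pathway = target_pathway
        self.ontogeny_family = ontogeny_family
        self.estimate = estimate
        self.theta_init = theta_init
        self.eta_names = eta_names
        self.omega_init = omega_init
        self.sigma_init = sigma_init
        self.estimate_omega = estimate_omega
        self.estimate_sigma = estimate_sigma
        self.multi_start = multi_start
        self.seed = seed
        self.maxiter = maxiter
        self.tol = tol
        self.compute_se = compute_se
        self.constants = constants

    # ------------------------------------------------------------------

    def build_spec(self) -> PopulationModelSpec:
        if self.drug is None:
            raise ValueError("a drug configuration is required")
        if self.estimate == "auto":
            est = ["CLint", "V_ref"]
            if self.ontogeny_family is not None:
                est += list(default_ontogeny_estimate(self.ontogeny_family))
            estimate = tuple(est)
        else:
            estimate = tuple(self.estimate)
        theta = dict(self.theta_init or {})
        omega = {name: self.omega_init[i] for i, name in enumerate(self.eta_names)}
        return PopulationModelSpec(
            drug=self.drug,
            target_pathway=self.target_pathway,
            ontogeny_family=self.ontogeny_family,
            theta=theta,
            estimate=estimate,
            eta_names=tuple(self.eta_names),
            omega=omega,
            sigma=tuple(self.sigma_init),
            estimate_omega=self.estimate_omega,
            estimate_sigma=self.estimate_sigma,
        )

    def fit(self, X, y=None):
        """Estimate the model from a NONMEM-style dataset (DataFrame or
        PKDataset)."""
        spec = self.build_spec()
        result: FitResult = _fit(
            spec, X, constants=self.constants, multi_start=self.multi_start,
            seed=self.seed, maxiter=self.maxiter, tol=self.tol,
            compute_se=self.compute_se,
        )
        self.result_ = result
        self.spec_ = spec
        self.theta_ = result.theta
        self.theta_se_ = result.theta_se
        self.omega_ = result.omega
        self.sigma_ = result.sigma
        self.ofv_ = result.ofv
        self.eta_ = result.eta
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.condition_number_ = result.condition_number
        return self

    def predict(self, X) -> np.ndarray:
        """Population (eta = 0) predictions for the observation rows of X,
        in dataset order (ng/mL)."""
        self._check_fitted()
        engine = LaplaceEngine(self.spec_, X, constants=self.constants)
        pred = engine.predict(self.theta_, np.zeros((engine.fd.n, engine.k)))
        return pred[engine.fd.mask]

    def empirical_bayes(self, X, subject_id=None) -> pd.DataFrame:
        self._check_fitted()
        return empirical_bayes(self.spec_, X, self.result_,
                               subject_id=subject_id, constants=self.constants)

    def ontogeny_curve(self, ages) -> np.ndarray:
        """Fitted F_activity of the target pathway on an age grid."""
        self._check_fitted()
        if self.spec_.ontogeny_family is None:
            return np.ones_like(np.asarray(ages, dtype=float))
        params = _ont.OntogenyParameters(**{
            name: self.theta_[name]
            for name in self.spec_.ontogeny_theta_names()
        })
        return np.asarray(_ont.evaluate_ontogeny(
            self.spec_.ontogeny_family, params, ages))

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
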