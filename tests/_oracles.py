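"""Independent oracles for likelihood-level tests.

These deliberately avoid the engine's own code paths: the closed-form
marginal OFV for a linear-Gaussian model comes straight from the
multivariate normal density, and the linear "model" is injected by
overriding the prediction method only.
"""

import numpy as np
from scipy.stats import multivariate_normal

from ontopbpk.nlme import LaplaceEngine, _VAR_FLOOR


class LinearModelEngine(LaplaceEngine):
    """Engine whose per-subject prediction is a + B @ eta (exactly
    linear in the random effects), for which the Laplace approximation
    is exact."""

    def __init__(self, spec, data, a, b, **kwargs):
        super().__init__(spec, data, **kwargs)
        self._a = np.asarray(a, dtype=float)      # (n, J)
        self._b = np.asarray(b, dtype=float)      # (n, J, k)

    def _typical(self, theta):
        return {}

    def predict(self, theta, eta, typ=None):
        eta = np.atleast_2d(eta)
        return self._a + np.einsum("njk,nk->nj", self._b, eta)


def closed_form_linear_ofv(a, b, dv, mask, omega, sigma_add):
    """Exact -2 log marginal likelihood for y = a + B eta + eps with
    eta ~ N(0, omega), eps ~ N(0, sigma_add^2 I) (residual variance
    includes the engine's additive floor)."""
    total = 0.0
    var = sigma_add**2 + _VAR_FLOOR
    for i in range(a.shape[0]):
        m = mask[i]
        mean = a[i][m]
        bb = b[i][m]
        cov = bb @ omega @ bb.T + var * np.eye(int(m.sum()))
        total += -2.0 * multivariate_normal.logpdf(dv[i][m], mean=mean, cov=cov)
    return float(total)
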