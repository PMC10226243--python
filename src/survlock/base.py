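"""Shared estimator machinery: RMST quadrature, information criteria, records."""

from __future__ import annotations

import numpy as np
from scipy import integrate
from sklearn.base import BaseEstimator

from .data import SurvivalDataset

__all__ = ["SurvivalEstimator", "rmst_from_survival", "as_time_status"]


def as_time_status(data, event=None):
    """Accept a SurvivalDataset or (time, event) arrays."""
    if isinstance(data, SurvivalDataset):
        return data.time, data.status
    time = np.asarray(data, dtype=float)
    if event is None:
        raise ValueError("event indicator required when passing a raw time array")
    status = np.asarray(event, dtype=int)
    SurvivalDataset(time, status)  # runs validation
    return time, status


def rmst_from_survival(survival, horizon, t0=0.0, log_substitution=False, epsabs=1e-8):
    """Restricted mean survival time by adaptive quadrature.

    ``t0 = 0`` gives the plain RMST; ``t0 > 0`` gives the restricted mean
    residual life on [t0, horizon] divided by S(t0).  With
    ``log_substitution`` the integral over [0, horizon] is computed in
    z = log t, which tames integrands whose derivative is singular at 0
    (spline models on the log-time scale).
    """
    if not 0 <= t0 < horizon:
        raise ValueError("need 0 <= t0 < horizon")

    def sf(t):
        return float(survival(t))

    if t0 == 0:
        if log_substitution:

            def integrand(z):
                t = np.exp(z)
                if t == 0.0:  # S(0+) = 1 and the Jacobian kills the integrand
                    return 0.0
                return sf(t) * t

            area, _ = integrate.quad(
                integrand, -np.inf, np.log(horizon), epsabs=epsabs, limit=200
            )
        else:
            area, _ = integrate.quad(sf, 0.0, horizon, epsabs=epsabs, limit=200)
        return float(area)
    s0 = sf(t0)
    if s0 <= 0 or not np.isfinite(s0):
        raise ValueError("S(t0) vanished: conditional RMST undefined")
    area, _ = integrate.quad(sf, t0, horizon, epsabs=epsabs, limit=200)
    return float(area / s0)


class SurvivalEstimator(BaseEstimator):
    """Base class for fitted survival models.

    Subclasses set ``loglik_``, ``n_used_``, ``k_`` (free parameters) and
    ``converged_`` during :meth:`fit` and implement ``survival_function``,
    ``hazard`` and ``density``.  ``predict(t)`` returns S(t) so models plug
    into scikit-learn tooling.
    """

    model_class = "standard"
    _rmst_log_substitution = False

    def _set_information_criteria(self):
        k, n = self.k_, self.n_used_
        self.aic_ = -2.0 * self.loglik_ + 2.0 * k
        self.bic_ = -2.0 * self.loglik_ + k * np.log(n)

    def predict(self, t):
        return self.survival_function(t)

    def survival_function(self, t):
        raise NotImplementedError

    def hazard(self, t):
        raise NotImplementedError

    def density(self, t):
        raise NotImplementedError

    def rmst(self, horizon, t0=0.0):
        """(Conditional) restricted mean survival time of the fitted model."""
        return rmst_from_survival(
            self.survival_function,
            horizon,
            t0=t0,
            log_substitution=self._rmst_log_substitution,
        )

    @property
    def label(self) -> str:
        return type(self).__name__

    def to_record(self) -> dict:
        """Flat serializable summary of the fit."""
        return {
            "model": self.label,
            "model_class": self.model_class,
            "k": self.k_,
            "n": self.n_used_,
            "loglik": self.loglik_,
            "aic": self.aic_,
            "bic": self.bic_,
            "converged": self.converged_,
        }
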