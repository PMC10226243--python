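"""The seven standard parametric survival families.

Parameterizations are pinned so that results are unambiguous and can be
cross-validated against other survival toolchains:

- exponential:   S(t) = exp(-rate * t)
- weibull:       S(t) = exp(-(t/scale)^shape)
- gompertz:      h(t) = rate * exp(shape * t), shape real, rate > 0
- gamma:         shape/rate density t^(k-1) r^k e^(-rt) / Gamma(k)
- loglogistic:   S(t) = 1 / (1 + (t/scale)^shape)
- lognormal:     S(t) = 1 - Phi((log t - mu) / sigma)
- gengamma:      (mu, sigma, Q) form; Q -> 0 is lognormal, Q = 1 with free
                 sigma is Weibull (shape 1/sigma, scale e^mu)

Each family exposes log-density and log-survival on the natural scale, a
bijection to an unconstrained fitting scale (log for positive parameters),
and deterministic moment-based starting values.  Out-of-domain parameters
yield -inf log-likelihood rather than an exception so optimizers can
recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["FamilySpec", "FAMILIES", "get_family"]

_GENGAMMA_LOGNORMAL_EPS = 1e-8


@dataclass(frozen=True)
class FamilySpec:
    """Static description of one parametric family."""

    name: str
    param_names: tuple
    positive: tuple  # which natural parameters are constrained positive

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_unconstrained(self, natural):
        x = np.asarray(natural, dtype=float).copy()
        for i, pos in enumerate(self.positive):
            if pos:
                x[i] = np.log(x[i])
        return x

    def to_natural(self, unconstrained):
        x = np.asarray(unconstrained, dtype=float).copy()
        for i, pos in enumerate(self.positive):
            if pos:
                x[i] = np.exp(x[i])
        return x

    def in_domain(self, natural) -> bool:
        natural = np.asarray(natural, dtype=float)
        if natural.shape != (self.n_params,) or not np.isfinite(natural).all():
            return False
        return all(
            (natural[i] > 0) if pos else True for i, pos in enumerate(self.positive)
        )

    # subclass-free dispatch: concrete behavior is attached per instance
    def logpdf(self, t, natural):
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            return self._logpdf(np.asarray(t, dtype=float), np.asarray(natural, dtype=float))

    def logsf(self, t, natural):
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            return self._logsf(np.asarray(t, dtype=float), np.asarray(natural, dtype=float))

    def sf(self, t, natural):
        return np.exp(self.logsf(t, natural))

    def hazard(self, t, natural):
        return np.exp(self.logpdf(t, natural) - self.logsf(t, natural))

    def init(self, time, status):
        """Deterministic moment-based starting value, unconstrained scale."""
        return self.to_unconstrained(self._init(time, status))


def _uncensored_moments(time, status):
    t = time[status == 1] if np.any(status == 1) else time
    m = float(np.mean(t))
    s = float(np.std(t)) or 0.5 * m
    return t, m, s


# --- exponential -----------------------------------------------------------

def _exp_logpdf(t, p):
    return np.log(p[0]) - p[0] * t


def _exp_logsf(t, p):
    return -p[0] * t


def _exp_init(time, status):
    rate = max(status.sum(), 1) / time.sum()
    return np.array([rate])


# --- weibull ---------------------------------------------------------------

def _wei_logH(t, p):
    shape, scale = p
    return shape * (np.log(t) - np.log(scale))


def _wei_logpdf(t, p):
    shape, scale = p
    logH = _wei_logH(t, p)
    return np.log(shape) - np.log(t) + logH - np.exp(logH)


def _wei_logsf(t, p):
    return -np.exp(_wei_logH(t, p))


def _wei_init(time, status):
    t, m, s = _uncensored_moments(time, status)
    shape = float(np.clip((m / s) ** 1.086, 0.2, 10.0))
    return np.array([shape, m])


# --- gompertz --------------------------------------------------------------

def _gom_H(t, p):
    a, b = p
    if abs(a) < 1e-10:
        return b * t
    return b * np.expm1(a * t) / a


def _gom_logpdf(t, p):
    a, b = p
    return np.log(b) + a * t - _gom_H(t, p)


def _gom_logsf(t, p):
    return -_gom_H(t, p)


def _gom_init(time, status):
    rate = max(status.sum(), 1) / time.sum()
    return np.array([1e-3, rate])


# --- gamma -----------------------------------------------------------------

def _gam_logpdf(t, p):
    k, r = p
    return k * np.log(r) + (k - 1) * np.log(t) - r * t - special.gammaln(k)


def _gam_logsf(t, p):
    k, r = p
    with np.errstate(divide="ignore"):
        return np.log(special.gammaincc(k, r * t))


def _gam_init(time, status):
    t, m, s = _uncensored_moments(time, status)
    k = float(np.clip((m / s) ** 2, 0.05, 50.0))
    return np.array([k, k / m])


# --- log-logistic ----------------------------------------------------------

def _llog_logpdf(t, p):
    shape, scale = p
    lp = shape * (np.log(t) - np.log(scale))
    return np.log(shape) - np.log(t) + lp - 2.0 * np.logaddexp(0.0, lp)


def _llog_logsf(t, p):
    shape, scale = p
    lp = shape * (np.log(t) - np.log(scale))
    return -np.logaddexp(0.0, lp)


def _llog_init(time, status):
    t, m, s = _uncensored_moments(time, status)
    return np.array([1.5, float(np.median(t))])


# --- lognormal -------------------------------------------------------------

def _lnorm_logpdf(t, p):
    mu, sigma = p
    w = (np.log(t) - mu) / sigma
    return stats.norm.logpdf(w) - np.log(sigma * t)


def _lnorm_logsf(t, p):
    mu, sigma = p
    return stats.norm.logsf((np.log(t) - mu) / sigma)


def _lnorm_init(time, status):
    t, m, s = _uncensored_moments(time, status)
    logt = np.log(t)
    return np.array([float(np.mean(logt)), float(np.std(logt)) or 1.0])


# --- generalized gamma -----------------------------------------------------

def _stirling_residual(a):
    """a*log(a) - lgamma(a) - a, computed without catastrophic cancellation."""
    if a > 1e7:
        return 0.5 * np.log(a / (2.0 * np.pi)) - 1.0 / (12.0 * a)
    return a * np.log(a) - special.gammaln(a) - a


def _gg_logpdf(t, p):
    mu, sigma, Q = p
    if abs(Q) < _GENGAMMA_LOGNORMAL_EPS:
        return _lnorm_logpdf(t, (mu, sigma))
    a = Q**-2
    w = (np.log(t) - mu) / sigma
    qw = Q * w
    # a*(qw - e^qw) = a*(qw - expm1(qw)) - a; fold the -a into the Stirling
    # residual so the Q -> 0 limit stays accurate
    return (
        np.log(abs(Q))
        - np.log(sigma * t)
        + _stirling_residual(a)
        + a * (qw - np.expm1(qw))
    )


def _gg_logsf(t, p):
    mu, sigma, Q = p
    if abs(Q) < _GENGAMMA_LOGNORMAL_EPS:
        return _lnorm_logsf(t, (mu, sigma))
    a = Q**-2
    w = (np.log(t) - mu) / sigma
    u = a * np.exp(Q * w)
    with np.errstate(divide="ignore"):
        if Q > 0:
            return np.log(special.gammaincc(a, u))
        return np.log(special.gammainc(a, u))


def _gg_init(time, status):
    t, m, s = _uncensored_moments(time, status)
    logt = np.log(t)
    return np.array([float(np.mean(logt)), float(np.std(logt)) or 1.0, 0.2])


def _make(name, param_names, positive, logpdf, logsf, init):
    spec = FamilySpec(name=name, param_names=tuple(param_names), positive=tuple(positive))
    object.__setattr__(spec, "_logpdf", logpdf)
    object.__setattr__(spec, "_logsf", logsf)
    object.__setattr__(spec, "_init", init)
    return spec


FAMILIES: dict[str, FamilySpec] = {
    f.name: f
    for f in [
        _make("exponential", ("rate",), (True,), _exp_logpdf, _exp_logsf, _exp_init),
        _make("weibull", ("shape", "scale"), (True, True), _wei_logpdf, _wei_logsf, _wei_init),
        _make("gompertz", ("shape", "rate"), (False, True), _gom_logpdf, _gom_logsf, _gom_init),
        _make("gamma", ("shape", "rate"), (True, True), _gam_logpdf, _gam_logsf, _gam_init),
        _make("loglogistic", ("shape", "scale"), (True, True), _llog_logpdf, _llog_logsf, _llog_init),
        _make("lognormal", ("mu", "sigma"), (False, True), _lnorm_logpdf, _lnorm_logsf, _lnorm_init),
        _make("gengamma", ("mu", "sigma", "Q"), (False, True, False), _gg_logpdf, _gg_logsf, _gg_init),
    ]
}


def get_family(name: str) -> FamilySpec:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(FAMILIES)}") from None
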