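"""Nonparametric reference machinery.

The Kaplan-Meier product-limit curve is the empirical benchmark every
extrapolation is judged against; restricted mean survival time (RMST) is
the exact area under its step function.  A kernel-smoothed hazard supports
visual diagnostics of fitted hazards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = [
    "KMCurve",
    "HazardCurve",
    "km_fit",
    "km_rmst",
    "km_conditional_rmst",
    "smoothed_hazard",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with risk/event counts and Greenwood variance.

    ``surv[i]`` is S(t) just after ``event_times[i]``; the curve is a
    right-continuous step function equal to 1 before the first event.
    """

    event_times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    last_obs: float
    greenwood_var: np.ndarray = field(default=None)

    def survival_at(self, t):
        """Step-function evaluation S(t), right-continuous at event times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[1.0], self.surv])
        out = padded[idx]
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(self.greenwood_var)
        # log-minus-log confidence limits, clipped to [0, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            logS = np.log(self.surv)
            z = 1.959963984540054
            theta = np.where(self.surv > 0, z * se / (self.surv * logS), np.nan)
            lower = self.surv ** np.exp(theta)
            upper = self.surv ** np.exp(-theta)
        return pd.DataFrame(
            {
                "time": self.event_times,
                "estimate": self.surv,
                "lower": np.where(self.surv > 0, lower, 0.0),
                "upper": np.where(self.surv > 0, upper, 0.0),
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


@dataclass(frozen=True)
class HazardCurve:
    """Kernel-smoothed hazard on a fixed grid."""

    grid: np.ndarray
    hazard: np.ndarray
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.grid, "hazard": self.hazard})


def km_fit(ds: SurvivalDataset) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times events are processed before censorings: a subject censored
    at t is still at risk for a death at t.  Greenwood's formula supplies
    the variance of S at each event time.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    evt = ds.time[ds.status == 1]
    event_times, d = np.unique(evt, return_counts=True)
    n = np.array([np.sum(ds.time >= et) for et in event_times])
    frac = 1.0 - d / n
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n > d, d / (n * (n - d)), np.inf)
        greenwood = surv**2 * np.cumsum(gw_terms)
    greenwood = np.where(np.isfinite(greenwood), greenwood, 0.0)
    return KMCurve(
        event_times=event_times,
        surv=surv,
        n_risk=n,
        n_event=d,
        last_obs=float(ds.time.max()),
        greenwood_var=greenwood,
    )


def _step_area(curve: KMCurve, a: float, b: float) -> float:
    """Exact area under the KM step function on [a, b], b <= last_obs not enforced."""
    knots = np.concatenate([[a], curve.event_times[(curve.event_times > a) & (curve.event_times < b)], [b]])
    widths = np.diff(knots)
    heights = curve.survival_at(knots[:-1])
    return float(np.sum(widths * np.atleast_1d(heights)))


def km_rmst(curve: KMCurve, horizon: float, extend_flat: bool = False) -> float:
    """Restricted mean survival time: area under the KM curve on [0, horizon].

    The curve is undefined beyond its largest observed time, so horizons
    past ``last_obs`` are refused unless ``extend_flat`` carries the final
    survival level forward (a warning flags the extension).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if horizon > curve.last_obs:
        if not extend_flat:
            raise ValueError(
                f"horizon {horizon} exceeds last observed time {curve.last_obs}; "
                "pass extend_flat=True to carry the final level forward"
            )
        warnings.warn(
            "KM RMST horizon beyond follow-up: survival extended flat", UserWarning
        )
    return _step_area(curve, 0.0, horizon)


def km_conditional_rmst(curve: KMCurve, t0: float, horizon: float, extend_flat: bool = False) -> float:
    """Restricted mean residual life on [t0, horizon] given survival to t0.

    Returns ``(integral of S from t0 to horizon) / S(t0)``.
    """
    if not 0 < t0 < horizon:
        raise ValueError("need 0 < t0 < horizon")
    s0 = curve.survival_at(t0)
    if s0 <= 0:
        raise ValueError("S(t0) = 0: conditional RMST undefined")
    if horizon > curve.last_obs and not extend_flat:
        raise ValueError(
            f"horizon {horizon} exceeds last observed time {curve.last_obs}"
        )
    return _step_area(curve, t0, horizon) / s0


def _epanechnikov_cdf(u):
    u = np.clip(u, -1.0, 1.0)
    return 0.25 * (2.0 + 3.0 * u - u**3)


def smoothed_hazard(ds: SurvivalDataset, bandwidth="auto") -> HazardCurve:
    """Kernel-smoothed hazard from Nelson-Aalen increments.

    An Epanechnikov kernel of fixed bandwidth is applied to the increments
    d_i/n_i at the event times, with a cut-and-normalize boundary
    correction at t = 0 so mass falling below zero is renormalized rather
    than lost.  ``bandwidth="auto"`` uses (last event - first event)/8.
    The grid is 256 equally spaced points from 0 to the last event time.
    """
    curve = km_fit(ds)
    if curve.event_times.size < 2:
        raise ValueError("need at least 2 events to smooth a hazard")
    increments = curve.n_event / curve.n_risk
    if bandwidth == "auto":
        bandwidth = (curve.event_times[-1] - curve.event_times[0]) / 8.0
    b = float(bandwidth)
    if b <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, curve.event_times[-1], 256)
    u = (grid[:, None] - curve.event_times[None, :]) / b
    kern = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0) / b
    # boundary correction: renormalize by the kernel mass inside [0, inf)
    denom = _epanechnikov_cdf(1.0) - _epanechnikov_cdf(-grid / b)
    denom = np.where(denom > 0, denom, 1.0)
    haz = (kern @ increments) / denom
    return HazardCurve(grid=grid, hazard=haz, bandwidth=b)
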