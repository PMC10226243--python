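"""Diagnostic plots: KM + smoothed-hazard panels and error scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .nonparametric import km_fit, smoothed_hazard

__all__ = ["plot_km_panel", "plot_error_scatter", "plot_lifetime_rmst"]

_CLASS_COLORS = {"standard": "tab:blue", "spline": "tab:orange"}


def _step_xy(curve):
    x = np.concatenate([[0.0], np.repeat(curve.event_times, 2), [curve.last_obs]])
    s = np.concatenate([[1.0], curve.surv])
    y = np.repeat(s, 2)[: x.size]
    return x, y


def plot_km_panel(ds: SurvivalDataset, path, models=None, horizon=None) -> None:
    """Survival + smoothed-hazard panel for one dataset, with optional
    fitted-model overlays and integer-year risk table ticks."""
    curve = km_fit(ds)
    fig, (ax_s, ax_h) = plt.subplots(1, 2, figsize=(10, 4))
    x, y = _step_xy(curve)
    ax_s.plot(x, y, color="black", lw=1.5, label="Kaplan-Meier")
    tmax = horizon or curve.last_obs
    grid = np.linspace(1e-3, tmax, 200)
    for model in models or []:
        ax_s.plot(grid, model.survival_function(grid), lw=1, alpha=0.8,
                  color=_CLASS_COLORS.get(model.model_class), label=model.label)
        ax_h.plot(grid, model.hazard(grid), lw=1, alpha=0.8,
                  color=_CLASS_COLORS.get(model.model_class))
    try:
        hz = smoothed_hazard(ds)
        ax_h.plot(hz.grid, hz.hazard, color="black", lw=1.5, label="smoothed hazard")
    except ValueError:
        pass
    years = np.arange(0, int(np.ceil(curve.last_obs)) + 1)
    at_risk = [(ds.time >= y).sum() for y in years]
    ax_s.set_xticks(years)
    ax_s.set_xticklabels([f"{y}\n{n}" for y, n in zip(years, at_risk)], fontsize=7)
    ax_s.set_xlabel("years (number at risk)")
    ax_s.set_ylabel("overall survival")
    ax_s.set_ylim(0, 1.02)
    ax_s.legend(fontsize=7)
    ax_h.set_xlabel("years")
    ax_h.set_ylabel("hazard (per year)")
    fig.suptitle(f"{ds.cohort} {ds.lock}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _scatter(records: pd.DataFrame, ycol: str, path, xcol="pct_censored", ylabel=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, grp in records.dropna(subset=[ycol]).groupby("model_class"):
        ax.scatter(grp[xcol], grp[ycol], s=14, alpha=0.6,
                   color=_CLASS_COLORS.get(cls), label=cls)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(xcol.replace("_", " "))
    ax.set_ylabel(ylabel or ycol.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lifetime_rmst(records: pd.DataFrame, path) -> None:
    """Lifetime RMST against percentage censored, by model class."""
    _scatter(records, "lifetime_rmst", path, ylabel="lifetime RMST (years)")


def plot_error_scatter(records: pd.DataFrame, path, conditional=False) -> None:
    """RMST error (or the conditional variant) against percentage censored."""
    col = "cond_rmst_error" if conditional else "rmst_error"
    _scatter(records, col, path, ylabel=f"{'conditional ' if conditional else ''}RMST error (years)")
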