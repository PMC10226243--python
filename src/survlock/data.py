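"""Right-censored survival datasets: the universal fitting input.

A :class:`SurvivalDataset` holds per-subject observed time since enrollment
(years) and an event indicator (1 = death observed, 0 = right censored),
plus dataset-level metadata describing how the data were cut (cohort label,
lock label, maximum follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "read_survival_csv", "write_survival_csv"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored (time, status) pairs after a database lock.

    Parameters
    ----------
    time : ndarray
        Years since enrollment, strictly positive.
    status : ndarray
        1 for an observed death, 0 for right censoring.
    cohort : str
        Label of the cohort the data came from.
    lock : str
        Label of the database lock (e.g. ``"<6y"``).
    max_followup : float or None
        Lock time minus enrollment start, in years; None when the data
        were not produced by a lock (e.g. user-supplied).
    """

    time: np.ndarray
    status: np.ndarray
    cohort: str = ""
    lock: str = ""
    max_followup: float | None = None
    min_potential_followup: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.status, dtype=int)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("time and status must be 1-d arrays of equal length")
        if t.size and np.any(t <= 0):
            raise ValueError("all observed times must be strictly positive")
        if s.size and not np.isin(s, (0, 1)).all():
            raise ValueError("status must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "status", s)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def n_censored(self) -> int:
        return int(len(self) - self.n_events)

    @property
    def pct_censored(self) -> float:
        if len(self) == 0:
            raise ValueError("empty dataset")
        return 100.0 * self.n_censored / len(self)

    def with_meta(self, **kwargs) -> "SurvivalDataset":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "time": self.time,
                "status": self.status,
            }
        )


def write_survival_csv(ds: SurvivalDataset, path) -> None:
    """Write the standard two-column survival layout (id, time, status)."""
    ds.to_frame().to_csv(path, index=False)


def read_survival_csv(path, time_col: str = "time", status_col: str = "status") -> SurvivalDataset:
    """Read delimited text with time/status columns into a dataset."""
    df = pd.read_csv(path)
    if time_col not in df or status_col not in df:
        raise ValueError(f"expected columns {time_col!r} and {status_col!r} in {path}")
    return SurvivalDataset(df[time_col].to_numpy(float), df[status_col].to_numpy(int))
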