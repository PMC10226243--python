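"""Database locks: artificial data cut-offs of increasing maximum follow-up.

A lock at calendar time L excludes subjects enrolled at or after L and
administratively censors everyone still alive and on study at L.  Applying
a grid of locks to one cohort produces the maturity axis of the analysis:
datasets that share a population but differ in follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .synthetic import RawCohort

__all__ = ["LockSpec", "apply_lock", "lock_grid", "censoring_summary"]


@dataclass(frozen=True)
class LockSpec:
    """A database lock at a calendar time, with a free-text label."""

    lock_time: float
    label: str = ""


def apply_lock(cohort: RawCohort, lock: LockSpec) -> SurvivalDataset:
    """Cut a raw cohort at a lock date.

    Subjects enrolled at or after the lock are excluded.  For each retained
    subject the observed time is ``min(death, ltfu, lock) - enroll`` and the
    status is 1 only when death strictly precedes both the lock and any loss
    to follow-up; a death exactly at the lock instant counts as censored
    (administrative censoring wins ties, which are measure-zero under
    continuous times anyway).
    """
    keep = cohort.enroll_time < lock.lock_time
    if not np.any(keep):
        raise ValueError(
            f"lock at {lock.lock_time} precedes every enrollment; empty dataset"
        )
    enroll = cohort.enroll_time[keep]
    death = cohort.death_time[keep]
    ltfu = cohort.ltfu_time[keep]
    exit_cal = np.fmin(np.fmin(death, ltfu), lock.lock_time)
    status = ((death <= exit_cal) & (death < lock.lock_time)).astype(int)
    time = exit_cal - enroll
    return SurvivalDataset(
        time,
        status,
        cohort=cohort.label,
        lock=lock.label or f"@{lock.lock_time:g}",
        max_followup=lock.lock_time - cohort.enroll_start,
    )


def lock_grid(cohort: RawCohort, max_followups) -> list[SurvivalDataset]:
    """One locked dataset per maximum follow-up, anchored at enrollment start.

    ``max_followups`` must be strictly increasing positive years.  Each
    dataset's metadata records the minimum potential follow-up
    (lock time minus enrollment end), reported as None ("n.a.") when the
    lock falls inside the enrollment window.
    """
    mfs = [float(m) for m in max_followups]
    if any(m <= 0 for m in mfs) or any(b <= a for a, b in zip(mfs, mfs[1:])):
        raise ValueError("max_followups must be strictly increasing and positive")
    start = cohort.enroll_start
    enroll_end = float(cohort.enroll_time.max())
    out = []
    for m in mfs:
        lock = LockSpec(lock_time=start + m, label=f"<{m:g}y")
        ds = apply_lock(cohort, lock)
        min_pot = lock.lock_time - enroll_end
        ds = ds.with_meta(min_potential_followup=min_pot if min_pot > 0 else None)
        out.append(ds)
    return out


def censoring_summary(ds: SurvivalDataset) -> tuple[float, int, int]:
    """(percentage censored, number of events, number of subjects)."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    return (ds.pct_censored, ds.n_events, len(ds))
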