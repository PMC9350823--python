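"""Session- and week-level domain scoring.

The domain score summarizes how far up a domain's task progression order
a patient is working.  Each practiced task in a session is classified by
accuracy — *passed* (>= 90%), *working* (40%..90%) or *failed* (< 40%) —
then the session score is built from two endpoints:

* ``hi``: the highest rank passed or working,
* ``lo``: the lowest rank working or failed.

An endpoint whose task was working or failed is adjusted by subtracting 1
(the last rank actually mastered is the previous one), floored at 0.  The
session score is the mean of the two adjusted ranks divided by the
domain's total number of levels ``L``, giving a value in [0, 1] that is
comparable across domains.  Weekly scores average the session scores of a
patient x domain within each 7-day week of use.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TaskStatus",
    "classify_task",
    "session_domain_score",
    "weekly_scores",
    "baseline_score",
    "DomainScorer",
]

PASS_THRESHOLD = 0.90
FAIL_THRESHOLD = 0.40


class TaskStatus(enum.Enum):
    PASSED = "passed"
    WORKING = "working"
    FAILED = "failed"


def classify_task(accuracy: float) -> TaskStatus:
    """Classify a task attempt: passed iff accuracy >= 0.90, failed iff
    accuracy < 0.40, working otherwise (0.40 itself is working)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    if accuracy >= PASS_THRESHOLD:
        return TaskStatus.PASSED
    if accuracy < FAIL_THRESHOLD:
        return TaskStatus.FAILED
    return TaskStatus.WORKING


def session_domain_score(tasks: Iterable[tuple[int, float]], n_levels: int) -> float:
    """Normalized domain score of one session.

    ``tasks`` is an iterable of ``(task_rank, accuracy)`` pairs; repeated
    attempts at the same rank are pooled by mean accuracy before
    classification.  One-sided sessions fall back to: all passed -> both
    endpoints at the highest passed rank unadjusted; all failed -> both
    endpoints at the lowest failed rank adjusted by -1.
    """
    pooled: dict[int, list[float]] = {}
    for rank, acc in tasks:
        rank = int(rank)
        if rank < 1:
            raise ValueError(f"task_rank must be >= 1, got {rank}")
        if rank > n_levels:
            raise ValueError(f"task_rank {rank} exceeds domain levels L={n_levels}")
        pooled.setdefault(rank, []).append(float(acc))
    if not pooled:
        raise ValueError("session must contain at least one task")

    status = {r: classify_task(float(np.mean(a))) for r, a in pooled.items()}
    hi_pool = [r for r, s in status.items() if s in (TaskStatus.PASSED, TaskStatus.WORKING)]
    lo_pool = [r for r, s in status.items() if s in (TaskStatus.WORKING, TaskStatus.FAILED)]

    if hi_pool and lo_pool:
        hi, lo = max(hi_pool), min(lo_pool)
        hi_adj = hi - 1 if status[hi] is not TaskStatus.PASSED else hi
        lo_adj = lo - 1  # lo's status is working or failed by construction
    elif hi_pool:  # every task passed
        hi_adj = lo_adj = max(hi_pool)
    else:  # every task failed
        hi_adj = lo_adj = min(lo_pool) - 1
    hi_adj = max(hi_adj, 0)
    lo_adj = max(lo_adj, 0)
    return (hi_adj + lo_adj) / 2.0 / n_levels


def _prepare_events(events: pd.DataFrame, n_levels_by_domain: dict[str, int]) -> pd.DataFrame:
    df = events.copy()
    unknown = set(df["domain_id"]) - set(n_levels_by_domain)
    if unknown:
        raise ValueError(f"events reference unknown domains: {sorted(unknown)}")
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    return df


def weekly_scores(
    events: pd.DataFrame,
    n_levels_by_domain: dict[str, int],
    windows: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Aggregate session events into weekly domain scores.

    A session is all events of one patient x domain on one calendar day.
    Weeks are 7-day bins anchored at each patient's first active day (in
    any domain).  If ``windows`` maps patient ids to their ordered
    analysis-week lists (user-relative week indices, from
    :func:`dosefreq.cohort.analysis_window`), only those weeks are kept
    and re-indexed 0..9; otherwise raw user-relative indices are emitted.

    Returns columns ``patient_id, domain_id, week_index, score,
    n_sessions, hours``; weeks without sessions produce no row.
    """
    df = _prepare_events(events, n_levels_by_domain)
    first_day = df.groupby("patient_id")["date"].transform("min")
    df["rel_week"] = ((df["date"] - first_day).dt.days // 7).astype(int)

    rows = []
    for (pid, dom, week, day), grp in df.groupby(
            ["patient_id", "domain_id", "rel_week", "date"], sort=True):
        score = session_domain_score(
            zip(grp["task_rank"], grp["accuracy"]), n_levels_by_domain[dom])
        rows.append((pid, dom, week, score, grp["minutes"].sum() / 60.0))
    sess = pd.DataFrame(rows, columns=["patient_id", "domain_id", "rel_week",
                                       "score", "hours"])
    weekly = (sess.groupby(["patient_id", "domain_id", "rel_week"], sort=True)
              .agg(score=("score", "mean"), n_sessions=("score", "size"),
                   hours=("hours", "sum"))
              .reset_index())

    if windows is None:
        return weekly.rename(columns={"rel_week": "week_index"})

    mapped = []
    for pid, wk_list in windows.items():
        idx_of = {cal: i for i, cal in enumerate(wk_list)}
        sub = weekly[weekly["patient_id"] == pid]
        sub = sub[sub["rel_week"].isin(idx_of)].copy()
        sub["week_index"] = sub["rel_week"].map(idx_of)
        mapped.append(sub.drop(columns="rel_week"))
    if not mapped:
        return pd.DataFrame(columns=["patient_id", "domain_id", "week_index",
                                     "score", "n_sessions", "hours"])
    out = pd.concat(mapped, ignore_index=True)
    return out[["patient_id", "domain_id", "week_index", "score", "n_sessions", "hours"]]


def baseline_score(weekly: pd.DataFrame) -> pd.Series:
    """Week-0 score per patient x domain, used as the severity covariate.

    Raises if any patient x domain present in the table lacks a week-0
    row (such units must be excluded upstream).
    """
    units = weekly[["patient_id", "domain_id"]].drop_duplicates()
    w0 = weekly[weekly["week_index"] == 0].set_index(["patient_id", "domain_id"])["score"]
    missing = [tuple(r) for r in units.itertuples(index=False) if tuple(r) not in w0.index]
    if missing:
        raise ValueError(f"missing week-0 baseline for {len(missing)} "
                         f"patient x domain units, e.g. {missing[:3]}")
    return w0


class DomainScorer(TransformerMixin, BaseEstimator):
    """Transformer turning session logs into weekly domain scores.

    Parameters
    ----------
    n_levels_by_domain
        Mapping domain_id -> total task levels L (the normalization
        denominator).
    windows
        Optional analysis-window mapping (patient_id -> ordered list of
        user-relative week indices) restricting and re-indexing weeks.
    """

    def __init__(self, n_levels_by_domain: dict[str, int] | None = None,
                 windows: dict[str, list[int]] | None = None):
        self.n_levels_by_domain = n_levels_by_domain
        self.windows = windows

    def fit(self, X: pd.DataFrame, y=None) -> "DomainScorer":
        if self.n_levels_by_domain is None:
            raise ValueError("n_levels_by_domain must be provided")
        self.domains_ = sorted(set(X["domain_id"]))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.n_levels_by_domain is None:
            raise ValueError("n_levels_by_domain must be provided")
        return weekly_scores(X, self.n_levels_by_domain, self.windows)
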