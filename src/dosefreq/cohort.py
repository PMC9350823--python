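"""Cohort construction: inclusion rule, analysis window, dosage binning.

The study design this package reimplements includes a patient when they
were active (>= 1 session on >= 1 day) in at least 10 of their first 15
user-relative calendar weeks.  The analysis window is the first 10 active
weeks among those 15, re-indexed 0..9 with week 0 the first active week
(an alternative "truncate" rule — calendar weeks 0..9 regardless of
activity — is available).  Dosage frequency is the median number of
active days per week over the 10 window weeks, rounded half up and binned
into groups ``1, 2, 3, 4, 5+``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .scoring import baseline_score, weekly_scores

__all__ = [
    "DosageAssignment",
    "activity_weeks",
    "eligible",
    "analysis_window",
    "dosage_group",
    "total_hours",
    "assemble_long_table",
    "CohortBuilder",
]

ELIGIBILITY_HORIZON_WEEKS = 15
MIN_ACTIVE_WEEKS = 10
ANALYSIS_WEEKS = 10


@dataclass(frozen=True)
class DosageAssignment:
    patient_id: str
    domain_id: str | None  # None in per-patient mode
    median_days_per_week: float
    group: str

    def __post_init__(self) -> None:
        if self.group not in ("1", "2", "3", "4", "5+"):
            raise ValueError(f"invalid dosage group {self.group}")


def _rel_weeks(active_days: pd.Series | list, anchor=None) -> np.ndarray:
    """User-relative week index of each active day (7-day bins from the
    first active day, or from ``anchor`` if given)."""
    days = pd.to_datetime(pd.Series(list(active_days))).dt.normalize()
    if days.empty:
        raise ValueError("activity calendar must be nonempty")
    anchor = days.min() if anchor is None else pd.Timestamp(anchor)
    return ((days - anchor).dt.days // 7).to_numpy()


def activity_weeks(active_days, anchor=None) -> dict[int, int]:
    """Map user-relative week index -> number of distinct active days."""
    days = pd.to_datetime(pd.Series(list(active_days))).dt.normalize().drop_duplicates()
    weeks = _rel_weeks(days, anchor)
    out: dict[int, int] = {}
    for w in weeks:
        out[int(w)] = out.get(int(w), 0) + 1
    return out


def eligible(active_days, anchor=None) -> bool:
    """True iff >= 10 of the first 15 user-relative weeks have >= 1
    active day."""
    weeks = activity_weeks(active_days, anchor)
    n_active = sum(1 for w in weeks if 0 <= w < ELIGIBILITY_HORIZON_WEEKS)
    return n_active >= MIN_ACTIVE_WEEKS


def analysis_window(active_days, anchor=None, rule: str = "active") -> list[int]:
    """Ordered user-relative week indices forming the 10-week window.

    ``rule='active'`` (default): the first 10 active weeks among the
    first 15.  ``rule='truncate'``: calendar weeks 0..9 regardless of
    activity.  Raises on ineligible calendars.
    """
    if not eligible(active_days, anchor):
        raise ValueError("patient is not eligible: fewer than "
                         f"{MIN_ACTIVE_WEEKS} active weeks in the first "
                         f"{ELIGIBILITY_HORIZON_WEEKS}")
    if rule == "truncate":
        return list(range(ANALYSIS_WEEKS))
    if rule != "active":
        raise ValueError(f"unknown window rule {rule!r}")
    weeks = sorted(w for w in activity_weeks(active_days, anchor)
                   if 0 <= w < ELIGIBILITY_HORIZON_WEEKS)
    return weeks[:ANALYSIS_WEEKS]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def dosage_group(
    active_days,
    window: list[int],
    patient_id: str = "",
    domain_id: str | None = None,
    anchor=None,
) -> DosageAssignment | None:
    """Median active days/week over the window weeks, binned to 1..5+.

    ``active_days`` should already be restricted to the relevant domain
    when per-domain assignment is wanted.  Window weeks with no activity
    contribute count 0.  Returns None when the rounded median is < 1
    (the unit carries too little activity to assign a dosage group).
    """
    counts_by_week = activity_weeks(active_days, anchor)
    counts = [counts_by_week.get(w, 0) for w in window]
    med = float(np.median(counts))
    rounded = _round_half_up(med)
    if rounded < 1:
        return None
    group = "5+" if rounded >= 5 else str(rounded)
    return DosageAssignment(patient_id, domain_id, med, group)


def total_hours(events: pd.DataFrame) -> float:
    """Total practice hours (sum of minutes / 60) in the given events."""
    if (events["minutes"] < 0).any():
        raise ValueError("minutes must be nonnegative")
    return float(events["minutes"].sum() / 60.0)


def assemble_long_table(
    weekly: pd.DataFrame,
    assignments: pd.DataFrame,
    profiles: pd.DataFrame,
    hours: pd.DataFrame,
) -> pd.DataFrame:
    """Join weekly scores, dosage groups, exposure and demographics into
    the model-ready long table.

    ``assignments`` columns: patient_id, [domain_id,] group.
    ``hours`` columns: patient_id, domain_id, total_hours.
    Chronicity is acute iff months_post_stroke <= 6.  Units without a
    week-0 row are dropped (no baseline covariate can be formed); week-0
    rows themselves are retained in the outcome.
    """
    weekly = weekly.copy()
    # drop units lacking a week-0 score, then attach baseline
    has_w0 = weekly[weekly["week_index"] == 0][["patient_id", "domain_id"]]
    n_before = weekly[["patient_id", "domain_id"]].drop_duplicates().shape[0]
    weekly = weekly.merge(has_w0, on=["patient_id", "domain_id"])
    n_after = weekly[["patient_id", "domain_id"]].drop_duplicates().shape[0]
    if n_after == 0:
        raise ValueError("no patient x domain unit has a week-0 score")
    base = baseline_score(weekly).rename("baseline").reset_index()
    out = weekly.merge(base, on=["patient_id", "domain_id"])

    join_keys = ["patient_id", "domain_id"] if "domain_id" in assignments else ["patient_id"]
    n_units = out[["patient_id", "domain_id"]].drop_duplicates().shape[0]
    out = out.merge(assignments[join_keys + ["group"]], on=join_keys)
    n_with_group = out[["patient_id", "domain_id"]].drop_duplicates().shape[0]
    n_no_group = n_units - n_with_group  # units whose median activity rounded to 0
    out = out.merge(hours[["patient_id", "domain_id", "total_hours"]],
                    on=["patient_id", "domain_id"])
    out = out.merge(profiles[["patient_id", "age", "sex", "months_post_stroke"]],
                    on="patient_id")
    n_joined = out[["patient_id", "domain_id"]].drop_duplicates().shape[0]
    if n_joined < n_with_group:
        raise ValueError(
            f"key mismatch while assembling: {n_with_group - n_joined} of "
            f"{n_with_group} patient x domain units lack an hours or profile row")

    out["chronicity"] = np.where(out["months_post_stroke"] <= 6.0, "acute", "chronic")
    out = out.rename(columns={"week_index": "week"})
    cols = ["patient_id", "domain_id", "week", "score", "group",
            "total_hours", "baseline", "age", "sex", "chronicity"]
    out = out[cols].sort_values(["patient_id", "domain_id", "week"]).reset_index(drop=True)
    out.attrs["n_units_dropped_no_baseline"] = n_before - n_after
    out.attrs["n_units_dropped_no_dosage"] = n_no_group
    return out


class CohortBuilder(TransformerMixin, BaseEstimator):
    """End-to-end transformer: session logs -> model-ready long table.

    Applies eligibility, derives per-patient analysis windows, computes
    weekly scores, dosage groups and exposure, and assembles the long
    table.  ``dosage_unit`` is ``'patient-domain'`` (default: median app
    use counted within the scored domain) or ``'patient'`` (use in any
    domain); ``window_rule`` is ``'active'`` or ``'truncate'``.

    Parameters are sklearn-style; ``profiles`` (patient demographics) is
    passed at construction because transform receives only the session
    table.
    """

    def __init__(self, n_levels_by_domain: dict[str, int] | None = None,
                 profiles: pd.DataFrame | None = None,
                 dosage_unit: str = "patient-domain",
                 window_rule: str = "active"):
        self.n_levels_by_domain = n_levels_by_domain
        self.profiles = profiles
        self.dosage_unit = dosage_unit
        self.window_rule = window_rule

    def fit(self, X: pd.DataFrame, y=None) -> "CohortBuilder":
        if self.dosage_unit not in ("patient", "patient-domain"):
            raise ValueError(f"unknown dosage_unit {self.dosage_unit!r}")
        if self.n_levels_by_domain is None or self.profiles is None:
            raise ValueError("n_levels_by_domain and profiles must be provided")

        df = X.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        windows: dict[str, list[int]] = {}
        anchors: dict[str, pd.Timestamp] = {}
        n_ineligible = 0
        for pid, grp in df.groupby("patient_id"):
            days = grp["date"].drop_duplicates()
            if not eligible(days):
                n_ineligible += 1
                continue
            anchors[pid] = days.min()
            windows[pid] = analysis_window(days, rule=self.window_rule)
        if not windows:
            raise ValueError("no eligible patients (need >= "
                             f"{MIN_ACTIVE_WEEKS} active weeks in the first "
                             f"{ELIGIBILITY_HORIZON_WEEKS})")
        self.windows_ = windows
        self.anchors_ = anchors
        self.n_ineligible_ = n_ineligible
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df = df[df["patient_id"].isin(self.windows_)]

        weekly = weekly_scores(df, self.n_levels_by_domain, self.windows_)

        # dosage assignments
        assign_rows = []
        for pid, window in self.windows_.items():
            sub = df[df["patient_id"] == pid]
            anchor = self.anchors_[pid]
            if self.dosage_unit == "patient":
                a = dosage_group(sub["date"].drop_duplicates(), window, pid, None, anchor)
                if a is not None:
                    assign_rows.append((pid, a.median_days_per_week, a.group))
            else:
                for dom, dgrp in sub.groupby("domain_id"):
                    a = dosage_group(dgrp["date"].drop_duplicates(), window, pid, dom, anchor)
                    if a is not None:
                        assign_rows.append((pid, dom, a.median_days_per_week, a.group))
        if self.dosage_unit == "patient":
            assignments = pd.DataFrame(assign_rows,
                                       columns=["patient_id", "median_days_per_week", "group"])
        else:
            assignments = pd.DataFrame(
                assign_rows,
                columns=["patient_id", "domain_id", "median_days_per_week", "group"])

        # per patient x domain total hours inside the window
        hour_rows = []
        for (pid, dom), grp in df.groupby(["patient_id", "domain_id"]):
            window = set(self.windows_[pid])
            rel = ((grp["date"] - self.anchors_[pid]).dt.days // 7).astype(int)
            hour_rows.append((pid, dom, total_hours(grp[rel.isin(window)])))
        hours = pd.DataFrame(hour_rows, columns=["patient_id", "domain_id", "total_hours"])

        return assemble_long_table(weekly, assignments, self.profiles, hours)
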