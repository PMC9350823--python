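"""Adaptive-practice session simulator.

Emulates the mechanics of a self-managed therapy app: each skill domain
has a universal task progression order (ranks 1..L with increasing
difficulty); within a session the current working rank is practiced, and
an adaptive algorithm advances the patient one rank once accuracy reaches
90% or higher on two occasions at that rank, and demotes one rank (floor
at 1) when accuracy drops below 40% or when the patient stops improving.

Observed accuracy follows a two-parameter logistic item-response form:
the probability of a correct item is ``pi = logistic(kappa * (theta -
delta_r))`` where ``theta`` is the patient's latent ability on the
difficulty scale and ``delta_r`` the difficulty of rank ``r``; a session
scores ``Binomial(n_items, pi) / n_items``.  Ability grows by a constant
``learning_rate`` after every completed session.

All functions are deterministic given their seed; per-patient RNG streams
are derived from the root seed so cohorts are reproducible patient by
patient.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .reference import REFERENCE_DEMOGRAPHICS

__all__ = [
    "TaskCatalog",
    "PatientProfile",
    "SimConfig",
    "make_task_catalog",
    "simulate_patient",
    "simulate_cohort",
]

SESSION_COLUMNS = ["patient_id", "domain_id", "date", "task_rank", "accuracy", "minutes"]
PROFILE_COLUMNS = ["patient_id", "age", "sex", "months_post_stroke", "target_days_per_week"]

_EPOCH = _dt.date(2017, 1, 2)  # arbitrary Monday anchoring simulated calendars


@dataclass(frozen=True)
class TaskCatalog:
    """Progression order of one skill domain: ranks 1..L with strictly
    increasing difficulty ``difficulties[r-1]``."""

    domain_id: str
    difficulties: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.difficulties) < 2:
            raise ValueError("a task catalog needs at least 2 levels")
        d = np.asarray(self.difficulties, dtype=float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("difficulties must be strictly increasing in rank")

    @property
    def n_levels(self) -> int:
        return len(self.difficulties)

    def difficulty(self, rank: int) -> float:
        if not 1 <= rank <= self.n_levels:
            raise ValueError(f"rank {rank} outside 1..{self.n_levels}")
        return self.difficulties[rank - 1]


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    age: float
    sex: str
    months_post_stroke: float
    ability: float
    learning_rate: float
    target_days_per_week: int

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 1 <= self.target_days_per_week <= 7:
            raise ValueError("target_days_per_week must lie in 1..7")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    ``target_frequencies`` lists the days-per-week targets, one dosage
    group per entry; ``n_patients_per_group`` patients are generated for
    each.  ``n_weeks`` is the number of simulated calendar weeks (10
    analysis weeks plus slack by default).  ``kappa`` and ``n_items``
    parameterize the accuracy model; ``n_items=None`` switches to
    noise-free accuracies (``pi`` used directly).
    """

    n_patients_per_group: int = 10
    n_domains: int = 3
    n_weeks: int = 12
    target_frequencies: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_levels: int = 20
    difficulty_step: float = 0.5
    kappa: float = 1.5
    n_items: int | None = 20
    ability_mean: float = 3.0
    ability_sd: float = 1.5
    learning_rate_mean: float = 0.06
    learning_rate_sd: float = 0.03
    minutes_mean: float = 20.0
    minutes_sd: float = 5.0
    demotion_window: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients_per_group, self.n_domains, self.n_weeks) < 1:
            raise ValueError("counts must be >= 1")
        if any(not 1 <= f <= 7 for f in self.target_frequencies):
            raise ValueError("target frequencies must lie in 1..7")


def make_task_catalog(n_domains: int, n_levels: int, difficulty_step: float) -> list[TaskCatalog]:
    """Build ``n_domains`` catalogs with ranks 1..n_levels and linearly
    spaced difficulties ``delta_r = r * difficulty_step``."""
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if difficulty_step <= 0:
        raise ValueError("difficulty_step must be > 0")
    deltas = tuple(r * difficulty_step for r in range(1, n_levels + 1))
    return [TaskCatalog(f"domain_{i + 1:02d}", deltas) for i in range(n_domains)]


def _active_days(rng: np.random.Generator, n_weeks: int, days_per_week: int) -> list[int]:
    """Day offsets (from day 0) of active days: ``days_per_week`` distinct
    days drawn uniformly within each 7-day week."""
    out: list[int] = []
    for w in range(n_weeks):
        days = rng.choice(7, size=days_per_week, replace=False)
        out.extend(7 * w + int(d) for d in sorted(days))
    return out


def simulate_patient(
    profile: PatientProfile,
    catalog: TaskCatalog,
    n_weeks: int,
    rng_seed: int | np.random.Generator,
    *,
    kappa: float = 1.5,
    n_items: int | None = 20,
    demotion_window: int = 3,
    minutes_mean: float = 20.0,
    minutes_sd: float = 5.0,
    start_date: _dt.date = _EPOCH,
) -> pd.DataFrame:
    """Simulate one patient's sessions in one domain.

    One session (one practiced rank) is emitted per active day.  Rank
    dynamics: advance after 2 sessions with accuracy >= 0.90 at the
    current rank; demote (floor 1) on accuracy < 0.40 or after
    ``demotion_window`` consecutive sessions without an accuracy
    increase.  Counters reset whenever the rank changes.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    days = _active_days(rng, n_weeks, profile.target_days_per_week)
    return _run_sessions(
        profile, catalog, days, rng,
        kappa=kappa, n_items=n_items, demotion_window=demotion_window,
        minutes_mean=minutes_mean, minutes_sd=minutes_sd, start_date=start_date,
    )


def _run_sessions(
    profile: PatientProfile,
    catalog: TaskCatalog,
    days: list[int],
    rng: np.random.Generator,
    *,
    kappa: float,
    n_items: int | None,
    demotion_window: int,
    minutes_mean: float,
    minutes_sd: float,
    start_date: _dt.date = _EPOCH,
) -> pd.DataFrame:
    theta = profile.ability
    rank = 1
    pass_count = 0
    stall_count = 0
    prev_acc: float | None = None
    rows = []
    for day in days:
        pi = float(expit(kappa * (theta - catalog.difficulty(rank))))
        acc = pi if n_items is None else rng.binomial(n_items, pi) / n_items
        minutes = max(1.0, rng.normal(minutes_mean, minutes_sd))
        rows.append((
            profile.patient_id,
            catalog.domain_id,
            (start_date + _dt.timedelta(days=day)).isoformat(),
            rank,
            acc,
            minutes,
        ))

        # adaptive difficulty update
        if acc >= 0.90:
            pass_count += 1
        stall_count = stall_count + 1 if (prev_acc is not None and acc <= prev_acc) else 0
        prev_acc = acc
        if pass_count >= 2:
            rank = min(rank + 1, catalog.n_levels)
            pass_count = stall_count = 0
            prev_acc = None
        elif acc < 0.40 or stall_count >= demotion_window:
            rank = max(rank - 1, 1)
            pass_count = stall_count = 0
            prev_acc = None
        theta += profile.learning_rate

    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def _sample_profiles(config: SimConfig, rng: np.random.Generator) -> list[PatientProfile]:
    demo = REFERENCE_DEMOGRAPHICS
    sexes = list(demo["sex_probs"])  # type: ignore[index]
    sex_p = np.array(list(demo["sex_probs"].values()))  # type: ignore[union-attr]
    sex_p = sex_p / sex_p.sum()
    profiles = []
    pid = 0
    for freq in config.target_frequencies:
        for _ in range(config.n_patients_per_group):
            pid += 1
            age = float(np.clip(rng.normal(demo["age_mean"], demo["age_sd"]), 20, 95))
            sex = str(rng.choice(sexes, p=sex_p))
            if rng.random() < demo["p_acute"]:
                months = float(rng.uniform(0.5, 6.0))
            else:
                months = float(rng.uniform(6.5, 60.0))
            profiles.append(PatientProfile(
                patient_id=f"p{pid:04d}",
                age=age,
                sex=sex,
                months_post_stroke=months,
                ability=float(rng.normal(config.ability_mean, config.ability_sd)),
                learning_rate=float(max(0.0, rng.normal(
                    config.learning_rate_mean, config.learning_rate_sd))),
                target_days_per_week=int(freq),
            ))
    return profiles


def simulate_cohort(
    config: SimConfig,
    catalogs: list[TaskCatalog] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: every patient practices every domain on
    the same active days (one session per domain per active day).

    Returns ``(sessions, profiles)`` data frames using the on-disk CSV
    schemas.  Per-patient RNG streams are spawned deterministically from
    ``config.rng_seed``, so the cohort is reproducible bit-for-bit.
    """
    if catalogs is None:
        catalogs = make_task_catalog(config.n_domains, config.n_levels, config.difficulty_step)
    if not catalogs:
        raise ValueError("catalogs must be nonempty")

    root = np.random.SeedSequence(config.rng_seed)
    profiles = _sample_profiles(config, np.random.default_rng(root.spawn(1)[0]))

    frames = []
    for idx, profile in enumerate(profiles):
        prng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(idx + 1,)))
        # one shared activity calendar per patient, then one rng stream
        # per domain so domains are independent but reproducible
        days = _active_days(prng, config.n_weeks, profile.target_days_per_week)
        for d, catalog in enumerate(catalogs):
            drng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(idx + 1, d + 1)))
            frames.append(_run_sessions(
                profile, catalog, days, drng,
                kappa=config.kappa, n_items=config.n_items,
                demotion_window=config.demotion_window,
                minutes_mean=config.minutes_mean, minutes_sd=config.minutes_sd,
            ))
    sessions = pd.concat(frames, ignore_index=True)
    prof_df = pd.DataFrame(
        [(p.patient_id, p.age, p.sex, p.months_post_stroke, p.target_days_per_week)
         for p in profiles],
        columns=PROFILE_COLUMNS,
    )
    return sessions, prof_df
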