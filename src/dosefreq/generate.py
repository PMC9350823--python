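"""Direct generator for weekly-score panels with known mixed-model structure.

Whereas :mod:`dosefreq.simulate` produces raw session logs mechanistically,
this module draws the analysis-ready long table straight from the linear
mixed model the inference layer fits:

    score = X beta + u0_p + u1_p * week + v0_d + v1_d * week + eps

with correlated bivariate-normal patient effects (u0, u1), correlated
domain effects (v0, v1) crossed with patients, and Gaussian residuals.
It is the ground-truth source for parameter-recovery and calibration
studies: the generating ``beta`` and variance components are known
exactly.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .reference import (
    GROUP_LEVELS,
    REFERENCE_DEMOGRAPHICS,
    REFERENCE_FIXED_EFFECTS,
    REFERENCE_VARCOMPS,
    TERM_ORDER,
    VarianceComponents,
)

__all__ = ["generate_lmm_dataset"]


def _beta_vector(beta: dict[str, float] | Sequence[float] | None) -> np.ndarray:
    if beta is None:
        beta = REFERENCE_FIXED_EFFECTS
    if isinstance(beta, dict):
        missing = set(TERM_ORDER) - set(beta)
        if missing:
            raise ValueError(f"beta missing terms: {sorted(missing)}")
        return np.array([beta[t] for t in TERM_ORDER], dtype=float)
    arr = np.asarray(beta, dtype=float)
    if arr.shape != (len(TERM_ORDER),):
        raise ValueError(
            f"beta must have {len(TERM_ORDER)} entries in canonical term order, "
            f"got shape {arr.shape}")
    return arr


def _bivariate(rng: np.random.Generator, n: int, var0: float, var1: float,
               corr: float) -> np.ndarray:
    if var0 == 0.0 and var1 == 0.0:
        return np.zeros((n, 2))
    cov01 = corr * np.sqrt(var0 * var1)
    cov = np.array([[var0, cov01], [cov01, var1]])
    # svd method: tolerates positive-semidefinite covariances
    return rng.multivariate_normal([0.0, 0.0], cov, size=n)


def generate_lmm_dataset(
    beta: dict[str, float] | Sequence[float] | None = None,
    varcomps: VarianceComponents | None = None,
    group_sizes: Sequence[int] = (10, 10, 10, 10, 10),
    n_domains: int = 3,
    n_weeks: int = 10,
    rng_seed: int = 0,
    *,
    clip_scores: bool = False,
) -> pd.DataFrame:
    """Draw a balanced long table of weekly scores from the mixed model.

    Parameters
    ----------
    beta
        Fixed effects, either a dict keyed by :data:`TERM_ORDER` names or a
        vector in that order.  Defaults to the reference estimates.
    varcomps
        Generating variance components; defaults to the reference values.
        Set all components to zero to obtain the noiseless linear predictor.
    group_sizes
        Patients per dosage group ``1, 2, 3, 4, 5+`` (in that order).
    clip_scores
        If True, clip scores into [0, 1]; off by default so the generative
        model stays exactly linear-Gaussian.

    Returns
    -------
    DataFrame with columns ``patient_id, domain_id, week, score, group,
    total_hours, baseline, age, sex, chronicity`` — one row per patient x
    domain x week (balanced panel).
    """
    if len(group_sizes) != len(GROUP_LEVELS):
        raise ValueError(f"group_sizes must have {len(GROUP_LEVELS)} entries")
    if n_domains < 1 or n_weeks < 1:
        raise ValueError("n_domains and n_weeks must be >= 1")
    b = _beta_vector(beta)
    vc = REFERENCE_VARCOMPS if varcomps is None else varcomps
    demo = REFERENCE_DEMOGRAPHICS
    rng = np.random.default_rng(rng_seed)

    n_patients = int(sum(group_sizes))
    u = _bivariate(rng, n_patients, vc.patient_intercept_var,
                   vc.patient_slope_var, vc.patient_corr)
    dv0 = vc.domain_intercept_var or 0.0
    dv1 = vc.domain_slope_var or 0.0
    v = _bivariate(rng, n_domains, dv0, dv1, vc.domain_corr or 0.0)

    sexes = list(demo["sex_probs"])
    sex_p = np.array(list(demo["sex_probs"].values()))
    sex_p = sex_p / sex_p.sum()
    hours_mean = demo["hours_mean_by_group"]

    weeks = np.arange(n_weeks, dtype=float)
    rows: list[dict] = []
    pid = 0
    for g_idx, (group, size) in enumerate(zip(GROUP_LEVELS, group_sizes)):
        for _ in range(size):
            pid += 1
            age = float(np.clip(rng.normal(demo["age_mean"], demo["age_sd"]), 20, 95))
            sex = str(rng.choice(sexes, p=sex_p))
            chron = "acute" if rng.random() < demo["p_acute"] else "chronic"
            hours = float(rng.gamma(2.0, hours_mean[g_idx] / 2.0))
            for d in range(n_domains):
                baseline = float(np.clip(rng.normal(
                    demo["baseline_mean"], demo["baseline_sd"]), 0.0, 1.0))
                x = np.zeros(len(TERM_ORDER))
                x[TERM_ORDER.index("Intercept")] = 1.0
                if group != "1":
                    x[TERM_ORDER.index(f"group[{group}]")] = 1.0
                x[TERM_ORDER.index("total_hours")] = hours
                x[TERM_ORDER.index("baseline")] = baseline
                x[TERM_ORDER.index("age")] = age
                if sex != "female":
                    x[TERM_ORDER.index(f"sex[{sex}]")] = 1.0
                if chron == "acute":
                    x[TERM_ORDER.index("chronicity[acute]")] = 1.0
                # week-dependent part assembled vectorized below
                base_pred = float(x @ b)
                slope = b[TERM_ORDER.index("week")] + b[TERM_ORDER.index("week:total_hours")] * hours
                if group != "1":
                    slope += b[TERM_ORDER.index(f"week:group[{group}]")]
                eps = (np.zeros(n_weeks) if vc.residual_var == 0
                       else rng.normal(0.0, np.sqrt(vc.residual_var), n_weeks))
                score = (base_pred + slope * weeks
                         + u[pid - 1, 0] + u[pid - 1, 1] * weeks
                         + v[d, 0] + v[d, 1] * weeks + eps)
                if clip_scores:
                    score = np.clip(score, 0.0, 1.0)
                for w in range(n_weeks):
                    rows.append(dict(
                        patient_id=f"p{pid:04d}", domain_id=f"domain_{d + 1:02d}",
                        week=w, score=float(score[w]), group=group,
                        total_hours=hours, baseline=baseline, age=age,
                        sex=sex, chronicity=chron,
                    ))
    return pd.DataFrame(rows)
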