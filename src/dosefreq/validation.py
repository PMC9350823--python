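"""Simulation studies validating the inference layer.

Two standard checks for a mixed-model pipeline:

* **Parameter recovery** — generate weekly-score panels from known fixed
  effects and variance components, refit, and measure (a) coverage of
  95% Wald intervals for the week x dosage-group interactions and (b)
  how often the estimated group slopes come out in increasing dose
  order.
* **Likelihood-ratio calibration** — generate data in which one
  coefficient (the week x total-hours interaction) is exactly zero, test
  it with a 1-df ML likelihood-ratio test, and measure the type-I error
  at alpha = 0.05.

Both return plain dicts so they can feed tests and reports alike.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .generate import generate_lmm_dataset
from .lmm import ModelSpec, compare_models, fit_lmm
from .reference import REFERENCE_FIXED_EFFECTS, REFERENCE_VARCOMPS

__all__ = ["recovery_study", "lrt_calibration_study"]

INTERACTION_TERMS = ("week:group[2]", "week:group[3]", "week:group[4]",
                     "week:group[5+]")


def recovery_study(
    n_replicates: int = 50,
    patients_per_group: int = 40,
    n_domains: int = 3,
    n_weeks: int = 10,
    rng_seed: int = 0,
) -> dict:
    """Coverage and slope-ordering rates under the reference generating
    values.

    Returns per-term 95% CI coverage of the four week x group
    interactions, the fraction of replicates with estimated group slopes
    nondecreasing across groups 1..4, and the per-replicate estimates.
    """
    truth = {t: REFERENCE_FIXED_EFFECTS[t] for t in INTERACTION_TERMS}
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates)
    cover = {t: 0 for t in INTERACTION_TERMS}
    ordered = 0
    n_converged = 0
    estimates = []
    for seed in seeds:
        table = generate_lmm_dataset(
            group_sizes=(patients_per_group,) * 5,
            n_domains=n_domains, n_weeks=n_weeks, rng_seed=int(seed) % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(table, ModelSpec(method="reml"))
        n_converged += fit.converged
        est = fit.beta[list(INTERACTION_TERMS)]
        se = pd.Series(np.sqrt(np.diag(fit.vcov.loc[list(INTERACTION_TERMS),
                                                    list(INTERACTION_TERMS)])),
                       index=INTERACTION_TERMS)
        for t in INTERACTION_TERMS:
            if abs(est[t] - truth[t]) <= 1.96 * se[t]:
                cover[t] += 1
        # group slopes relative to group 1: 0 <= w2 <= w3 <= w4
        w = [0.0] + [est[t] for t in INTERACTION_TERMS[:3]]
        ordered += all(a <= b for a, b in zip(w, w[1:]))
        estimates.append(est.to_dict())
    return {
        "n_replicates": n_replicates,
        "coverage": {t: cover[t] / n_replicates for t in INTERACTION_TERMS},
        # pooled rate over all (replicate, interaction) intervals — the
        # standard simulation-study coverage summary
        "pooled_coverage": sum(cover.values()) / (n_replicates * len(INTERACTION_TERMS)),
        "min_coverage": min(cover.values()) / n_replicates,
        "slope_ordering_rate": ordered / n_replicates,
        "n_converged": n_converged,
        "estimates": estimates,
    }


def lrt_calibration_study(
    n_replicates: int = 500,
    patients_per_group: int = 8,
    n_domains: int = 1,
    n_weeks: int = 10,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> dict:
    """Type-I error of the 1-df ML likelihood-ratio test under a true
    null.

    Data are generated with the week x total-hours coefficient set to
    exactly zero; each replicate fits the model with and without that
    term by ML and records whether the LRT rejects at ``alpha``.
    """
    beta = dict(REFERENCE_FIXED_EFFECTS)
    beta["week:total_hours"] = 0.0
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates)
    rejections = 0
    n_degenerate = 0
    lrts = []
    for seed in seeds:
        table = generate_lmm_dataset(
            beta=beta, group_sizes=(patients_per_group,) * 5,
            n_domains=n_domains, n_weeks=n_weeks, rng_seed=int(seed) % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_fit = fit_lmm(table, ModelSpec(method="ml",
                                                include_hours_interaction=False))
            alt_fit = fit_lmm(table, ModelSpec(method="ml"))
        res = compare_models(null_fit, alt_fit)
        if not np.isfinite(res["lrt"]):
            n_degenerate += 1  # counted as a non-rejection
            continue
        lrts.append(res["lrt"])
        rejections += res["p"] < alpha
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "type_i_error": rejections / n_replicates,
        "mean_lrt": float(np.mean(lrts)) if lrts else float("nan"),
        "frac_negative_lrt": float(np.mean(np.array(lrts) < -1e-6)) if lrts else 0.0,
        "n_degenerate": n_degenerate,
    }
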