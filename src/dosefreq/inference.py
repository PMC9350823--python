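"""Post-hoc inference: slope contrasts, estimated marginal means, Tukey
adjustment and standardized treatment effect sizes.

All quantities are linear functions of the fixed-effect vector, so they
can be computed either from a full fit (estimates + SEs + adjusted p) or
from a published coefficient vector alone (estimates only).  Degrees of
freedom are asymptotic: t ratios are treated as standard normal and the
Tukey adjustment uses the studentized range distribution in its
normal-limit form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LmmFit
from .reference import GROUP_LEVELS

__all__ = [
    "ContrastResult",
    "EffectSize",
    "tukey_p",
    "slope_contrasts",
    "emm_at_week",
    "emm_contrasts",
    "treatment_effect_size",
]


@dataclass(frozen=True)
class ContrastResult:
    """A linear combination of fixed effects with Tukey-adjusted p."""

    label: str
    weights: pd.Series
    estimate: float
    se: float | None
    t_ratio: float | None
    df: float
    p_adjusted: float | None

    def __post_init__(self) -> None:
        if self.p_adjusted is not None and not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("adjusted p must lie in [0, 1]")


@dataclass(frozen=True)
class EffectSize:
    group: str
    emm_week0: float
    emm_week9: float
    sigma_standardizer: float
    d: float


def tukey_p(t_ratio: float, k: int, df: float = np.inf) -> float:
    """Tukey-adjusted p for one of a family of ``k`` estimates.

    The adjusted p is the upper-tail probability of the studentized range
    distribution (k groups, ``df`` error degrees of freedom, ``np.inf``
    for the normal limit) evaluated at ``|t| * sqrt(2)``.
    """
    if k < 2:
        raise ValueError("family size k must be >= 2")
    q = abs(float(t_ratio)) * np.sqrt(2.0)
    if q == 0.0:
        return 1.0
    p = float(stats.studentized_range.sf(q, k, df))
    return float(min(max(p, 0.0), 1.0))


def _group_slope_weights(terms: pd.Index, group: str) -> pd.Series:
    """Weights extracting group ``g``'s weekly slope relative to the
    shared week effect: beta_week + beta_{week x g} (reference group has
    no interaction term)."""
    w = pd.Series(0.0, index=terms)
    w["week"] = 1.0
    if group != GROUP_LEVELS[0]:
        term = f"week:group[{group}]"
        if term not in terms:
            raise ValueError(f"fit lacks interaction term {term}")
        w[term] = 1.0
    return w


def _contrast(fit: LmmFit, weights: pd.Series, label: str, k_family: int) -> ContrastResult:
    est = float(weights @ fit.beta.reindex(weights.index).fillna(0.0))
    se = t = p = None
    if fit.vcov is not None:
        v = fit.vcov.reindex(index=weights.index, columns=weights.index).fillna(0.0)
        se = float(np.sqrt(weights @ v.to_numpy() @ weights))
        if se > 0:
            t = est / se
            p = tukey_p(t, k_family)
    return ContrastResult(label, weights, est, se, t, np.inf, p)


def slope_contrasts(fit: LmmFit, groups: tuple[str, ...] = GROUP_LEVELS) -> pd.DataFrame:
    """All pairwise slope differences between dosage groups.

    The contrast ``g vs h`` (g listed before h) estimates
    ``slope_g - slope_h``; with the lower-frequency group listed first
    and slopes increasing in dose, estimates are negative.  P values are
    Tukey-adjusted for the family of ``len(groups)`` slopes.
    """
    missing = [t for t in ("week",) if t not in fit.beta.index]
    if missing:
        raise ValueError(f"fit lacks terms {missing}")
    results = []
    for g, h in combinations(groups, 2):
        w = _group_slope_weights(fit.beta.index, g) - _group_slope_weights(fit.beta.index, h)
        results.append(_contrast(fit, w, f"{g} vs {h}", len(groups)))
    return pd.DataFrame(
        [(r.label, r.estimate, r.se, r.t_ratio, r.df, r.p_adjusted) for r in results],
        columns=["contrast", "estimate", "se", "t_ratio", "df", "p_adjusted"],
    )


def _emm_row(fit: LmmFit, group: str, week: float) -> pd.Series:
    """Reference-grid design row for one group at one week: categorical
    covariates equally weighted over levels, continuous covariates at
    their sample means."""
    terms = fit.beta.index
    x = pd.Series(0.0, index=terms)
    means = fit.covariate_means
    if "Intercept" in terms:
        x["Intercept"] = 1.0
    x["week"] = week
    if group != GROUP_LEVELS[0]:
        gterm = f"group[{group}]"
        if gterm not in terms:
            raise ValueError(f"fit lacks term {gterm}")
        x[gterm] = 1.0
        iterm = f"week:group[{group}]"
        if iterm in terms:
            x[iterm] = week
    for name in ("total_hours", "baseline", "age"):
        if name in terms:
            x[name] = means.get(name, 0.0)
    if "week:total_hours" in terms:
        x["week:total_hours"] = week * means.get("total_hours", 0.0)
    # equal weights over the observed levels of each categorical covariate
    sex_terms = [t for t in terms if t.startswith("sex[")]
    for t in sex_terms:
        x[t] = 1.0 / (len(sex_terms) + 1)  # +1 for the reference level
    if "chronicity[acute]" in terms:
        x["chronicity[acute]"] = 0.5
    return x


def emm_at_week(fit: LmmFit, week: float,
                groups: tuple[str, ...] = GROUP_LEVELS) -> pd.DataFrame:
    """Estimated marginal mean score per dosage group at ``week``.

    Emits a warning (not an error) when extrapolating outside weeks 0..9.
    """
    if not 0 <= week <= 9:
        import warnings
        warnings.warn(f"week {week} lies outside the fitted range 0..9; "
                      "EMMs are extrapolations")
    rows = []
    for g in groups:
        x = _emm_row(fit, g, week)
        est = float(x @ fit.beta)
        se = None
        if fit.vcov is not None:
            se = float(np.sqrt(x @ fit.vcov.to_numpy() @ x))
        rows.append((g, week, est, se))
    return pd.DataFrame(rows, columns=["group", "week", "emm", "se"])


def emm_contrasts(fit: LmmFit, week: float,
                  groups: tuple[str, ...] = GROUP_LEVELS) -> pd.DataFrame:
    """Pairwise EMM differences between dosage groups at ``week`` with
    Tukey-adjusted p values (family of ``len(groups)`` means).

    The difference ``g vs h`` equals ``EMM_g - EMM_h``; continuous and
    equally-weighted categorical covariates cancel, leaving the group
    main effect plus ``week x`` interaction difference.
    """
    results = []
    for g, h in combinations(groups, 2):
        w = _emm_row(fit, g, week) - _emm_row(fit, h, week)
        results.append(_contrast(fit, w, f"{g} vs {h}", len(groups)))
    return pd.DataFrame(
        [(r.label, week, r.estimate, r.se, r.t_ratio, r.df, r.p_adjusted) for r in results],
        columns=["contrast", "week", "estimate", "se", "t_ratio", "df", "p_adjusted"],
    )


def treatment_effect_size(fit: LmmFit, sigma_mode: str = "residual",
                          groups: tuple[str, ...] = GROUP_LEVELS) -> pd.DataFrame:
    """Standardized pre/post effect size per dosage group.

    ``d_g = (EMM_g(week 9) - EMM_g(week 0)) / sigma`` where sigma is the
    residual SD (default) or the square root of the summed variance
    components (``sigma_mode='total'``).
    """
    if sigma_mode not in ("residual", "total"):
        raise ValueError("sigma_mode must be 'residual' or 'total'")
    if fit.varcomps is None:
        raise ValueError("fit carries no variance components")
    var = (fit.varcomps.residual_var if sigma_mode == "residual"
           else fit.varcomps.total_var)
    sigma = float(np.sqrt(var))
    if sigma == 0.0:
        raise ValueError("standardizer sigma is zero")
    e0 = emm_at_week(fit, 0, groups).set_index("group")["emm"]
    e9 = emm_at_week(fit, 9, groups).set_index("group")["emm"]
    rows = [EffectSize(g, float(e0[g]), float(e9[g]), sigma,
                       float((e9[g] - e0[g]) / sigma)) for g in groups]
    return pd.DataFrame(
        [(r.group, r.emm_week0, r.emm_week9, r.sigma_standardizer, r.d) for r in rows],
        columns=["group", "emm_week0", "emm_week9", "sigma", "d"],
    )
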