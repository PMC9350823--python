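"""Linear mixed-effects fitting for the dose-response model.

Model (pooled over domains):

    score ~ week * (group + total_hours) + baseline + age + sex
            + chronicity + random intercept & slope per patient

with reference levels group "1", sex "female", chronicity "chronic", so
the fixed-effect vector aligns with the canonical term order in
:data:`dosefreq.reference.TERM_ORDER`.  Patient random intercepts and
week slopes are correlated.  The study design also carries domain-level
random intercepts/slopes crossed with patients; this engine retains the
dominant patient components and absorbs domain-level variation into the
residual — group allocation is balanced across domains, so domain random
effects cancel exactly in every week x group contrast (per-domain fits
exclude the domain term by design, matching the estimand there exactly).

REML is used for reported fits, ML for likelihood-ratio tests on fixed
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM

from .reference import (
    CHRONICITY_LEVELS,
    GROUP_LEVELS,
    SEX_LEVELS,
    TERM_ORDER,
    VarianceComponents,
)

__all__ = [
    "ModelSpec",
    "LmmFit",
    "design_matrix",
    "fit_lmm",
    "compare_models",
    "DoseResponseLMM",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed- and random-effects specification.

    ``include_group_interaction=False`` drops the week x group terms (the
    null model of the dosage-effect LRT).  ``per_domain=True`` marks a
    single-domain fit (no domain-level variation to absorb).
    """

    method: str = "reml"  # 'reml' or 'ml'
    include_group_interaction: bool = True
    include_hours_interaction: bool = True
    per_domain: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")

    @property
    def terms(self) -> tuple[str, ...]:
        terms = TERM_ORDER
        if not self.include_group_interaction:
            terms = tuple(t for t in terms if not t.startswith("week:group"))
        if not self.include_hours_interaction:
            terms = tuple(t for t in terms if t != "week:total_hours")
        return terms


@dataclass
class LmmFit:
    """Fitted (or externally supplied) fixed-effect vector with inference
    metadata.

    ``beta`` is indexed by canonical term names.  ``vcov`` may be None
    when the fit was constructed from published coefficients only (point
    arithmetic such as contrast estimates still works; SEs do not).
    ``covariate_means`` holds the reference-grid means of the continuous
    covariates (age, total_hours, baseline) used for estimated marginal
    means.
    """

    beta: pd.Series
    vcov: pd.DataFrame | None = None
    varcomps: VarianceComponents | None = None
    loglik: float | None = None
    n_obs: int | None = None
    n_params: int | None = None
    converged: bool = True
    method: str = "reml"
    covariate_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vcov is not None:
            v = self.vcov.to_numpy()
            scale = max(float(np.abs(v).max()), 1e-300)
            if not np.allclose(v, v.T, atol=1e-8 * scale):
                raise ValueError("vcov must be symmetric")

    @classmethod
    def from_coefficients(
        cls,
        beta: dict[str, float] | pd.Series,
        vcov: pd.DataFrame | None = None,
        covariate_means: dict[str, float] | None = None,
    ) -> "LmmFit":
        """Build a fit object from a published coefficient vector."""
        s = pd.Series(beta, dtype=float)
        return cls(beta=s, vcov=vcov, covariate_means=covariate_means or {})


def design_matrix(table: pd.DataFrame, terms: tuple[str, ...] = TERM_ORDER) -> pd.DataFrame:
    """Fixed-effects design matrix in canonical term order.

    Treatment coding with references group "1", sex "female", chronicity
    "chronic"; interactions are elementwise products with week.
    """
    bad_groups = set(table["group"].astype(str)) - set(GROUP_LEVELS)
    if bad_groups:
        raise ValueError(f"unknown dosage groups: {sorted(bad_groups)}")
    bad_sex = set(table["sex"]) - set(SEX_LEVELS)
    if bad_sex:
        raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
    bad_chron = set(table["chronicity"]) - set(CHRONICITY_LEVELS)
    if bad_chron:
        raise ValueError(f"unknown chronicity levels: {sorted(bad_chron)}")

    week = table["week"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {
        "Intercept": np.ones(len(table)),
        "week": week,
    }
    grp = table["group"].astype(str)
    for g in GROUP_LEVELS[1:]:
        cols[f"group[{g}]"] = (grp == g).to_numpy(dtype=float)
    cols["total_hours"] = table["total_hours"].to_numpy(dtype=float)
    cols["baseline"] = table["baseline"].to_numpy(dtype=float)
    cols["age"] = table["age"].to_numpy(dtype=float)
    for s in SEX_LEVELS[1:]:
        cols[f"sex[{s}]"] = (table["sex"] == s).to_numpy(dtype=float)
    cols["chronicity[acute]"] = (table["chronicity"] == "acute").to_numpy(dtype=float)
    for g in GROUP_LEVELS[1:]:
        cols[f"week:group[{g}]"] = week * cols[f"group[{g}]"]
    cols["week:total_hours"] = week * cols["total_hours"]
    X = pd.DataFrame({t: cols[t] for t in terms}, index=table.index)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # identify offending columns by greedy elimination
        keep: list[int] = []
        bad: list[str] = []
        for j in range(X.shape[1]):
            cand = keep + [j]
            if np.linalg.matrix_rank(arr[:, cand]) == len(cand):
                keep.append(j)
            else:
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_lmm(table: pd.DataFrame, spec: ModelSpec | None = None) -> LmmFit:
    """Fit the dose-response mixed model; see module docstring.

    Requires >= 2 dosage groups in the data.  Non-convergence returns a
    fit flagged ``converged=False`` with a warning rather than raising.
    """
    spec = spec or ModelSpec()
    if table.empty:
        raise ValueError("table is empty")
    if table["group"].nunique() < 2:
        raise ValueError("need >= 2 dosage groups to fit the model")

    terms = spec.terms
    X = design_matrix(table, terms)
    # drop factor-level columns that are all zero (level absent from data)
    absent = [c for c in X.columns
              if c != "Intercept" and not np.any(X[c].to_numpy())]
    X = X.drop(columns=absent)
    _check_rank(X)

    y = table["score"].to_numpy(dtype=float)
    groups = table["patient_id"].to_numpy()
    exog_re = X[["Intercept", "week"]]

    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    reml = spec.method == "reml"
    # The profiled (RE)ML surface often has a ridge near the variance
    # boundary: gradient methods are fast but can stall there, while
    # Powell is slower but reliable.  REML point estimates are
    # insensitive to the residual stall, so lbfgs leads; ML log
    # likelihoods feed LRTs and need the robust path plus a warm-started
    # gradient polish.
    order = ("lbfgs", "powell", "cg") if reml else ("powell", "lbfgs", "cg")
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in order:
            try:
                candidate = model.fit(reml=reml, method=method, maxiter=500)
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(candidate.llf):
                result = candidate
                break
        if result is not None and not reml:
            try:
                polished = model.fit(reml=False, method="lbfgs",
                                     start_params=result.params_object,
                                     maxiter=200)
                if np.isfinite(polished.llf) and polished.llf >= result.llf:
                    result = polished
            except np.linalg.LinAlgError:
                pass
    if result is None:
        raise RuntimeError("all optimizers failed on this fit")
    if not result.converged:
        warnings.warn("mixed-model fit did not converge; interpret with care")

    cov_re = np.asarray(result.cov_re)
    sd_prod = np.sqrt(cov_re[0, 0] * cov_re[1, 1])
    corr = float(cov_re[0, 1] / sd_prod) if sd_prod > 0 else 0.0
    varcomps = VarianceComponents(
        residual_var=float(result.scale),
        patient_intercept_var=float(max(cov_re[0, 0], 0.0)),
        patient_slope_var=float(max(cov_re[1, 1], 0.0)),
        patient_corr=float(np.clip(corr, -1.0, 1.0)),
    )
    k_fe = X.shape[1]
    beta = pd.Series(np.asarray(result.fe_params), index=list(X.columns))
    v = np.asarray(result.cov_params())[:k_fe, :k_fe]
    v = (v + v.T) / 2.0  # symmetrize away inverse-Hessian round-off
    vcov = pd.DataFrame(v, index=list(X.columns), columns=list(X.columns))
    means = {c: float(table[c].mean()) for c in ("age", "total_hours", "baseline")}
    return LmmFit(
        beta=beta,
        vcov=vcov,
        varcomps=varcomps,
        loglik=float(result.llf),
        n_obs=int(len(y)),
        n_params=int(k_fe + 3 + 1),  # fe + (2 var, 1 cov) + residual
        converged=bool(result.converged),
        method=spec.method,
        covariate_means=means,
    )


def compare_models(fit_a: LmmFit, fit_b: LmmFit) -> dict[str, float]:
    """Likelihood-ratio test of nested fits (``fit_b`` nests ``fit_a``),
    with AIC/BIC deltas.

    Both fits must be ML when fixed effects differ.  Returns a dict with
    ``lrt, df, p, delta_aic, delta_bic`` (deltas are B minus A).
    """
    terms_a, terms_b = set(fit_a.beta.index), set(fit_b.beta.index)
    if not terms_a <= terms_b:
        raise ValueError("models are not nested: A has terms absent from B")
    if terms_a != terms_b and not (fit_a.method == fit_b.method == "ml"):
        raise ValueError("fixed-effects comparison requires both fits by ML")
    for f in (fit_a, fit_b):
        if f.loglik is None or f.n_params is None or f.n_obs is None:
            raise ValueError("both fits need loglik, n_params and n_obs")

    lrt = 2.0 * (fit_b.loglik - fit_a.loglik)
    df = fit_b.n_params - fit_a.n_params
    if df < 0:
        raise ValueError("fit_b has fewer parameters than fit_a")
    p = 1.0 if df == 0 and abs(lrt) < 1e-10 else float(stats.chi2.sf(max(lrt, 0.0), max(df, 1)))
    aic = [-2.0 * f.loglik + 2.0 * f.n_params for f in (fit_a, fit_b)]
    bic = [-2.0 * f.loglik + f.n_params * np.log(f.n_obs) for f in (fit_a, fit_b)]
    return {
        "lrt": float(lrt),
        "df": int(df),
        "p": p,
        "delta_aic": float(aic[1] - aic[0]),
        "delta_bic": float(bic[1] - bic[0]),
    }


class DoseResponseLMM(BaseEstimator):
    """Scikit-learn style estimator for the dose-response mixed model.

    ``fit(X)`` takes the model-ready long table (as produced by
    :class:`dosefreq.cohort.CohortBuilder` or
    :func:`dosefreq.generate.generate_lmm_dataset`) and exposes

    - ``beta_`` / ``vcov_`` — fixed effects and their covariance,
    - ``varcomps_`` — residual and patient variance components,
    - ``fit_`` — an :class:`LmmFit` consumed by the inference helpers
      (slope contrasts, estimated marginal means, effect sizes).

    ``predict(X)`` returns the population-level (fixed-effects) linear
    predictor.
    """

    def __init__(self, method: str = "reml",
                 include_group_interaction: bool = True,
                 per_domain: bool = False):
        self.method = method
        self.include_group_interaction = include_group_interaction
        self.per_domain = per_domain

    def _spec(self) -> ModelSpec:
        return ModelSpec(method=self.method,
                         include_group_interaction=self.include_group_interaction,
                         per_domain=self.per_domain)

    def fit(self, X: pd.DataFrame, y=None) -> "DoseResponseLMM":
        fit = fit_lmm(X, self._spec())
        self.fit_ = fit
        self.beta_ = fit.beta
        self.vcov_ = fit.vcov
        self.varcomps_ = fit.varcomps
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_obs_ = fit.n_obs
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise ValueError("estimator is not fitted yet")
        Xd = design_matrix(X, tuple(self.beta_.index))
        return Xd.to_numpy() @ self.beta_.to_numpy()
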