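"""Reproducible end-to-end pipeline: simulate -> score -> prepare -> fit ->
report, with a manifest and publication-style output tables."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortBuilder
from .inference import emm_contrasts, slope_contrasts, treatment_effect_size
from .lmm import DoseResponseLMM
from .scoring import weekly_scores
from .simulate import SimConfig, make_task_catalog, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_tables"]

log = logging.getLogger("dosefreq")


@dataclass
class PipelineConfig:
    """Serializable configuration; a run is reproducible from config +
    seed alone."""

    seed: int = 0
    # simulator
    n_patients_per_group: int = 10
    n_domains: int = 3
    n_weeks: int = 12
    n_levels: int = 20
    # cohort
    dosage_unit: str = "patient-domain"
    window_rule: str = "active"
    # model
    per_domain: bool = False
    sigma_mode: str = "residual"
    alpha: float = 0.05
    verbosity: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def stage_simulate(config: PipelineConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    sim = SimConfig(
        n_patients_per_group=config.n_patients_per_group,
        n_domains=config.n_domains,
        n_weeks=config.n_weeks,
        n_levels=config.n_levels,
        rng_seed=config.seed,
    )
    sessions, profiles = simulate_cohort(sim)
    _write_csv(sessions, outdir / "sessions.csv")
    _write_csv(profiles, outdir / "profiles.csv")
    return sessions, profiles


def stage_prepare(config: PipelineConfig, sessions: pd.DataFrame,
                  profiles: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    catalogs = make_task_catalog(config.n_domains, config.n_levels, 0.5)
    levels = {c.domain_id: c.n_levels for c in catalogs}
    builder = CohortBuilder(
        n_levels_by_domain=levels, profiles=profiles,
        dosage_unit=config.dosage_unit, window_rule=config.window_rule)
    builder.fit(sessions)
    eligible_sessions = sessions[sessions["patient_id"].isin(builder.windows_)]
    weekly = weekly_scores(eligible_sessions, levels, builder.windows_)
    _write_csv(weekly, outdir / "weekly_scores.csv")
    table = builder.transform(sessions)
    _write_csv(table, outdir / "analysis_table.csv")
    return table


def stage_fit(config: PipelineConfig, table: pd.DataFrame, outdir: Path) -> dict:
    """Fit the pooled model (and per-domain models when requested) and
    write the report tables."""
    model = DoseResponseLMM(method="reml", per_domain=False)
    model.fit(table)
    fit = model.fit_

    fixed = pd.DataFrame({
        "term": fit.beta.index,
        "estimate": fit.beta.to_numpy(),
        "se": np.sqrt(np.diag(fit.vcov.to_numpy())),
    })
    fixed["t"] = fixed["estimate"] / fixed["se"]
    from scipy import stats as _st
    fixed["p"] = 2.0 * _st.norm.sf(np.abs(fixed["t"]))
    _write_csv(fixed, outdir / "fixed_effects.csv")

    vc = fit.varcomps
    _write_csv(pd.DataFrame([
        ("residual", vc.residual_var, np.sqrt(vc.residual_var), np.nan),
        ("patient_intercept", vc.patient_intercept_var,
         np.sqrt(vc.patient_intercept_var), np.nan),
        ("patient_week_slope", vc.patient_slope_var,
         np.sqrt(vc.patient_slope_var), vc.patient_corr),
    ], columns=["component", "variance", "sd", "correlation"]),
        outdir / "varcomps.csv")

    contrasts = slope_contrasts(fit)
    _write_csv(contrasts, outdir / "contrasts_slopes.csv")
    emm0 = emm_contrasts(fit, 0)
    emm9 = emm_contrasts(fit, 9)
    _write_csv(emm0, outdir / "emm_contrasts_week0.csv")
    _write_csv(emm9, outdir / "emm_contrasts_week9.csv")
    effects = treatment_effect_size(fit, config.sigma_mode)
    _write_csv(effects, outdir / "effect_sizes.csv")

    per_domain = None
    if config.per_domain:
        per_domain = fit_per_domain(table, alpha=config.alpha)
        _write_csv(per_domain, outdir / "domain_summary.csv")

    return {
        "fit": fit,
        "fixed": fixed,
        "contrasts": contrasts,
        "emm0": emm0,
        "emm9": emm9,
        "effects": effects,
        "per_domain": per_domain,
        "converged": fit.converged,
    }


def fit_per_domain(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit the model separately per domain (domain random effect excluded)
    and flag domains with a significant week x group interaction (joint
    Wald chi-square on the interaction terms)."""
    from scipy import stats as _st
    rows = []
    for dom, sub in table.groupby("domain_id"):
        model = DoseResponseLMM(method="reml", per_domain=True).fit(sub)
        fit = model.fit_
        iterms = [t for t in fit.beta.index if t.startswith("week:group")]
        b = fit.beta[iterms].to_numpy()
        V = fit.vcov.loc[iterms, iterms].to_numpy()
        wald = float(b @ np.linalg.solve(V, b))
        p = float(_st.chi2.sf(wald, len(iterms)))
        rows.append((dom, len(sub), wald, len(iterms), p, p < alpha,
                     model.converged_))
    return pd.DataFrame(rows, columns=[
        "domain_id", "n_rows", "wald_chi2", "df", "p_interaction",
        "significant_interaction", "converged"])


def render_tables(fixed: pd.DataFrame, contrasts: pd.DataFrame,
                  emm0: pd.DataFrame, emm9: pd.DataFrame,
                  effects: pd.DataFrame,
                  per_domain: pd.DataFrame | None = None,
                  alpha: float = 0.05) -> str:
    """Plain-text report; significance markers are applied to
    Tukey-adjusted p values only."""
    for name, df in [("fixed effects", fixed), ("slope contrasts", contrasts),
                     ("week-0 EMMs", emm0), ("week-9 EMMs", emm9),
                     ("effect sizes", effects)]:
        if df is None or df.empty:
            raise ValueError(f"missing or empty input table: {name}")

    def mark(p):
        return " *" if (p is not None and not np.isnan(p) and p < alpha) else ""

    lines = ["Fixed effects", "-" * 60]
    for _, r in fixed.iterrows():
        lines.append(f"{r['term']:<24s} {r['estimate']:>12.4g} ({r['se']:.3g}) "
                     f"t={r['t']:.2f}")
    lines += ["", "Pairwise slope contrasts (Tukey-adjusted, df=inf)", "-" * 60]
    for _, r in contrasts.iterrows():
        lines.append(f"{r['contrast']:<10s} {r['estimate']:>12.4g} "
                     f"({r['se']:.3g}) t={r['t_ratio']:.2f} "
                     f"p={r['p_adjusted']:.3f}{mark(r['p_adjusted'])}")
    for label, emm in [("week 0", emm0), ("week 9", emm9)]:
        lines += ["", f"Pairwise EMM differences at {label} (Tukey-adjusted)", "-" * 60]
        for _, r in emm.iterrows():
            lines.append(f"{r['contrast']:<10s} {r['estimate']:>12.4g} "
                         f"({r['se']:.3g}) p={r['p_adjusted']:.3f}"
                         f"{mark(r['p_adjusted'])}")
    lines += ["", "Standardized pre/post effect sizes", "-" * 60]
    for _, r in effects.iterrows():
        lines.append(f"group {r['group']:<3s} d = {r['d']:.3f} "
                     f"(EMM {r['emm_week0']:.3f} -> {r['emm_week9']:.3f}, "
                     f"sigma = {r['sigma']:.3f})")
    if per_domain is not None:
        lines += ["", "Per-domain week x group interaction", "-" * 60]
        for _, r in per_domain.iterrows():
            sig = "significant" if r["significant_interaction"] else "ns"
            lines.append(f"{r['domain_id']:<12s} chi2={r['wald_chi2']:.2f} "
                         f"df={r['df']} p={r['p_interaction']:.4f} [{sig}]")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages, writing outputs, a manifest and a log under
    ``outdir``.  Raises with the failing stage named."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if config.verbosity else logging.WARNING)

    manifest: dict = {"config_hash": config.digest(), "seed": config.seed,
                      "stages": {}}
    stage = "simulate"
    try:
        sessions, profiles = stage_simulate(config, outdir)
        manifest["stages"]["simulate"] = {
            "n_sessions": int(len(sessions)), "n_patients": int(len(profiles))}
        log.info("simulate: %d sessions, %d patients", len(sessions), len(profiles))

        stage = "prepare"
        table = stage_prepare(config, sessions, profiles, outdir)
        manifest["stages"]["prepare"] = {
            "n_rows": int(len(table)),
            "n_groups": int(table["group"].nunique()),
            "groups": sorted(table["group"].unique().tolist()),
        }
        log.info("prepare: %d analysis rows, %d dosage groups",
                 len(table), table["group"].nunique())

        stage = "fit"
        results = stage_fit(config, table, outdir)
        manifest["stages"]["fit"] = {"converged": bool(results["converged"]),
                                     "n_obs": int(results["fit"].n_obs)}

        stage = "report"
        report = render_tables(results["fixed"], results["contrasts"],
                               results["emm0"], results["emm9"],
                               results["effects"], results["per_domain"],
                               alpha=config.alpha)
        (outdir / "report.txt").write_text(report)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
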