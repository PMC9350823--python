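"""Reference generating values for the cohort simulator.

The default parameters of the synthetic-cohort generator are taken from a
published linear mixed-effects analysis of a large real-world cohort of
post-stroke users of a self-managed digital speech-language therapy app
(weekly normalized domain score modelled on week, dosage-frequency group,
cumulative hours, baseline severity and demographics, with random
intercepts and slopes for patient and skill domain).  Simulating from
these values gives synthetic data with the variance structure and effect
sizes the inference layer is meant to detect.

Scores are on a 0-1 normalized difficulty scale; week runs 0..9; dosage
groups are days-per-week bins ``1, 2, 3, 4, 5+`` with ``1`` the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

GROUP_LEVELS: tuple[str, ...] = ("1", "2", "3", "4", "5+")
SEX_LEVELS: tuple[str, ...] = ("female", "male", "not_specified")
CHRONICITY_LEVELS: tuple[str, ...] = ("chronic", "acute")

#: Canonical fixed-effect term order used by every design matrix in the
#: package.  Interaction terms use ``week:`` prefixes.
TERM_ORDER: tuple[str, ...] = (
    "Intercept",
    "week",
    "group[2]",
    "group[3]",
    "group[4]",
    "group[5+]",
    "total_hours",
    "baseline",
    "age",
    "sex[male]",
    "sex[not_specified]",
    "chronicity[acute]",
    "week:group[2]",
    "week:group[3]",
    "week:group[4]",
    "week:group[5+]",
    "week:total_hours",
)

#: Fixed-effect estimates (response scale: normalized domain score).
REFERENCE_FIXED_EFFECTS: dict[str, float] = {
    "Intercept": 1.36e-1,
    "week": 9.28e-3,
    "group[2]": 1.15e-3,
    "group[3]": 8.00e-3,
    "group[4]": 8.30e-3,
    "group[5+]": 1.13e-2,
    "total_hours": 1.13e-4,
    "baseline": 6.62e-1,
    "age": -1.54e-4,
    "sex[male]": -1.39e-4,
    "sex[not_specified]": 2.13e-2,
    "chronicity[acute]": 9.93e-3,
    "week:group[2]": 1.13e-3,
    "week:group[3]": 2.82e-3,
    "week:group[4]": 4.73e-3,
    "week:group[5+]": 5.03e-3,
    "week:total_hours": 6.01e-6,
}


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the generating / fitted mixed model.

    Variances are on the squared score scale; correlations couple the
    intercept and slope of the same grouping factor.  Domain components
    may be ``None`` on fits that exclude the domain term.
    """

    residual_var: float
    patient_intercept_var: float = 0.0
    patient_slope_var: float = 0.0
    patient_corr: float = 0.0
    domain_intercept_var: float | None = None
    domain_slope_var: float | None = None
    domain_corr: float | None = None

    def __post_init__(self) -> None:
        for name in ("residual_var", "patient_intercept_var", "patient_slope_var",
                     "domain_intercept_var", "domain_slope_var"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("patient_corr", "domain_corr"):
            c = getattr(self, name)
            if c is not None and abs(c) > 1:
                raise ValueError(f"{name} must lie in [-1, 1], got {c}")

    @property
    def total_var(self) -> float:
        """Sum of every available variance component (incl. residual)."""
        parts = [self.residual_var, self.patient_intercept_var, self.patient_slope_var]
        if self.domain_intercept_var is not None:
            parts.append(self.domain_intercept_var)
        if self.domain_slope_var is not None:
            parts.append(self.domain_slope_var)
        return float(sum(parts))


#: Reference variance components of the same published model.
REFERENCE_VARCOMPS = VarianceComponents(
    residual_var=1.4e-2,
    patient_intercept_var=2.2e-3,
    patient_slope_var=1.5e-5,
    patient_corr=5.2e-1,
    domain_intercept_var=1.3e-3,
    domain_slope_var=1.6e-5,
    domain_corr=3.0e-2,
)

#: Demographic distributions of the reference cohort (used when sampling
#: synthetic covariates): age ~ Normal(63, 14) years, ~56% male / ~43%
#: female / remainder unspecified, ~59% acute (<=6 months post-stroke),
#: baseline score ~ Normal(0.33, 0.20) clipped to [0, 1].
REFERENCE_DEMOGRAPHICS: dict[str, object] = {
    "age_mean": 63.0,
    "age_sd": 14.0,
    "sex_probs": {"male": 0.564, "female": 0.430, "not_specified": 0.006},
    "p_acute": 0.586,
    "baseline_mean": 0.33,
    "baseline_sd": 0.20,
    # Mean total practice hours per dosage group (1..5+ days/week).
    "hours_mean_by_group": (3.7, 5.3, 6.1, 6.9, 10.6),
}
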