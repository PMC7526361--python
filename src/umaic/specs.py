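"""Generative specifications for the simulated single-arm trials.

Two hypothetical breast-cancer trials are emulated: arm A (the trial whose
individual patient data the analyst holds) and arm B (the comparator, available
only as published aggregates plus a Kaplan-Meier figure).  Recurrence-free
survival follows a Weibull proportional-hazards model,

    S(t | x) = exp(-lambda * t**gamma * exp(x @ beta)),

with prognostic covariates age (years), post-menopausal status, and tumour
grade (grade 1 as reference).  In scenario 2 menopausal status additionally
modifies the effect of treatment B via a B x menopause interaction, calibrated
so the population-average treatment effect is logHR = -0.5 in both scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from .errors import ConfigurationError

#: Marginal true treatment effect (log hazard ratio of B vs A), both scenarios.
TRUE_LOG_HR = -0.5

_PROP_TOL = 1e-12


@dataclass(frozen=True)
class ArmSpec:
    """Generative parameters for one single-arm trial.

    ``weibull_scale`` is the lambda multiplying ``t**gamma`` in the cumulative
    hazard (units: day**-gamma); ``weibull_shape`` is gamma.  Coefficients are
    log hazard ratios.  ``beta_treatment``/``beta_interaction`` are only
    meaningful for the treated (B) arm; ``None`` means "not applicable".
    """

    n: int
    age_mean: float
    age_sd: float
    age_range: Tuple[float, float]
    p_postmenopausal: float
    p_grade1: float
    p_grade2: float
    p_grade3: float
    weibull_scale: float = 4e-8
    weibull_shape: float = 2.2
    beta_age: float = 0.02
    beta_meno: float = 0.5
    beta_grade2: float = 0.3
    beta_grade3: float = 0.6
    beta_treatment: Optional[float] = None
    beta_interaction: Optional[float] = None
    max_followup: float = 2500.0
    #: Upper bound of the uniform censoring draw before the administrative cap
    #: at ``max_followup``; ``None`` means equal to ``max_followup`` (so the
    #: cap is redundant).  A wider bound is a sensitivity setting: it thins
    #: random censoring toward purely administrative censoring.
    censor_upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        if self.age_sd <= 0:
            raise ConfigurationError(f"age_sd must be > 0, got {self.age_sd}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range bounds reversed: [{lo}, {hi}]")
        for name in ("p_postmenopausal", "p_grade1", "p_grade2", "p_grade3"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        grade_sum = self.p_grade1 + self.p_grade2 + self.p_grade3
        if abs(grade_sum - 1.0) > _PROP_TOL:
            raise ConfigurationError(
                f"grade proportions must sum to 1, got {grade_sum!r}"
            )
        if self.weibull_scale <= 0:
            raise ConfigurationError(
                f"weibull_scale must be > 0, got {self.weibull_scale}"
            )
        if self.weibull_shape <= 0:
            raise ConfigurationError(
                f"weibull_shape must be > 0, got {self.weibull_shape}"
            )
        if self.max_followup <= 0:
            raise ConfigurationError(
                f"max_followup must be > 0, got {self.max_followup}"
            )
        if self.censor_upper is not None and self.censor_upper <= 0:
            raise ConfigurationError(
                f"censor_upper must be > 0, got {self.censor_upper}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: the pair of arms and the target effect."""

    scenario_id: int
    arm_a: ArmSpec
    arm_b: ArmSpec
    true_log_hr: float = TRUE_LOG_HR

    def __post_init__(self) -> None:
        if self.scenario_id not in (1, 2):
            raise ConfigurationError(
                f"scenario_id must be 1 or 2, got {self.scenario_id}"
            )
        if self.arm_b.beta_treatment is None:
            raise ConfigurationError("arm_b.beta_treatment is required")


def default_arm_a(**overrides) -> ArmSpec:
    """Arm A defaults: n=1000, milder prognostic profile, no treatment term."""
    base = dict(
        n=1000,
        age_mean=53.0,
        age_sd=11.0,
        age_range=(21.0, 80.0),
        p_postmenopausal=0.40,
        p_grade1=0.20,
        p_grade2=0.65,
        p_grade3=0.15,
    )
    base.update(overrides)
    return ArmSpec(**base)


def default_arm_b(scenario_id: int = 1, **overrides) -> ArmSpec:
    """Arm B defaults: n=800, more severe profile; treatment logHR -0.5
    (scenario 1) or -0.4 with a -0.2 B x menopause interaction (scenario 2)."""
    base = dict(
        n=800,
        age_mean=56.0,
        age_sd=12.0,
        age_range=(23.0, 85.0),
        p_postmenopausal=0.50,
        p_grade1=0.10,
        p_grade2=0.70,
        p_grade3=0.20,
    )
    if scenario_id == 1:
        base.update(beta_treatment=-0.5, beta_interaction=None)
    elif scenario_id == 2:
        base.update(beta_treatment=-0.4, beta_interaction=-0.2)
    else:
        raise ConfigurationError(f"scenario_id must be 1 or 2, got {scenario_id}")
    base.update(overrides)
    return ArmSpec(**base)


def default_scenario(scenario_id: int) -> ScenarioSpec:
    """The shipped study conditions for scenario 1 or 2."""
    return ScenarioSpec(
        scenario_id=scenario_id,
        arm_a=default_arm_a(),
        arm_b=default_arm_b(scenario_id),
    )


def with_overrides(spec: ArmSpec, **overrides) -> ArmSpec:
    """Return a copy of ``spec`` with the given fields replaced (re-validated)."""
    return replace(spec, **overrides)
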