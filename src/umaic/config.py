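"""Run configuration: YAML parsing, validation, defaults.

An empty (or absent) configuration reproduces the shipped study conditions
exactly; any key can be overridden.  Unknown keys are an error, never silently
ignored, and validation messages name the offending key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .errors import ConfigurationError
from .publication import DEFAULT_PRECISION, DEFAULT_RISK_TIMES
from .specs import ArmSpec, ScenarioSpec, default_arm_a, default_arm_b

_ARM_KEYS = {
    "n",
    "age_mean",
    "age_sd",
    "age_range",
    "p_postmenopausal",
    "p_grade1",
    "p_grade2",
    "p_grade3",
    "weibull_scale",
    "weibull_shape",
    "beta_age",
    "beta_meno",
    "beta_grade2",
    "beta_grade3",
    "beta_treatment",
    "beta_interaction",
    "max_followup",
    "censor_upper",
}

_PUBLICATION_KEYS = {
    "risk_times",
    "precision",
    "round_times",
    "publish_total_events",
    "time_jitter",
    "survival_jitter",
}

_TOP_KEYS = {
    "scenario",
    "n_reps",
    "seed",
    "out_dir",
    "arm_a",
    "arm_b",
    "publication",
    "balance_tol",
    "include_omit_em_scenario1",
    "bias_factor",
}

_BIAS_FACTOR_KEYS = {"hr_ud", "rr_eu"}


@dataclass(frozen=True)
class PublicationConfig:
    risk_times: Tuple[float, ...] = DEFAULT_RISK_TIMES
    precision: Optional[int] = DEFAULT_PRECISION
    round_times: bool = True
    publish_total_events: bool = True
    time_jitter: float = 0.0
    survival_jitter: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one study run."""

    scenario_id: int = 1
    n_reps: int = 200
    master_seed: int = 1729
    out_dir: Optional[str] = None
    arm_a_overrides: Dict = field(default_factory=dict)
    arm_b_overrides: Dict = field(default_factory=dict)
    publication: PublicationConfig = field(default_factory=PublicationConfig)
    balance_tol: float = 1e-8
    include_omit_em_scenario1: bool = True
    hr_ud: Optional[float] = None
    rr_eu: Optional[float] = None

    def scenario(self) -> ScenarioSpec:
        arm_a = default_arm_a(**self.arm_a_overrides)
        arm_b = default_arm_b(self.scenario_id, **self.arm_b_overrides)
        return ScenarioSpec(scenario_id=self.scenario_id, arm_a=arm_a, arm_b=arm_b)

    def to_dict(self) -> Dict:
        return asdict(self)


def _check_keys(mapping: Dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}"
        )


def validate_config(raw: Optional[Dict]) -> RunConfig:
    """Turn a parsed mapping into a validated RunConfig."""
    raw = dict(raw or {})
    _check_keys(raw, _TOP_KEYS, "config")
    scenario_id = raw.get("scenario", 1)
    if scenario_id not in (1, 2):
        raise ConfigurationError(f"scenario must be 1 or 2, got {scenario_id}")
    n_reps = raw.get("n_reps", 200)
    if not isinstance(n_reps, int) or n_reps < 2:
        raise ConfigurationError(f"n_reps must be an integer >= 2, got {n_reps}")
    arm_a = dict(raw.get("arm_a") or {})
    arm_b = dict(raw.get("arm_b") or {})
    _check_keys(arm_a, _ARM_KEYS, "arm_a")
    _check_keys(arm_b, _ARM_KEYS, "arm_b")
    for overrides in (arm_a, arm_b):
        if "age_range" in overrides:
            overrides["age_range"] = tuple(overrides["age_range"])
    pub_raw = dict(raw.get("publication") or {})
    _check_keys(pub_raw, _PUBLICATION_KEYS, "publication")
    if "risk_times" in pub_raw:
        pub_raw["risk_times"] = tuple(float(t) for t in pub_raw["risk_times"])
    publication = PublicationConfig(**pub_raw)
    bf_raw = dict(raw.get("bias_factor") or {})
    _check_keys(bf_raw, _BIAS_FACTOR_KEYS, "bias_factor")
    cfg = RunConfig(
        scenario_id=scenario_id,
        n_reps=n_reps,
        master_seed=int(raw.get("seed", 1729)),
        out_dir=raw.get("out_dir"),
        arm_a_overrides=arm_a,
        arm_b_overrides=arm_b,
        publication=publication,
        balance_tol=float(raw.get("balance_tol", 1e-8)),
        include_omit_em_scenario1=bool(raw.get("include_omit_em_scenario1", True)),
        hr_ud=bf_raw.get("hr_ud"),
        rr_eu=bf_raw.get("rr_eu"),
    )
    cfg.scenario()  # force ArmSpec validation now, before any computation
    return cfg


def read_config(path: Optional[str]) -> RunConfig:
    """Read a YAML config file; ``None`` or an empty file give the defaults."""
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    return validate_config(raw)
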