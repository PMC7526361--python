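"""Patient-level data generation under the Weibull proportional-hazards model.

Covariates are drawn from a truncated normal (age, inverse-CDF sampling so the
random stream is reproducible draw-for-draw) and Bernoulli/categorical
distributions.  Latent event times invert the Weibull survival function
S(t|x) = exp(-lambda t^gamma e^{x beta}); censoring is uniform on
(0, max_followup), independent of covariates and treatment.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .specs import ArmSpec

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: Column order of a patient-record table.
RECORD_COLUMNS = [
    "arm",
    "age",
    "postmenopausal",
    "grade2",
    "grade3",
    "treated",
    "time",
    "event",
]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_covariates(spec: ArmSpec, rng: SeedLike) -> pd.DataFrame:
    """Draw ``spec.n`` covariate profiles.

    Age comes from a normal(age_mean, age_sd) truncated at the arm's bounds,
    sampled by inverse CDF on the truncated interval; menopausal status is
    Bernoulli; tumour grade is categorical over {1, 2, 3} and encoded as the
    indicator pair (grade2, grade3) with grade 1 as reference.
    """
    rng = _as_rng(rng)
    n = spec.n
    a = (spec.age_range[0] - spec.age_mean) / spec.age_sd
    b = (spec.age_range[1] - spec.age_mean) / spec.age_sd
    u_age = rng.random(n)
    age = truncnorm.ppf(u_age, a, b, loc=spec.age_mean, scale=spec.age_sd)
    meno = (rng.random(n) < spec.p_postmenopausal).astype(np.int64)
    u_grade = rng.random(n)
    grade2 = (u_grade >= spec.p_grade1) & (u_grade < spec.p_grade1 + spec.p_grade2)
    grade3 = u_grade >= spec.p_grade1 + spec.p_grade2
    return pd.DataFrame(
        {
            "age": age,
            "postmenopausal": meno,
            "grade2": grade2.astype(np.int64),
            "grade3": grade3.astype(np.int64),
        }
    )


def linear_predictor(
    profiles: pd.DataFrame, spec: ArmSpec, treated: bool
) -> np.ndarray:
    """Log-hazard linear component x @ beta for each profile.

    For treated subjects the treatment main effect and (if present) the
    treatment x menopause interaction are added.
    """
    xb = (
        spec.beta_age * profiles["age"].to_numpy(dtype=float)
        + spec.beta_meno * profiles["postmenopausal"].to_numpy(dtype=float)
        + spec.beta_grade2 * profiles["grade2"].to_numpy(dtype=float)
        + spec.beta_grade3 * profiles["grade3"].to_numpy(dtype=float)
    )
    if treated:
        if spec.beta_treatment is None:
            raise ConfigurationError(
                "beta_treatment is required to simulate a treated arm"
            )
        xb = xb + spec.beta_treatment
        if spec.beta_interaction is not None:
            xb = xb + spec.beta_interaction * profiles["postmenopausal"].to_numpy(
                dtype=float
            )
    return xb


def simulate_event_time(
    xb: Union[float, np.ndarray], spec: ArmSpec, u: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Invert S(t|x) = exp(-lambda t^gamma e^{xb}) at survival quantile ``u``.

    T = (-ln u / (lambda e^{xb}))**(1/gamma).  ``u`` must lie in (0, 1];
    u = 1 maps to T = 0 and T is strictly decreasing in u (and in xb).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u > 1.0):
        raise ValueError("u must lie in (0, 1]; u = 0 would give infinite time")
    xb = np.asarray(xb, dtype=float)
    t = (-np.log(u) / (spec.weibull_scale * np.exp(xb))) ** (1.0 / spec.weibull_shape)
    if t.ndim == 0:
        return float(t)
    return t


def apply_censoring(
    latent_time: np.ndarray, spec: ArmSpec, rng: SeedLike
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform random censoring truncated at the follow-up horizon.

    C ~ Uniform(0, censor_upper), capped at max_followup (with the default
    censor_upper = max_followup the cap is redundant and C ~ U(0,
    max_followup)).  Returns (observed_time, event) with event = 1 iff the
    latent time is reached before the censoring draw.
    """
    rng = _as_rng(rng)
    latent_time = np.asarray(latent_time, dtype=float)
    if np.any(latent_time < 0):
        raise ValueError("latent event times must be nonnegative")
    upper = spec.censor_upper if spec.censor_upper is not None else spec.max_followup
    c = np.minimum(rng.uniform(0.0, upper, size=latent_time.shape), spec.max_followup)
    event = (latent_time <= c).astype(np.int64)
    observed = np.minimum(latent_time, c)
    return observed, event


def simulate_arm(
    spec: ArmSpec,
    treated: bool,
    rng: SeedLike,
    arm_label: Optional[str] = None,
    censor: bool = True,
) -> pd.DataFrame:
    """Simulate one full arm: covariates, latent times, censoring.

    Returns a patient-record table with columns ``RECORD_COLUMNS`` plus the
    latent event time (``latent_time``), reproducible given the seed.  With
    ``censor=False`` every latent time is observed as an event (used for
    parameter-recovery checks).
    """
    rng = _as_rng(rng)
    if arm_label is None:
        arm_label = "B" if treated else "A"
    profiles = simulate_covariates(spec, rng)
    xb = linear_predictor(profiles, spec, treated)
    u = 1.0 - rng.random(spec.n)  # in (0, 1]
    latent = np.asarray(simulate_event_time(xb, spec, u), dtype=float)
    if spec.n == 0:
        latent = latent.reshape(0)
    if censor:
        time, event = apply_censoring(latent, spec, rng)
    else:
        time, event = latent.copy(), np.ones(spec.n, dtype=np.int64)
    out = profiles.copy()
    out.insert(0, "arm", arm_label)
    out["treated"] = np.int64(bool(treated))
    out["time"] = time
    out["event"] = event
    out["latent_time"] = latent
    return out
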