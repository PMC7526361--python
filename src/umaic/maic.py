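"""Unanchored MAIC estimation: entropy balancing and pooled weighted Cox.

Entropy balancing finds subject weights for the IPD arm that minimize the
Kullback-Leibler divergence from uniform base weights subject to exact moment
constraints on the published aggregates of the comparator arm (age balanced on
its first two raw moments, binary covariates on their proportions).  The dual
problem is an unconstrained convex minimization over one multiplier per
constraint, with weights of exponential-tilting form w_i ~ exp(c_i . lam);
it is solved by damped Newton iteration with a quasi-Newton fallback.

The treatment contrast is then a Cox regression of the pooled data (weighted
IPD arm + unit-weighted reconstructed comparator arm) on the comparator
indicator alone, with a robust sandwich variance treating the balancing
weights as sampling weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import optimize
from scipy.stats import norm

from .errors import ConvergenceError, InfeasibleTargetError
from .publication import AggregateSummary, KMPublication
from .reconstruct import ReconstructedIPD

_Z975 = float(norm.ppf(0.975))

#: Strategy labels (which covariate moments enter the balance target).
UNWEIGHTED = "unweighted"
BALANCE_ALL = "all_covariates"
OMIT_EM = "omit_effect_modifier"
OMIT_EM_GRADES = "omit_effect_modifier_and_grades"

#: Moments balanced under each weighted strategy.
_STRATEGY_MOMENTS: Dict[str, Tuple[str, ...]] = {
    BALANCE_ALL: ("age_m1", "age_m2", "postmenopausal", "grade2", "grade3"),
    OMIT_EM: ("age_m1", "age_m2", "grade2", "grade3"),
    OMIT_EM_GRADES: ("age_m1", "age_m2"),
}


@dataclass(frozen=True)
class BalanceTarget:
    """Named moment targets for entropy balancing plus the comparator size."""

    moments: Tuple[str, ...]
    targets: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "targets", targets)
        if len(self.moments) == 0:
            raise InfeasibleTargetError("balance target selects no moments")
        if targets.shape != (len(self.moments),) or not np.all(np.isfinite(targets)):
            raise InfeasibleTargetError("targets must be finite, one per moment")


def balance_target(
    aggregates: AggregateSummary, strategy: str = BALANCE_ALL
) -> BalanceTarget:
    """Build the moment targets for a weighting strategy from published
    aggregates.  The age second raw moment is var + mean**2."""
    if strategy not in _STRATEGY_MOMENTS:
        raise KeyError(f"unknown weighted strategy {strategy!r}")
    values = {
        "age_m1": aggregates.mean_age,
        "age_m2": aggregates.var_age + aggregates.mean_age**2,
        "postmenopausal": aggregates.p_postmenopausal,
        "grade2": aggregates.p_grade2,
        "grade3": aggregates.p_grade3,
    }
    moments = _STRATEGY_MOMENTS[strategy]
    return BalanceTarget(
        moments=moments,
        targets=np.array([values[m] for m in moments]),
        n_total=aggregates.n_total,
    )


@dataclass(frozen=True)
class WeightSet:
    """Balancing weights (scaled to sum to the comparator n) with diagnostics."""

    weights: np.ndarray
    achieved: Dict[str, float]
    targets: Dict[str, float]
    ess: float
    multipliers: Optional[np.ndarray] = None


def _moment_columns(covariates: pd.DataFrame, moments: Sequence[str]) -> np.ndarray:
    cols = []
    for m in moments:
        if m == "age_m1":
            cols.append(covariates["age"].to_numpy(dtype=float))
        elif m == "age_m2":
            cols.append(covariates["age"].to_numpy(dtype=float) ** 2)
        else:
            cols.append(covariates[m].to_numpy(dtype=float))
    return np.column_stack(cols)


def ess(weights: np.ndarray) -> float:
    """Effective sample size (sum w)^2 / sum w^2; scale-invariant, <= n."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w < 0):
        raise ValueError("weights must be nonnegative and nonempty")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("weights must not be all zero")
    return float(sw**2 / np.sum(w**2))


def entropy_balance(
    covariates: pd.DataFrame,
    target: BalanceTarget,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> WeightSet:
    """Solve the entropy-balancing program for one IPD arm.

    Raises :class:`InfeasibleTargetError` when a target moment lies outside
    the open range of the corresponding source column, and
    :class:`ConvergenceError` when the dual Newton solve cannot drive every
    achieved moment within ``tol`` (relative) of its target.
    """
    C = _moment_columns(covariates, target.moments)
    n = C.shape[0]
    if n == 0:
        raise InfeasibleTargetError("no source subjects to balance")
    m = target.targets
    keep = []
    for j, name in enumerate(target.moments):
        lo, hi = C[:, j].min(), C[:, j].max()
        if lo == hi:
            if abs(lo - m[j]) > tol * max(1.0, abs(m[j])):
                raise InfeasibleTargetError(
                    f"moment {name!r}: source is constant at {lo}, target {m[j]}"
                )
            continue  # constraint satisfied by any weights
        if not lo < m[j] < hi:
            raise InfeasibleTargetError(
                f"moment {name!r}: target {m[j]} outside source range ({lo}, {hi})"
            )
        keep.append(j)
    if not keep:  # every selected moment is constant and already on target
        w = np.full(n, target.n_total / n)
        achieved = C.T @ np.full(n, 1.0 / n)
        return WeightSet(
            weights=w,
            achieved={nm: float(v) for nm, v in zip(target.moments, achieved)},
            targets={nm: float(v) for nm, v in zip(target.moments, m)},
            ess=ess(w),
            multipliers=np.zeros(len(target.moments)),
        )
    Ck = C[:, keep]
    scale = Ck.std(axis=0)
    Z = (Ck - m[keep]) / scale  # centered at target, unit scale

    def dual(lam):
        zl = Z @ lam
        zmax = zl.max()
        return zmax + np.log(np.mean(np.exp(zl - zmax)))

    def weights_of(lam):
        zl = Z @ lam
        p = np.exp(zl - zl.max())
        return p / p.sum()

    lam = np.zeros(len(keep))
    f = dual(lam)
    ok = False
    for _ in range(max_iter):
        p = weights_of(lam)
        g = Z.T @ p
        if np.max(np.abs(g)) < 1e-12:
            ok = True
            break
        H = (Z * p[:, None]).T @ Z - np.outer(g, g)
        try:
            cond = np.linalg.cond(H)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            break  # hand over to the quasi-Newton fallback
        step = np.linalg.solve(H, -g)
        alpha = 1.0
        for _ in range(50):
            f_cand = dual(lam + alpha * step)
            if f_cand <= f + 1e-14:
                break
            alpha *= 0.5
        lam, f = lam + alpha * step, f_cand
    if not ok:
        res = optimize.minimize(dual, lam, method="BFGS", options={"gtol": 1e-12})
        lam = res.x
        g = Z.T @ weights_of(lam)
        if np.max(np.abs(g)) > 1e-8:
            raise ConvergenceError(
                f"entropy balancing did not converge; gradient norm {np.max(np.abs(g)):.3e}"
            )
    p = weights_of(lam)
    achieved_all = C.T @ p
    rel_err = np.abs(achieved_all - m) / np.maximum(1.0, np.abs(m))
    if np.max(rel_err) > tol:
        raise ConvergenceError(
            f"achieved moments off target: max relative error {np.max(rel_err):.3e}"
        )
    w = p * target.n_total  # rescale so both arms carry equal weighted n
    lam_full = np.zeros(len(target.moments))
    if keep:
        lam_full[keep] = lam / scale
    return WeightSet(
        weights=w,
        achieved={name: float(v) for name, v in zip(target.moments, achieved_all)},
        targets={name: float(v) for name, v in zip(target.moments, m)},
        ess=ess(w),
        multipliers=lam_full,
    )


@dataclass(frozen=True)
class EstimateResult:
    """One unanchored MAIC hazard-ratio estimate (B vs A)."""

    strategy: str
    log_hr: float
    se: float
    ess: float
    converged: bool = True

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_hr - _Z975 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_hr + _Z975 * self.se))


def pooled_weighted_cox(
    arm_a: pd.DataFrame,
    arm_b: Union[ReconstructedIPD, pd.DataFrame],
    weights: Optional[np.ndarray] = None,
    strategy: str = UNWEIGHTED,
    arm_b_weights: Optional[np.ndarray] = None,
) -> EstimateResult:
    """Weighted Cox regression of pooled (A + reconstructed B) data on the
    B indicator, with robust sandwich variance (weights as sampling weights).

    Weights are used as given (balancing weights sum to the comparator n, so
    the two arms carry equal weighted sample sizes); estimates are invariant
    to rescaling the *pooled* weight vector by a constant, but not to scaling
    one arm against the other.  ``arm_b_weights`` defaults to unit weights.
    """
    b_df = arm_b.data if isinstance(arm_b, ReconstructedIPD) else arm_b
    if len(arm_a) == 0 or len(b_df) == 0:
        raise ValueError("both arms must be nonempty")
    if weights is None:
        w_a = np.ones(len(arm_a))
    else:
        w_a = np.asarray(weights, dtype=float)
        if w_a.shape != (len(arm_a),):
            raise ValueError("weights must have one entry per A-arm subject")
    if arm_b_weights is None:
        w_b = np.ones(len(b_df))
    else:
        w_b = np.asarray(arm_b_weights, dtype=float)
        if w_b.shape != (len(b_df),):
            raise ValueError("arm_b_weights must have one entry per B-arm subject")
    n_events_a = int(arm_a["event"].sum())
    n_events_b = int(b_df["event"].sum())
    es = ess(w_a)
    if n_events_a == 0 or n_events_b == 0:
        return EstimateResult(strategy, np.nan, np.nan, es, converged=False)
    df = pd.DataFrame(
        {
            "time": np.concatenate(
                [arm_a["time"].to_numpy(float), b_df["time"].to_numpy(float)]
            ),
            "event": np.concatenate(
                [arm_a["event"].to_numpy(int), b_df["event"].to_numpy(int)]
            ),
            "treated_b": np.concatenate(
                [np.zeros(len(arm_a)), np.ones(len(b_df))]
            ),
            "w": np.concatenate([w_a, w_b]),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                weights_col="w",
                robust=True,
            )
        log_hr = float(cph.params_["treated_b"])
        se = float(cph.standard_errors_["treated_b"])
    except Exception:
        return EstimateResult(strategy, np.nan, np.nan, es, converged=False)
    if not np.isfinite(log_hr) or not np.isfinite(se) or se <= 0:
        return EstimateResult(strategy, np.nan, np.nan, es, converged=False)
    return EstimateResult(strategy, log_hr, se, es, converged=True)


def run_strategies(
    arm_a: pd.DataFrame,
    publication: KMPublication,
    recon: ReconstructedIPD,
    scenario_id: int,
    include_omit_em_scenario1: bool = False,
    tol: float = 1e-8,
) -> List[EstimateResult]:
    """Run every analytic strategy of one repetition.

    Scenario 1: unweighted, balance-all, omit menopause + grades (plus,
    optionally, omit menopause only — needed by the bias-factor adjustment).
    Scenario 2: unweighted, balance-all, omit menopause, omit menopause +
    grades.
    """
    if scenario_id == 1:
        strategies = [UNWEIGHTED, BALANCE_ALL, OMIT_EM_GRADES]
        if include_omit_em_scenario1:
            strategies.append(OMIT_EM)
    elif scenario_id == 2:
        strategies = [UNWEIGHTED, BALANCE_ALL, OMIT_EM, OMIT_EM_GRADES]
    else:
        raise ValueError(f"scenario_id must be 1 or 2, got {scenario_id}")
    results = []
    for strat in strategies:
        if strat == UNWEIGHTED:
            results.append(pooled_weighted_cox(arm_a, recon, None, strat))
        else:
            ws = entropy_balance(
                arm_a, balance_target(publication.aggregates, strat), tol=tol
            )
            results.append(pooled_weighted_cox(arm_a, recon, ws.weights, strat))
    return results
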