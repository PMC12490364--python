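"""Cox partial-likelihood machinery for two-group survival comparisons.

Implements the semi-parametric Cox proportional hazards model with a single
dichotomous covariate (control = 0, experimental = 1):

    lambda(t | x) = lambda0(t) * exp(x * beta),

so the hazard ratio is HR = exp(beta).  Tied event times are handled with
Efron's approximation to the partial likelihood, which coincides with the
exact Cox partial likelihood when all event times are distinct.  The baseline
hazard lambda0(t) cancels out of the partial likelihood and is never
estimated.

Also provides Kaplan-Meier product-limit summaries (median survival with a
Brookmeyer-Crowley confidence interval on the log-survival scale), which the
summary-statistics reconstruction machinery optionally targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "SurvivalData",
    "CoxFit",
    "KMEstimate",
    "InvalidDataError",
    "NoEventsError",
    "DivergenceError",
    "efron_log_partial_likelihood",
    "fit_cox",
    "km_summary",
]

# Newton-Raphson settings for the scalar beta maximisation.
NEWTON_SCORE_TOL = 1e-9
NEWTON_STEP_TOL = 1e-10
NEWTON_MAX_ITER = 50
# |beta| beyond this is treated as a monotone-likelihood divergence:
# exp(20) ~ 4.9e8 is far outside any meaningful hazard ratio.
BETA_DIVERGENCE_LIMIT = 20.0


class InvalidDataError(ValueError):
    """Input data violate the survival-data contract."""


class NoEventsError(ValueError):
    """The data carry no information about beta (no observed events)."""


class DivergenceError(RuntimeError):
    """The partial-likelihood maximiser diverges (monotone likelihood)."""


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored two-group survival data.

    Attributes
    ----------
    times : ndarray
        Observed response (survival or censoring) time per subject, strictly
        positive and finite.
    events : ndarray
        Event indicator per subject; 1 = event observed, 0 = right censored.
    groups : ndarray
        Condition indicator per subject; 0 = control, 1 = experimental.
    """

    times: np.ndarray
    events: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        groups = np.asarray(self.groups)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int8)
                           if _is_binary(events) else events)
        object.__setattr__(self, "groups", groups.astype(np.int8)
                           if _is_binary(groups) else groups)
        if times.ndim != 1 or events.ndim != 1 or groups.ndim != 1:
            raise InvalidDataError("times, events, groups must be 1-d vectors")
        n = times.shape[0]
        if events.shape[0] != n or groups.shape[0] != n:
            raise InvalidDataError(
                f"length mismatch: times={n}, events={events.shape[0]}, "
                f"groups={groups.shape[0]}")
        if n < 2:
            raise InvalidDataError("need at least two subjects")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise InvalidDataError("times must be strictly positive and finite")
        if not _is_binary(events):
            raise InvalidDataError("events must contain only 0/1")
        if not _is_binary(groups):
            raise InvalidDataError("groups must contain only 0/1")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def both_groups_present(self) -> bool:
        g = self.groups
        return bool((g == 0).any() and (g == 1).any())

    def with_times(self, times: np.ndarray) -> "SurvivalData":
        """Same subjects and indicators with replaced times."""
        return SurvivalData(np.asarray(times, dtype=float),
                            self.events, self.groups)


def _is_binary(a: np.ndarray) -> bool:
    a = np.asarray(a)
    return bool(np.isin(a, (0, 1)).all())


@dataclass(frozen=True)
class CoxFit:
    """Maximum-partial-likelihood fit of the two-group Cox model."""

    beta_hat: float
    se: float
    hr: float
    ci_lower: float
    ci_upper: float
    loglik_at_mle: float
    loglik_at_null: float
    conf_level: float = 0.95
    iterations: int = 0


@dataclass(frozen=True)
class KMEstimate:
    """Kaplan-Meier product-limit summary of one sample.

    ``median`` and its confidence bounds are ``None`` when the survival curve
    never reaches 0.5 (heavily censored data) — an undefined median is a
    legitimate outcome, not an error.  ``survival_curve`` is a (k, 2) array of
    (time, survival probability) pairs starting at (0, 1).
    """

    median: float | None
    ci_lower: float | None
    ci_upper: float | None
    survival_curve: np.ndarray
    conf_level: float = 0.95


# ---------------------------------------------------------------------------
# Efron partial likelihood
# ---------------------------------------------------------------------------

class _EfronTerms:
    """Precomputed risk-set counts for fast repeated likelihood evaluation.

    With a single binary covariate every risk-set sum reduces to counts:
    exp(beta * x) is 1 for controls and e^beta for the experimental group, so
    for each distinct event time t_j with d_j tied events the Efron
    denominator at tie position l in {0..d_j-1} is

        A_jl = (n0R_j - (l/d_j) d0_j) + (n1R_j - (l/d_j) d1_j) e^beta,

    where n0R/n1R count subjects at risk (Y >= t_j; subjects censored exactly
    at t_j remain at risk, i.e. events precede censorings) and d0/d1 count
    tied events by group.  Tie grouping uses exact floating-point equality.
    """

    __slots__ = ("a0", "a1", "sum_x_events", "n_events")

    def __init__(self, data: SurvivalData) -> None:
        t = data.times
        e = data.events.astype(bool)
        g = data.groups.astype(np.int64)
        et = t[e]
        self.n_events = et.shape[0]
        self.sum_x_events = float(g[e].sum())
        if self.n_events == 0:
            self.a0 = np.empty(0)
            self.a1 = np.empty(0)
            return
        ut, inv = np.unique(et, return_inverse=True)
        d = np.bincount(inv).astype(np.int64)
        d1 = np.bincount(inv, weights=g[e].astype(float))
        d0 = d - d1
        ts_all = np.sort(t)
        ts1 = np.sort(t[g == 1])
        n_risk = t.shape[0] - np.searchsorted(ts_all, ut, side="left")
        n1_risk = ts1.shape[0] - np.searchsorted(ts1, ut, side="left")
        n0_risk = n_risk - n1_risk
        # expand tie positions l = 0..d_j-1 for each distinct event time
        idx = np.repeat(np.arange(ut.shape[0]), d)
        starts = np.repeat(np.cumsum(d) - d, d)
        frac = (np.arange(idx.shape[0]) - starts) / d[idx]
        self.a0 = n0_risk[idx] - frac * d0[idx]
        self.a1 = n1_risk[idx] - frac * d1[idx]

    def loglik(self, beta: float) -> float:
        if self.n_events == 0:
            return 0.0
        eb = math.exp(beta)
        return beta * self.sum_x_events - float(
            np.log(self.a0 + self.a1 * eb).sum())

    def score_info(self, beta: float) -> tuple[float, float]:
        """First derivative (score) and negative second derivative
        (observed information) of the log partial likelihood."""
        if self.n_events == 0:
            return 0.0, 0.0
        eb = math.exp(beta)
        denom = self.a0 + self.a1 * eb
        p = self.a1 * eb / denom
        score = self.sum_x_events - float(p.sum())
        info = float((p * (1.0 - p)).sum())
        return score, info


def efron_log_partial_likelihood(data: SurvivalData, beta: float) -> float:
    """Efron-approximation log partial likelihood of the two-group Cox model.

    Returns 0.0 (log of an empty product) when the data contain no events.
    Equals the exact Cox log partial likelihood whenever all event times are
    distinct.
    """
    if not isinstance(data, SurvivalData):
        data = SurvivalData(*data)
    beta = float(beta)
    if not math.isfinite(beta):
        raise InvalidDataError("beta must be finite")
    return _EfronTerms(data).loglik(beta)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def fit_cox(data: SurvivalData, conf_level: float = 0.95) -> CoxFit:
    """Fit the two-group Cox model by Newton-Raphson on the scalar beta.

    The standard error comes from the inverse observed information at the
    MLE; the confidence interval for HR is the Wald interval
    exp(beta_hat +/- z * se).

    Raises
    ------
    NoEventsError
        If no events are observed (flat partial likelihood).
    DivergenceError
        If the likelihood is monotone (|beta_hat| exceeds 20) or carries no
        information about beta.
    InvalidDataError
        If a group is absent or conf_level is outside (0, 1).
    """
    if not data.both_groups_present():
        raise InvalidDataError("both groups must be present to fit")
    if not (0.0 < conf_level < 1.0):
        raise InvalidDataError("conf_level must lie in (0, 1)")
    terms = _EfronTerms(data)
    if terms.n_events == 0:
        raise NoEventsError("no events observed: beta is not identified")

    beta = 0.0
    ll = terms.loglik(beta)
    iterations = 0
    for iterations in range(1, NEWTON_MAX_ITER + 1):
        score, info = terms.score_info(beta)
        if info <= 0.0:
            raise DivergenceError(
                "observed information is zero: no group contrast in any "
                "risk set (beta unidentified)")
        if abs(score) < NEWTON_SCORE_TOL:
            break
        step = score / info
        # the scalar log partial likelihood is concave; halve an
        # overshooting step until the likelihood does not decrease
        new_beta = beta + step
        new_ll = terms.loglik(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = terms.loglik(new_beta)
            halvings += 1
        beta, ll = new_beta, new_ll
        if abs(beta) > BETA_DIVERGENCE_LIMIT:
            raise DivergenceError(
                f"monotone partial likelihood: |beta| exceeded "
                f"{BETA_DIVERGENCE_LIMIT} (all events ordered by group); "
                f"the MLE does not exist")
        if abs(step) < NEWTON_STEP_TOL:
            break

    score, info = terms.score_info(beta)
    if info <= 0.0:
        raise DivergenceError("observed information is zero at the optimum")
    se = 1.0 / math.sqrt(info)
    z = _stats.norm.ppf(0.5 + conf_level / 2.0)
    return CoxFit(
        beta_hat=beta,
        se=se,
        hr=math.exp(beta),
        ci_lower=math.exp(beta - z * se),
        ci_upper=math.exp(beta + z * se),
        loglik_at_mle=ll,
        loglik_at_null=terms.loglik(0.0),
        conf_level=conf_level,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_summary(times: np.ndarray, events: np.ndarray,
               conf_level: float = 0.95) -> KMEstimate:
    """Product-limit survival estimate with median and Brookmeyer-Crowley CI.

    The survival curve steps at each distinct observed time; subjects
    censored at an event time remain in that risk set.  The median is the
    first time at which S(t) <= 0.5.  Its confidence interval inverts the
    pointwise CI of the curve computed on the log-survival scale with
    Greenwood's variance: the bounds are the first times at which the upper
    and lower confidence curves cross 0.5.  Bounds that never cross are
    returned as ``None``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.ndim != 1 or e.ndim != 1 or t.shape != e.shape:
        raise InvalidDataError("times and events must be equal-length vectors")
    if t.shape[0] < 1:
        raise InvalidDataError("need at least one observation")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise InvalidDataError("times must be strictly positive and finite")
    if not _is_binary(e):
        raise InvalidDataError("events must contain only 0/1")
    if not (0.0 < conf_level < 1.0):
        raise InvalidDataError("conf_level must lie in (0, 1)")

    ut, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e)            # events at each distinct time
    n_risk = t.shape[0] - np.searchsorted(np.sort(t), ut, side="left")

    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_risk)
        # Greenwood variance of log S(t)
        var_term = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
        var_log_s = np.cumsum(var_term)
        z = _stats.norm.ppf(0.5 + conf_level / 2.0)
        log_s = np.log(np.maximum(surv, 1e-300))
        lower = np.exp(log_s - z * np.sqrt(var_log_s))
        upper = np.exp(log_s + z * np.sqrt(var_log_s))
    lower = np.clip(np.where(surv > 0, lower, 0.0), 0.0, 1.0)
    upper = np.clip(np.where(surv > 0, upper, 1.0), 0.0, 1.0)

    def _first_leq(curve: np.ndarray, level: float = 0.5) -> float | None:
        hit = np.nonzero(curve <= level + 1e-12)[0]
        return float(ut[hit[0]]) if hit.size else None

    median = _first_leq(surv)
    # Brookmeyer-Crowley: median CI = {t : S_lower(t) <= 0.5 <= S_upper(t)}
    ci_lo = _first_leq(lower)
    ci_up = _first_leq(upper)
    if median is None:
        ci_up = None

    curve = np.column_stack([np.concatenate([[0.0], ut]),
                             np.concatenate([[1.0], surv])])
    return KMEstimate(median=median, ci_lower=ci_lo, ci_upper=ci_up,
                      survival_curve=curve, conf_level=conf_level)
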