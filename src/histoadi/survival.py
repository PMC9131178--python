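"""Survival analysis for ADI-stratified cohorts, from first principles.

Implements the product-limit (Kaplan-Meier) estimator, the two-group
log-rank test, univariate Cox proportional-hazards regression (Newton-
Raphson on the partial likelihood, Efron tie handling by default,
Breslow by flag), maximally selected cutpoint search in the style of
survminer's surv_cutpoint, and a median split. ``stratify_and_test``
bundles these into the high- vs low-ADI overall-survival comparison.

Conventions: subjects censored exactly at an event time are still at
risk at that time; Wald 95% confidence intervals exp(beta +/- 1.96 se);
cutpoint candidates are midpoints between consecutive distinct scores,
feasible when both groups hold at least minprop * n subjects, ties in
the maximal statistic broken toward the lower threshold; a median split
assigns subjects at the median to the low group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


def _validate(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if time.size == 0:
        raise ValueError("need at least one record")
    if np.any(time <= 0) or np.any(~np.isfinite(time)):
        raise ValueError("all times must be finite and > 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return time, event


@dataclass
class KMCurve:
    """Kaplan-Meier estimate: step function over distinct event times."""

    event_times: np.ndarray  # distinct, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk at each event time
    n_events: np.ndarray  # d at each event time
    censor_times: np.ndarray  # times of censored exits (for tick marks)

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event, right-continuous steps after."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median_survival(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else math.nan


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    time, event = _validate(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    event_times = np.unique(time[event == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(time >= t))
        n_events[i] = int(np.sum((time == t) & (event == 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=n_events,
        censor_times=np.sort(time[event == 0]),
    )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    observed_a: float  # total events in group a
    expected_a: float  # expected events in group a under the null


def _logrank_sums(
    time_a, event_a, time_b, event_b
) -> tuple[float, float, float]:
    """(O_a - E_a, Var, O_a) summed over distinct event times."""
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    in_a = np.concatenate([np.ones(len(time_a), bool), np.zeros(len(time_b), bool)])

    o_minus_e = 0.0
    var = 0.0
    observed_a = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        frac = n_a / n
        o_minus_e += d_a - d * frac
        if n > 1:
            var += d * frac * (1.0 - frac) * (n - d) / (n - 1)
        observed_a += d_a
    return o_minus_e, var, observed_a


def logrank_test(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group a are
    compared with their hypergeometric expectation given the risk sets;
    chi2 = (sum O-E)^2 / sum Var on 1 df.
    """
    time_a, event_a = _validate(time_a, event_a)
    time_b, event_b = _validate(time_b, event_b)
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    o_minus_e, var, observed_a = _logrank_sums(time_a, event_a, time_b, event_b)
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = o_minus_e**2 / var
    return LogRankResult(
        chi2=float(chi2),
        df=1,
        p_value=float(sps.chi2.sf(chi2, df=1)),
        observed_a=float(observed_a),
        expected_a=float(observed_a - o_minus_e),
    )


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    iterations: int
    converged: bool
    n: int
    n_events: int


def _cox_derivatives(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray, ties: str
) -> tuple[float, float, float]:
    """(log partial likelihood, score, information) at beta."""
    eta = beta * x
    w = np.exp(eta)
    loglik = score = info = 0.0
    for t in np.unique(time[event == 1]):
        risk = time >= t
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        s0 = w[risk].sum()
        s1 = (w[risk] * x[risk]).sum()
        s2 = (w[risk] * x[risk] ** 2).sum()
        loglik += eta[dying].sum()
        if ties == "breslow" or d == 1:
            for _ in range(d):
                loglik -= math.log(s0)
                score += -s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
        else:  # Efron: tied deaths progressively discount the tied set
            wd = w[dying].sum()
            wxd = (w[dying] * x[dying]).sum()
            wx2d = (w[dying] * x[dying] ** 2).sum()
            for k in range(d):
                f = k / d
                a0 = s0 - f * wd
                a1 = s1 - f * wxd
                a2 = s2 - f * wx2d
                loglik -= math.log(a0)
                score += -a1 / a0
                info += a2 / a0 - (a1 / a0) ** 2
    score += (x[event == 1]).sum()
    return loglik, score, info


def cox_fit(
    time,
    event,
    covariate,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Univariate Cox proportional-hazards fit by Newton-Raphson.

    Efron tie handling by default (``ties="breslow"`` for Breslow).
    Convergence when the step size falls below ``tol``; a monotone
    partial likelihood (perfect separation) is flagged via
    ``converged=False`` rather than silently returned.
    """
    time, event = _validate(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != time.shape:
        raise ValueError("covariate must align with time")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant; no hazard contrast to estimate")
    if event.sum() == 0:
        raise ValueError("Cox fit needs at least one event")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")

    # center for numerical stability; beta is unaffected
    x = x - x.mean()
    beta = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        _, score, info = _cox_derivatives(beta, time, event, x, ties)
        if info <= 0 or not np.isfinite(info):
            break
        step = score / info
        # dampen wild steps; diverging |beta| signals monotone likelihood
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(beta) > 25:
            break
        if abs(step) < tol:
            converged = True
            break

    _, _, info = _cox_derivatives(beta, time, event, x, ties)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    z = sps.norm.ppf(0.975)
    return CoxFit(
        beta=float(beta),
        se=float(se),
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),  # np.exp: inf-safe under separation
        ci_high=float(np.exp(beta + z * se)),
        iterations=iterations,
        converged=converged,
        n=int(time.size),
        n_events=int(event.sum()),
    )


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # max |standardized log-rank| over the grid
    candidates: np.ndarray
    statistics: np.ndarray
    minprop: float


def find_cutpoint(time, event, scores, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cutpoint over feasible thresholds.

    Candidates are midpoints between consecutive distinct scores; a
    candidate is feasible when both resulting groups contain at least
    ``minprop * n`` subjects. The chosen cutpoint maximizes the absolute
    standardized log-rank statistic |O - E| / sqrt(V); exact ties go to
    the lower threshold.
    """
    time, event = _validate(time, event)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != time.shape:
        raise ValueError("scores must align with time")
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct scores")

    n = scores.size
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = []
    statistics = []
    for c in midpoints:
        high = scores > c
        n_high = int(high.sum())
        if min(n_high, n - n_high) < minprop * n:
            continue
        o_minus_e, var, _ = _logrank_sums(
            time[high], event[high], time[~high], event[~high]
        )
        stat = abs(o_minus_e) / math.sqrt(var) if var > 0 else 0.0
        candidates.append(c)
        statistics.append(stat)
    if not candidates:
        raise ValueError("no feasible cutpoint under the minprop constraint")

    candidates = np.asarray(candidates)
    statistics = np.asarray(statistics)
    best = int(np.argmax(statistics))  # first max -> lowest threshold
    return CutpointResult(
        cutpoint=float(candidates[best]),
        statistic=float(statistics[best]),
        candidates=candidates,
        statistics=statistics,
        minprop=minprop,
    )


def median_split(scores) -> np.ndarray:
    """Dichotomize scores at the median: high means score > median.

    Subjects whose score equals the median land in the low group. All-
    identical scores admit no split and are rejected.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.all(scores == scores[0]):
        raise ValueError("all scores identical; no median split exists")
    med = float(np.median(scores))
    labels = np.where(scores > med, "high", "low")
    if len(np.unique(labels)) < 2:
        # e.g. scores {0,0,0,1}: median 0, but nothing above it on one side
        raise ValueError("median split leaves one group empty")
    return labels


@dataclass
class SurvivalResult:
    """High- vs low-ADI overall-survival comparison for one (sub)cohort."""

    method: str
    threshold: float
    n_high: int
    n_low: int
    events_high: int
    events_low: int
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogRankResult
    cox: CoxFit
    cutpoint: CutpointResult | None = None
    reliable: bool = True
    warnings: list[str] = field(default_factory=list)


def stratify_and_test(
    time,
    event,
    scores,
    method: str = "cutpoint",
    minprop: float = 0.1,
    subgroup_mask=None,
) -> SurvivalResult:
    """Stratify a cohort by ADI and compare overall survival.

    ``method`` is "cutpoint" (maximally selected log-rank threshold) or
    "median". An optional boolean ``subgroup_mask`` restricts the
    analysis (e.g. one sex or histology). Groups with fewer than 2
    events mark the result unreliable rather than failing.
    """
    time, event = _validate(time, event)
    scores = np.asarray(scores, dtype=float)
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        time, event, scores = time[mask], event[mask], scores[mask]
        if time.size < 2:
            raise ValueError("subgroup has fewer than 2 subjects")

    cut: CutpointResult | None = None
    if method == "cutpoint":
        cut = find_cutpoint(time, event, scores, minprop=minprop)
        threshold = cut.cutpoint
        high = scores > threshold
    elif method == "median":
        labels = median_split(scores)
        threshold = float(np.median(scores))
        high = labels == "high"
    else:
        raise ValueError(f"unknown stratification method {method!r}")

    warnings_: list[str] = []
    ev_high = int(event[high].sum())
    ev_low = int(event[~high].sum())
    reliable = True
    if min(ev_high, ev_low) < 2:
        reliable = False
        warnings_.append("a group has fewer than 2 events; estimates unreliable")

    logrank = logrank_test(time[high], event[high], time[~high], event[~high])
    cox = cox_fit(time, event, high.astype(float))
    return SurvivalResult(
        method=method,
        threshold=float(threshold),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        events_high=ev_high,
        events_low=ev_low,
        km_high=km_estimate(time[high], event[high]),
        km_low=km_estimate(time[~high], event[~high]),
        logrank=logrank,
        cox=cox,
        cutpoint=cut,
        reliable=reliable,
        warnings=warnings_,
    )
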