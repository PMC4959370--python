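"""Core right-censored survival statistics.

Implements the three primitives the screening and validation stages are
built on: the (unweighted) two-sample log-rank test, the Kaplan-Meier
product-limit estimator, and the hazard ratio for a single binary group
covariate.  The hazard ratio is estimated by maximizing the Cox partial
likelihood with Efron tie handling; the cruder Pike (O/E ratio) estimator
is available as an alternative and is also attached to every log-rank
result because it falls out of the same risk table.

All functions take plain numpy arrays of times (non-negative) and event
indicators (1 = event observed, 0 = right-censored).  Ties between an
event and a censoring at the same time are resolved with the standard
convention that events precede censoring, i.e. a subject censored at an
event time is still at risk for that event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LogRankResult",
    "KMCurve",
    "logrank",
    "hazard_ratio",
    "km_curve",
    "adjust_pvalues",
]

_BETA_BOUND = 15.0  # |log HR| cap; beyond this the MLE is effectively infinite


def _validate_arm(times, events, name: str):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError(f"{name}: times and events must be 1-D and equal length")
    if t.size == 0:
        raise ValueError(f"{name}: group is empty")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError(f"{name}: times must be finite and non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError(f"{name}: events must be binary 0/1")
    return t, e.astype(np.int64)


@dataclass(frozen=True)
class LogRankResult:
    """Two-sample log-rank test summary.

    ``observed``/``expected`` are per-group (A, B) event counts under the
    pooled risk sets; ``hazard_ratio`` is the Pike O/E-ratio estimate of
    the hazard of A relative to B (NaN when a group has no events), which
    is a by-product of the same risk table — use :func:`hazard_ratio` for
    the partial-likelihood estimate.
    """

    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    hazard_ratio: float
    degenerate: bool = False


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve.

    ``event_times`` are the distinct times with >= 1 observed event, in
    ascending order, with the survival probability immediately after each
    and the number at risk immediately before.  ``censor_times`` records
    the individual censoring times (for tick marks on plots).
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right")
        out = np.where(idx == 0, 1.0, self.survival_prob[np.maximum(idx - 1, 0)])
        return out


def _risk_table(times_a, events_a, times_b, events_b):
    """Pooled risk table at distinct event times.

    Returns (d, d1, n, n1): total deaths, group-A deaths, total at risk
    and group-A at risk at each distinct pooled event time.
    """
    ta, ea = times_a, events_a
    tb, eb = times_b, events_b
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones(ta.size, dtype=bool), np.zeros(tb.size, dtype=bool)])

    ut = np.unique(t[e == 1])
    if ut.size == 0:
        return (np.empty(0),) * 4
    # at risk just before each event time: subjects with time >= t
    n = (t[None, :] >= ut[:, None]).sum(axis=1).astype(float)
    n1 = ((t[None, :] >= ut[:, None]) & g[None, :]).sum(axis=1).astype(float)
    at = (t[None, :] == ut[:, None]) & (e[None, :] == 1)
    d = at.sum(axis=1).astype(float)
    d1 = (at & g[None, :]).sum(axis=1).astype(float)
    return d, d1, n, n1


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Unweighted two-sample log-rank (Mantel-Cox) test.

    The statistic is ``(O_A - E_A)^2 / V`` summed over the pooled distinct
    event times with the hypergeometric variance, referred to chi-square
    with 1 df.  With zero total events the comparison is degenerate and
    reported as statistic 0, p = 1 with ``degenerate=True``.
    """
    ta, ea = _validate_arm(times_a, events_a, "group A")
    tb, eb = _validate_arm(times_b, events_b, "group B")
    if ta.size < 2 or tb.size < 2:
        raise ValueError("each group needs >= 2 subjects")

    d, d1, n, n1 = _risk_table(ta, ea, tb, eb)
    if d.size == 0:
        return LogRankResult(0.0, 1.0, (0.0, 0.0), (0.0, 0.0), np.nan, degenerate=True)

    e1 = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(n > 1, d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1), 0.0)
    o1 = d1.sum()
    o2 = d.sum() - o1
    exp1 = e1.sum()
    exp2 = d.sum() - exp1
    var = v.sum()
    if var <= 0:
        # all events in risk sets of size 1, or one group already exhausted
        return LogRankResult(0.0, 1.0, (o1, o2), (exp1, exp2), np.nan, degenerate=True)
    stat = (o1 - exp1) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    if o1 > 0 and o2 > 0:
        hr_pike = (o1 / exp1) / (o2 / exp2)
    else:
        hr_pike = np.nan
    return LogRankResult(float(stat), p, (o1, o2), (exp1, exp2), float(hr_pike))


def _efron_terms(times_a, events_a, times_b, events_b):
    """Precompute per-event-time quantities for the binary-covariate
    Efron partial likelihood (covariate x=1 for group A)."""
    d, d1, n, n1 = _risk_table(times_a, events_a, times_b, events_b)
    keep = d > 0
    d, d1, n, n1 = d[keep], d1[keep], n[keep], n1[keep]
    # ragged l = 0..d_j-1 flattened
    reps = d.astype(int)
    idx = np.repeat(np.arange(d.size), reps)
    l_over_d = np.concatenate([np.arange(k) / k for k in reps]) if reps.size else np.empty(0)
    return d, d1, n, n1, idx, l_over_d


def _cox_nll_factory(times_a, events_a, times_b, events_b):
    d, d1, n, n1, idx, l_over_d = _efron_terms(times_a, events_a, times_b, events_b)
    sum_d1 = d1.sum()

    def nll(beta: float) -> float:
        eb = np.exp(beta)
        s = (n - n1) + n1 * eb          # risk-set score sum
        s_d = (d - d1) + d1 * eb        # tied-death score sum
        terms = np.log(s[idx] - l_over_d * s_d[idx])
        return float(terms.sum() - beta * sum_d1)

    return nll


def hazard_ratio(times_a, events_a, times_b, events_b, method: str = "cox") -> float:
    """Hazard ratio of group A relative to group B.

    method='cox' (default): MLE of exp(beta) under the Cox partial
    likelihood with a single binary covariate and Efron tie handling.
    method='pike': (O_A/E_A) / (O_B/E_B) from the log-rank risk table.

    Returns NaN when either group has zero events (the ratio is not
    identified); callers screening genes treat that as an exclusion flag.
    """
    ta, ea = _validate_arm(times_a, events_a, "group A")
    tb, eb = _validate_arm(times_b, events_b, "group B")
    if ea.sum() == 0 or eb.sum() == 0:
        return float("nan")
    if method == "pike":
        return logrank(ta, ea, tb, eb).hazard_ratio
    if method != "cox":
        raise ValueError(f"unknown hazard-ratio method: {method!r}")
    nll = _cox_nll_factory(ta, ea, tb, eb)
    res = optimize.minimize_scalar(
        nll, bounds=(-_BETA_BOUND, _BETA_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Subjects censored exactly at an event time remain at risk for that
    time.  The curve starts at S=1; ``survival_at`` evaluates the step
    function at arbitrary times.
    """
    t, e = _validate_arm(times, events, "sample")
    ut = np.unique(t[e == 1])
    if ut.size == 0:
        return KMCurve(
            event_times=np.empty(0), survival_prob=np.empty(0),
            at_risk=np.empty(0, dtype=np.int64), n_events=np.empty(0, dtype=np.int64),
            censor_times=np.sort(t[e == 0]),
        )
    n_at = (t[None, :] >= ut[:, None]).sum(axis=1)
    d = ((t[None, :] == ut[:, None]) & (e[None, :] == 1)).sum(axis=1)
    surv = np.cumprod(1.0 - d / n_at)
    return KMCurve(
        event_times=ut, survival_prob=surv, at_risk=n_at.astype(np.int64),
        n_events=d.astype(np.int64), censor_times=np.sort(t[e == 0]),
    )


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment ('bh' Benjamini-Hochberg step-up, or
    'bonferroni'), preserving input order.  NaNs pass through as NaN and
    do not count toward the number of tests."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        smethod = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
        if smethod is None:
            raise ValueError(f"unknown adjustment method: {method!r}")
        out[ok] = multipletests(p[ok], method=smethod)[1]
    return out
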