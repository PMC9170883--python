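"""Kaplan–Meier curves, log-rank tests, univariate Cox models, reverse-KM.

Kaplan–Meier estimation and Cox partial-likelihood fitting delegate to
lifelines.  The log-rank statistic is computed directly (observed minus
expected event counts with the hypergeometric variance) because the
cutpoint scan needs it vectorized over many candidate dichotomizations and
the result type exposes per-group observed/expected counts.

Conventions: times in months; at tied times events precede censorings
(both estimators); Cox uses Efron's tie approximation (the lifelines
default) and Wald confidence intervals on the log-hazard scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "km_curve",
    "survival_at",
    "km_median",
    "logrank_test",
    "logrank_chi2_scan",
    "cox_univariate",
    "reverse_km_followup",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray  # distinct times with >=1 event, ascending
    survival_probs: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    censor_times: np.ndarray  # individual censoring times, ascending
    max_observed: float  # largest observed time (event or censoring)


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray  # per-group expected events under H0
    df: int


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and nonnegative")
    return t, e


def km_curve(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev_times = table.index.values[mask].astype(float)
    sf = kmf.survival_function_["KM_estimate"]
    probs = sf.loc[ev_times].to_numpy(dtype=float)
    at_risk = table["at_risk"][mask].to_numpy(dtype=float)
    return KMCurve(
        event_times=ev_times,
        survival_probs=probs,
        at_risk=at_risk,
        censor_times=np.sort(t[~e]),
        max_observed=float(t.max()),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous S(t); warns when extrapolating past the last observation."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t > curve.max_observed:
        warnings.warn(
            f"survival queried at t={t:g} beyond the last observed time "
            f"{curve.max_observed:g}; returning the last estimate",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.event_times, t, side="right")
    if idx == 0:
        return 1.0
    return float(curve.survival_probs[idx - 1])


def km_median(curve: KMCurve) -> Optional[float]:
    """Smallest event time with S(t) <= 0.5, or None if never reached."""
    below = curve.survival_probs <= 0.5
    if not below.any():
        return None
    return float(curve.event_times[np.argmax(below)])


def _logrank_oe(times: np.ndarray, events: np.ndarray, labels: np.ndarray):
    """Per-group observed/expected events and the full covariance matrix."""
    groups = np.unique(labels)
    k = groups.size
    ev_times = np.unique(times[events])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in ev_times:
        at_risk = times >= tt
        n = at_risk.sum()
        d = (events & (times == tt)).sum()
        ng = np.array([(at_risk & (labels == g)).sum() for g in groups], dtype=float)
        dg = np.array(
            [(events & (times == tt) & (labels == g)).sum() for g in groups],
            dtype=float,
        )
        observed += dg
        expected += d * ng / n
        if n > 1:
            frac = ng / n
            c = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += c
    return groups, observed, expected, cov


def logrank_test(groups: Sequence[tuple]) -> LogRankResult:
    """k-sample log-rank test; ``groups`` is a sequence of (times, events).

    The chi-square is u' V^- u over the first k-1 groups' observed-minus-
    expected vector with the summed hypergeometric covariance.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    parts = [_as_arrays(t, e) for t, e in groups]
    labels = np.concatenate(
        [np.full(t.size, i) for i, (t, _) in enumerate(parts)]
    )
    times = np.concatenate([t for t, _ in parts])
    events = np.concatenate([e for _, e in parts])
    if events.sum() == 0:
        raise ValueError("no events in any group")

    _, observed, expected, cov = _logrank_oe(times, events, labels)
    u = (observed - expected)[:-1]
    V = cov[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(V) @ u)
    df = len(groups) - 1
    return LogRankResult(
        chi_square=chi2,
        p_value=float(stats.chi2.sf(chi2, df)),
        observed=observed,
        expected=expected,
        df=df,
    )


def logrank_chi2_scan(
    times: np.ndarray, events: np.ndarray, marker: np.ndarray, cutoffs: np.ndarray
) -> np.ndarray:
    """Two-group log-rank chi-squares for every split ``marker <= cutoff``.

    Vectorized over cutoffs with one O(n log n) precomputation; degenerate
    splits (zero variance) get chi-square 0.
    """
    t, e = _as_arrays(times, events)
    m = np.asarray(marker, dtype=float)
    order = np.argsort(t, kind="stable")
    t_s, e_s, m_s = t[order], e[order], m[order]
    n = t_s.size

    ev_times = np.unique(t_s[e_s])
    start = np.searchsorted(t_s, ev_times, side="left")  # at-risk start index
    n_at = n - start
    ev_rows = np.flatnonzero(e_s)
    pos = np.searchsorted(ev_times, t_s[ev_rows])  # event-time bin per event row
    d_tot = np.bincount(pos, minlength=ev_times.size).astype(float)

    chi2s = np.empty(len(cutoffs))
    for i, c in enumerate(np.asarray(cutoffs, dtype=float)):
        g = (m_s <= c).astype(float)
        csum = np.concatenate(([0.0], np.cumsum(g)))
        n1 = g.sum() - csum[start]  # group-1 members at risk at each event time
        d1 = np.bincount(pos, weights=g[ev_rows], minlength=ev_times.size)
        frac = n1 / n_at
        oe = d1.sum() - (d_tot * frac).sum()
        valid = n_at > 1
        var = np.sum(
            d_tot[valid]
            * frac[valid]
            * (1.0 - frac[valid])
            * (n_at[valid] - d_tot[valid])
            / (n_at[valid] - 1.0)
        )
        chi2s[i] = (oe * oe / var) if var > 0 else 0.0
    return chi2s


def cox_univariate(indicator, times, events) -> CoxResult:
    """Univariate Cox PH hazard ratio for a binary indicator (Efron ties).

    If either indicator level has no events the partial likelihood is
    monotone; a warning is issued and a small L2 penalty stabilizes the fit.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(indicator, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("indicator must take two distinct values")
    if e.sum() == 0:
        raise ValueError("no events observed")

    penalizer = 0.0
    for level in np.unique(x):
        if e[x == level].sum() == 0:
            warnings.warn(
                "one indicator level has no events: the partial likelihood is "
                "monotone; fitting with a small L2 penalty",
                stacklevel=2,
            )
            penalizer = 0.1
    df = pd.DataFrame({"x": x, "T": t, "E": e.astype(int)})
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="T", event_col="E")
    s = cph.summary.loc["x"]
    return CoxResult(
        hazard_ratio=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p_value=float(s["p"]),
        n_events=int(e.sum()),
    )


def reverse_km_followup(times, events) -> Optional[float]:
    """Median follow-up by reverse Kaplan–Meier (censorings become events).

    Returns ``None`` when no observation is censored (the estimate is
    undefined) or when the reversed curve never reaches 0.5.
    """
    t, e = _as_arrays(times, events)
    if (~e).sum() == 0:
        return None
    curve = km_curve(t, ~e)
    return km_median(curve)
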