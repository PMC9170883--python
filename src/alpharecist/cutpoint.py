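"""Maximally selected log-rank cutpoint search for continuous markers.

Given a continuous marker (e.g. the fractional AFP change) and a censored
endpoint, every admissible dichotomization ``marker <= c`` vs ``> c`` is
scored by the two-group log-rank chi-square and the maximizing cutoff is
returned.  This is the standard, auditable equivalent of cutoff-optimizing
tools used in clinical biomarker work: candidates are midpoints between
consecutive distinct marker values, restricted so each side keeps at least
``floor(min_frac * n)`` patients (default 10%).

Because the cutoff is selected to maximize the statistic, the naive
chi-square p-value is anti-conservative; the Miller–Siegmund approximation
corrects for the selection over the scanned quantile range and is reported
alongside.

Orientation is the caller's concern: the scan is invariant to which side
is called "response" (the chi-square is symmetric), so a cutoff of -0.76
on the AFP change supports either reading of the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .survival import logrank_chi2_scan

__all__ = [
    "CutpointResult",
    "candidate_cutpoints",
    "optimal_cutpoint",
    "miller_siegmund_p",
    "NoValidCutpointError",
]


class NoValidCutpointError(ValueError):
    """No admissible split exists (e.g. all marker values identical)."""


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    chi_square: float
    naive_p: float
    corrected_p: Optional[float]
    candidates: np.ndarray  # admissible cutoffs, ascending
    chi_squares: np.ndarray  # log-rank chi-square per candidate
    group_sizes: tuple[int, int]  # (n <= cutoff, n > cutoff)


def candidate_cutpoints(values, min_frac: float = 0.10) -> np.ndarray:
    """Admissible cutoffs: midpoints between consecutive distinct values.

    A cutoff is admissible when both induced groups keep at least
    ``floor(min_frac * n)`` (and at least 1) members.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least two marker values")
    if not (0.0 <= min_frac < 0.5):
        raise ValueError("min_frac must lie in [0, 0.5)")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise NoValidCutpointError("all marker values are identical")
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    n = v.size
    floor_size = max(1, int(np.floor(min_frac * n)))
    n_low = np.searchsorted(np.sort(v), mids, side="right")
    ok = (n_low >= floor_size) & ((n - n_low) >= floor_size)
    if not ok.any():
        raise NoValidCutpointError(
            f"no split keeps >= {floor_size} patients on both sides"
        )
    return mids[ok]


def miller_siegmund_p(
    chi_square: float, eps_low: float, eps_high: float
) -> float:
    """Selection-corrected p-value for a maximally selected chi-square.

    ``eps_low``/``eps_high`` are the marker quantile fractions of the
    smallest and largest scanned cutoff.  The approximation is clamped to
    [naive p, 1]; it is conservative for small statistics.
    """
    if not (0.0 < eps_low < eps_high < 1.0):
        raise ValueError("need 0 < eps_low < eps_high < 1")
    b = float(np.sqrt(chi_square))
    naive = float(stats.chi2.sf(chi_square, 1))
    if b <= 1.0:
        return 1.0
    phi = stats.norm.pdf(b)
    span = np.log(eps_high * (1.0 - eps_low) / (eps_low * (1.0 - eps_high)))
    p = phi * (b - 1.0 / b) * span + 4.0 * phi / b
    return float(min(1.0, max(naive, p)))


def optimal_cutpoint(
    values,
    times,
    events,
    min_frac: float = 0.10,
    correction: bool = True,
) -> CutpointResult:
    """Exhaustive maximally selected log-rank scan.

    Ties in the maximal chi-square break toward the more balanced split,
    then toward the smaller cutoff.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (v.size == t.size == e.size):
        raise ValueError("values, times and events must have equal length")
    if e.sum() == 0:
        raise ValueError("no events observed; the log-rank scan is undefined")

    cands = candidate_cutpoints(v, min_frac=min_frac)
    chi2s = logrank_chi2_scan(t, e, v, cands)

    best = chi2s.max()
    tied = np.flatnonzero(np.isclose(chi2s, best, rtol=1e-12, atol=1e-12))
    n = v.size
    sorted_v = np.sort(v)
    n_low = np.searchsorted(sorted_v, cands[tied], side="right")
    balance = np.abs(n_low - n / 2.0)
    # most balanced split first, then smallest cutoff
    pick = tied[np.lexsort((cands[tied], balance))[0]]

    cutoff = float(cands[pick])
    chi2 = float(chi2s[pick])
    naive = float(stats.chi2.sf(chi2, 1))
    corrected = None
    if correction:
        eps_low = np.searchsorted(sorted_v, cands[0], side="right") / n
        eps_high = np.searchsorted(sorted_v, cands[-1], side="right") / n
        corrected = miller_siegmund_p(chi2, eps_low, eps_high)

    n_low_pick = int(np.searchsorted(sorted_v, cutoff, side="right"))
    return CutpointResult(
        cutoff=cutoff,
        chi_square=chi2,
        naive_p=naive,
        corrected_p=corrected,
        candidates=cands,
        chi_squares=chi2s,
        group_sizes=(n_low_pick, n - n_low_pick),
    )
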