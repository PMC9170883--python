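"""Inter-reader agreement, pathologic response bins, and rank correlation.

Weighted Cohen's kappa uses similarity weights over the fixed category
order CR < PR < SD < PD: ``w_ij = 1 - |i-j|/(k-1)`` (linear, the default)
or ``1 - (|i-j|/(k-1))^2`` (quadratic).  When only two categories occur,
the weighted kappa equals the unweighted one for any scheme (numerator and
denominator both scale by the single off-diagonal weight complement), so
two-category results are scheme-invariant.

The kappa confidence interval is the Fleiss–Cohen–Everitt large-sample
standard error; the upper bound is *not* truncated at 1 by default, which
mirrors how such intervals are commonly printed in radiology agreement
tables (a ``truncate`` flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .criteria import ResponseCategory

__all__ = [
    "CATEGORY_ORDER",
    "ConfusionMatrix",
    "KappaResult",
    "PathologyCategory",
    "confusion_matrix",
    "weighted_kappa",
    "pathologic_category",
    "spearman_correlation",
    "SpearmanResult",
]

CATEGORY_ORDER = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # 4x4, rows = reader A, cols = reader B
    categories: tuple[str, ...] = CATEGORY_ORDER
    reader_a: str = "reader1"
    reader_b: str = "reader2"

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percent_agreement(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    weighting: str
    percent_agreement: float


class PathologyCategory:
    COMPLETE = "complete"  # no residual cancer cells
    MAJOR = "major"  # under half the tumor viable
    MINOR = "minor"  # half or more viable


def _to_name(rating) -> str:
    if isinstance(rating, ResponseCategory):
        return rating.name
    s = str(rating).strip().upper()
    if s not in CATEGORY_ORDER:
        raise ValueError(f"unknown response category {rating!r}")
    return s


def confusion_matrix(
    ratings_a: Sequence, ratings_b: Sequence,
    reader_a: str = "reader1", reader_b: str = "reader2",
) -> ConfusionMatrix:
    """4x4 cross-tabulation of two readers' ordered categories."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    idx = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    counts = np.zeros((4, 4), dtype=int)
    for a, b in zip(ratings_a, ratings_b):
        counts[idx[_to_name(a)], idx[_to_name(b)]] += 1
    return ConfusionMatrix(counts=counts, reader_a=reader_a, reader_b=reader_b)


def _weights(k: int, weighting: str) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    if weighting == "linear":
        return 1.0 - d
    if weighting == "quadratic":
        return 1.0 - d**2
    if weighting == "none":
        return (d == 0).astype(float)
    raise ValueError(f"unknown weighting {weighting!r}")


def weighted_kappa(
    matrix: ConfusionMatrix,
    weighting: str = "linear",
    alpha: float = 0.05,
    truncate: bool = False,
) -> KappaResult:
    """Weighted Cohen's kappa with a large-sample Wald interval.

    Raises when both readers put all mass in a single shared category
    (chance agreement 1, kappa undefined).
    """
    counts = matrix.counts.astype(float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    k = counts.shape[0]
    w = _weights(k, weighting)
    p = counts / n
    pa = p.sum(axis=1)  # reader A marginals
    pb = p.sum(axis=0)
    po_w = float((w * p).sum())
    pe_w = float((w * np.outer(pa, pb)).sum())
    if np.isclose(pe_w, 1.0):
        raise ValueError(
            "degenerate table: all mass in one category for both readers; "
            "kappa is undefined"
        )
    kappa = (po_w - pe_w) / (1.0 - pe_w)

    # Fleiss–Cohen–Everitt large-sample variance of weighted kappa
    wbar_a = w @ pb  # row-wise expected weight for reader A's categories
    wbar_b = pa @ w
    term = w - np.add.outer(wbar_a, wbar_b) * (1.0 - kappa)
    var = (
        (p * term**2).sum() - (kappa - pe_w * (1.0 - kappa)) ** 2
    ) / (n * (1.0 - pe_w) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = kappa - z * se, kappa + z * se
    if truncate:
        lo, hi = max(lo, -1.0), min(hi, 1.0)
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(lo),
        ci_high=float(hi),
        weighting=weighting,
        percent_agreement=matrix.percent_agreement,
    )


def pathologic_category(percent_viable: float) -> str:
    """Bin the residual-viable-tumor fraction of the resected specimen.

    ``complete`` = no residual cancer cells; ``major`` = any residual up
    to (but excluding) half; ``minor`` = half or more.  Fractions strictly
    between 0 and 1% count as major.
    """
    pv = float(percent_viable)
    if not (0.0 <= pv <= 1.0) or not np.isfinite(pv):
        raise ValueError("percent_viable must lie in [0, 1]")
    if pv == 0.0:
        return PathologyCategory.COMPLETE
    if pv < 0.50:
        return PathologyCategory.MAJOR
    return PathologyCategory.MINOR


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def spearman_correlation(x, y, alpha: float = 0.05) -> SpearmanResult:
    """Mid-rank Spearman correlation with a Fisher-z confidence interval.

    For two binary vectors this equals the phi coefficient of the 2x2
    table.  The Fisher-z interval (se = 1/sqrt(n-3)) is a standard
    approximation, adequate away from |rho| = 1.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise ValueError("zero variance in one of the vectors; rho undefined")
    rho, p = stats.spearmanr(xv, yv)
    z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / np.sqrt(xv.size - 3)
    return SpearmanResult(
        rho=float(rho),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        p_value=float(p),
        n=int(xv.size),
    )
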