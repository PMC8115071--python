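"""Classical statistics used alongside the Bayesian machinery.

Spearman correlation, Mann-Whitney tests, OLS with r-squared, 95%
confidence (data) ellipses and per-group neuron-count summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from oxprof.errors import DataError, DegenerateDesignError


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Two-sided p: exact permutation enumeration for n <= 9, t approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise DataError("spearman requires equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # enumerate all pairings of the observed rank vectors
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        perm_c = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c**2).sum() * (perm_c**2).sum(axis=1))
        r_all = perm_c @ rx_c / denom
        p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test.

    U counts (a, b) pairs with a > b plus half the ties.  p is exact (full
    null distribution) when n_a * n_b <= 400 and there are no ties; a
    normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def linreg_r2(x, y) -> tuple[float, float, float, float]:
    """OLS slope/intercept with r^2 and two-sided p on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("linreg requires equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("no spread in x")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


@dataclass
class EllipseSpec:
    """Confidence ellipse of a 2-D scatter (mean + covariance form)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_rad: float  # orientation of the major axis
    level: float
    k2: float  # squared Mahalanobis radius

    def contains(self, points: np.ndarray, cov_inv: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - np.asarray(self.center)
        m2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
        return m2 <= self.k2


def confidence_ellipse(points, level: float = 0.95, form: str = "chi2") -> EllipseSpec:
    """Data ellipse from the sample mean and covariance.

    ``form='chi2'`` uses the chi-square(2) quantile (5.991 at 0.95);
    ``form='f'`` the small-sample F-based multiplier.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DataError("need an (n, 2) array with n >= 3")
    if not 0.0 < level < 1.0:
        raise DataError("level must lie in (0, 1)")
    n = pts.shape[0]
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise DegenerateDesignError("singular covariance: degenerate scatter")
    if form == "chi2":
        k2 = float(stats.chi2.ppf(level, 2))
    elif form == "f":
        k2 = float(2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2))
    else:
        raise DataError(f"unknown ellipse form {form!r}")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi = tuple(float(np.sqrt(v * k2)) for v in eigval)
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return EllipseSpec(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=semi,
        angle_rad=angle,
        level=level,
        k2=k2,
    )


@dataclass
class CountSummary:
    group: str
    counts: list[int]
    mean: float
    sd: float
    total: int


def summarize_counts(counts_by_group: dict[str, list[int]]) -> dict[str, CountSummary]:
    """Per-group mean, sample SD (n-1) and total of per-case neuron counts."""
    out = {}
    for group, counts in counts_by_group.items():
        if len(counts) < 1:
            raise DataError(f"group {group!r} has no cases")
        arr = np.asarray(counts, dtype=float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        out[group] = CountSummary(
            group=group,
            counts=[int(c) for c in counts],
            mean=float(arr.mean()),
            sd=sd,
            total=int(arr.sum()),
        )
    return out
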