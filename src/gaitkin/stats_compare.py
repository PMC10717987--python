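"""Statistical comparison layer for the two-marker-set gait study.

Covers the analyses a marker-set comparison needs: Shapiro–Wilk normality
checks, paired t-tests (between-model and MAV comparisons on the same
subjects), independent t-tests (between-group comparisons), point-by-point
paired testing along the 101-point normalized gait cycle, and the a-priori
sample-size computation for an independent two-sample t-test via the
noncentral t distribution.

The t statistics are computed in closed form here (they are two lines
each), and the test suite cross-checks them against scipy's reference
implementations; Shapiro–Wilk delegates to :func:`scipy.stats.shapiro`.
Point-wise comparisons report raw (uncorrected) significance counts at
``alpha``, matching how point counts are conventionally reported; Holm or
Benjamini–Hochberg correction is available as an option for reuse outside
that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    n: int


@dataclass
class PointwiseComparison:
    """Per-point paired tests along the normalized gait cycle."""

    p_values: np.ndarray           # (101,)
    significant_mask: np.ndarray   # (101,) bool, p < alpha
    n_significant_points: int
    alpha: float


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------

def _as_sample(x, min_n: int, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_n:
        raise InvalidParameterError(f"{label} needs n >= {min_n}, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError(f"{label} contains non-finite values")
    return x


def shapiro_wilk(x) -> TestResult:
    """Shapiro–Wilk W test of normality (3 <= n <= 5000)."""
    x = _as_sample(x, 3, "Shapiro-Wilk sample")
    if len(x) > 5000:
        raise InvalidParameterError("Shapiro-Wilk supports n <= 5000")
    if np.ptp(x) == 0:
        raise InvalidParameterError("Shapiro-Wilk undefined for a zero-variance sample")
    w, p = stats.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), df=float(len(x)), n=len(x))


def paired_t(a, b) -> TestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    a = _as_sample(a, 2, "paired sample a")
    b = _as_sample(b, 2, "paired sample b")
    if len(a) != len(b):
        raise InvalidParameterError("paired samples must have equal length")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise InvalidParameterError("zero-variance differences: paired t undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), p_value=float(p), df=float(n - 1), n=n)


def independent_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided independent two-sample t-test (pooled or Welch)."""
    a = _as_sample(a, 2, "sample a")
    b = _as_sample(b, 2, "sample b")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise InvalidParameterError("both samples have zero variance")
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        sa, sb = va / na, vb / nb
        se = np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(p), df=float(df), n=na + nb)


# ---------------------------------------------------------------------------
# Point-wise gait-curve comparison
# ---------------------------------------------------------------------------

def _curve_matrix(curves, label: str):
    """(subject keys or None, (n_subjects, 101) array) from dict or array."""
    if isinstance(curves, dict):
        keys = tuple(sorted(curves))
        return keys, np.array([np.asarray(curves[k], dtype=float) for k in keys])
    arr = np.asarray(curves, dtype=float)
    if arr.ndim != 2:
        raise InvalidParameterError(f"{label} must be (n_subjects, n_points)")
    return None, arr


def pointwise_compare(curves_m1, curves_m2, alpha: float = DEFAULT_ALPHA,
                      correction: str | None = None) -> PointwiseComparison:
    """Paired t-test at every normalized cycle point across subjects.

    ``curves_m1`` / ``curves_m2`` hold one curve per subject under each
    model condition, as ``{subject: (101,)}`` dicts (keys must match) or
    aligned 2-D arrays.  Points with zero-variance differences are reported
    as non-significant when the conditions agree there (p = 1) and as
    maximally significant when they differ by an exact constant (p = 0).
    """
    k1, m1 = _curve_matrix(curves_m1, "curves_m1")
    k2, m2 = _curve_matrix(curves_m2, "curves_m2")
    if k1 != k2:
        raise InvalidParameterError("subject sets differ between model conditions")
    if m1.shape != m2.shape:
        raise InvalidParameterError(f"curve matrices differ in shape: {m1.shape} vs {m2.shape}")
    if m1.shape[0] < 2:
        raise InvalidParameterError("pointwise comparison needs >= 2 subjects")

    n_points = m1.shape[1]
    p = np.empty(n_points)
    for k in range(n_points):
        try:
            p[k] = paired_t(m1[:, k], m2[:, k]).p_value
        except InvalidParameterError:
            p[k] = 1.0 if np.allclose(m1[:, k], m2[:, k]) else 0.0
    if correction is not None:
        p = _adjust(p, correction)
    mask = p < alpha
    return PointwiseComparison(p_values=p, significant_mask=mask,
                               n_significant_points=int(mask.sum()), alpha=alpha)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise InvalidParameterError(f"unknown correction {method!r} (use 'holm' or 'bh')")
    return multipletests(p, method=key)[1]


def normality_warning(samples: dict[str, np.ndarray],
                      alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Shapiro–Wilk screen; t-tests are still used, non-normality is logged."""
    flagged = []
    for name, x in samples.items():
        try:
            if shapiro_wilk(x).p_value < alpha:
                flagged.append(name)
        except InvalidParameterError:
            continue
    if flagged:
        warnings.warn("normality rejected (Shapiro-Wilk, alpha="
                      f"{alpha}) for: {', '.join(flagged)}; t-tests reported anyway",
                      stacklevel=2)
    return flagged


# ---------------------------------------------------------------------------
# Power / sample size
# ---------------------------------------------------------------------------

def power_two_sample(n_per_group: int, effect_size_d: float,
                     alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the independent two-sample t-test via the noncentral t."""
    if n_per_group < 2:
        raise InvalidParameterError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    ncp = effect_size_d * np.sqrt(n_per_group / 2.0)
    if tails == 1:
        tc = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tc, df, ncp))
    if tails == 2:
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    raise InvalidParameterError("tails must be 1 or 2")


_MAX_N_PER_GROUP = 1_000_000


def power_n_two_sample(effect_size_d: float, alpha: float = 0.05,
                       power: float = 0.80, tails: int = 2) -> int:
    """Smallest total N (two equal groups) reaching the target power.

    A-priori sample size for the independent two-sample t-test: group sizes
    are increased until the noncentral-t power at effect size ``d`` meets
    ``power``.  Returns the total N (both groups).
    """
    if not (effect_size_d > 0):
        raise InvalidParameterError("effect size d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidParameterError("alpha and power must lie in (0, 1)")
    for n in range(2, _MAX_N_PER_GROUP + 1):
        if power_two_sample(n, effect_size_d, alpha, tails) >= power:
            return 2 * n
    raise InvalidParameterError(
        f"target power {power} unattainable below N={2 * _MAX_N_PER_GROUP}")
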