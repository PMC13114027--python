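"""Inferential layer: Pearson and partial correlation, t-tests, Bonferroni.

Partial correlation is computed by residualization: both variables are
regressed (ordinary least squares, with intercept) on the covariates, and
the Pearson correlation of the residuals is taken.  Significance uses the
exact t transform ``t = r sqrt(df / (1 - r^2))`` with ``df = n - 2 - k``
covariate-adjusted degrees of freedom; the two-sided p-value comes from
the Student t distribution.  Family-wise error over a grid of tests is
controlled by Bonferroni division of the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TestFamily",
    "TTestResult",
    "pearson",
    "partial_correlation",
    "two_sample_t",
    "bonferroni",
    "apply_bonferroni",
    "p_value_from_r",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A (partial) correlation with its exact t-based significance test."""

    r: float
    n: int
    k: int
    df: int
    t_stat: float
    p: float
    significant_raw: bool | None = None
    significant_bonferroni: bool | None = None


@dataclass(frozen=True)
class TestFamily:
    """A family of m tests controlled at family-wise level alpha."""

    __test__ = False  # not a pytest case, despite the name

    alpha: float = 0.05
    m: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be at least 1")

    @property
    def corrected_threshold(self) -> float:
        return self.alpha / self.m


def p_value_from_r(r: float, n: int, k: int = 0) -> float:
    """Two-sided p-value for a (partial) correlation via the t transform."""
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"insufficient degrees of freedom: n={n}, k={k}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def _validate_vector(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if len(a) < 3:
        raise ValueError(f"{name} needs at least 3 observations, got {len(a)}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    if np.ptp(a) == 0:
        raise ValueError(f"{name} has zero variance; correlation undefined")
    return a


def _result(r: float, n: int, k: int, family: TestFamily | None) -> CorrelationResult:
    df = n - 2 - k
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    res = CorrelationResult(r=r, n=n, k=k, df=df, t_stat=float(t), p=p)
    if family is not None:
        res = replace(
            res,
            significant_raw=p < family.alpha,
            significant_bonferroni=p < family.corrected_threshold,
        )
    return res


def pearson(x, y, family: TestFamily | None = None) -> CorrelationResult:
    """Product-moment correlation with a two-sided t test (df = n - 2)."""
    xa = _validate_vector(x, "x")
    ya = _validate_vector(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return _result(r, len(xa), 0, family)


def partial_correlation(
    x, y, covariates=None, family: TestFamily | None = None
) -> CorrelationResult:
    """Correlation of x and y after removing linear effects of covariates.

    Residualizes both variables on ``[1, covariates]`` by least squares
    and correlates the residuals; ``df = n - 2 - k``.  With no covariates
    this reduces exactly to :func:`pearson`.
    """
    xa = _validate_vector(x, "x")
    ya = _validate_vector(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if covariates is None:
        return pearson(xa, ya, family)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != len(xa):
        raise ValueError(f"covariates have {Z.shape[0]} rows for n={len(xa)}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("covariates contain non-finite values")
    n, k = Z.shape
    if k == 0:
        return pearson(xa, ya, family)
    if n < k + 4:
        raise ValueError(f"need n >= k + 4 observations, got n={n}, k={k}")

    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < k + 1:
        for j in range(k):
            if np.linalg.matrix_rank(design[:, : j + 2]) < j + 2:
                raise ValueError(
                    f"covariate column {j} is collinear with the preceding columns"
                )
    rx = xa - design @ np.linalg.lstsq(design, xa, rcond=None)[0]
    ry = ya - design @ np.linalg.lstsq(design, ya, rcond=None)[0]
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return _result(r, n, k, family)


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p: float
    welch: bool = False


def two_sample_t(a, b, welch: bool = False) -> TTestResult:
    """Two-sample t-test; Student pooled-variance by default, Welch by flag."""
    aa = np.asarray(a, dtype=float).ravel()
    ba = np.asarray(b, dtype=float).ravel()
    if len(aa) < 2 or len(ba) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(aa)) and np.all(np.isfinite(ba))):
        raise ValueError("groups contain non-finite values")
    res = sps.ttest_ind(aa, ba, equal_var=not welch)
    df = res.df if hasattr(res, "df") else (len(aa) + len(ba) - 2)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), welch)


def bonferroni(family: TestFamily) -> float:
    """Corrected per-test significance threshold alpha / m."""
    return family.corrected_threshold


def apply_bonferroni(
    results: list[CorrelationResult], family: TestFamily
) -> list[CorrelationResult]:
    """Flag raw and family-wise significance on each result."""
    thr = family.corrected_threshold
    return [
        replace(r, significant_raw=r.p < family.alpha, significant_bonferroni=r.p < thr)
        for r in results
    ]
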