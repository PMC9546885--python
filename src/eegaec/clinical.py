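"""Clinical associations and cohort descriptive statistics.

Covers the statistics run outside the connectivity contrast itself:

* Monte-Carlo permutation tests of the Pearson correlation between
  extracted AEC values and clinical covariates (AEC values are bounded and
  typically non-normal, so a permutation null is used instead of the
  t-approximation), with BH-FDR applied across the covariate family;
* an overall-F linear model (ANCOVA-style) checking whether an
  association survives adjustment for demographic covariates;
* Welch t-tests computed from printed summary statistics (mean, SD, n per
  group) and chi-square tests of independence for categorical
  demographics, the tests used for cohort description tables.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .group_stats import bh_fdr

__all__ = [
    "perm_pearson",
    "clinical_correlations",
    "linear_model_f",
    "welch_t_summary",
    "chisq_independence",
    "LinearModelResult",
]


def perm_pearson(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Pearson r with a two-tailed Monte-Carlo permutation p-value.

    The null is built by permuting ``y``; p uses the add-one estimator
    (1 + #{|r*| >= |r|}) / (1 + n_perm), so the smallest attainable p is
    1/(1 + n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("x and y must be equal-length vectors of length >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))

    rng = np.random.default_rng(seed)
    perm = np.broadcast_to(yc, (n_perm, y.size)).copy()
    perm = rng.permuted(perm, axis=1)
    r_null = np.abs(perm @ xc) / (nx * ny)
    p = (1.0 + np.count_nonzero(r_null >= abs(r) - 1e-12)) / (1.0 + n_perm)
    return r, float(p)


def clinical_correlations(
    aec_values: np.ndarray,
    covariates: pd.DataFrame,
    columns: list[str],
    n_perm: int = 10000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Permutation Pearson r of AEC against each covariate, FDR-corrected.

    Rows with missing covariate values are dropped pairwise; the BH step-up
    runs over the listed covariate family.
    """
    rows = []
    for k, col in enumerate(columns):
        v = pd.to_numeric(covariates[col], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(v) & np.isfinite(aec_values)
        r, p = perm_pearson(
            aec_values[mask], v[mask], n_perm=n_perm, seed=seed + k
        )
        rows.append({"covariate": col, "n": int(mask.sum()), "r": r, "p": p})
    out = pd.DataFrame(rows)
    reject, thr = bh_fdr(out["p"].to_numpy(), q)
    out["fdr_reject"] = reject
    out.attrs["fdr_threshold"] = thr
    return out


class LinearModelResult(NamedTuple):
    f: float
    df1: int
    df2: int
    p: float
    r_squared: float
    overflow: bool


def linear_model_f(y: np.ndarray, x: pd.DataFrame) -> LinearModelResult:
    """Overall F of an OLS fit of ``y`` on intercept + predictors.

    Categorical columns are expanded to indicator columns (first level
    dropped).  A perfect fit (R^2 = 1) cannot produce a finite F and is
    reported with the ``overflow`` flag set.
    """
    y = np.asarray(y, dtype=float)
    x = pd.DataFrame(x).copy()
    design = pd.get_dummies(x, drop_first=True, dtype=float)
    n, k = design.shape
    if n <= k + 1:
        raise ValueError(f"need n > predictors + 1 (n={n}, predictors={k})")
    mat = np.column_stack([np.ones(n), design.to_numpy()])
    rank = np.linalg.matrix_rank(mat)
    if rank < k + 1:
        # name a dependent column for the error message
        for j, col in enumerate(design.columns):
            sub = np.delete(mat, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"design is rank-deficient: column {col!r}")
        raise ValueError("design is rank-deficient")
    fit = sm.OLS(y, mat).fit()
    df1, df2 = k, n - k - 1
    r2 = float(fit.rsquared)
    if r2 >= 1.0 - 1e-12:
        return LinearModelResult(np.inf, df1, df2, 0.0, r2, True)
    return LinearModelResult(
        float(fit.fvalue), df1, df2, float(fit.f_pvalue), r2, False
    )


def welch_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Welch t and Welch–Satterthwaite df from per-group summary statistics."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("both group variances are zero")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df)


def chisq_independence(
    counts: np.ndarray, yates: bool = True
) -> tuple[float, int]:
    """Pearson chi-square test of independence on a contingency table.

    Yates' continuity correction is applied by default on 2x2 tables (and
    only there); larger tables always use the plain Pearson statistic.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    use_correction = bool(yates) and counts.shape == (2, 2)
    chi2, _, dof, _ = scipy.stats.chi2_contingency(
        counts, correction=use_correction
    )
    return float(chi2), int(dof)
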