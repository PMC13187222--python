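"""Questionnaire scoring and the univariate statistics used across the pipeline.

Cohen's d uses the pooled standard deviation, so effect sizes reported from
group means/SDs/ns (the usual table format) can be reproduced exactly.
The Welch t statistic with Satterthwaite degrees of freedom is the default
two-group test, robust regression inference uses HC3 sandwich standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from scalenet.types import ResponseMatrix


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_values(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass
class RegressionFit:
    """OLS fit with HC3 heteroscedasticity-consistent standard errors."""

    b: np.ndarray
    se_hc3: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    leverage: np.ndarray
    residuals: np.ndarray


def score_total(
    matrix: ResponseMatrix,
    items: list[str] | None = None,
    reverse: set[str] | frozenset[str] = frozenset(),
) -> np.ndarray:
    """Sum-score the given items, reverse-coding items in ``reverse`` as 8 - x.

    Parameters
    ----------
    matrix : ResponseMatrix
        Ratings in 1..7.
    items : list of item ids, optional
        Items entering the total (default: all items, in matrix order).
    reverse : set of item ids
        Items scored on the reversed scale.

    Returns
    -------
    ndarray of per-participant totals.
    """
    if items is None:
        items = list(matrix.item_ids)
    total = np.zeros(matrix.n_participants, dtype=float)
    for item in items:
        col = matrix.column(item)
        bad = (col < 1) | (col > 7)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"rating out of range 1..7 at participant "
                f"{matrix.participant_ids[i]!r}, item {item!r}: {col[i]}"
            )
        total += (8 - col) if item in reverse else col
    return total


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Standardized mean difference with the pooled SD denominator."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("Cohen's d undefined: both group SDs are zero")
    pooled = np.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )
    return float((a.mean - b.mean) / pooled)


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch two-sample t test from group summaries.

    Returns
    -------
    (t, df, p) with Welch-Satterthwaite degrees of freedom and the
    two-sided p-value.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("Welch t undefined: both group SDs are zero")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cronbach_alpha(matrix: ResponseMatrix | np.ndarray, items: list[str] | None = None) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance).

    Sample (n-1) variances throughout. Accepts a ResponseMatrix plus an item
    subset, or a raw participants x items array.
    """
    if isinstance(matrix, ResponseMatrix):
        if items is None:
            items = list(matrix.item_ids)
        data = np.column_stack([matrix.column(i) for i in items]).astype(float)
    else:
        data = np.asarray(matrix, dtype=float)
    k = data.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least two items")
    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_r undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def item_level_d(matrix: ResponseMatrix, case_label: str = "case") -> dict[str, float]:
    """Per-item pooled-SD Cohen's d, case minus comparison."""
    mask = matrix.group_mask(case_label)
    if not mask.any() or mask.all():
        raise ValueError("both groups must be present")
    out: dict[str, float] = {}
    for item in matrix.item_ids:
        col = matrix.column(item).astype(float)
        out[item] = cohens_d(
            GroupSummary.from_values(col[mask]), GroupSummary.from_values(col[~mask])
        )
    return out


def ols_hc3(y: np.ndarray, design: np.ndarray) -> RegressionFit:
    """Least-squares fit with HC3 sandwich covariance.

    The design matrix is used as given (include a constant column yourself
    if an intercept is wanted). HC3 weights squared residuals by
    1/(1 - h_i)^2 where h_i is the leverage.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] <= X.shape[1]:
        raise ValueError("design must be 2-D with more rows than columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a leverage value equals 1; HC3 weights undefined")
    res = sm.OLS(y, X).fit(cov_type="HC3")
    b = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    return RegressionFit(
        b=b,
        se_hc3=se,
        t=t,
        p=np.asarray(res.pvalues, dtype=float),
        r_squared=float(res.rsquared),
        leverage=h,
        residuals=np.asarray(res.resid, dtype=float),
    )
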