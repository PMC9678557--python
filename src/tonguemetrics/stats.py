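"""Case-control statistics: contingency tests, logistic regression, rank tests, ROC.

Every procedure here is implemented from first principles (closed forms, rank
arithmetic, IRLS) rather than delegated to a statistics library; only the
reference distributions (chi-squared, t, normal) come from :mod:`scipy.stats`.
This keeps the computation transparent and lets the test suite cross-check each
routine against an independent implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "LogisticFit",
    "RocResult",
    "chi_square_2x2",
    "logistic_univariate_2x2",
    "logistic_fit",
    "mann_whitney_u",
    "two_sample_t",
    "two_sample_t_data",
    "spearman",
    "roc_auc_binary",
    "roc_auc",
]

#: two-sided 95% normal quantile used for every Wald interval
Z_95 = float(_sps.norm.ppf(0.975))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts.

    Rows are exposure (yes/no), columns are group (case/control):

    ==========  =====  =======
    .           case   control
    ==========  =====  =======
    exposed     a      b
    unexposed   c      d
    ==========  =====  =======
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @classmethod
    def from_counts(
        cls, exposed_cases: int, total_cases: int, exposed_controls: int, total_controls: int
    ) -> "ContingencyTable2x2":
        """Build from exposure counts as reports typically print them:
        exposed among cases, total cases, exposed among controls, total controls."""
        return cls(
            a=exposed_cases,
            b=exposed_controls,
            c=total_cases - exposed_cases,
            d=total_controls - exposed_controls,
        )

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class LogisticFit:
    """Logistic-regression estimates with Wald inference.

    ``odds_ratios = exp(coefficients)``; confidence bounds are
    ``exp(coef ± z_{.975} · SE)`` on the log-odds scale.
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iter: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):  # inf bound is meaningful under separation
            return np.exp(self.coefficients - Z_95 * self.standard_errors)

    @property
    def ci_high(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coefficients + Z_95 * self.standard_errors)


@dataclass(frozen=True)
class RocResult:
    """AUC with a Hanley–McNeil 95% interval and a two-sided test vs AUC=0.5."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC outside [0, 1]: {self.auc}")


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table.

    Without correction (the default) the statistic is the classic
    ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with ``yates=True`` the
    continuity correction subtracts ``n/2`` from ``|ad - bc|`` first.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate margin: a row or column of the table is all zero")
    n = table.total
    cross = abs(a * d - b * c)
    if yates:
        cross = max(cross - n / 2.0, 0.0)
    stat = n * cross**2 / (r1 * r2 * c1 * c2)
    p = float(_sps.chi2.sf(stat, df=1))
    return TestResult(
        statistic=float(stat),
        p_value=p,
        method="pearson-chi2-yates" if yates else "pearson-chi2",
        df=1,
    )


def logistic_univariate_2x2(
    table: ContingencyTable2x2, haldane: bool = False
) -> LogisticFit:
    """Univariate logistic regression of group on a binary exposure.

    For a single binary predictor the model is saturated, so the MLE odds ratio
    is the cross-product ratio ``ad/(bc)`` and ``SE(log OR) =
    sqrt(1/a + 1/b + 1/c + 1/d)``.  Zero cells make the OR undefined (complete
    or quasi-separation); ``haldane=True`` applies the Haldane–Anscombe +0.5
    continuity correction instead of raising.
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if np.any(cells == 0):
        if not haldane:
            raise ValueError("separation: OR undefined (zero cell; pass haldane=True to correct)")
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * float(_sps.norm.sf(abs(z)))
    return LogisticFit(
        names=("exposure",),
        coefficients=np.array([log_or]),
        standard_errors=np.array([se]),
        p_values=np.array([min(p, 1.0)]),
        converged=True,
        n_iter=0,
    )


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------


def logistic_fit(
    y: Sequence[int] | np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton–Raphson (IRLS).

    Parameters
    ----------
    y
        Binary outcomes (0/1); both classes must be present.
    X
        Design matrix, one column per predictor.  Include the intercept column
        yourself if you want one.
    names
        Optional column labels; defaults to ``x0, x1, ...``.

    Convergence is declared when the largest score (gradient) component falls
    below ``tol``.  Diverging coefficients (perfect separation) are flagged via
    ``converged=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different lengths")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than predictors ({k})")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("y must contain both classes, coded 0/1")
    if names is None:
        names = tuple(f"x{j}" for j in range(k))
    else:
        names = tuple(names)
        if len(names) != k:
            raise ValueError("names length does not match number of predictors")

    beta = np.zeros(k)
    converged = False
    it = 0
    info = np.eye(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        # clip to keep the weights finite under near-separation
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:  # diverging: (quasi-)separation
            break

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_values = np.clip(2.0 * _sps.norm.sf(np.abs(z)), 0.0, 1.0)
    return LogisticFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        p_values=p_values,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_exact_sf_table(n1: int, n2: int) -> dict[float, float]:
    """Exact null distribution of U by enumerating rank assignments (no ties)."""
    ranks = range(1, n1 + n2 + 1)
    counts: dict[float, int] = {}
    total = 0
    for combo in combinations(ranks, n1):
        u = sum(combo) - n1 * (n1 + 1) / 2.0
        counts[u] = counts.get(u, 0) + 1
        total += 1
    return {u: c / total for u, c in counts.items()}


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 12
) -> TestResult:
    """Mann–Whitney U (Wilcoxon rank-sum) test, two-sided.

    Ties receive midranks.  The p-value is exact — full enumeration of the
    ``C(n1+n2, n1)`` rank assignments — when ``n1+n2 <= exact_limit`` and there
    are no ties; otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 + n2 <= exact_limit and not has_ties:
        dist = _u_exact_sf_table(n1, n2)
        p_le = sum(pr for u, pr in dist.items() if u <= u1)
        p_ge = sum(pr for u, pr in dist.items() if u >= u1)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "mann-whitney-exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            return TestResult(u1, 1.0, "mann-whitney-normal", n=(n1, n2))
        diff = abs(u1 - mu)
        z = max(diff - 0.5, 0.0) / math.sqrt(var)  # continuity correction
        p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
        method = "mann-whitney-normal"
    return TestResult(statistic=float(u1), p_value=p, method=method, n=(n1, n2))


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t test from summary statistics, two-sided."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(_sps.t.sf(abs(t), df=df))
    return TestResult(statistic=float(t), p_value=min(p, 1.0), method="t-pooled", df=df, n=(n1, n2))


def two_sample_t_data(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t test from raw data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value (df = n-2).

    The coefficient is the Pearson correlation of midranks, which handles ties
    exactly.  Raises on a constant input vector (rank variance zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must be paired (equal length)")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = _midranks(x)
    ry = _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: constant input vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), df=n - 2)))
    return TestResult(statistic=r, p_value=p, method="spearman", df=n - 2, n=(n,))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _hanley_mcneil(auc: float, n1: int, n2: int) -> tuple[float, float, float]:
    """(ci_low, ci_high, p vs 0.5) via the Hanley–McNeil variance."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, auc - Z_95 * se)
    hi = min(1.0, auc + Z_95 * se)
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = min(1.0, 2.0 * float(_sps.norm.sf(abs(auc - 0.5) / se)))
    return lo, hi, p


def roc_auc_binary(
    exposed_cases: int, total_cases: int, exposed_controls: int, total_controls: int
) -> RocResult:
    """AUC of a binary marker: (sensitivity + specificity) / 2.

    Equivalent to the midrank Mann–Whitney AUC of 0/1 scores.  The interval is
    Hanley–McNeil; the p-value tests AUC = 0.5 two-sided.
    """
    if total_cases <= 0 or total_controls <= 0:
        raise ValueError("group totals must be positive")
    sens = exposed_cases / total_cases
    spec = 1.0 - exposed_controls / total_controls
    auc = (sens + spec) / 2.0
    lo, hi, p = _hanley_mcneil(auc, total_cases, total_controls)
    return RocResult(auc, lo, hi, p, total_cases, total_controls)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Rank-based AUC of a continuous marker (ties midranked).

    ``labels`` is 1 for cases, 0 for controls; higher scores should indicate
    cases.  On 0/1 scores this reduces exactly to :func:`roc_auc_binary`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    n1 = int(np.sum(labels == 1))
    n2 = int(np.sum(labels == 0))
    ranks = _midranks(scores)
    r1 = ranks[labels == 1].sum()
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    lo, hi, p = _hanley_mcneil(auc, n1, n2)
    return RocResult(float(auc), lo, hi, p, n1, n2)
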