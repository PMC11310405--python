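"""Cohort statistics: exact and asymptotic 2x2 tests, odds ratios, and a
multivariable logistic model for thrombotic-event risk.

All test statistics are computed here from first principles (log-gamma
arithmetic for the exact test, IRLS for the logistic model); SciPy supplies
only distribution functions.  No multiplicity correction is applied anywhere
and every report labels its p-values unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "LogisticFitResult",
    "fisher_exact",
    "two_proportion_test",
    "odds_ratio_ci",
    "logistic_regression",
    "build_cohort_report",
    "cohort_report_from_counts",
]

_TWO_SIDED_SLACK = 1 + 1e-7  # relative tolerance when comparing point probabilities


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (rows = exposure, columns = outcome)::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell count in {cells}")
        if sum(cells) == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # {"fisher", "two_proportion_z"}
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _log_hypergeom_pmf(k: int, n_total: int, n_success: int, n_draw: int) -> float:
    """log P(X = k) for X ~ Hypergeometric(n_total, n_success, n_draw)."""
    lg = math.lgamma

    def logc(n: int, r: int) -> float:
        return lg(n + 1) - lg(r + 1) - lg(n - r + 1)

    return (logc(n_success, k) + logc(n_total - n_success, n_draw - k)
            - logc(n_total, n_draw))


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value follows the minimum-likelihood convention: the sum,
    over the support of cell ``a`` at fixed margins, of hypergeometric point
    probabilities no larger than the observed one.  One-sided alternatives
    ("greater", "less") refer to the odds ratio of the first row.

    A table with an empty row or column margin carries no information and
    returns p = 1 with the degenerate flag set.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, table.n
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return TestResult(float("nan"), 1.0, "fisher", degenerate=True,
                          detail={"table": (a, b, c, d)})

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    log_pmf = {k: _log_hypergeom_pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    p_obs = math.exp(log_pmf[a])

    if alternative == "two-sided":
        p = sum(math.exp(lp) for lp in log_pmf.values()
                if math.exp(lp) <= p_obs * _TWO_SIDED_SLACK)
    elif alternative == "greater":
        p = sum(math.exp(log_pmf[k]) for k in range(a, hi + 1))
    elif alternative == "less":
        p = sum(math.exp(log_pmf[k]) for k in range(lo, a + 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult(odds, min(p, 1.0), "fisher",
                      detail={"table": (a, b, c, d), "alternative": alternative})


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test (no continuity correction), two-sided.

    Degenerate when the pooled proportion is 0 or 1 (both groups all-negative
    or all-positive): z = 0, p = 1, flagged.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("require 0 <= x <= n in both groups")
    if n1 < 1 or n2 < 1:
        raise ValueError("require n >= 1 in both groups")
    pooled = (x1 + x2) / (n1 + n2)
    detail = {"p1": x1 / n1, "p2": x2 / n2, "pooled": pooled,
              "x1": x1, "n1": n1, "x2": x2, "n2": n2}
    if pooled in (0.0, 1.0):
        return TestResult(0.0, 1.0, "two_proportion_z", degenerate=True, detail=detail)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = math.erfc(abs(z) / math.sqrt(2))
    return TestResult(z, p, "two_proportion_z", detail=detail)


def odds_ratio_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio ad/bc with a Wald CI on the log scale.

    The Haldane–Anscombe 0.5 continuity correction is applied to every cell
    iff any cell is zero, so the estimate and interval are always finite.
    """
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _norm_ppf(0.5 + level / 2)
    return (or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se))


def _norm_ppf(q: float) -> float:
    from scipy.special import ndtri
    return float(ndtri(q))


@dataclass
class LogisticFitResult:
    """Maximum-likelihood logistic fit summary (Wald inference)."""

    params: pd.DataFrame  # index: covariate; columns: coef, se, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    iterations: int
    separation: bool = False

    def odds_ratio(self, name: str) -> float:
        return float(self.params.loc[name, "odds_ratio"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.params.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


def logistic_regression(
    design: pd.DataFrame | np.ndarray,
    outcome: Sequence[int] | np.ndarray,
    add_intercept: bool = True,
    level: float = 0.95,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFitResult:
    """Binary logistic regression fit by iteratively reweighted least squares.

    Convergence: max absolute coefficient change < ``tol`` (default 1e-8)
    within ``max_iter`` iterations, else the result is flagged unconverged.
    Standard errors come from the observed information X'WX.  A coefficient
    diverging past 15 in absolute value signals (quasi-)separation: the fit
    is flagged and its confidence intervals suppressed (NaN).
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome lengths differ")
    if X.shape[0] <= X.shape[1] + int(add_intercept):
        raise ValueError("more covariates than observations")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names

    beta = np.zeros(X.shape[1])
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        # Fisher scoring step: (X'WX) delta = X'(y - p)
        xtw = X.T * w
        info = xtw @ X
        grad = X.T @ (y - p)
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, grad, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > 15)
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)

    z = _norm_ppf(0.5 + level / 2)
    with np.errstate(over="ignore"):
        or_ = np.exp(beta)
        lo = np.exp(beta - z * se)
        hi = np.exp(beta + z * se)
    wald = beta / se
    pvals = np.array([math.erfc(abs(v) / math.sqrt(2)) if np.isfinite(v) else np.nan
                      for v in wald])
    if separation:
        lo = np.full(len(beta), np.nan)
        hi = np.full(len(beta), np.nan)

    params = pd.DataFrame(
        {"coef": beta, "se": se, "odds_ratio": or_,
         "ci_low": lo, "ci_high": hi, "p_value": pvals},
        index=pd.Index(names, name="covariate"),
    )
    return LogisticFitResult(params, converged, iterations, separation)


def cohort_report_from_counts(
    rows: Mapping[str, tuple[int, int]],
    n_a: int,
    n_b: int,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Cohort-comparison table from per-event positive counts.

    ``rows`` maps event name -> (count in cohort A, count in cohort B).
    Each row gets counts, percentages, and a pooled two-proportion z p-value
    (reported unadjusted).
    """
    records = []
    for event, (xa, xb) in rows.items():
        res = two_proportion_test(xa, n_a, xb, n_b)
        records.append({
            "event": event,
            f"n_{label_a}": xa,
            f"pct_{label_a}": 100 * xa / n_a,
            f"n_{label_b}": xb,
            f"pct_{label_b}": 100 * xb / n_b,
            "p_unadjusted": res.p_value,
            "method": res.method,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame.from_records(records)


def build_cohort_report(
    pheno_a: pd.DataFrame,
    pheno_b: pd.DataFrame,
    event_columns: Sequence[str] | None = None,
    label_a: str = "A",
    label_b: str = "B",
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Table-1-style comparison of event phenotypes between two cohorts.

    Both matrices must share the compared columns (binary 0/1).  By default
    every shared column is reported, which for pipeline phenotype matrices
    includes the derived VTE and overall-TE columns.
    """
    if event_columns is None:
        event_columns = [c for c in pheno_a.columns if c in pheno_b.columns]
    else:
        missing = [c for c in event_columns
                   if c not in pheno_a.columns or c not in pheno_b.columns]
        if missing:
            raise ValueError(f"columns missing from a cohort: {missing}")
    rows = {}
    for col in event_columns:
        name = labels.get(col, col) if labels else col
        rows[name] = (int(pheno_a[col].sum()), int(pheno_b[col].sum()))
    return cohort_report_from_counts(rows, len(pheno_a), len(pheno_b),
                                     label_a=label_a, label_b=label_b)
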