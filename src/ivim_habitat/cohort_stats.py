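"""Cohort-comparison statistics for train/test characteristic tables.

Categorical variables (2x2 collapses) are compared with the Pearson
chi-square test, switching to the Yates continuity-corrected variant when
any expected cell count falls below 5; normally distributed continuous
variables use the two-sample t-test (recomputable from printed mean +/- SD
summaries), and non-normal ones the Mann-Whitney U test with tie-corrected
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "pearson_chi2",
    "yates_chi2",
    "two_sample_t",
    "mann_whitney_u",
    "compare_cohorts",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are cohorts, columns are category levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be nonnegative integers")
        if self.total == 0:
            raise ValueError("table must contain observations")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)

    @property
    def expected(self) -> np.ndarray:
        r1, r2, c1, c2 = self.margins
        n = self.total
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]]) / n


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | None
    p: float


def _check_margins(t: ContingencyTable2x2) -> None:
    if any(m == 0 for m in t.margins):
        raise ValueError("chi-square test undefined with a zero marginal")


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table: N (ad - bc)^2 over the product of
    the four marginals, referred to chi-square with 1 df."""
    _check_margins(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2, c1, c2 = table.margins
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult("pearson-chi2", float(chi2), 1.0,
                      float(stats.chi2.sf(chi2, 1)))


def yates_chi2(table: ContingencyTable2x2) -> TestResult:
    """Continuity-corrected chi-square: |ad - bc| is shrunk by N/2 (floored
    at zero) before squaring."""
    _check_margins(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2, c1, c2 = table.margins
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * num ** 2 / (r1 * r2 * c1 * c2)
    return TestResult("yates-chi2", float(chi2), 1.0,
                      float(stats.chi2.sf(chi2, 1)))


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int,
                 pooled: bool = True) -> TestResult:
    """Two-sample t-test from summary statistics (SDs are sample SDs).

    *pooled* selects the equal-variance test; otherwise Welch's with
    Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1 ** 2, sd2 ** 2
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = float(n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)
    if se2 == 0:
        if mean1 == mean2:
            return TestResult("t-test", 0.0, df, 1.0)
        return TestResult("t-test", float("inf"), df, 0.0)
    t = (mean1 - mean2) / np.sqrt(se2)
    return TestResult("t-test", float(t), df, float(2 * stats.t.sf(abs(t), df)))


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts)).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult("mann-whitney-u", float(u1), None, 1.0)
    z = (u1 - mu) / np.sqrt(sigma2)
    return TestResult("mann-whitney-u", float(u1), None,
                      float(min(2 * stats.norm.sf(abs(z)), 1.0)))


def compare_cohorts(variables: list[dict]) -> pd.DataFrame:
    """Dispatch each typed variable to its test and report in table order.

    Each entry needs ``name`` and ``type``:

    * ``categorical``: ``table`` = (a, b, c, d); Pearson chi-square, or the
      continuity-corrected variant when any expected cell count is below 5;
    * ``continuous-normal``: ``summary`` = (mean1, sd1, n1, mean2, sd2, n2);
    * ``continuous-nonnormal``: ``x`` and ``y`` raw sample arrays.
    """
    rows = []
    for var in variables:
        vtype = var.get("type")
        if vtype == "categorical":
            t = ContingencyTable2x2(*var["table"])
            res = yates_chi2(t) if (t.expected < 5).any() else pearson_chi2(t)
        elif vtype == "continuous-normal":
            res = two_sample_t(*var["summary"], pooled=var.get("pooled", True))
        elif vtype == "continuous-nonnormal":
            res = mann_whitney_u(var["x"], var["y"])
        else:
            raise ValueError(f"variable {var.get('name')!r} has no known type")
        rows.append({"variable": var["name"], "test": res.name,
                     "statistic": res.statistic, "p": res.p})
    return pd.DataFrame(rows)
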