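"""Statistical kernels shared by the analysis modules.

Test statistics are computed from their closed-form definitions so that
printed report tables are exactly reproducible; p-values come from the
closed-form distribution functions in :mod:`scipy.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class CountTable:
    """Observed vs expected counts for a goodness-of-fit comparison."""

    labels: list[str]
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.observed.shape != self.expected.shape:
            raise ValueError("observed and expected differ in length")


@dataclass(frozen=True)
class TestResult:
    statistic: str  # chi2 | chi2_yates | t | F
    value: float
    df: tuple[int, ...]
    p: float


def chi2_gof(observed, expected) -> TestResult:
    """Pearson goodness-of-fit chi-squared: sum (O-E)^2/E, df = k-1, upper-tail p."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected differ in length")
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be positive")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return TestResult("chi2", chi2, (df,), p)


def chi2_2x2_yates(table) -> TestResult:
    """2x2 chi-squared with Yates continuity correction (df=1, two-tailed p).

    Expected counts come from the row/column margins; the correction term
    |O-E| - 0.5 is floored at zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    if np.any(row <= 0) or np.any(col <= 0):
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(row, col) / total
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float(np.sum(adj ** 2 / expected))
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult("chi2_yates", chi2, (1,), p)


def t_test_ind(sample_a, sample_b) -> TestResult:
    """Equal-variance two-sample t-test; df = n_a + n_b - 2; two-tailed p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    df = na + nb - 2
    var_pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if var_pooled == 0:
        if diff == 0:
            return TestResult("t", 0.0, (df,), 1.0)
        raise ValueError("zero pooled variance with unequal means (degenerate)")
    t = diff / np.sqrt(var_pooled * (1 / na + 1 / nb))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult("t", float(t), (df,), p)


def anova_oneway(*groups) -> TestResult:
    """One-way ANOVA by the between/within sum-of-squares decomposition."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1 = len(gs) - 1
    df2 = n_total - len(gs)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("F", 0.0, (df1, df2), 1.0)
        return TestResult("F", float("inf"), (df1, df2), 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("F", float(f), (df1, df2), p)


def round_for_report(p: float, ratio: float | None = None) -> tuple[float, float | None]:
    """Report-table rounding: p to 4 decimals, ratios to 2 decimals."""
    return round(p, 4), None if ratio is None else round(ratio, 2)
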