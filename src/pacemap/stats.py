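"""Statistical tests and rank-based correlation analysis.

Two-sample and one-sample comparisons follow a Shapiro-Wilk gate:
normally distributed data use Student's t test (paired or one-sample),
otherwise the Wilcoxon signed rank test.  All tests are two-tailed.

The Wilcoxon p-value uses the large-sample normal approximation of the
signed-rank statistic *without* continuity correction,

    z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24),

which for n = 25 all-positive differences gives p = 1.23e-5.

Correlations are Spearman rank correlations, accompanied by a relative
density map over 0.2 x 0.2 quantile rectangles: observed count divided by
the count expected under independence (n * 0.04).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "CorrelationResult",
    "TestResult",
    "spearman_quantile_correlation",
    "wilcoxon_signed_rank_p",
    "paired_or_wilcoxon",
    "one_sample_t_p",
    "one_sample_or_wilcoxon",
]


@dataclass
class CorrelationResult:
    rho: float
    n: int
    density_map: np.ndarray     # (5, 5) relative densities; rows = x bins

    def to_dict(self) -> dict:
        return {"rho": self.rho, "n": self.n, "density_map": self.density_map.tolist()}


@dataclass
class TestResult:
    test: str
    n: int
    statistic: float
    p: float
    rationale: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "n": self.n,
            "statistic": self.statistic,
            "p": self.p,
            "rationale": self.rationale,
        }


def _quantile_bin(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Bin index in [0, k) from mid-rank quantiles rank/n; points exactly
    on a boundary go to the lower rectangle."""
    n = values.size
    q = sstats.rankdata(values) / n
    idx = np.ceil(q * k).astype(int) - 1
    return np.clip(idx, 0, k - 1)


def spearman_quantile_correlation(x, y) -> CorrelationResult:
    """Spearman rho (Pearson on mid-ranks) plus the quantile density map."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("series must have equal length >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    rho = float(np.corrcoef(sstats.rankdata(x), sstats.rankdata(y))[0, 1])
    ix, iy = _quantile_bin(x), _quantile_bin(y)
    counts = np.zeros((5, 5))
    np.add.at(counts, (ix, iy), 1.0)
    density = counts / (x.size * 0.04)
    return CorrelationResult(rho=rho, n=int(x.size), density_map=density)


def wilcoxon_signed_rank_p(values, null_value: float = 0.0) -> TestResult:
    """Two-tailed Wilcoxon signed rank test by normal approximation.

    Exact ties with the null are dropped; absolute differences are
    mid-ranked; no continuity correction is applied.
    """
    d = np.asarray(values, dtype=float) - null_value
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal the null value")
    if n < 5:
        raise ValueError("need at least 5 non-tied values")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_plus - mean) / sd
    p = float(2.0 * sstats.norm.sf(abs(z)))
    return TestResult(
        test="wilcoxon_signed_rank",
        n=n,
        statistic=w_plus,
        p=min(p, 1.0),
        rationale="normal approximation, no continuity correction",
    )


def one_sample_t_p(values, null_value: float = 0.0) -> TestResult:
    """Two-tailed one-sample Student's t test."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    t, p = sstats.ttest_1samp(x, null_value)
    return TestResult(test="one_sample_t", n=int(x.size), statistic=float(t), p=float(p))


def paired_or_wilcoxon(before, after, alpha_normality: float = 0.05) -> TestResult:
    """Shapiro-Wilk gate on the paired differences, then paired t or
    Wilcoxon signed rank (two-tailed)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size or b.size < 3:
        raise ValueError("need equal-length series with >= 3 pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences")
    sw_p = float(sstats.shapiro(d).pvalue)
    if sw_p >= alpha_normality:
        t, p = sstats.ttest_rel(a, b)
        return TestResult(
            test="paired_t", n=int(b.size), statistic=float(t), p=float(p),
            rationale=f"Shapiro-Wilk p = {sw_p:.3g} >= {alpha_normality}",
        )
    res = wilcoxon_signed_rank_p(d, 0.0)
    res.rationale = f"Shapiro-Wilk p = {sw_p:.3g} < {alpha_normality}; " + res.rationale
    return res


def one_sample_or_wilcoxon(values, null_value: float, alpha_normality: float = 0.05) -> TestResult:
    """Shapiro-Wilk gate, then one-sample t against ``null_value`` or
    Wilcoxon signed rank against it."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sw_p = float(sstats.shapiro(x).pvalue)
    if sw_p >= alpha_normality:
        res = one_sample_t_p(x, null_value)
        res.rationale = f"Shapiro-Wilk p = {sw_p:.3g} >= {alpha_normality}"
        return res
    res = wilcoxon_signed_rank_p(x, null_value)
    res.rationale = f"Shapiro-Wilk p = {sw_p:.3g} < {alpha_normality}; " + res.rationale
    return res
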