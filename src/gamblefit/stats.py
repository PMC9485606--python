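"""Paired condition contrasts, effect sizes, and the a priori power analysis.

The contrast machinery mirrors a common clinical-statistics workflow: check
normality of the within-subject differences with the Shapiro–Wilk test, then
run a paired t-test if the differences look normal, otherwise a Wilcoxon
signed-rank test; always report the paired effect size Cohen's
dz = mean(diff) / sd(diff).

The Wilcoxon implementation follows the conventions of mainstream clinical
software: exact two-sided p by the full sign-flip distribution for n <= 25
without ties, otherwise a normal approximation with midranks, tie-corrected
variance and continuity correction, reported as a (signed) Z statistic.

``required_sample_size`` inverts the power function of the two-sided paired
t-test (noncentral t) to the smallest n reaching the target power.

``rationality_contrast`` compares conditions on |theta - 1|, the distance of
a prospect-theory parameter from its risk-neutral / objective-weighting
value of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class WilcoxonResult:
    w_plus: float
    z: float
    p_value: float
    exact: bool
    n_used: int


@dataclass
class PairedComparisonResult:
    """One paired contrast: chosen test, statistic, p, and effect size."""

    variable: str
    test_used: str  # "paired_t" | "wilcoxon"
    statistic: float  # t or Z
    p_value: float
    effect_size_d: float
    n_pairs: int
    normality_p: float
    mean_difference: float


def _diffs(x, y) -> np.ndarray:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    return x - y


def shapiro_wilk_p(differences) -> float:
    """Two-sided Shapiro–Wilk p-value for normality of the differences."""
    d = np.asarray(differences, float)
    if d.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    if np.ptp(d) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant vector")
    return float(sps.shapiro(d).pvalue)


def paired_t(x, y) -> tuple[float, float, int]:
    """Paired t-test: one-sample t on x - y; returns (t, two-sided p, df)."""
    d = _diffs(x, y)
    if d.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of differences; t undefined")
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue), d.size - 1


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p of W+ via the sign-flip rank-sum distribution.

    Dynamic-programming convolution over integer ranks — identical to
    enumerating all 2^n sign assignments, but polynomial time.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus))
    p_low = counts[: w + 1].sum()
    p_high = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(x, y, exact_n_max: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired data.

    Zero differences are dropped. Exact two-sided p for n <= ``exact_n_max``
    without ties in |differences|; otherwise midranks with tie-corrected
    variance and continuity correction. The Z statistic (reported either
    way) is signed so that W+ below its null mean gives a negative Z.
    """
    d = _diffs(x, y)
    d = d[d != 0]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 non-zero differences")
    abs_d = np.abs(d)
    ranks = sps.rankdata(abs_d)
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(abs_d, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if sigma2 <= 0:
        raise ValueError("degenerate rank variance")
    cc = 0.5 * np.sign(w_plus - mu)
    z = (w_plus - mu - cc) / np.sqrt(sigma2) if w_plus != mu else 0.0
    has_ties = np.any(tie_counts > 1)
    if n <= exact_n_max and not has_ties:
        p = _signed_rank_exact_p(w_plus, ranks)
        return WilcoxonResult(w_plus, float(z), p, True, n)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, float(z), min(p, 1.0), False, n)


def cohens_dz(x, y) -> float:
    """Paired Cohen's dz = mean(x - y) / sd(x - y) (sample sd, n - 1)."""
    d = _diffs(x, y)
    s = np.std(d, ddof=1)
    if s == 0:
        raise ValueError("zero variance of differences; dz undefined")
    return float(d.mean() / s)


def paired_compare(
    x,
    y,
    variable: str = "value",
    alpha_normality: float = 0.05,
) -> PairedComparisonResult:
    """Normality-gated paired contrast of x vs y (differences x - y).

    Shapiro–Wilk p >= ``alpha_normality`` selects the paired t-test,
    otherwise the Wilcoxon signed-rank test; Cohen's dz is reported either
    way.
    """
    d = _diffs(x, y)
    norm_p = shapiro_wilk_p(d)
    dz = cohens_dz(x, y)
    if norm_p >= alpha_normality:
        t, p, _ = paired_t(x, y)
        return PairedComparisonResult(
            variable, "paired_t", t, p, dz, d.size, norm_p, float(d.mean())
        )
    res = wilcoxon_signed_rank(x, y)
    return PairedComparisonResult(
        variable, "wilcoxon", res.z, res.p_value, dz, d.size, norm_p, float(d.mean())
    )


def rationality_contrast(
    params_neutral,
    params_positive,
    which: str,
    alpha_normality: float = 0.05,
) -> PairedComparisonResult:
    """Paired contrast of |theta - 1| (positive minus neutral).

    theta = 1 is the risk-neutral (lam) or objective-weighting (gam) value,
    so a negative mean difference means the positive condition sits closer
    to rationality.
    """
    if which not in ("lam", "gam"):
        raise ValueError("which must be 'lam' or 'gam'")
    a_neutral = np.abs(np.asarray(params_neutral, float) - 1.0)
    a_positive = np.abs(np.asarray(params_positive, float) - 1.0)
    return paired_compare(
        a_positive, a_neutral, variable=f"abs({which}-1)",
        alpha_normality=alpha_normality,
    )


def _power_one_sample_t(n: int, d: float, alpha: float, two_sided: bool) -> float:
    df = n - 1
    ncp = d * np.sqrt(n)
    if two_sided:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(
            1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        )
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(1 - sps.nct.cdf(tcrit, df, ncp))


def required_sample_size(
    d: float,
    power: float = 0.8,
    alpha: float = 0.05,
    two_sided: bool = True,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n giving a paired t-test the target power at effect size d.

    Exact noncentral-t power computation; e.g. d = 0.5, power 0.8,
    alpha 0.05 two-sided requires n = 34 pairs.
    """
    if not (d > 0 and 0 < power < 1 and 0 < alpha < 1):
        raise ValueError("require d > 0, 0 < power < 1, 0 < alpha < 1")
    for n in range(2, max_n + 1):
        if _power_one_sample_t(n, d, alpha, two_sided) >= power:
            return n
    raise ValueError(f"power {power} unattainable below n = {max_n}")
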