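"""Occupancy statistics for stem-loop sites and the paired-rank correlation.

The headline test compares the observed coding/intergenic split of site
counts with the split expected if sites fell uniformly, i.e. proportional
to the coding fraction of the genome. The expected counts are rounded to
integers (half-even) and the two rows are compared with a two-sided Fisher
exact test. Building a contingency table from an expected row is not an
orthodox use of Fisher's test (the second row is not an independent
sample), so an exact binomial test of the observed coding count against
the coding fraction is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float


@dataclass(frozen=True)
class OccupancyResult:
    obs_coding: int
    obs_intergenic: int
    exp_coding: int
    exp_intergenic: int
    coding_fraction: float
    fisher: FisherResult
    binomial_p: float

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.obs_coding, self.obs_intergenic, self.exp_coding, self.exp_intergenic)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


def expected_counts(total: int, coding_fraction: float) -> tuple[int, int]:
    """Expected (coding, intergenic) counts under the genome-fraction null.

    The coding cell is rounded half-even so the pair stays integer and
    sums to ``total``.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    if not 0.0 <= coding_fraction <= 1.0:
        raise ValueError("coding_fraction must be in [0, 1]")
    exp_coding = int(round(total * coding_fraction))
    return exp_coding, total - exp_coding


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on the table ((a, b), (c, d)).

    The two-sided p sums the hypergeometric probabilities of every table
    with the same margins whose probability does not exceed that of the
    observed table (relative tolerance factor 1 + 1e-7 on the inequality).
    All probabilities are computed in log space.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all margins zero")
    r1, r2, c1 = a + b, c + d, a + c
    log_denom = _log_comb(n, c1)

    def log_pmf(k: int) -> float:
        return _log_comb(r1, k) + _log_comb(r2, c1 - k) - log_denom

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = log_pmf(a)
    cutoff = lp_obs + math.log1p(1e-7)
    terms = [log_pmf(k) for k in range(lo, hi + 1) if log_pmf(k) <= cutoff]
    m = max(terms)
    p = math.exp(m) * sum(math.exp(t - m) for t in terms)
    p = min(1.0, p)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p_two_sided=p, odds_ratio=odds)


def occupancy_test(
    obs_coding: int, obs_intergenic: int, coding_fraction: float
) -> OccupancyResult:
    """Observed-vs-expected occupancy test on site counts.

    Builds the expected row from the coding fraction on the same total,
    runs the two-sided Fisher exact test on (obs_c, obs_i; exp_c, exp_i)
    and an exact two-sided binomial test of obs_coding successes in
    ``total`` trials with success probability ``coding_fraction``.
    """
    if obs_coding < 0 or obs_intergenic < 0:
        raise ValueError("negative observed count")
    total = obs_coding + obs_intergenic
    if total == 0:
        raise ValueError("no sites to test")
    exp_c, exp_i = expected_counts(total, coding_fraction)
    fisher = fisher_exact_2x2(obs_coding, obs_intergenic, exp_c, exp_i)
    binom_p = float(
        _stats.binomtest(obs_coding, total, coding_fraction, alternative="two-sided").pvalue
    )
    return OccupancyResult(
        obs_coding=obs_coding,
        obs_intergenic=obs_intergenic,
        exp_coding=exp_c,
        exp_intergenic=exp_i,
        coding_fraction=coding_fraction,
        fisher=fisher,
        binomial_p=binom_p,
    )


def pearson_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if 1.0 - r * r < 1e-15:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, r_squared=r * r, p_value=p, n=n)
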