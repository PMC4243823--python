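"""Closed-form sequencing-depth model.

For a clone at true proportion p_i sequenced to depth N, the number of
reads recovered is Binomial(N, p), where p = p_i - e*l discounts reads
ruined by a per-base error rate e over a sequence of length l (e defaults
to 0: with realistic per-base rates the e*l term would exceed small clone
proportions, and the reference results treat the error term as negligible;
the adjustment is implemented and exposed). The probability of observing
the clone within a +/-10% accuracy band of its expected count is the
binomial sum over the integer counts inside

    b_lower = N*p_i*(1-band)   b_upper = N*p_i*(1+band)

summed from ceil(b_lower) to floor(b_upper) inclusive, both clipped to
[0, N]. The probability of detecting at least one read of a type with
per-read probability p is the Poisson tail P(X != 0) = 1 - exp(-N*p).

A hypergeometric mode (sampling without replacement from a finite
amplified population) is available for small populations; with populations
of ~5e7 molecules it is indistinguishable from the binomial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Depths plotted in the reference depth-accuracy curve.
DEFAULT_DEPTHS = (10_000, 25_000, 100_000, 1_000_000, 10_000_000)


@dataclass(frozen=True)
class SamplingParams:
    N: int
    p_i: float
    e: float = 0.0
    l: int = 300
    accuracy_band: float = 0.10
    population: int | None = None  # finite population -> hypergeometric

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be a positive integer")
        if not 0 <= self.p_i <= 1:
            raise ValueError("p_i must lie in [0, 1]")
        if not 0 <= self.e <= 1:
            raise ValueError("e must lie in [0, 1]")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if not 0 < self.accuracy_band < 1:
            raise ValueError("accuracy_band must lie in (0, 1)")
        if self.population is not None and self.population < self.N:
            raise ValueError("population must be >= N")

    @property
    def p(self) -> float:
        """Error-adjusted per-read success probability, clipped at 0."""
        adjusted = self.p_i - self.e * self.l
        if adjusted < 0:
            logger.warning(
                "e*l = %.3g exceeds p_i = %.3g; adjusted p clipped to 0",
                self.e * self.l,
                self.p_i,
            )
            return 0.0
        return adjusted


def accuracy_probability(params: SamplingParams) -> float:
    """Probability that the observed read count of the clone falls within
    the accuracy band around its expected count N*p_i."""
    lo = math.ceil(params.N * params.p_i * (1.0 - params.accuracy_band))
    hi = math.floor(params.N * params.p_i * (1.0 + params.accuracy_band))
    lo = max(lo, 0)
    hi = min(hi, params.N)
    if hi < lo:
        return 0.0
    p = params.p
    if params.population is not None:
        k_success = round(params.population * p)
        dist = stats.hypergeom(params.population, k_success, params.N)
        return float(dist.cdf(hi) - (dist.cdf(lo - 1) if lo > 0 else 0.0))
    if p == 0.0:
        return 1.0 if lo == 0 else 0.0
    if p == 1.0:
        return 1.0 if hi == params.N else 0.0
    return min(1.0, _binomial_band_sum(params.N, p, lo, hi))


def _log_binom_coeff(n: int, k: int) -> float:
    """log C(n, k) as an fsum of term logs — keeps the absolute error near
    k ulps instead of the ~1e-8 floor lgamma(n+1) has for n ~ 1e7."""
    k = min(k, n - k)
    return math.fsum(math.log((n - k + j) / j) for j in range(1, k + 1))


def _binomial_band_sum(n: int, p: float, lo: int, hi: int) -> float:
    """Sum of Binomial(n, p) pmf over lo..hi inclusive.

    One term is anchored in log space at the in-band point nearest the mode
    (where the pmf is largest, so the anchor carries no underflow risk) and
    the rest follow by the exact ratio recurrence
    T(k+1)/T(k) = (n-k)/(k+1) * p/(1-p); terms are fsum-accumulated. The
    result agrees with an arbitrary-precision summation to ~1e-10 for
    n <= 1e7, where a CDF difference or a gammaln-based pmf does not.
    """
    mode = int((n + 1) * p)
    anchor = min(max(mode, lo), hi)
    log_anchor = (
        _log_binom_coeff(n, anchor)
        + anchor * math.log(p)
        + (n - anchor) * math.log1p(-p)
    )
    t_anchor = math.exp(log_anchor)
    odds = p / (1.0 - p)
    terms = [t_anchor]
    t = t_anchor
    for k in range(anchor, hi):  # upward from anchor
        t *= (n - k) / (k + 1) * odds
        terms.append(t)
    t = t_anchor
    for k in range(anchor, lo, -1):  # downward from anchor
        t *= k / ((n - k + 1) * odds)
        terms.append(t)
    return math.fsum(terms)


def detection_probability(N: int, p: float) -> float:
    """Poisson probability of sequencing at least one read of a type with
    per-read probability p at depth N: 1 - exp(-N*p)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return float(-np.expm1(-N * p))


def depth_curve(
    depths=DEFAULT_DEPTHS,
    proportions=(0.04, 0.004, 0.0004, 4e-5, 1e-5),
    e: float = 0.0,
    l: int = 300,
    accuracy_band: float = 0.10,
) -> pd.DataFrame:
    """Accuracy-band probability over the depth x proportion grid; rows are
    depths, columns clone proportions."""
    table = pd.DataFrame(
        index=pd.Index(list(depths), name="depth"),
        columns=pd.Index([float(p) for p in proportions], name="proportion"),
        dtype=float,
    )
    for N in depths:
        for p_i in proportions:
            table.loc[N, float(p_i)] = accuracy_probability(
                SamplingParams(N=int(N), p_i=float(p_i), e=e, l=l, accuracy_band=accuracy_band)
            )
    return table
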