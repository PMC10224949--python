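"""Directional Bayes-factor t-tests with half-normal priors.

The data model is a Student-t likelihood on the observed mean difference in
categorical-encoding strength (percent): under an effect delta the density
of the observed difference d is t_df((d - delta)/se)/se, with se the
standard error of the difference under unequal variances and df from the
Welch-Satterthwaite equation.  H0 is a point mass at delta = 0; H1 is a
half-normal on the hypothesized half-line, with scale chosen so that 99% of
its mass covers the theoretically possible range of the effect given the
reference condition's mean (e.g. a decrease from an 89.1% reference can at
most be -89.1 points, giving sigma = 89.1 / z_0.995 = 34.59).

B10 is the ratio of the prior-averaged marginal likelihood under H1 to the
point likelihood under H0, evaluated by adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, stats

Direction = Literal["increase", "decrease"]

#: Standard-normal 0.995 quantile (full double precision via scipy).
Z_995 = float(stats.norm.ppf(0.995))


@dataclass(frozen=True)
class SummaryStats:
    """Summary of a two-group comparison on the percent scale."""

    mean_diff: float
    se_diff: float
    df: float

    def __post_init__(self) -> None:
        if self.se_diff <= 0:
            raise ValueError("se_diff must be positive")
        if self.df <= 0:
            raise ValueError("df must be positive")


@dataclass(frozen=True)
class HypothesisPair:
    """Point null at zero vs. a directional half-normal alternative."""

    sigma: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("half-normal scale must be positive")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")

    def prior_pdf(self, delta: float) -> float:
        """Half-normal density on the hypothesized half-line (integrates to 1)."""
        sign_ok = delta >= 0 if self.direction == "increase" else delta <= 0
        if not sign_ok:
            return 0.0
        return 2.0 * stats.norm.pdf(delta / self.sigma) / self.sigma


@dataclass(frozen=True)
class BayesResult:
    b10: float
    label: str


def hn_scale(reference_mean: float, direction: Direction) -> float:
    """Half-normal scale covering the possible effect range at 99% mass.

    For a hypothesized decrease the range is the reference mean itself (the
    effect can at most erase it); for an increase it is 100 minus the
    reference mean (encoding strength cannot exceed 100%).
    """
    if direction == "decrease":
        if not 0.0 < reference_mean:
            raise ValueError("decrease requires a positive reference mean")
        rng = reference_mean
    else:
        rng = 100.0 - reference_mean
    if rng <= 0:
        raise ValueError("zero effect range; cannot set a prior scale")
    return rng / Z_995


def welch_summary(group_a: Sequence[float], group_b: Sequence[float]) -> SummaryStats:
    """Unequal-variance summary of ``mean(b) - mean(a)``.

    ``group_a`` is the reference condition, ``group_b`` the manipulated one,
    so the sign matches the comparison convention (condition minus
    reference).  df follows the Welch-Satterthwaite equation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    ra, rb = va / a.size, vb / b.size
    se = math.sqrt(ra + rb)
    df = (ra + rb) ** 2 / (ra**2 / (a.size - 1) + rb**2 / (b.size - 1))
    return SummaryStats(mean_diff=float(b.mean() - a.mean()), se_diff=se, df=df)


def bayes_factor(summary: SummaryStats, hyp: HypothesisPair) -> BayesResult:
    """B10 for the directional test, by adaptive quadrature.

    numerator = integral over the half-line of the t likelihood of the
    observed difference at effect delta, weighted by the half-normal prior;
    denominator = the t likelihood at delta = 0.
    """
    d, se, df = summary.mean_diff, summary.se_diff, summary.df
    # mirror symmetry: a decrease test on d equals an increase test on -d,
    # so integrate on the positive half-line throughout
    d_work = d if hyp.direction == "increase" else -d
    sigma = hyp.sigma

    def likelihood(delta: float) -> float:
        return stats.t.pdf((d_work - delta) / se, df) / se

    def integrand(delta: float) -> float:
        return likelihood(delta) * 2.0 * stats.norm.pdf(delta / sigma) / sigma

    # the half-normal carries < 1e-40 mass beyond 13.5 sigma; any likelihood
    # peak out there is annihilated by the prior, so the support is finite
    hi = 13.5 * sigma
    breaks = [d_work] if 0.0 < d_work < hi else None
    alt, err = integrate.quad(
        integrand, 0.0, hi, points=breaks, epsrel=1e-10, epsabs=0.0, limit=200
    )
    if alt <= 0 or not math.isfinite(alt) or err > 1e-6 * alt:
        raise RuntimeError(
            f"marginal-likelihood quadrature did not converge (value={alt}, err={err})"
        )
    null = stats.t.pdf(d_work / se, df) / se
    b10 = alt / null
    return BayesResult(b10=b10, label=classify(b10))


#: Evidential bands (Wagenmakers-style classification).
_H1_BANDS = [
    (100.0, "extreme evidence for H1"),
    (30.0, "very strong evidence for H1"),
    (10.0, "strong evidence for H1"),
    (3.0, "moderate evidence for H1"),
    (1.0, "anecdotal evidence for H1"),
]


def classify(b10: float) -> str:
    """Evidential category of a Bayes factor (reciprocal bands favor H0)."""
    if b10 <= 0:
        raise ValueError("Bayes factor must be positive")
    if b10 == 1.0:
        return "no evidence"
    if b10 > 1.0:
        for cut, label in _H1_BANDS:
            if b10 > cut:
                return label
    else:
        for cut, label in _H1_BANDS:
            if 1.0 / b10 > cut:
                return label.replace("H1", "H0")
    raise AssertionError("unreachable")


def combined_scale(sigma1: float, sigma2: float) -> float:
    """Prior scale for a pooled comparison: the root-mean variance of the two
    separate alternatives, sqrt((sigma1^2 + sigma2^2)/2)."""
    return math.sqrt((sigma1**2 + sigma2**2) / 2.0)


def combined_comparison(
    pair1: tuple[Sequence[float], Sequence[float], float],
    pair2: tuple[Sequence[float], Sequence[float], float],
    direction: Direction,
) -> tuple[BayesResult, SummaryStats, HypothesisPair]:
    """Pool two condition-reference pairs into one directional test.

    Each pair is (condition values, reference values, prior sigma).  Both
    conditions and both references are centered on their own reference mean,
    then pooled; the prior scale is the root-mean variance of the two
    separate alternatives.
    """
    cond_pooled, ref_pooled = [], []
    for cond, ref, _sigma in (pair1, pair2):
        ref = np.asarray(ref, dtype=float)
        cond = np.asarray(cond, dtype=float)
        ref_pooled.append(ref - ref.mean())
        cond_pooled.append(cond - ref.mean())
    summary = welch_summary(np.concatenate(ref_pooled), np.concatenate(cond_pooled))
    hyp = HypothesisPair(sigma=combined_scale(pair1[2], pair2[2]), direction=direction)
    return bayes_factor(summary, hyp), summary, hyp
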