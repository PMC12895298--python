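"""Species-level effective-population-size estimation.

The long-term (coalescent) effective population size is estimated as

    Ne = pi / (2 x mu)

where pi is nucleotide diversity per site, x the ploidy and mu the
per-site per-generation mutation rate.  Diversity at mutation-drift
equilibrium is E[pi] = 2 x Ne mu (4 Ne mu for diploids), so the estimator
inverts that expectation.  Uncertainty in Ne is dominated by the mutation
rate; confidence intervals are therefore propagated from the mu CI alone
by monotone inversion, with no pi error term.

Per-study mutation rates are combined into a species rate by an
effort-weighted mean (trios for pedigree studies, lines x generations for
mutation-accumulation studies), with within-study variances propagated
onto the combined standard error.  Multiple population-level pi values
are averaged arithmetically rather than pooled, since within-population
diversity is the quantity comparable across subdivided species.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError
from .types import DiversityEstimate, MutationRateEstimate

__all__ = [
    "binomial_rate_ci",
    "weighted_mean_mu",
    "mean_pi_across_populations",
    "estimate_ne",
    "propagate_ne_ci",
    "geometric_mean",
    "paired_log_t_test",
    "fit_lognormal",
    "rank_correlation",
]

#: Binomial CI method used when a study reports counts but no interval.
#: "wilson" (score interval, the default) or "beta" (Clopper-Pearson exact).
BINOMIAL_CI_METHOD = "wilson"


def binomial_rate_ci(
    n_mutations: int,
    opportunity: int,
    level: float = 0.95,
    method: str | None = None,
) -> Tuple[float, float]:
    """Confidence interval for a rate observed as ``n_mutations`` events in
    ``opportunity`` trials (e.g. callable sites x generations).

    Uses the Wilson score interval by default, which behaves well for the
    very small proportions typical of de novo mutation rates (~1e-8): the
    interval is asymmetric and its lower bound stays positive whenever at
    least one event was observed.
    """
    if opportunity <= 0:
        raise InvalidInputError("opportunity must be > 0")
    if not (0 <= n_mutations <= opportunity):
        raise InvalidInputError(
            f"n_mutations must be in [0, opportunity], got {n_mutations}"
        )
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must be in (0, 1)")
    low, high = proportion_confint(
        n_mutations, opportunity, alpha=1.0 - level,
        method=method or BINOMIAL_CI_METHOD,
    )
    # exact boundary cases (guard against float round-off in the score form)
    if n_mutations == 0:
        low = 0.0
    if n_mutations == opportunity:
        high = 1.0
    return float(low), float(high)


def weighted_mean_mu(
    estimates: Sequence[MutationRateEstimate],
) -> MutationRateEstimate:
    """Effort-weighted mean mutation rate across studies of one species.

    rate = sum(w_i r_i) / sum(w_i) with w_i the study effort.  Within-study
    standard errors (from the 95% CI half-width, SE_i = (hi - lo)/3.92) are
    propagated as SE = sqrt(sum(w_i^2 SE_i^2)) / sum(w_i); the combined CI
    is rate +/- 1.96 SE, floored at zero.  Studies lacking both a CI and
    counts get the largest within-species variance imputed (conservative).
    """
    estimates = list(estimates)
    if not estimates:
        raise InvalidInputError("no mutation-rate estimates supplied")
    species = {e.species_id for e in estimates}
    if len(species) != 1:
        raise InvalidInputError(f"mixed species in weighted mean: {species}")
    if len(estimates) == 1:
        return estimates[0]

    ses = []
    for e in estimates:
        se = e.se()
        if se is None and e.n_mutations is not None and e.callable_sites:
            lo, hi = binomial_rate_ci(e.n_mutations, e.callable_sites)
            se = (hi - lo) / (2.0 * 1.96)
        ses.append(se)
    known = [s for s in ses if s is not None]

    w = np.array([e.effort for e in estimates], dtype=float)
    r = np.array([e.rate for e in estimates], dtype=float)
    rate = float(np.sum(w * r) / np.sum(w))

    ci_low = ci_high = None
    if known:
        # variance imputation for CI-less, count-less studies: largest
        # observed within-species SE (conservative)
        se_arr = np.array(
            [s if s is not None else max(known) for s in ses], dtype=float
        )
        se = float(np.sqrt(np.sum(w**2 * se_arr**2)) / np.sum(w))
        ci_low = max(0.0, rate - 1.96 * se)
        ci_high = rate + 1.96 * se

    total_effort = float(np.sum(w))
    return MutationRateEstimate(
        species_id=estimates[0].species_id,
        rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        effort=total_effort,
        method=estimates[0].method,
    )


def mean_pi_across_populations(
    estimates: Sequence[DiversityEstimate],
) -> DiversityEstimate:
    """Arithmetic mean of pi across populations of one species.

    Genome-wide and synonymous estimates are treated as equivalent; the
    returned ``site_class`` is genome_wide if any input is, for record
    keeping only.
    """
    estimates = list(estimates)
    if not estimates:
        raise InvalidInputError("no diversity estimates supplied")
    species = {e.species_id for e in estimates}
    if len(species) != 1:
        raise InvalidInputError(f"mixed species in pi mean: {species}")
    pi = float(np.mean([e.pi for e in estimates]))
    site_class = (
        "genome_wide"
        if any(e.site_class == "genome_wide" for e in estimates)
        else "synonymous"
    )
    return DiversityEstimate(
        species_id=estimates[0].species_id,
        pi=pi,
        site_class=site_class,
        population_label="mean",
        sampling_scope=estimates[0].sampling_scope
        if len({e.sampling_scope for e in estimates}) == 1
        else "unknown",
    )


def estimate_ne(pi: float, ploidy: int, mu: float) -> float:
    """Point estimate Ne = pi / (2 * ploidy * mu)."""
    if mu <= 0:
        raise InvalidInputError("mu must be > 0")
    if pi < 0:
        raise InvalidInputError("pi must be >= 0")
    if ploidy < 1:
        raise InvalidInputError("ploidy must be >= 1")
    return pi / (2.0 * ploidy * mu)


def propagate_ne_ci(
    pi: float, ploidy: int, mu_ci: Tuple[float, float]
) -> Tuple[float, float]:
    """Propagate the mutation-rate CI onto Ne by monotone inversion.

    Ne is decreasing in mu, so the upper mu bound gives the lower Ne bound
    and vice versa.  No pi error term is included.
    """
    mu_low, mu_high = mu_ci
    if mu_low <= 0:
        raise InvalidInputError("mu_low must be > 0")
    if mu_low > mu_high:
        raise InvalidInputError("mu_low must be <= mu_high")
    return (
        estimate_ne(pi, ploidy, mu_high),
        estimate_ne(pi, ploidy, mu_low),
    )


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(ln values)); all values must be positive."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise InvalidInputError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def paired_log_t_test(
    a: Sequence[float], b: Sequence[float]
) -> Tuple[float, int, float]:
    """Paired t test on ln(a) - ln(b); returns (t, df, two-sided p).

    Used e.g. to compare genome-wide with synonymous diversity in species
    reporting both.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("a and b must be equal-length 1-d sequences")
    n = a.size
    if n < 2:
        raise InvalidInputError("need at least 2 pairs")
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidInputError("all values must be positive for log transform")
    d = np.log(a) - np.log(b)
    if np.allclose(d, d[0]):
        if math.isclose(d[0], 0.0, abs_tol=1e-300):
            return 0.0, n - 1, 1.0
        raise InvalidInputError(
            "zero variance in paired log differences (t undefined)"
        )
    t, p = stats.ttest_rel(np.log(a), np.log(b))
    return float(t), n - 1, float(p)


def fit_lognormal(values: Sequence[float]) -> Tuple[float, float]:
    """Maximum-likelihood log-normal fit: (meanlog, sdlog).

    sdlog is the population (ddof=0) standard deviation of the logs, i.e.
    the MLE.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("need at least 2 values")
    if np.any(arr <= 0):
        raise InvalidInputError("log-normal fit requires positive values")
    logs = np.log(arr)
    return float(np.mean(logs)), float(np.std(logs, ddof=0))


def rank_correlation(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Spearman's rank correlation with mid-rank ties; (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidInputError("need two equal-length sequences with n >= 3")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
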