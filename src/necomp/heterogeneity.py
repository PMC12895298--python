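"""Heterogeneity of log Ne within taxonomic groups (Cochran's Q).

Within a group, each species contributes a log-scale Ne estimate and a
variance derived from its 95% CI.  Under the null that all species share
one underlying log Ne, the inverse-variance weighted sum of squared
deviations from the weighted mean is chi-squared with k - 1 degrees of
freedom.  A significant Q indicates more spread in Ne than the
mutation-rate sampling error alone can explain.

Natural logs are used throughout; Q and its p-value are invariant to the
log base provided values and variances use the same base.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .types import HeterogeneityResult

__all__ = ["log_variance_from_ci", "cochran_q"]

#: Variance assigned to degenerate (point) CIs to keep weights finite.
DEGENERATE_CI_VARIANCE = 1e-6


def log_variance_from_ci(ne_ci: Tuple[float, float]) -> float:
    """Variance of ln Ne implied by a 95% CI: ((ln hi - ln lo) / 3.92)^2.

    Scale-free: depends only on the CI ratio.  A point CI maps to variance
    zero; :func:`cochran_q` floors such variances so weights stay finite.
    """
    low, high = ne_ci
    if low <= 0:
        raise InvalidInputError("CI lower bound must be > 0")
    if low > high:
        raise InvalidInputError("CI bounds out of order")
    return float(((np.log(high) - np.log(low)) / (2.0 * 1.96)) ** 2)


def cochran_q(
    log_values: Sequence[float],
    variances: Sequence[float],
    group: str = "",
) -> HeterogeneityResult:
    """Cochran's Q test for heterogeneity of a set of estimates.

    w_i = 1/var_i; xbar = sum(w_i x_i)/sum(w_i); Q = sum(w_i (x_i - xbar)^2);
    p is the upper chi-squared tail with df = k - 1.  Zero variances are
    floored at ``DEGENERATE_CI_VARIANCE``.
    """
    x = np.asarray(log_values, dtype=float)
    v = np.asarray(variances, dtype=float)
    if x.shape != v.shape or x.ndim != 1:
        raise InvalidInputError("values and variances must be equal-length 1-d")
    k = x.size
    if k < 2:
        raise InvalidInputError("need at least 2 estimates")
    if np.any(v < 0):
        raise InvalidInputError("variances must be > 0")
    v = np.where(v == 0.0, DEGENERATE_CI_VARIANCE, v)
    w = 1.0 / v
    xbar = float(np.sum(w * x) / np.sum(w))
    q = float(np.sum(w * (x - xbar) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(
        group=group, q=q, df=df, p=p, weighted_mean_log_ne=xbar, n=k
    )
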