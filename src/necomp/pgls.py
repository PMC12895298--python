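"""Generalized least squares on phylogenies, from first principles.

PGLS fits y = X b + e with e ~ MVN(0, sigma^2 V_lambda), where V is the
Brownian covariance implied by the tree and V_lambda has its off-diagonal
entries scaled by Pagel's lambda.  Lambda is estimated by maximizing the
profile (ML) log-likelihood over [0, lambda_max], where lambda_max is the
numeric positive-definiteness boundary of V_lambda for the tree at hand —
deliberately allowed to exceed 1.  The likelihood-ratio test against
lambda = 0 uses the 50:50 boundary mixture of chi-squared(0) and
chi-squared(1).

All fits are computed through a Cholesky whitening of V: with V = L L',
GLS on (y, X) is OLS on (L^-1 y, L^-1 X).  R^2 is defined against the
intercept-only GLS model under the same V, the convention of the
comparative-methods literature; the source analyses never pin down a
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import InvalidInputError, ModelError
from .phylo import (
    Phylogeny,
    PhyloCovariance,
    lambda_transform,
    max_feasible_lambda,
    vcv_matrix,
)

__all__ = [
    "PGLSResult",
    "gls_fit",
    "ols_fit",
    "fit_pgls_ml_lambda",
    "pagel_lambda_signal",
    "build_design",
]

#: Convergence tolerance of the lambda profile search.
LAMBDA_XTOL = 1e-4
#: Number of coarse grid points bracketing the profile optimum.
LAMBDA_GRID = 20


@dataclass
class PGLSResult:
    """Coefficients and fit statistics for one (P)GLS regression."""

    names: List[str]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    log_likelihood: float
    r2: float
    adj_r2: float
    n: int
    k: int
    lambda_: Optional[float] = None
    lambda_p: Optional[float] = None
    lambda_max: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def summary_row(self) -> Dict[str, object]:
        """Flat dict for tabular reporting (one model per row)."""
        out: Dict[str, object] = {
            "n": self.n,
            "k": self.k,
            "lambda": self.lambda_,
            "lambda_p": self.lambda_p,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "log_likelihood": self.log_likelihood,
        }
        for name, b, s, p in zip(self.names, self.coef, self.se, self.pvalues):
            out[f"coef_{name}"] = b
            out[f"se_{name}"] = s
            out[f"p_{name}"] = p
        return out

    def coef_named(self, name: str) -> Tuple[float, float, float]:
        """(coefficient, SE, p) for a named design column."""
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i]), float(self.pvalues[i])


def _as_design(x_design: np.ndarray, names: Optional[Sequence[str]]):
    x = np.asarray(x_design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
        if x.shape[1] >= 1 and np.allclose(x[:, 0], 1.0):
            names[0] = "intercept"
    return x, list(names)


def _whiten(v: np.ndarray):
    try:
        cho = linalg.cho_factor(v, lower=True)
    except linalg.LinAlgError as exc:
        raise ModelError("covariance matrix not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return cho, logdet


def gls_fit(
    y: Sequence[float],
    x_design: np.ndarray,
    v: PhyloCovariance | np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> PGLSResult:
    """Generalized least squares of ``y`` on ``x_design`` under covariance V.

    b = (X' V^-1 X)^-1 X' V^-1 y; sigma2 = RSS_V/(n-k); SEs from
    sigma2 * diag((X' V^-1 X)^-1); two-sided t p-values with df = n - k.
    The reported log-likelihood is the ML multivariate-normal likelihood
    (variance RSS_V/n).
    """
    y = np.asarray(y, dtype=float)
    x, names = _as_design(x_design, names)
    vm = v.matrix if isinstance(v, PhyloCovariance) else np.asarray(v, float)
    n = y.size
    k = x.shape[1]
    if x.shape[0] != n or vm.shape != (n, n):
        raise InvalidInputError("y, X and V dimensions do not agree")
    if n <= k:
        raise InvalidInputError(f"need n > k (n={n}, k={k})")

    cho, logdet = _whiten(vm)
    yt = linalg.cho_solve(cho, y)       # V^-1 y
    xt = linalg.cho_solve(cho, x)       # V^-1 X
    xtvx = x.T @ xt
    xtvy = x.T @ yt
    try:
        xtvx_inv = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError as exc:
        raise ModelError("singular X' V^-1 X (collinear design)") from exc
    cond = np.linalg.cond(xtvx)
    if cond > 1e12:
        raise ModelError(f"near-singular design (cond={cond:.3g})")
    beta = xtvx_inv @ xtvy
    resid = y - x @ beta
    rss = float(resid @ linalg.cho_solve(cho, resid))
    rss = max(rss, 0.0)
    sigma2 = rss / (n - k)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtvx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    # ML log-likelihood (variance rss/n)
    sig_ml = max(rss / n, 1e-300)
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sig_ml) + logdet + n)

    # R^2 against the intercept-only GLS fit under the same V
    ones = np.ones((n, 1))
    ot = linalg.cho_solve(cho, ones)
    mu = float((ones[:, 0] @ yt) / (ones[:, 0] @ ot[:, 0]))
    r0 = y - mu
    tss = float(r0 @ linalg.cho_solve(cho, r0))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else np.nan)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k)

    return PGLSResult(
        names=names,
        coef=beta,
        se=se,
        tvalues=np.asarray(tvals, float),
        pvalues=np.asarray(pvals, float),
        sigma2=sigma2,
        log_likelihood=float(loglik),
        r2=float(r2),
        adj_r2=float(adj_r2),
        n=n,
        k=k,
    )


def ols_fit(
    y: Sequence[float],
    x_design: np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> PGLSResult:
    """Ordinary least squares: :func:`gls_fit` with identity covariance."""
    y = np.asarray(y, dtype=float)
    return gls_fit(y, x_design, np.eye(y.size), names=names)


def _profile_loglik(
    lam: float, y: np.ndarray, x: np.ndarray, v: PhyloCovariance
) -> float:
    m = v.matrix * lam
    np.fill_diagonal(m, np.diag(v.matrix))
    n, k = x.shape
    try:
        cho, logdet = _whiten(m)
    except ModelError:
        return -np.inf
    yt = linalg.cho_solve(cho, y)
    xt = linalg.cho_solve(cho, x)
    xtvx = x.T @ xt
    try:
        beta = np.linalg.solve(xtvx, x.T @ yt)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = y - x @ beta
    rss = float(resid @ linalg.cho_solve(cho, resid))
    sig_ml = max(rss / n, 1e-300)
    return float(-0.5 * (n * np.log(2.0 * np.pi * sig_ml) + logdet + n))


def fit_pgls_ml_lambda(
    y: Sequence[float],
    x_design: np.ndarray,
    tree: Phylogeny | PhyloCovariance,
    taxa: Optional[Sequence[str]] = None,
    names: Optional[Sequence[str]] = None,
    lambda_bound: str = "brownian",
) -> PGLSResult:
    """PGLS with Pagel's lambda estimated by maximum likelihood.

    ``taxa`` gives the row order of ``y``/``x_design``; it defaults to the
    tree's tip order.  The profile likelihood is maximized on
    [0, upper] with a coarse grid followed by bounded Brent refinement.

    ``lambda_bound`` selects the upper search limit: ``"brownian"`` (the
    default) caps lambda at 1, which keeps slope confidence intervals at
    nominal coverage when the truth sits at the Brownian ceiling;
    ``"pd"`` searches up to the numeric positive-definiteness boundary of
    the tree's covariance, allowing super-Brownian estimates (e.g. 1.02)
    for comparability with analyses that report lambda > 1, at the cost
    of mildly anticonservative slope intervals near lambda = 1.
    """
    y = np.asarray(y, dtype=float)
    x, names = _as_design(x_design, names)
    if isinstance(tree, Phylogeny):
        if tree.n_tips < 4:
            raise InvalidInputError("need at least 4 taxa for lambda ML")
        tree.check_ultrametric()
        v = vcv_matrix(tree)
    else:
        v = tree
    if taxa is not None:
        v = v.reorder(taxa)
    elif len(v.taxa) != y.size:
        raise InvalidInputError("y length does not match tree tips")

    if np.var(y) == 0:
        raise InvalidInputError("response has zero variance")

    offdiag = v.matrix[~np.eye(len(v.taxa), dtype=bool)]
    flags: List[str] = []
    if np.allclose(offdiag, 0.0):
        # star phylogeny: profile flat in lambda, signal non-identifiable
        res = gls_fit(y, x, v, names=names)
        res.lambda_ = 0.0
        res.lambda_p = 1.0
        res.lambda_max = 0.0
        res.flags.append("lambda-non-identifiable")
        return res

    lam_pd = max_feasible_lambda(v)
    # stay strictly inside the PD boundary for numerical stability
    if lambda_bound == "pd":
        lam_max = lam_pd
    elif lambda_bound == "brownian":
        lam_max = min(1.0, lam_pd)
    else:
        raise InvalidInputError(
            f"lambda_bound must be 'brownian' or 'pd', got {lambda_bound!r}"
        )
    hi = lam_max * (1.0 - 1e-6)

    grid = np.linspace(0.0, hi, LAMBDA_GRID)
    ll_grid = np.array([_profile_loglik(l, y, x, v) for l in grid])
    if not np.any(np.isfinite(ll_grid)):
        raise ModelError(
            "lambda profile likelihood non-finite everywhere; "
            f"grid={list(grid)}"
        )
    best = int(np.nanargmax(ll_grid))
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, len(grid) - 1)]
    if lo_b == hi_b:
        lam_hat = float(grid[best])
    else:
        opt = optimize.minimize_scalar(
            lambda l: -_profile_loglik(l, y, x, v),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": LAMBDA_XTOL},
        )
        lam_hat = float(opt.x)
        # keep whichever is better of the grid point and the refinement
        if _profile_loglik(lam_hat, y, x, v) < ll_grid[best]:
            lam_hat = float(grid[best])
    if lam_hat < LAMBDA_XTOL:
        lam_hat = 0.0

    v_hat = lambda_transform(v, lam_hat)
    res = gls_fit(y, x, v_hat, names=names)
    ll_hat = _profile_loglik(lam_hat, y, x, v)
    ll_0 = _profile_loglik(0.0, y, x, v)
    lrt = max(0.0, 2.0 * (ll_hat - ll_0))
    # boundary-corrected: 50:50 mixture of chi2(0) and chi2(1)
    res.lambda_ = lam_hat
    res.lambda_p = 1.0 if lrt <= 0 else float(0.5 * stats.chi2.sf(lrt, 1))
    res.lambda_max = lam_max
    res.log_likelihood = float(ll_hat)
    res.flags.extend(flags)
    return res


def pagel_lambda_signal(
    trait: Sequence[float],
    tree: Phylogeny | PhyloCovariance,
    taxa: Optional[Sequence[str]] = None,
) -> Tuple[float, float]:
    """Phylogenetic signal of a single trait: ML lambda of the
    intercept-only model and the boundary-corrected LRT p versus
    lambda = 0."""
    trait = np.asarray(trait, dtype=float)
    x = np.ones((trait.size, 1))
    res = fit_pgls_ml_lambda(trait, x, tree, taxa=taxa, names=["intercept"])
    return float(res.lambda_), float(res.lambda_p)


def build_design(
    traits: pd.DataFrame,
    predictors: Sequence[str],
    fixed_effects: Sequence[str] = (),
    interactions: Sequence[Tuple[str, str]] = (),
    standardize: bool = False,
) -> Tuple[np.ndarray, List[str]]:
    """Design matrix: intercept + log10 continuous predictors (+ optional
    z-scoring) + dummy-coded categoricals (reference = first level
    alphabetically) + requested interactions.

    Rows with missing values must be dropped by the caller beforehand
    (with the tree pruned to match); missing values here are an error.
    """
    cols: List[np.ndarray] = [np.ones(len(traits))]
    names: List[str] = ["intercept"]
    by_name: Dict[str, np.ndarray] = {}

    selected = list(predictors) + list(fixed_effects)
    for c in selected:
        if c not in traits.columns:
            raise InvalidInputError(f"unknown column {c!r}")
        if traits[c].isna().any():
            bad = traits.index[traits[c].isna()].tolist()
            raise InvalidInputError(f"missing values in {c!r}: rows {bad}")

    for c in predictors:
        vals = traits[c].to_numpy(dtype=float)
        if np.any(vals <= 0):
            bad = traits.index[traits[c] <= 0].tolist()
            raise InvalidInputError(
                f"nonpositive values in {c!r} (log transform): rows {bad}"
            )
        col = np.log10(vals)
        if standardize:
            sd = col.std(ddof=0)
            if sd == 0:
                raise InvalidInputError(f"constant predictor {c!r}")
            col = (col - col.mean()) / sd
        name = f"log_{c}"
        cols.append(col)
        names.append(name)
        by_name[c] = col

    for c in fixed_effects:
        levels = sorted(pd.unique(traits[c].astype(str)))
        if len(levels) < 2:
            raise InvalidInputError(
                f"categorical {c!r} has a single level: {levels}"
            )
        for lev in levels[1:]:  # first level alphabetically is reference
            col = (traits[c].astype(str) == lev).to_numpy(dtype=float)
            name = f"{c}[{lev}]"
            cols.append(col)
            names.append(name)
            by_name[f"{c}[{lev}]"] = col

    for a, b in interactions:
        ca = by_name.get(a)
        cb = by_name.get(b)
        # allow interacting a categorical dummy by bare factor name
        if ca is None:
            matches = [k for k in by_name if k.startswith(f"{a}[")]
            if len(matches) == 1:
                ca = by_name[matches[0]]
                a = matches[0]
        if cb is None:
            matches = [k for k in by_name if k.startswith(f"{b}[")]
            if len(matches) == 1:
                cb = by_name[matches[0]]
                b = matches[0]
        if ca is None or cb is None:
            raise InvalidInputError(f"interaction terms unknown: ({a}, {b})")
        cols.append(ca * cb)
        names.append(f"{a}:{b}")

    return np.column_stack(cols), names
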