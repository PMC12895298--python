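"""Self-calibration experiments.

Each function runs one end-to-end check of the package's statistical
machinery on synthetic data with known truth and returns the measured
quantities: estimator recovery, GLS equivalence with the closed-form
solution, ML-lambda recovery with slope CI coverage, Cochran's Q type-I
error, and Wilson-interval coverage at mutation-rate-scale proportions.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats

from .heterogeneity import cochran_q
from .ne_core import binomial_rate_ci
from .pgls import fit_pgls_ml_lambda, gls_fit, ols_fit
from .phylo import lambda_transform, vcv_matrix
from .pipeline import run_ne_pipeline
from .simulate import SimulationConfig, simulate_bundle, simulate_tree

__all__ = [
    "exact_pipeline_recovery",
    "gls_oracle_check",
    "lambda_recovery",
    "cochran_q_type1_error",
    "wilson_coverage",
]


def exact_pipeline_recovery(seed: int = 0, n_tips: int = 200) -> float:
    """Max relative Ne error when pi is generated exactly as 2 x Ne mu
    and every observation noise source is off.  Should be ~1e-16."""
    cfg = SimulationConfig(
        n_tips=n_tips, seed=seed, exact=True,
        studies_per_species=1, pi_per_species=1,
    )
    tree, truth, mut, div, spt = simulate_bundle(cfg)
    ne = run_ne_pipeline(spt, mut, div)
    merged = ne.merge(truth.reset_index(), on="species_id")
    if len(merged) != n_tips:
        raise AssertionError("species lost in exact-mode pipeline")
    rel = np.abs(merged["ne"].to_numpy() / 10.0 ** merged["log10_ne_true"].to_numpy() - 1.0)
    return float(rel.max())


def gls_oracle_check(seed: int = 0) -> Dict[str, float]:
    """Two equivalences: GLS on the worked 3-taxon tree versus the direct
    matrix formula, and GLS under V = I versus OLS.  Returns max absolute
    coefficient discrepancies."""
    from .phylo import parse_newick

    tree = parse_newick("((A:1,B:1):1,C:2);")
    v = vcv_matrix(tree).reorder(["A", "B", "C"])
    y = np.array([1.0, 2.0, 4.0])
    x = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
    vi = np.linalg.inv(v.matrix)
    beta_oracle = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    diff_tree = float(np.abs(gls_fit(y, x, v).coef - beta_oracle).max())

    rng = np.random.default_rng(seed)
    n = 40
    xr = np.column_stack([np.ones(n), rng.normal(size=n)])
    yr = 1.0 + 0.5 * xr[:, 1] + rng.normal(size=n)
    g = gls_fit(yr, xr, np.eye(n))
    o = ols_fit(yr, xr)
    diff_ols = float(
        max(
            np.abs(g.coef - o.coef).max(),
            np.abs(g.se - o.se).max(),
            abs(g.r2 - o.r2),
        )
    )
    return {"tree_oracle": diff_tree, "ols_identity": diff_ols}


def lambda_recovery(
    lambda_true: float,
    seed: int,
    n_tips: int = 200,
    reps: int = 500,
    beta1: float = -0.5,
    sigma: float = 0.5,
) -> Dict[str, float]:
    """Repeatedly simulate a regression with residual signal
    ``lambda_true`` on one fixed Yule tree and refit by ML.

    Returns the mean lambda estimate and the fraction of replicates whose
    95% t-interval on the slope covers the truth.
    """
    ss = np.random.SeedSequence([seed, int(round(lambda_true * 1000))])
    rng_tree_seed, rng = ss.spawn(2)
    tree = simulate_tree(n_tips, int(rng_tree_seed.generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(rng)
    v = vcv_matrix(tree)
    vl = lambda_transform(v, lambda_true)
    l_pred = np.linalg.cholesky(v.matrix)
    l_eps = np.linalg.cholesky(vl.matrix) * sigma
    lam_hats = np.empty(reps)
    covered = 0
    for r in range(reps):
        x1 = l_pred @ rng.standard_normal(n_tips)
        y = 2.0 + beta1 * x1 + l_eps @ rng.standard_normal(n_tips)
        res = fit_pgls_ml_lambda(
            y, np.column_stack([np.ones(n_tips), x1]), v,
            names=["intercept", "x1"],
        )
        lam_hats[r] = res.lambda_
        b, se, _ = res.coef_named("x1")
        tcrit = stats.t.ppf(0.975, res.n - res.k)
        if abs(b - beta1) <= tcrit * se:
            covered += 1
    return {
        "lambda_true": lambda_true,
        "mean_lambda_hat": float(lam_hats.mean()),
        "sd_lambda_hat": float(lam_hats.std(ddof=1)),
        "beta1_coverage": covered / reps,
        "reps": reps,
        "n_tips": n_tips,
    }


def cochran_q_type1_error(
    seed: int, reps: int = 10_000, k: int = 10, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of Cochran's Q when all estimates share
    one mean and their stated variances are correct (should be ~alpha)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51]))
    rejections = 0
    for _ in range(reps):
        var = rng.uniform(0.5, 2.0, size=k)
        x = rng.standard_normal(k) * np.sqrt(var)
        if cochran_q(x, var).p < alpha:
            rejections += 1
    return rejections / reps


def wilson_coverage(
    seed: int,
    reps: int = 2_000,
    p: float = 1e-8,
    n: int = 10**9,
    level: float = 0.95,
) -> float:
    """Coverage of the Wilson interval for a rare-event proportion at the
    scale of de novo mutation rates (expected count n p = 10)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x717]))
    counts = rng.binomial(n, p, size=reps)
    hits = 0
    for c in counts:
        lo, hi = binomial_rate_ci(int(c), n, level)
        if lo <= p <= hi:
            hits += 1
    return hits / reps
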