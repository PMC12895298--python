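"""End-to-end orchestration of the comparative Ne analysis.

Stages: (1) species-level Ne table from raw mutation-rate and diversity
tables, with domesticated species excluded, pi averaged across
populations, mutation rates effort-weighted across studies and the mu CI
propagated onto Ne; (2) per-group summaries and heterogeneity; (3) PGLS
model suites on derived traits; (4) the split-half validation that guards
the diversity-vs-Ne regression against correlated sampling error.

Every row excluded at any stage is logged with a machine-readable reason
code; output tables are sorted by species_id so re-runs are
byte-identical.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .heterogeneity import cochran_q, log_variance_from_ci
from .ne_core import (
    estimate_ne,
    fit_lognormal,
    mean_pi_across_populations,
    propagate_ne_ci,
    weighted_mean_mu,
)
from .pgls import PGLSResult, build_design, fit_pgls_ml_lambda, pagel_lambda_signal
from .phylo import Phylogeny, prune_to_taxa
from .types import DiversityEstimate, GroupSummary, MutationRateEstimate

logger = logging.getLogger("necomp")

__all__ = [
    "run_ne_pipeline",
    "group_summaries",
    "group_signal_table",
    "split_half_validation",
    "run_model_suite",
]


def _mutation_records(df: pd.DataFrame) -> List[MutationRateEstimate]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key, cast=float):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

        recs.append(
            MutationRateEstimate(
                species_id=str(d["species_id"]),
                rate=float(d["rate"]),
                n_mutations=opt("n_mutations", int),
                callable_sites=opt("callable_sites", int),
                ci_low=opt("ci_low"),
                ci_high=opt("ci_high"),
                effort=float(d.get("effort", 1.0)),
                method=str(d.get("method", "pedigree")),
            )
        )
    return recs


def _species_mu(
    records: List[MutationRateEstimate], species_id: str
) -> Tuple[Optional[MutationRateEstimate], int, Optional[str]]:
    """Weighted-mean mu for one species; zero-rate studies are dropped
    (their log-scale information content is nil) with a warning."""
    mine = [r for r in records if r.species_id == species_id]
    usable = [r for r in mine if r.rate > 0]
    dropped = len(mine) - len(usable)
    if dropped:
        logger.warning(
            "%s: dropped %d zero-rate mutation stud%s [reason=zero_rate_study]",
            species_id,
            dropped,
            "y" if dropped == 1 else "ies",
        )
    if not usable:
        return None, 0, "no_usable_mu"
    return weighted_mean_mu(usable), len(usable), None


def run_ne_pipeline(
    species: pd.DataFrame,
    mutation: pd.DataFrame,
    diversity: pd.DataFrame,
) -> pd.DataFrame:
    """Species-level Ne table.

    Columns: species_id, ne, ci_low, ci_high, mu_used, pi_used,
    n_mu_studies, n_pi_estimates, group, log_ne_variance, plus species
    metadata carried through.  Species lacking either a usable mutation
    rate or a diversity estimate, and domesticated species, are excluded
    with logged reasons.
    """
    n_in = species["species_id"].nunique()
    sp = species.copy()
    dom = sp.loc[sp["domesticated"].astype(bool), "species_id"].tolist()
    if dom:
        logger.info(
            "excluding %d domesticated species [reason=domesticated]: %s",
            len(dom),
            ", ".join(sorted(dom)),
        )
    sp = sp[~sp["domesticated"].astype(bool)]

    mut_records = _mutation_records(mutation)
    rows = []
    excluded: Dict[str, str] = {}
    for row in sp.itertuples(index=False):
        sid = str(row.species_id)
        div = diversity[diversity["species_id"] == sid]
        if div.empty:
            excluded[sid] = "no_pi"
            continue
        mu, n_mu, reason = _species_mu(mut_records, sid)
        if mu is None:
            excluded[sid] = reason or "no_usable_mu"
            continue
        div_records = [
            DiversityEstimate(
                species_id=sid,
                pi=float(r.pi),
                site_class=str(r.site_class),
                population_label=str(r.population_label),
                sampling_scope=str(r.sampling_scope),
            )
            for r in div.itertuples(index=False)
        ]
        pi = mean_pi_across_populations(div_records)
        if pi.pi <= 0:
            excluded[sid] = "zero_pi"
            continue
        ploidy = int(row.ploidy)
        ne = estimate_ne(pi.pi, ploidy, mu.rate)
        if mu.has_ci and mu.ci_low > 0:
            lo, hi = propagate_ne_ci(pi.pi, ploidy, (mu.ci_low, mu.ci_high))
        else:
            lo, hi = ne, ne
            logger.warning(
                "%s: no positive mu CI, Ne CI degenerate [reason=no_mu_ci]",
                sid,
            )
        rows.append(
            {
                "species_id": sid,
                "ne": ne,
                "ci_low": lo,
                "ci_high": hi,
                "mu_used": mu.rate,
                "pi_used": pi.pi,
                "n_mu_studies": n_mu,
                "n_pi_estimates": len(div_records),
                "group": str(row.group),
                "reproductive_mode": str(row.reproductive_mode),
                "ploidy": ploidy,
                "log_ne_variance": log_variance_from_ci((lo, hi))
                if lo > 0
                else np.nan,
            }
        )
    for sid, reason in excluded.items():
        logger.info("excluded %s [reason=%s]", sid, reason)
    out = pd.DataFrame(rows).sort_values("species_id").reset_index(drop=True)
    logger.info(
        "Ne pipeline: %d species in, %d domesticated, %d excluded, %d out",
        n_in,
        len(dom),
        len(excluded),
        len(out),
    )
    return out


def group_summaries(
    ne_table: pd.DataFrame, min_n_lognormal: int = 10
) -> List[GroupSummary]:
    """Per-group n, median (midpoint convention), extremes with species
    names, and a log-normal fit where n >= ``min_n_lognormal``."""
    out = []
    for group, sub in ne_table.groupby("group"):
        if sub.empty:
            logger.warning("empty group %s omitted", group)
            continue
        ne = sub["ne"].to_numpy()
        imin = int(np.argmin(ne))
        imax = int(np.argmax(ne))
        meanlog = sdlog = None
        if len(ne) >= min_n_lognormal:
            meanlog, sdlog = fit_lognormal(ne)
        out.append(
            GroupSummary(
                group=str(group),
                n=len(sub),
                median_ne=float(np.median(ne)),
                min_ne=float(ne[imin]),
                max_ne=float(ne[imax]),
                min_species=str(sub["species_id"].iloc[imin]),
                max_species=str(sub["species_id"].iloc[imax]),
                lognormal_meanlog=meanlog,
                lognormal_sdlog=sdlog,
            )
        )
    return sorted(out, key=lambda g: g.group)


def group_signal_table(
    ne_table: pd.DataFrame,
    tree: Phylogeny,
    min_group_n: int = 4,
) -> pd.DataFrame:
    """Per-group phylogenetic signal (Pagel's lambda of log10 Ne) and
    Cochran's Q heterogeneity, plus an "all" row for lambda across the
    whole tree."""
    in_tree = set(tree.tip_labels)
    tab = ne_table[ne_table["species_id"].isin(in_tree)]
    lost = sorted(set(ne_table["species_id"]) - in_tree)
    if lost:
        logger.warning(
            "%d species absent from tree dropped [reason=not_in_tree]: %s",
            len(lost),
            ", ".join(lost),
        )
    rows = []

    def _signal(sub: pd.DataFrame):
        sub = sub.sort_values("species_id")
        sub_tree = prune_to_taxa(tree, sub["species_id"])
        lam, p = pagel_lambda_signal(
            np.log10(sub["ne"].to_numpy()),
            sub_tree,
            taxa=list(sub["species_id"]),
        )
        return lam, p

    groups = list(tab.groupby("group")) + [("all", tab)]
    for group, sub in groups:
        row: Dict[str, object] = {"group": group, "n": len(sub)}
        if len(sub) >= min_group_n:
            lam, lam_p = _signal(sub)
            row["lambda"] = lam
            row["lambda_p"] = lam_p
        else:
            row["lambda"] = np.nan
            row["lambda_p"] = np.nan
            logger.warning(
                "group %s too small for lambda (n=%d)", group, len(sub)
            )
        if group != "all" and len(sub) >= 2:
            var = sub["log_ne_variance"].to_numpy(dtype=float)
            var = np.where(np.isnan(var), 1e-6, var)
            het = cochran_q(np.log(sub["ne"].to_numpy()), var, group=str(group))
            row.update(q=het.q, q_df=het.df, q_p=het.p)
        rows.append(row)
    return pd.DataFrame(rows)


def split_half_validation(
    diversity: pd.DataFrame,
    mutation: pd.DataFrame,
    species: pd.DataFrame,
    tree: Phylogeny,
    min_species: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PGLSResult, PGLSResult]:
    """Diversity-vs-Ne regression free of correlated sampling error.

    Species with >= 2 independent pi estimates have them split into two
    sets (deterministic alternation after sorting by population_label, or
    a seeded random split when ``rng`` is given).  Set B's mean pi builds
    Ne while set A's is the response, and vice versa; returns the two
    PGLS fits (log10 pi on log10 Ne, ML lambda).
    """
    counts = diversity.groupby("species_id").size()
    eligible = set(counts[counts >= 2].index) & set(tree.tip_labels)
    sp_ok = species[
        species["species_id"].isin(eligible)
        & ~species["domesticated"].astype(bool)
    ]
    eligible = sorted(set(sp_ok["species_id"]))
    if len(eligible) < min_species:
        raise InvalidInputError(
            f"split-half needs >= {min_species} species with >= 2 pi "
            f"estimates, found {len(eligible)}"
        )
    div = diversity[diversity["species_id"].isin(eligible)].copy()
    div = div.sort_values(["species_id", "population_label"]).reset_index(
        drop=True
    )
    halves = {0: [], 1: []}
    for _, sub in div.groupby("species_id", sort=True):
        order = np.arange(len(sub))
        if rng is not None:
            order = rng.permutation(order)
        for pos, (_, r) in zip(order, sub.iterrows()):
            halves[int(pos) % 2].append(r)
    half_a = pd.DataFrame(halves[0])
    half_b = pd.DataFrame(halves[1])

    results = []
    for resp_half, ne_half in ((half_a, half_b), (half_b, half_a)):
        ne_tab = run_ne_pipeline(sp_ok, mutation, ne_half)
        resp_pi = resp_half.groupby("species_id")["pi"].mean()
        merged = ne_tab.merge(
            resp_pi.rename("pi_resp"), left_on="species_id", right_index=True
        ).sort_values("species_id")
        sub_tree = prune_to_taxa(tree, merged["species_id"])
        x, names = build_design(
            merged.set_index("species_id"), predictors=["ne"]
        )
        res = fit_pgls_ml_lambda(
            np.log10(merged["pi_resp"].to_numpy()),
            x,
            sub_tree,
            taxa=list(merged["species_id"]),
            names=names,
        )
        results.append(res)
    return results[0], results[1]


def run_model_suite(
    ne_table: pd.DataFrame,
    traits: pd.DataFrame,
    tree: Phylogeny,
    model_specs: Sequence[Dict],
) -> pd.DataFrame:
    """Fit a batch of PGLS models, one row of summary output per model.

    Each spec is a dict with keys ``response`` (column name; log10 applied
    unless it already starts with "log"), ``predictors`` (list),
    optional ``fixed_effects``, ``interactions``, ``standardize`` and
    ``name``.  Rows with missing data are dropped per model and the tree
    pruned to match.
    """
    data = ne_table.merge(traits, on="species_id", how="left")
    data = data[data["species_id"].isin(set(tree.tip_labels))]
    rows = []
    for spec in model_specs:
        response = spec["response"]
        predictors = list(spec.get("predictors", []))
        fixed = list(spec.get("fixed_effects", []))
        inter = [tuple(p) for p in spec.get("interactions", [])]
        standardize = bool(spec.get("standardize", False))
        for col in [response] + predictors + fixed:
            if col not in data.columns:
                raise InvalidInputError(
                    f"model {spec.get('name', response)!r}: unknown column {col!r}"
                )
        cols = [response] + predictors + fixed
        sub = data.dropna(subset=cols).sort_values("species_id")
        sub = sub.set_index("species_id")
        if len(sub) < 4:
            logger.warning(
                "model %s skipped: only %d complete cases",
                spec.get("name", response),
                len(sub),
            )
            continue
        x, names = build_design(
            sub,
            predictors=predictors,
            fixed_effects=fixed,
            interactions=inter,
            standardize=standardize,
        )
        y = sub[response].to_numpy(dtype=float)
        if not str(response).startswith("log"):
            if np.any(y <= 0):
                raise InvalidInputError(
                    f"response {response!r} must be positive for log scale"
                )
            y = np.log10(y)
        sub_tree = prune_to_taxa(tree, sub.index)
        res = fit_pgls_ml_lambda(
            y, x, sub_tree, taxa=list(sub.index), names=names
        )
        row = {"model": spec.get("name", response), "response": response}
        row.update(res.summary_row())
        rows.append(row)
    return pd.DataFrame(rows)
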