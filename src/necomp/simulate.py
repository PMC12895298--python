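"""Synthetic study generator with known ground truth.

Emulates the structure of a literature-curated comparative dataset:

* an ultrametric Yule phylogeny (rescaled to unit root-to-tip depth);
* a log10 predictor trait evolving by Brownian motion on the tree;
* true log10 Ne = beta0 + beta1 * log10 predictor + eps, with eps drawn
  MVN(0, sigma2 * V_lambda) so the residual carries tunable phylogenetic
  signal lambda_true;
* per-species true mutation rates drawn log-normally (log10 scale);
* per-study observed mutation counts ~ Poisson(mu * callable_sites)
  (an excellent approximation to the binomial at rates ~1e-8), reported
  as rate = count / callable_sites with a Wilson CI and a random effort;
* true pi = 2 * ploidy * Ne_true * mu, observed as one or more
  multiplicatively log-normal-perturbed population estimates.

``exact=True`` switches off every observation noise source, so the
reported rate equals the true mu and the reported pi equals the true pi;
the pipeline must then recover Ne_true to machine precision.

One global seed is expanded into independent per-stage substreams
(tree / traits / observations) so stages re-run independently but
reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .ne_core import binomial_rate_ci
from .phylo import Phylogeny, lambda_transform, vcv_matrix

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_comparative_traits",
    "simulate_observation_layer",
    "simulate_bundle",
]

GROUP_NAMES = (
    "mammals",
    "birds",
    "fish",
    "arthropods",
    "fungi",
    "plants",
    "protists",
    "reptiles",
)


@dataclass
class SimulationConfig:
    """Study-scale generator settings.

    Defaults mirror a literature-compilation comparative study: ~200
    species, strong residual phylogenetic signal (lambda 0.9), a shallow
    negative log-log trait effect, species mutation rates scattered around
    10^-8.5 per site per generation, and a couple of independent diversity
    estimates per species with ~10% log-scale observation noise.
    """

    n_tips: int = 200
    seed: int = 0
    lambda_true: float = 0.9
    sigma2: float = 0.2
    beta0: float = 5.0
    beta1: float = -0.5
    mu_log10_mean: float = -8.5
    mu_log10_sd: float = 0.3
    callable_sites: int = 10_000_000_000
    studies_per_species: int = 2
    pi_obs_cv: float = 0.1
    ploidy: int = 2
    pi_per_species: int = 2
    n_groups: int = 4
    frac_asexual: float = 0.1
    frac_domesticated: float = 0.06
    exact: bool = False

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise InvalidInputError("n_tips must be >= 4")
        if self.lambda_true < 0 or self.sigma2 <= 0:
            raise InvalidInputError("lambda_true >= 0 and sigma2 > 0 required")
        if self.studies_per_species < 1 or self.pi_per_species < 1:
            raise InvalidInputError("need >= 1 study and pi estimate each")
        if self.pi_obs_cv < 0:
            raise InvalidInputError("pi_obs_cv must be >= 0")
        if self.ploidy < 1:
            raise InvalidInputError("ploidy must be >= 1")


def _substreams(seed: int, n: int = 3):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Yule (pure-birth) tree on ``n_tips`` extant tips, rescaled to unit
    root-to-tip depth.  Deterministic: one seed, one Newick string."""
    if n_tips < 4:
        raise InvalidInputError("n_tips must be >= 4")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EE]))

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    # active lineages: (node, birth_time)
    root = tree.seed_node
    t = 0.0
    active = []
    birth = {id(root): 0.0}
    # split the root immediately so the tree is rooted-bifurcating
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active.pop(int(i))
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    labels = [f"s{i:04d}" for i in range(n_tips)]
    for node, label in zip(active, labels):
        node.edge.length = t_end - birth[id(node)]
        node.taxon = taxon_ns.new_taxon(label)
    # rescale to unit depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_end
    return Phylogeny(tree)


def simulate_comparative_traits(
    tree: Phylogeny, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ground-truth trait table: ``log10_predictor`` (Brownian on the tree)
    and ``log10_ne_true`` with residual signal ``lambda_true``."""
    if rng is None:
        rng = _substreams(config.seed)[1]
    v = vcv_matrix(tree)
    n = len(v.taxa)
    lv = lambda_transform(v, config.lambda_true)
    l_pred = np.linalg.cholesky(v.matrix)
    l_eps = np.linalg.cholesky(config.sigma2 * lv.matrix)
    log_pred = l_pred @ rng.standard_normal(n)
    eps = l_eps @ rng.standard_normal(n)
    log_ne = config.beta0 + config.beta1 * log_pred + eps
    return pd.DataFrame(
        {
            "species_id": v.taxa,
            "log10_predictor": log_pred,
            "log10_ne_true": log_ne,
        }
    ).set_index("species_id")


def simulate_observation_layer(
    tree: Phylogeny,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Observation tables (mutation studies, diversity estimates, species
    metadata) for a ground-truth table aligned to the tree tips."""
    if rng is None:
        rng = _substreams(config.seed)[2]
    taxa = list(truth.index)
    if set(taxa) != set(tree.tip_labels):
        raise InvalidInputError("truth table does not match tree tips")
    n = len(taxa)

    ne_true = 10.0 ** truth["log10_ne_true"].to_numpy()
    mu_true = 10.0 ** (
        config.mu_log10_mean + config.mu_log10_sd * rng.standard_normal(n)
    )
    pi_true = 2.0 * config.ploidy * ne_true * mu_true
    if np.any(pi_true >= 1.0):
        raise InvalidInputError(
            "simulated pi >= 1; lower beta0 or mu_log10_mean"
        )

    mut_rows = []
    div_rows = []
    sp_rows = []
    # contiguous blocks of tips in tree order stand in for taxonomic groups
    group_of = {
        t: GROUP_NAMES[min(i * config.n_groups // n, config.n_groups - 1)]
        for i, t in enumerate(tree.tip_labels)
    }

    for i, sp in enumerate(taxa):
        for j in range(config.studies_per_species):
            method = "pedigree" if j % 2 == 0 else "mutation_accumulation"
            if config.exact:
                rate = mu_true[i]
                count = int(round(rate * config.callable_sites))
                lo = hi = rate
                effort = 1.0
            else:
                count = int(rng.poisson(mu_true[i] * config.callable_sites))
                rate = count / config.callable_sites
                lo, hi = binomial_rate_ci(count, config.callable_sites)
                effort = float(rng.integers(2, 51))
            mut_rows.append(
                {
                    "species_id": sp,
                    "rate": rate,
                    "n_mutations": count,
                    "callable_sites": config.callable_sites,
                    "ci_low": lo,
                    "ci_high": hi,
                    "effort": effort,
                    "method": method,
                }
            )
        for j in range(config.pi_per_species):
            if config.exact or config.pi_obs_cv == 0:
                pi_obs = pi_true[i]
            else:
                sd = np.sqrt(np.log1p(config.pi_obs_cv**2))
                # mean-one multiplicative log-normal perturbation
                pi_obs = pi_true[i] * np.exp(
                    sd * rng.standard_normal() - 0.5 * sd**2
                )
            div_rows.append(
                {
                    "species_id": sp,
                    "pi": min(pi_obs, 0.999),
                    "site_class": "genome_wide" if j % 2 == 0 else "synonymous",
                    "theta_w": np.nan,
                    "population_label": f"pop{j:02d}",
                    "sampling_scope": "single_population",
                }
            )
        asexual = (not config.exact) and rng.random() < config.frac_asexual
        domesticated = (
            (not config.exact) and rng.random() < config.frac_domesticated
        )
        sp_rows.append(
            {
                "species_id": sp,
                "ploidy": config.ploidy,
                "group": group_of[sp],
                "reproductive_mode": "asexual" if asexual else "sexual",
                "domesticated": domesticated,
            }
        )

    mut = pd.DataFrame(mut_rows)
    div = pd.DataFrame(div_rows)
    spt = pd.DataFrame(sp_rows)
    return mut, div, spt


def simulate_bundle(config: SimulationConfig):
    """Full synthetic study: (tree, truth, mutation, diversity, species)."""
    rng_tree, rng_traits, rng_obs = _substreams(config.seed)
    del rng_tree  # simulate_tree derives its own stream from the seed
    tree = simulate_tree(config.n_tips, config.seed)
    truth = simulate_comparative_traits(tree, config, rng_traits)
    mut, div, spt = simulate_observation_layer(tree, truth, config, rng_obs)
    return tree, truth, mut, div, spt
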