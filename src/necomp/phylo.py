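"""Phylogenies and phylogenetic covariance.

A :class:`Phylogeny` wraps a rooted, ultrametric dendropy tree with
branch lengths in time units.  Under Brownian-motion trait evolution,
the expected covariance between two tips equals the shared path length
from the root to their most recent common ancestor; root-to-tip depth
gives the variance.  That matrix (the phylogenetic VCV) is what the
comparative regressions consume.

Pagel's lambda rescales the off-diagonal covariances: lambda = 0 removes
all phylogenetic structure (independent tips), lambda = 1 is pure
Brownian motion, and values slightly above 1 can remain feasible
(positive definite) on real trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import dendropy
import numpy as np

from .errors import TreeError

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "vcv_matrix",
    "lambda_transform",
]

#: Relative tolerance on root-to-tip depth spread for the ultrametric check.
ULTRAMETRIC_RTOL = 1e-3


@dataclass
class PhyloCovariance:
    """Square Brownian covariance matrix indexed by tip labels."""

    taxa: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise TreeError("covariance matrix shape does not match taxa")

    def reorder(self, taxa: Sequence[str]) -> "PhyloCovariance":
        """Return a copy with rows/columns in the order of ``taxa``."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise TreeError(f"taxa absent from covariance: {missing}")
        idx = np.array([index[t] for t in taxa])
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)])


class Phylogeny:
    """Rooted ultrametric tree with unique tip labels and branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise TreeError(
                    "missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise TreeError("negative branch length")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> Dict[str, float]:
        """Root-to-tip path length for every tip."""
        out: Dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = np.array(list(self.depths().values()))
        dmax = d.max()
        return bool(dmax == 0 or (dmax - d.min()) <= rtol * dmax)

    def check_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> None:
        if not self.is_ultrametric(rtol):
            d = self.depths()
            raise TreeError(
                "tree is not ultrametric within relative tolerance "
                f"{rtol}: depths range {min(d.values()):.6g}"
                f"..{max(d.values()):.6g}"
            )

    def distance_matrix(self) -> PhyloCovariance:
        """Pairwise patristic distances between tips (not a covariance;
        reuses the labelled-matrix container)."""
        taxa = self.tip_labels
        v = vcv_matrix(self).matrix
        depth = np.diag(v)
        dist = depth[:, None] + depth[None, :] - 2.0 * v
        np.fill_diagonal(dist, 0.0)
        return PhyloCovariance(taxa, dist)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required, quoted labels ok)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"newick parse failure: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialize to Newick; round-trips through :func:`parse_newick`."""
    return (
        phy.dendropy_tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        ).strip()
    )


def prune_to_taxa(phy: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``; pairwise tip distances are preserved and
    degree-2 nodes are collapsed with branch lengths summed."""
    keep = sorted(set(keep))
    labels = set(phy.tip_labels)
    unknown = [t for t in keep if t not in labels]
    if unknown:
        raise TreeError(f"taxa not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeError("need at least 2 taxa to keep")
    if len(keep) == len(labels):
        return phy
    clone = phy.dendropy_tree.clone(depth=1)
    clone.retain_taxa_with_labels(keep)
    clone.purge_taxon_namespace()
    return Phylogeny(clone)


def vcv_matrix(phy: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: V[i, j] = root-to-MRCA(i, j) depth,
    V[i, i] = root-to-tip depth."""
    tree = phy.dendropy_tree
    taxa = phy.tip_labels
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    v = np.zeros((n, n))

    # node depth from root, then each internal node sets the covariance of
    # tip pairs split across its children
    depth: Dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (
                node.edge.length or 0.0
            )

    leafsets: Dict[int, List[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            leafsets[id(node)] = [i]
            v[i, i] = depth[id(node)]
        else:
            children = [leafsets[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            v[i, j] = v[j, i] = d
            merged: List[int] = []
            for c in children:
                merged.extend(c)
            leafsets[id(node)] = merged
    return PhyloCovariance(taxa, v)


def lambda_transform(v: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by ``lam`` (Pagel's lambda).

    Raises if the transformed matrix is no longer positive definite
    (``lam`` above the feasible bound for this tree).
    """
    if lam < 0:
        raise TreeError("lambda must be >= 0")
    m = v.matrix * lam
    np.fill_diagonal(m, np.diag(v.matrix))
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise TreeError(
            f"lambda = {lam} leaves covariance non positive definite"
        ) from exc
    return PhyloCovariance(list(v.taxa), m)


def max_feasible_lambda(v: PhyloCovariance, upper: float = 10.0) -> float:
    """Largest lambda keeping the transformed covariance positive definite,
    found by bisection on Cholesky feasibility."""

    def feasible(lam: float) -> bool:
        m = v.matrix * lam
        np.fill_diagonal(m, np.diag(v.matrix))
        try:
            np.linalg.cholesky(m)
            return True
        except np.linalg.LinAlgError:
            return False

    if not feasible(1.0):
        lo, hi = 0.0, 1.0
    elif feasible(upper):
        return upper
    else:
        lo, hi = 1.0, upper
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo
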