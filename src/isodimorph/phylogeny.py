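"""Phylogenetic correlation structure and local phylogenetic signal.

Species enter the multilevel model through a random effect whose covariance
is proportional to shared evolutionary history: under a Brownian-motion
model on an ultrametric tree, the covariance of two species is the depth of
their most recent common ancestor, so dividing by total tree depth gives a
correlation matrix with unit diagonal.  Trees delivered without branch
lengths get Grafen heights (node height proportional to descendant-tip
count minus one).

The module also computes a per-species local Moran statistic — a "local
indicator of phylogenetic association" — measuring whether a species and
its phylogenetic neighbourhood share similar trait values, with permutation
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloCorrelation",
    "LocalSignal",
    "load_alias_map",
    "grafen_lengths",
    "correlation_from_tree",
    "local_phylo_signal",
]


def _norm(label: str) -> str:
    return label.strip().replace("_", " ")


def _parse_tree(tree: "str | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=tree, schema="newick",
                             preserve_underscores=True)


@dataclass(frozen=True)
class PhyloCorrelation:
    """Species-labelled correlation matrix for the phylogenetic random effect.

    Symmetric, unit diagonal, positive semidefinite; order of ``species``
    matches rows/columns of ``matrix``.
    """

    species: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("correlation matrix must be positive semidefinite")
        object.__setattr__(self, "matrix", m)

    def submatrix(self, species: Sequence[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(tuple(species), self.matrix[np.ix_(idx, idx)])


@dataclass(frozen=True)
class LocalSignal:
    """Per-species local Moran statistic and permutation p-value."""

    species: tuple[str, ...]
    statistic: np.ndarray
    p_value: np.ndarray


def load_alias_map(path) -> dict[str, str]:
    """Two-column delimited file mapping data names to tree tip names."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace(",", "\t").split("\t") if p.strip()]
            if len(parts) != 2:
                raise ValueError(f"alias map line not two columns: {line!r}")
            out[parts[0]] = parts[1]
    return out


def grafen_lengths(tree: "str | dendropy.Tree") -> str:
    """Assign Grafen branch lengths to a rooted topology; return Newick.

    Each node gets height (number of descendant tips - 1), normalized so the
    root has height 1; tips sit at height 0, so the output is ultrametric.
    """
    t = _parse_tree(tree)
    if t.seed_node is None or len(t.leaf_nodes()) < 2:
        raise ValueError("need a rooted tree with at least two tips")
    n_tips = len(t.leaf_nodes())
    heights = {}
    for node in t.postorder_node_iter():
        k = len([lf for lf in node.leaf_iter()])
        heights[node] = (k - 1) / (n_tips - 1)
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = heights[node.parent_node] - heights[node]
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def _has_branch_lengths(t: dendropy.Tree) -> bool:
    lengths = [
        nd.edge.length
        for nd in t.preorder_node_iter()
        if nd.parent_node is not None
    ]
    return all(l is not None for l in lengths) and any(l > 0 for l in lengths)


def correlation_from_tree(
    tree: "str | dendropy.Tree",
    species: Sequence[str],
    aliases: Optional[Mapping[str, str]] = None,
    use_grafen_if_no_lengths: bool = True,
) -> PhyloCorrelation:
    """Correlation matrix of the requested species under Brownian motion.

    Entry (i, j) is the shared root-to-tip path length of species i and j,
    standardized to a correlation (for an ultrametric tree this is shared
    depth divided by total depth).  The tree is pruned to the requested
    species first; tip matching tolerates underscore/space differences and
    an explicit alias map (data name -> tip name).
    """
    species = list(species)
    if len(set(species)) != len(species):
        raise ValueError("duplicate species in request")
    t = _parse_tree(tree)
    if not _has_branch_lengths(t):
        if not use_grafen_if_no_lengths:
            raise ValueError("tree has no branch lengths")
        t = _parse_tree(grafen_lengths(t))

    aliases = dict(aliases or {})
    tip_by_norm = {}
    for leaf in t.leaf_node_iter():
        tip_by_norm.setdefault(_norm(leaf.taxon.label), leaf.taxon)
    taxa, missing = [], []
    for sp in species:
        name = aliases.get(sp, sp)
        taxon = tip_by_norm.get(_norm(name))
        if taxon is None:
            missing.append(sp)
        else:
            taxa.append(taxon)
    if missing:
        raise ValueError(f"species not found as tree tips: {missing}")

    # Root-to-node depths on the full tree, then cov(i, j) = depth of the
    # MRCA of i and j, restricted to the requested tips.  Working on the full
    # tree keeps the stem to a pruned-out clade in the shared path, so
    # subsetting species commutes with building the matrix.
    n = len(species)
    norm_to_idx = {_norm(aliases.get(sp, sp)): i for i, sp in enumerate(species)}
    cov = np.zeros((n, n))
    depth = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaf_sets = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            idx = norm_to_idx.get(_norm(node.taxon.label))
            leaf_sets[node] = [] if idx is None else [idx]
            if idx is not None:
                cov[idx, idx] = depth[node]
        else:
            kids = [leaf_sets[c] for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            cov[i, j] = cov[j, i] = depth[node]
            leaf_sets[node] = [i for k in kids for i in k]

    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise ValueError("zero-depth tree: some tips have no path length")
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return PhyloCorrelation(tuple(species), corr)


def local_phylo_signal(
    values: Sequence[float],
    corr: PhyloCorrelation,
    n_perm: int = 999,
    seed: int = 0,
    weights: Optional[np.ndarray] = None,
) -> LocalSignal:
    """Local Moran statistic per species with permutation p-values.

    I_i = n (x_i - xbar) * sum_j w_ij (x_j - xbar) / sum_k (x_k - xbar)^2

    with row-standardized weights from the off-diagonal correlation matrix
    (an alternative proximity matrix, e.g. patristic-distance based, may be
    supplied via ``weights``).  p-values are one-sided (upper tail: value
    more similar to its phylogenetic neighbourhood than expected) from
    ``n_perm`` permutations of the values across tips.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 species")
    if n != len(corr.species):
        raise ValueError("values do not match correlation labels")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")

    if weights is None:
        w = corr.matrix.copy()
        np.fill_diagonal(w, 0.0)
    else:
        w = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1)
    rs[rs == 0] = 1.0  # isolated tip: all weights zero, statistic will be 0
    w = w / rs[:, None]

    dev = x - x.mean()
    ss = (dev**2).sum()
    if ss <= 0:
        import warnings

        warnings.warn("constant trait values: local signal undefined, set to 0")
        return LocalSignal(corr.species, np.zeros(n), np.ones(n))

    def moran(d):
        return n * d * (w @ d) / ss

    obs = moran(dev)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n)
    for _ in range(n_perm):
        perm = rng.permutation(dev)
        exceed += moran(perm) >= obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return LocalSignal(corr.species, obs, p)
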