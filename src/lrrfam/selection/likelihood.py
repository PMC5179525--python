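"""Felsenstein pruning over codon site-class mixtures.

The engine works on an indexed tree (postorder arrays) and a
pattern-compressed alignment. Per ω class the partial likelihoods are
propagated from the tips to the root with per-node rescaling to avoid
underflow; gaps contribute a partial likelihood of 1 over all codons
(missing data). Site likelihoods mix the classes by their proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .geneticcode import N_CODONS
from .ratematrix import SpectralMatrix, build_class_matrices


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


@dataclass
class TreeIndex:
    """Array representation of a (possibly unrooted) tree for pruning.

    Nodes are numbered in postorder with the root last. ``children[i]``
    lists child node indices; ``edge_lengths[i]`` is the length of the edge
    above node *i* (ignored for the root). The free branch-length vector
    used in optimization covers every non-root edge in node order.
    """

    children: list[list[int]]
    edge_lengths: np.ndarray
    leaf_names: list[str]
    leaf_nodes: list[int]
    root: int
    branch_nodes: list[int] = field(default_factory=list)

    @classmethod
    def from_tree(cls, tree: dendropy.Tree | str) -> "TreeIndex":
        if isinstance(tree, str):
            tree = parse_tree(tree)
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children = [[index[id(c)] for c in n.child_nodes()] for n in nodes]
        lengths = np.array(
            [n.edge.length if n.edge and n.edge.length is not None else 0.0 for n in nodes]
        )
        leaf_names, leaf_nodes = [], []
        for i, n in enumerate(nodes):
            if n.is_leaf():
                if n.taxon is None or n.taxon.label is None:
                    raise ValueError("every leaf must be labelled")
                leaf_names.append(n.taxon.label)
                leaf_nodes.append(i)
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("leaf labels must be unique")
        root = len(nodes) - 1
        branch_nodes = [i for i in range(len(nodes)) if i != root]
        return cls(children, lengths, leaf_names, leaf_nodes, root, branch_nodes)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def branch_vector(self) -> np.ndarray:
        """Branch lengths read from the input tree, in free-vector order."""
        return self.edge_lengths[self.branch_nodes].copy()


def compress_patterns(
    alignment: CodonAlignment, leaf_names: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns over the tree's leaves.

    Returns (patterns, weights, site_to_pattern) where patterns is
    (n_leaves, n_patterns) with rows ordered like ``leaf_names``.
    """
    missing = [n for n in leaf_names if n not in alignment.ids]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {missing}")
    rows = np.stack([alignment.row(n) for n in leaf_names])
    patterns, site_to_pattern = np.unique(rows, axis=1, return_inverse=True)
    weights = np.bincount(site_to_pattern, minlength=patterns.shape[1]).astype(float)
    return patterns, weights, site_to_pattern


def class_site_log_likelihoods(
    tree: TreeIndex,
    patterns: np.ndarray,
    branch_lengths: np.ndarray,
    spectra: list[SpectralMatrix],
    pi: np.ndarray,
) -> np.ndarray:
    """(n_classes, n_patterns) log-likelihoods, one pruning pass per class."""
    n_pat = patterns.shape[1]
    lengths = np.zeros(len(tree.children))
    lengths[tree.branch_nodes] = branch_lengths
    leaf_row = {node: k for k, node in enumerate(tree.leaf_nodes)}
    out = np.empty((len(spectra), n_pat))
    for ci, spec in enumerate(spectra):
        partials: dict[int, np.ndarray] = {}
        log_scale = np.zeros(n_pat)
        for node, kids in enumerate(tree.children):
            if not kids:
                continue
            partial = np.ones((N_CODONS, n_pat))
            for child in kids:
                p = spec.transition_matrix(lengths[child])
                if not tree.children[child]:  # leaf child
                    obs = patterns[leaf_row[child]]
                    contrib = p[:, obs]
                    gap = obs < 0
                    if gap.any():
                        contrib = contrib.copy()
                        contrib[:, gap] = 1.0
                else:
                    contrib = p @ partials.pop(child)
                partial *= contrib
            scale = partial.max(axis=0)
            scale[scale == 0] = 1.0
            partial /= scale
            log_scale += np.log(scale)
            partials[node] = partial
        site_l = pi @ partials[tree.root]
        out[ci] = np.log(np.maximum(site_l, 1e-300)) + log_scale
    return out


def mixture_log_likelihood(
    class_loglik: np.ndarray, proportions: np.ndarray, weights: np.ndarray
) -> float:
    """Total lnL of a site-class mixture from per-class pattern logs."""
    props = np.asarray(proportions, dtype=float)
    keep = props > 0
    site_log = logsumexp(
        class_loglik[keep] + np.log(props[keep])[:, None], axis=0
    )
    return float(weights @ site_log)


def site_likelihoods(
    alignment: CodonAlignment,
    tree: TreeIndex | dendropy.Tree | str,
    kappa: float,
    omegas: np.ndarray,
    proportions: np.ndarray,
    pi: np.ndarray,
    branch_lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-site per-class likelihood table and total lnL for fixed parameters.

    Returns (site_class_loglik, site_log_likelihood, total_lnl) where
    site_class_loglik has shape (n_classes, n_sites) in original site order.
    """
    if not isinstance(tree, TreeIndex):
        tree = TreeIndex.from_tree(tree)
    if branch_lengths is None:
        branch_lengths = tree.branch_vector()
    patterns, weights, site_to_pattern = compress_patterns(alignment, tree.leaf_names)
    qs = build_class_matrices(kappa, omegas, proportions, pi)
    spectra = [SpectralMatrix.from_rate_matrix(q, pi) for q in qs]
    class_loglik = class_site_log_likelihoods(tree, patterns, branch_lengths, spectra, pi)
    props = np.asarray(proportions, dtype=float)
    keep = props > 0
    pattern_log = logsumexp(class_loglik[keep] + np.log(props[keep])[:, None], axis=0)
    total = float(weights @ pattern_log)
    return class_loglik[:, site_to_pattern], pattern_log[site_to_pattern], total
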