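"""Simulation of codon alignments under site-class ω mixtures.

Each site draws its ω class from the mixture proportions; the root codon is
drawn from the stationary distribution and evolved down the tree through the
class's transition matrices. The per-site true class labels are returned so
recovery tests have ground truth.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment
from .likelihood import TreeIndex
from .models import SiteModelSpec
from .ratematrix import SpectralMatrix, build_class_matrices, equal_frequencies


def simulate_alignment(
    tree: TreeIndex | str,
    kappa: float,
    omegas: np.ndarray,
    proportions: np.ndarray,
    n_sites: int,
    rng: np.random.Generator | int,
    pi: np.ndarray | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve ``n_sites`` codon sites down ``tree``; returns (alignment, class labels).

    Deterministic given the generator state. ``pi`` defaults to equal
    frequencies over the 61 sense codons.
    """
    if not isinstance(tree, TreeIndex):
        tree = TreeIndex.from_tree(tree)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if pi is None:
        pi = equal_frequencies()
    omegas = np.asarray(omegas, dtype=float)
    proportions = np.asarray(proportions, dtype=float)

    qs = build_class_matrices(kappa, omegas, proportions, pi)
    spectra = [SpectralMatrix.from_rate_matrix(q, pi) for q in qs]

    labels = rng.choice(len(omegas), size=n_sites, p=proportions)
    states = np.empty((len(tree.children), n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(len(pi), size=n_sites, p=pi)

    # transition matrices per (class, edge) — cached because class count is small
    lengths = np.zeros(len(tree.children))
    lengths[tree.branch_nodes] = tree.branch_vector()
    pmats = {
        (ci, node): spectra[ci].transition_matrix(lengths[node])
        for ci in range(len(omegas))
        for node in tree.branch_nodes
    }
    for node in reversed(range(len(tree.children))):  # preorder (root first)
        for child in tree.children[node]:
            for ci in np.unique(labels):
                sel = labels == ci
                p = pmats[(ci, child)]
                rows = p[states[node, sel]]
                rows = rows / rows.sum(axis=1, keepdims=True)
                u = rng.random(sel.sum())
                states[child, sel] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)

    rows = states[tree.leaf_nodes]
    aln = CodonAlignment(ids=list(tree.leaf_names), codons=rows)
    return aln, labels


def simulate_under_spec(
    tree: TreeIndex | str,
    spec: SiteModelSpec,
    params: dict[str, float],
    n_sites: int,
    rng: np.random.Generator | int,
    pi: np.ndarray | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate under a named site model with its natural parameters."""
    omegas, props = spec.class_distribution(params)
    return simulate_alignment(tree, params["kappa"], omegas, props, n_sites, rng, pi)


def random_tree(
    n_taxa: int,
    rng: np.random.Generator | int,
    total_length: float = 2.0,
    prefix: str = "t",
) -> str:
    """Random bifurcating rooted tree as newick, branch lengths scaled so the
    total tree length equals ``total_length`` (expected substitutions/codon)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    n_edges = 2 * n_taxa - 2
    lengths = rng.exponential(1.0, size=n_edges)
    lengths *= total_length / lengths.sum()
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:{lengths[k]:.8f},{b}:{lengths[k + 1]:.8f})")
        k += 2
    return nodes[0] + ";"
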