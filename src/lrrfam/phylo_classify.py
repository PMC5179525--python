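"""Midpoint rooting and reference-guided subfamily assignment on gene trees.

Query genes inherit the subfamily label of the reference-labelled clade
they fall into. A subfamily is trusted as a clade only when its reference
leaves are monophyletic; clades with bootstrap support at or below the
threshold are marked unsupported, and subfamilies whose references are not
monophyletic get an asterisk-style uncertainty flag with a majority-rule
fallback assignment (the label of the majority of reference leaves in the
query's smallest reference-containing ancestor clade).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

DEFAULT_SUPPORT_THRESHOLD = 80.0
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SubfamilyCall:
    gene_id: str
    subfamily: str
    supported: bool
    monophyly_uncertain: bool  # the asterisk flag


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick tree (support values as internal node labels)."""
    try:
        is_file = Path(source).exists()
    except OSError:  # e.g. a long newick string passed directly
        is_file = False
    if is_file:
        tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=str(source), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _leaf_distances(tree: dendropy.Tree) -> tuple[dict, dict]:
    """Root-to-leaf distances and leaf list, via one traversal."""
    dist = {id(tree.seed_node): 0.0}
    leaves = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        dist[id(node)] = dist[id(node.parent_node)] + length
        if node.is_leaf():
            leaves.append(node)
    return dist, leaves


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path.

    The root is placed on that path at half the maximal patristic distance;
    ties between equally distant leaf pairs break by the lexicographic order
    of the pair's labels. All pairwise patristic distances are preserved.
    Raises if every branch length is zero (midpoint undefined).
    """
    tree = tree.clone(depth=1)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    if len(taxa) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    best = None
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            key = (-d, taxa[i].label, taxa[j].label)
            if best is None or key < best[0]:
                best = (key, taxa[i], taxa[j], d)
    _, taxon_a, taxon_b, dmax = best
    if dmax <= 0:
        raise ValueError("all branch lengths are zero; midpoint is undefined")

    leaf_a = tree.find_node_with_taxon_label(taxon_a.label)
    leaf_b = tree.find_node_with_taxon_label(taxon_b.label)
    path = _path_between(leaf_a, leaf_b)
    # walk from leaf_a toward leaf_b until half the distance is covered
    half = dmax / 2.0
    walked = 0.0
    for node, via_parent in path:
        edge_len = node.edge.length or 0.0
        if walked + edge_len >= half - 1e-12:
            remainder = half - walked
            if via_parent:
                # moving rootward along node's edge: split at remainder above node
                tree.reroot_at_edge(
                    node.edge,
                    length1=edge_len - remainder,  # parent side
                    length2=remainder,  # child (node) side
                    update_bipartitions=False,
                )
            else:
                # moving tipward along node's edge from its parent
                tree.reroot_at_edge(
                    node.edge,
                    length1=remainder,
                    length2=edge_len - remainder,
                    update_bipartitions=False,
                )
            return tree
        walked += edge_len
    raise AssertionError("midpoint not found on path")  # pragma: no cover


def _path_between(leaf_a, leaf_b):
    """Edges on the path a→b as (node, via_parent) steps.

    ``via_parent=True`` means the step climbs from ``node`` to its parent;
    ``False`` means the step descends from the node's parent to ``node``.
    """
    ancestors_a = []
    node = leaf_a
    while node is not None:
        ancestors_a.append(node)
        node = node.parent_node
    ancestors_b = []
    node = leaf_b
    while node is not None:
        ancestors_b.append(node)
        node = node.parent_node
    set_a = {id(n) for n in ancestors_a}
    mrca = next(n for n in ancestors_b if id(n) in set_a)
    up = []
    for n in ancestors_a:
        if n is mrca:
            break
        up.append((n, True))
    down = []
    for n in ancestors_b:
        if n is mrca:
            break
        down.append((n, False))
    return up + list(reversed(down))


def _node_support(node) -> float | None:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def read_reference_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (leaf label, subfamily) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["leaf", "subfamily"])
    return dict(zip(df["leaf"].astype(str), df["subfamily"].astype(str)))


def assign_subfamilies(
    tree: dendropy.Tree,
    reference_labels: dict[str, str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> list[SubfamilyCall]:
    """Assign every non-reference leaf to a subfamily.

    For each label the maximal clade containing only that label's reference
    leaves (and at least one of them) donates the label to the query leaves
    inside it; ``supported`` requires the clade's bootstrap support to be
    strictly above ``support_threshold``. Labels whose references are not
    monophyletic fall back to majority rule in each query's smallest
    reference-containing ancestor clade, and every resulting call carries
    the ``monophyly_uncertain`` (asterisk) flag. Queries under no labelled
    clade are "unclassified".
    """
    if not reference_labels:
        raise ValueError("no reference labels supplied")
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    refs_in_tree = {name: lab for name, lab in reference_labels.items() if name in leaves}
    if not refs_in_tree:
        raise ValueError("none of the reference labels occur in the tree")
    queries = [name for name in leaves if name not in refs_in_tree]

    # reference leaf-label sets per node (one postorder pass)
    ref_under: dict[int, set[str]] = {}
    refleaves_under: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            lab = refs_in_tree.get(name)
            ref_under[id(node)] = {lab} if lab else set()
            refleaves_under[id(node)] = {name} if lab else set()
        else:
            acc, accl = set(), set()
            for child in node.child_nodes():
                acc |= ref_under[id(child)]
                accl |= refleaves_under[id(child)]
            ref_under[id(node)] = acc
            refleaves_under[id(node)] = accl

    label_set = sorted(set(refs_in_tree.values()))
    monophyletic: dict[str, object] = {}
    for label in label_set:
        members = [n for n, l in refs_in_tree.items() if l == label]
        mrca = tree.mrca(taxon_labels=members)
        monophyletic[label] = mrca if ref_under[id(mrca)] == {label} else None

    # maximal clade per monophyletic label: climb while no foreign reference joins
    clade_of: dict[str, object] = {}
    for label, mrca in monophyletic.items():
        if mrca is None:
            continue
        node = mrca
        while (
            node.parent_node is not None
            and ref_under[id(node.parent_node)] == {label}
        ):
            node = node.parent_node
        clade_of[label] = node

    calls: list[SubfamilyCall] = []
    any_paraphyletic = any(v is None for v in monophyletic.values())
    for name in sorted(queries):
        node = leaves[name]
        assigned = None
        for label, clade in clade_of.items():
            anc = node
            while anc is not None:
                if anc is clade:
                    support = _node_support(clade)
                    assigned = SubfamilyCall(
                        name,
                        label,
                        supported=support is not None and support > support_threshold,
                        monophyly_uncertain=False,
                    )
                    break
                anc = anc.parent_node
            if assigned:
                break
        if assigned is None and any_paraphyletic:
            anc = node.parent_node
            while anc is not None and not refleaves_under[id(anc)]:
                anc = anc.parent_node
            if anc is not None:
                counts: dict[str, int] = {}
                for ref_name in refleaves_under[id(anc)]:
                    lab = refs_in_tree[ref_name]
                    counts[lab] = counts.get(lab, 0) + 1
                majority = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
                support = _node_support(anc)
                assigned = SubfamilyCall(
                    name,
                    majority,
                    supported=support is not None and support > support_threshold,
                    monophyly_uncertain=True,
                )
        if assigned is None:
            assigned = SubfamilyCall(name, UNCLASSIFIED, False, False)
        # any call landing on a paraphyletic label is uncertain
        if assigned.subfamily in monophyletic and monophyletic[assigned.subfamily] is None:
            assigned = SubfamilyCall(
                assigned.gene_id, assigned.subfamily, assigned.supported, True
            )
        calls.append(assigned)
    return calls


def calls_to_frame(calls: list[SubfamilyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.subfamily, c.supported, c.monophyly_uncertain) for c in calls],
        columns=["gene_id", "subfamily", "supported", "monophyly_uncertain"],
    )
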