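"""Scaffold placement, proximity clustering, and tandem-duplication calls.

Genes on the same scaffold whose start positions lie within a window
(200 kb by default) are chained into proximity clusters. A cluster is
called a tandem-duplication cluster only if its members also form a clade
in the gene phylogeny: the most recent common ancestor of the members has
exactly the members as leaf descendants (strict monophyly). A lenient mode
accepts shared subfamily assignment instead of strict monophyly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from ._util import round_half_up

DEFAULT_WINDOW_BP = 200_000

Interval = tuple[int, int]


@dataclass
class GeneLocus:
    """A gene's placement on a scaffold (1-based inclusive coordinates)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons.sort()
        prev = 0
        for s, e in self.exons:
            if s < self.start or e > self.end or s > e:
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene body")
            if s <= prev:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev = e


@dataclass
class ProximityCluster:
    """Two or more neighbouring genes on one scaffold."""

    scaffold: str
    member_ids: list[str]
    span_bp: int
    tandem: bool | None = None  # set by validate_tandem

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a proximity cluster needs at least 2 members")


@dataclass(frozen=True)
class ExpansionRate:
    """Reference-to-query copy-number ratio for one subfamily."""

    subfamily: str
    n_reference: int
    n_query: int
    ratio: float  # n_reference / n_query, rounded to 1 decimal for reporting
    missing_partner: bool = False


def read_gff3(path: str | Path) -> list[GeneLocus]:
    """Load gene loci (with exon and CDS intervals) from a GFF3 file.

    Uses the first mRNA of each gene; feature types gene/mRNA/exon/CDS.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    loci: list[GeneLocus] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        loci.append(
            GeneLocus(
                gene_id=gene.id,
                scaffold=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=sorted(exons),
                cds=sorted(cds),
            )
        )
    return loci


def chain_clusters(
    loci: list[GeneLocus], window_bp: int = DEFAULT_WINDOW_BP
) -> list[ProximityCluster]:
    """Chain genes into proximity clusters per scaffold.

    Genes are sorted by start; consecutive genes whose start-to-start
    distance is <= ``window_bp`` (boundary inclusive) are linked, and chains
    of two or more genes become clusters. Deterministic given input.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    seen: set[str] = set()
    for locus in loci:
        if locus.gene_id in seen:
            raise ValueError(f"duplicate gene id {locus.gene_id}")
        seen.add(locus.gene_id)

    by_scaffold: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold, []).append(locus)

    clusters: list[ProximityCluster] = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        chain: list[GeneLocus] = []
        for gene in genes:
            if chain and gene.start - chain[-1].start <= window_bp:
                chain.append(gene)
            else:
                if len(chain) >= 2:
                    clusters.append(_to_cluster(scaffold, chain))
                chain = [gene]
        if len(chain) >= 2:
            clusters.append(_to_cluster(scaffold, chain))
    return clusters


def _to_cluster(scaffold: str, chain: list[GeneLocus]) -> ProximityCluster:
    return ProximityCluster(
        scaffold=scaffold,
        member_ids=[g.gene_id for g in chain],
        span_bp=max(g.end for g in chain) - min(g.start for g in chain) + 1,
    )


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def validate_tandem(
    clusters: list[ProximityCluster],
    tree: dendropy.Tree | str,
    mode: str = "monophyly",
    subfamily_calls: dict[str, str] | None = None,
) -> list[ProximityCluster]:
    """Flag each cluster tandem/non-tandem against the gene phylogeny.

    ``mode='monophyly'`` (default): the MRCA of the cluster members must
    have exactly the members as leaf descendants. ``mode='subfamily'``
    (lenient): all members share one subfamily assignment
    (``subfamily_calls`` required). Flags are written onto the clusters
    (``tandem`` attribute) and the list is returned.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    if mode not in ("monophyly", "subfamily"):
        raise ValueError("mode must be 'monophyly' or 'subfamily'")
    if mode == "subfamily" and subfamily_calls is None:
        raise ValueError("subfamily mode requires subfamily_calls")
    labels = _leaf_labels(tree)
    for cluster in clusters:
        missing = [m for m in cluster.member_ids if m not in labels]
        if missing:
            raise ValueError(f"cluster member(s) absent from tree: {missing}")
        if mode == "subfamily":
            calls = {subfamily_calls.get(m) for m in cluster.member_ids}
            cluster.tandem = len(calls) == 1 and None not in calls
            continue
        mrca = tree.mrca(taxon_labels=cluster.member_ids)
        descendants = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        cluster.tandem = descendants == set(cluster.member_ids)
    return clusters


def tandem_subpairs(
    cluster: ProximityCluster, tree: dendropy.Tree
) -> list[tuple[str, str]]:
    """Monophyletic pairs inside a cluster that failed whole-cluster monophyly."""
    pairs = []
    members = cluster.member_ids
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            mrca = tree.mrca(taxon_labels=[members[i], members[j]])
            desc = {leaf.taxon.label for leaf in mrca.leaf_iter()}
            if desc == {members[i], members[j]}:
                pairs.append((members[i], members[j]))
    return pairs


def tandem_fraction(
    loci: list[GeneLocus], flagged_clusters: list[ProximityCluster]
) -> tuple[int, int, float]:
    """(n_tandem_genes, n_total_genes, fraction) from tandem-flagged clusters."""
    n_total = len(loci)
    if n_total == 0:
        raise ValueError("no gene loci supplied")
    tandem_genes: set[str] = set()
    known = {locus.gene_id for locus in loci}
    for cluster in flagged_clusters:
        stray = set(cluster.member_ids) - known
        if stray:
            raise ValueError(f"cluster members not among the loci: {sorted(stray)}")
        if cluster.tandem:
            tandem_genes.update(cluster.member_ids)
    n_tandem = len(tandem_genes)
    return n_tandem, n_total, n_tandem / n_total


def expansion_rates(
    counts_reference: dict[str, int], counts_query: dict[str, int]
) -> list[ExpansionRate]:
    """Reference/query copy-number ratios per subfamily, 1-decimal rounded.

    Subfamilies present in only one of the two tables are reported with a
    missing-partner flag (ratio 0 there).
    """
    rates: list[ExpansionRate] = []
    for sub in sorted(set(counts_reference) | set(counts_query)):
        n_ref = counts_reference.get(sub)
        n_query = counts_query.get(sub)
        if n_ref is None or n_query is None:
            rates.append(
                ExpansionRate(sub, n_ref or 0, n_query or 0, 0.0, missing_partner=True)
            )
            continue
        if n_query < 1:
            raise ValueError(f"{sub}: query count must be >= 1 for a ratio")
        rates.append(ExpansionRate(sub, n_ref, n_query, round_half_up(n_ref / n_query, 1)))
    return rates


def clusters_to_frame(clusters: list[ProximityCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.scaffold, ",".join(c.member_ids), len(c.member_ids), c.span_bp, c.tandem)
            for c in clusters
        ],
        columns=["scaffold", "members", "n_genes", "span_bp", "tandem"],
    )
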