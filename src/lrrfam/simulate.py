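"""Synthetic study inputs with known ground truth.

Generates a complete input set for the pipeline — scaffold-placed gene
family with tandem and dispersed duplicates, subfamily-structured domain
architectures and intron counts, subfamily-specific motif occurrences,
codon sequences evolved under per-subfamily ω site models, a gene tree with
reference-labelled leaves and bootstrap-style supports, homology hits with
decoys, and negative-binomial expression counts — so every pipeline stage
can be checked against generator truth without external downloads.

The default configuration reproduces the shape of the study system: 94
family genes over 60 scaffolds in 18 subfamilies with the published size
spectrum, five tandem clusters (sizes 3,2,2,2,2) well inside the 200-kb
window, and two same-scaffold gene pairs from different subfamilies that
form proximity clusters but are not tandem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .family_screen import DomainArchitecture
from .genome_map import GeneLocus
from .selection.alignment import CodonAlignment
from .selection.evolve import simulate_alignment
from .selection.likelihood import TreeIndex
from .selection.models import SiteModelSpec

logger = logging.getLogger(__name__)

TISSUES = ("whole_plant", "amyl", "female_bud")

# protein layout (aa): LRRs of 24 aa from position 31, then linkers, one TM
# span, one kinase domain, and a short tail
_LRR_START = 31
_LRR_LEN = 24
_TM_LEN = 23
_KD_LEN = 290

CORE_MOTIFS = ("M1", "M2", "M4", "M5", "M7", "M10", "M12", "M15")


@dataclass
class SubfamilySimConfig:
    name: str
    n_members: int
    lrr_counts: tuple[int, ...]  # drawn per member (subfamily-conserved range)
    n_introns: int  # shared modal intron count
    extra_motifs: tuple[str, ...] = ()
    omega: float = 0.2  # M0-style single ratio used to evolve the codons
    tandem_cluster_sizes: tuple[int, ...] = ()  # e.g. (3, 2)
    expression_fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.tandem_cluster_sizes) > self.n_members:
            raise ValueError(f"{self.name}: tandem clusters exceed member count")
        if any(s < 2 for s in self.tandem_cluster_sizes):
            raise ValueError(f"{self.name}: tandem clusters need >= 2 genes")


@dataclass
class FamilySimConfig:
    """Study-shaped defaults; all sizes and rates are overridable."""

    subfamilies: list[SubfamilySimConfig] = field(default_factory=lambda: default_subfamilies())
    n_scaffolds: int = 60
    scaffold_length_bp: int = 3_000_000
    tandem_offset_bp: int = 50_000  # max start-to-start spacing inside a cluster
    dispersed_gap_bp: int = 600_000  # min spacing between unrelated genes
    n_nontandem_pairs: int = 2  # same-scaffold pairs from different subfamilies
    nontandem_pair_gap_bp: int = 150_000
    n_reference_per_subfamily: int = 2
    kappa: float = 2.0
    library_size: int = 20_000_000
    nb_dispersion: float = 0.1
    n_decoys: int = 12
    min_intron_bp: int = 80
    max_intron_bp: int = 500
    plant_paraphyly: str | None = None  # subfamily whose references are split
    seed: int = 0


def default_subfamilies() -> list[SubfamilySimConfig]:
    """The published subfamily size spectrum (94 genes, 18 subfamilies) with
    per-subfamily LRR ranges, modal intron counts, motif patterns, and the
    five selection-analysed subfamilies carrying their published ω."""
    high = {"whole_plant": 50.0, "amyl": 30.0, "female_bud": 50.0}
    low = {"whole_plant": 0.1, "amyl": 0.1, "female_bud": 0.2}
    mixed = {"whole_plant": 5.0, "amyl": 20.0, "female_bud": 40.0}
    rows = [
        #      name   n  lrr_counts        introns extra motifs                 omega  clusters
        ("I", 5, (3, 3, 3, 3, 4), 10, ("M3", "M8", "M11", "M13"), 0.3743, (2,), high),
        ("II", 6, (3, 4), 10, ("M3", "M9", "M11", "M13"), 0.0920, (), high),
        ("III", 16, (3, 5, 6, 17), 1, ("M13",), 0.2292, (2,), mixed),
        ("IV", 1, (6,), 3, ("M3", "M11"), 0.2, (), high),
        ("V", 2, (6, 8), 15, ("M11", "M13"), 0.2, (), low),
        ("VI-1", 3, (7, 8, 9), 6, (), 0.2, (), low),
        ("VI-2", 1, (4,), 11, (), 0.2, (), high),
        ("VII-1", 1, (23,), 0, ("M3", "M11", "M13"), 0.2, (), high),
        ("VII-2", 3, (13, 15, 18), 2, ("M3", "M11"), 0.2, (), low),
        ("VIII-1", 4, (7, 11, 11, 11), 18, ("M3", "M11", "M13"), 0.2949, (), high),
        ("VIII-2", 3, (4, 8, 8), 16, ("M3", "M11"), 0.2, (), low),
        ("IX", 3, (8, 9, 11), 1, ("M3", "M11", "M13"), 0.2, (), mixed),
        ("X", 9, (14, 20, 25, 28), 0, ("M6", "M11", "M13"), 0.2, (), mixed),
        ("XI", 24, (17, 20, 24, 27), 1, ("M3", "M8", "M11", "M13"), 0.2, (3, 2), mixed),
        ("XII", 7, (10, 16, 20, 26), 1, ("M3", "M11", "M13"), 0.2182, (2,), mixed),
        ("XIII-1", 3, (3, 4, 4), 12, ("M3", "M8", "M11", "M13"), 0.2, (), low),
        ("XIII-2", 1, (19,), 26, ("M3", "M8", "M11", "M13"), 0.2, (), low),
        ("XV", 2, (15, 18), 0, ("M3", "M11", "M13"), 0.2, (), mixed),
    ]
    return [
        SubfamilySimConfig(
            name=name,
            n_members=n,
            lrr_counts=lrr,
            n_introns=introns,
            extra_motifs=motifs,
            omega=omega,
            tandem_cluster_sizes=clusters,
            expression_fpkm=dict(expr),
        )
        for name, n, lrr, introns, motifs, omega, clusters, expr in rows
    ]


class _Node:
    __slots__ = ("children", "length", "name", "support")

    def __init__(self, name=None, length=0.0, children=None, support=None):
        self.name = name
        self.length = length
        self.children = children or []
        self.support = support

    def newick(self, top=True) -> str:
        if not self.children:
            body = self.name
        else:
            inner = ",".join(c.newick(top=False) for c in self.children)
            label = "" if self.support is None else f"{self.support:d}"
            body = f"({inner}){label}"
        if top:
            return body + ";"
        return f"{body}:{self.length:.6f}"

    def leaves(self):
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class GroundTruth:
    subfamily: dict[str, str]
    origin: dict[str, str]  # ancestral | tandem | dispersed
    tandem_clusters: list[list[str]]
    nontandem_pairs: list[tuple[str, str]]
    tree_newick: str
    site_omegas: dict[str, float]
    expression_fpkm: dict[str, dict[str, float]]  # subfamily -> tissue -> mean


@dataclass
class SimulatedFamily:
    config: FamilySimConfig
    loci: list[GeneLocus]
    architectures: dict[str, DomainArchitecture]
    proteins: dict[str, str]
    cds: dict[str, str]
    alignments: dict[str, CodonAlignment]  # per subfamily (queries + references)
    subfamily_trees: dict[str, str]
    tree_newick: str
    reference_labels: dict[str, str]
    motif_table: pd.DataFrame
    hit_table: pd.DataFrame
    domain_table: pd.DataFrame
    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the standard-format files; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": out / "family.gff3",
            "protein_fasta": out / "proteins.faa",
            "cds_fasta": out / "cds.fna",
            "tree": out / "family.nwk",
            "reference_labels": out / "reference_labels.tsv",
            "hits": out / "hits.tsv",
            "domains": out / "domains.tsv",
            "motifs": out / "motifs.tsv",
            "counts": out / "counts.tsv",
            "truth": out / "truth.tsv",
        }
        write_gff3(self.loci, paths["gff3"])
        _write_fasta(self.proteins, paths["protein_fasta"])
        _write_fasta(self.cds, paths["cds_fasta"])
        paths["tree"].write_text(self.tree_newick + "\n")
        with open(paths["reference_labels"], "w") as fh:
            for leaf, label in self.reference_labels.items():
                fh.write(f"{leaf}\t{label}\n")
        self.hit_table.to_csv(paths["hits"], sep="\t", index=False)
        self.domain_table.to_csv(paths["domains"], sep="\t", index=False)
        self.motif_table.to_csv(paths["motifs"], sep="\t", index=False)
        self.counts.to_csv(paths["counts"], sep="\t")
        truth_df = pd.DataFrame(
            [
                (g, self.truth.subfamily[g], self.truth.origin[g])
                for g in sorted(self.truth.subfamily)
            ],
            columns=["gene_id", "subfamily", "origin"],
        )
        truth_df.to_csv(paths["truth"], sep="\t", index=False)
        for sub, aln in self.alignments.items():
            p = out / f"codon_{sub}.fna"
            aln.to_fasta(p)
            paths[f"codon_{sub}"] = p
        return paths


def _protein_layout(max_lrr: int) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """(aa_length, lrr region end, TM interval, KD interval) for a subfamily."""
    lrr_end = _LRR_START + max_lrr * _LRR_LEN - 1
    tm = (lrr_end + 11, lrr_end + 10 + _TM_LEN)
    kd = (tm[1] + 21, tm[1] + 20 + _KD_LEN)
    return kd[1] + 10, lrr_end, tm, kd


def simulate_family(config: FamilySimConfig | None = None) -> SimulatedFamily:
    """Generate the full synthetic study input set (deterministic per seed)."""
    config = config or FamilySimConfig()
    rng = np.random.default_rng(config.seed)

    # ---- per-subfamily gene lists, origins, tandem clusters -------------
    genes_by_sub: dict[str, list[str]] = {}
    origin: dict[str, str] = {}
    tandem_clusters: list[list[str]] = []
    cluster_of_sub: dict[str, list[list[str]]] = {}
    for sub in config.subfamilies:
        names = [f"Atr_{sub.name}_{k + 1:02d}" for k in range(sub.n_members)]
        genes_by_sub[sub.name] = names
        clusters = []
        cursor = 0
        for size in sub.tandem_cluster_sizes:
            members = names[cursor : cursor + size]
            clusters.append(members)
            for g in members:
                origin[g] = "tandem"
            cursor += size
        for i, g in enumerate(names[cursor:]):
            origin[g] = "ancestral" if i == 0 else "dispersed"
        cluster_of_sub[sub.name] = clusters
        tandem_clusters.extend(clusters)

    # ---- gene tree: caterpillar backbone of subfamily clades ------------
    ref_labels: dict[str, str] = {}
    clade_roots: dict[str, _Node] = {}
    for sub in config.subfamilies:
        units: list[_Node] = []
        clustered = {g for cl in cluster_of_sub[sub.name] for g in cl}
        for cl in cluster_of_sub[sub.name]:
            node = _Node(name=cl[0], length=round(rng.uniform(0.01, 0.04), 6))
            for g in cl[1:]:
                sibling = _Node(name=g, length=round(rng.uniform(0.01, 0.04), 6))
                node = _Node(
                    children=[node, sibling],
                    length=round(rng.uniform(0.01, 0.04), 6),
                    support=int(rng.integers(60, 100)),
                )
            units.append(node)
        for g in genes_by_sub[sub.name]:
            if g not in clustered:
                units.append(_Node(name=g, length=round(rng.uniform(0.03, 0.12), 6)))
        for i in range(config.n_reference_per_subfamily):
            ref = f"Ath_{sub.name}_{i + 1}"
            ref_labels[ref] = sub.name
            units.append(_Node(name=ref, length=round(rng.uniform(0.05, 0.15), 6)))
        rng.shuffle(units)
        node = units[0]
        for u in units[1:]:
            node = _Node(
                children=[node, u],
                length=round(rng.uniform(0.02, 0.10), 6),
                support=int(rng.integers(60, 100)),
            )
        node.support = 95  # subfamily crown group: well supported
        clade_roots[sub.name] = node

    displaced_ref = None
    if config.plant_paraphyly is not None:
        target = config.plant_paraphyly
        if target not in clade_roots:
            raise ValueError(f"unknown subfamily {target!r} for paraphyly planting")
        displaced_ref = f"Ath_{target}_out"
        ref_labels[displaced_ref] = target

    backbone = None
    for sub in config.subfamilies:
        clade = clade_roots[sub.name]
        clade.length = round(rng.uniform(0.2, 0.4), 6)
        if backbone is None:
            backbone = clade
        else:
            backbone = _Node(
                children=[backbone, clade],
                length=round(rng.uniform(0.05, 0.15), 6),
                support=int(rng.integers(20, 60)),
            )
        if displaced_ref is not None and sub.name == config.subfamilies[-1].name:
            # attach the stray reference outside its subfamily's clade
            stray = _Node(name=displaced_ref, length=0.3)
            backbone = _Node(children=[backbone, stray], length=0.1, support=40)
    tree_newick = backbone.newick()

    # ---- codon alignments per subfamily ---------------------------------
    alignments: dict[str, CodonAlignment] = {}
    subfamily_trees: dict[str, str] = {}
    site_omegas: dict[str, float] = {}
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    for sub in config.subfamilies:
        aa_len, _, _, _ = _protein_layout(max(sub.lrr_counts))
        clade = clade_roots[sub.name]
        sub_newick = _Node(children=clade.children, support=clade.support).newick() \
            if clade.children else f"({clade.name}:0.0);"
        subfamily_trees[sub.name] = sub_newick
        site_omegas[sub.name] = sub.omega
        if clade.children:
            aln, _ = simulate_alignment(
                sub_newick,
                config.kappa,
                [sub.omega],
                [1.0],
                aa_len,
                rng,
            )
        else:  # single-leaf subfamily: draw one sequence from the base frequencies
            codons = rng.integers(0, 61, size=(1, aa_len))
            aln = CodonAlignment(ids=[clade.name], codons=codons)
        alignments[sub.name] = aln
        for gene in genes_by_sub[sub.name]:
            seq = aln.sequence(gene)
            cds[gene] = seq
            proteins[gene] = aln.translate(gene)

    # ---- architectures and motif occurrences ----------------------------
    architectures: dict[str, DomainArchitecture] = {}
    motif_rows = []
    for sub in config.subfamilies:
        aa_len, _, tm, kd = _protein_layout(max(sub.lrr_counts))
        motifs = tuple(CORE_MOTIFS) + tuple(sub.extra_motifs)
        for gene in genes_by_sub[sub.name]:
            n_lrr = int(rng.choice(sub.lrr_counts))
            lrrs = [
                (_LRR_START + i * _LRR_LEN, _LRR_START + (i + 1) * _LRR_LEN - 1)
                for i in range(n_lrr)
            ]
            architectures[gene] = DomainArchitecture(
                protein_id=gene,
                lrr_repeats=lrrs,
                tm_spans=[tm],
                kinase_domains=[kd],
                protein_length=aa_len,
            )
            pos = kd[0]
            for motif in motifs:
                width = 15
                motif_rows.append((gene, motif, pos, pos + width - 1, round(rng.uniform(20, 60), 2)))
                pos += width + 2
    motif_table = pd.DataFrame(
        motif_rows, columns=["protein_id", "motif_id", "start", "end", "score"]
    )

    # ---- genomic placement ----------------------------------------------
    scaffolds = [f"sc{i + 1:02d}" for i in range(config.n_scaffolds)]
    cursor = {s: 0 for s in scaffolds}

    def place_gene(gene: str, scaffold: str, start: int) -> None:
        sub_cfg = next(s for s in config.subfamilies if gene in genes_by_sub[s.name])
        cds_len = len(cds[gene]) // 3 * 3
        n_int = sub_cfg.n_introns
        if n_int > 0:
            offsets = np.sort(
                rng.choice(np.arange(3, cds_len - 3), size=n_int, replace=False)
            )
            intron_lens = rng.integers(config.min_intron_bp, config.max_intron_bp + 1, n_int)
        else:
            offsets = np.array([], dtype=int)
            intron_lens = np.array([], dtype=int)
        strand = "+" if rng.random() < 0.5 else "-"
        # build genomic CDS intervals in transcription order, then map to + axis
        pieces = []
        prev = 0
        for off in list(offsets) + [cds_len]:
            pieces.append(int(off) - prev)
            prev = int(off)
        genomic_len = cds_len + int(intron_lens.sum())
        g_start = start
        g_end = start + genomic_len - 1
        intervals = []
        if strand == "+":
            pos = g_start
            for k, piece in enumerate(pieces):
                intervals.append((pos, pos + piece - 1))
                pos += piece
                if k < len(intron_lens):
                    pos += int(intron_lens[k])
        else:
            pos = g_end
            for k, piece in enumerate(pieces):
                intervals.append((pos - piece + 1, pos))
                pos -= piece
                if k < len(intron_lens):
                    pos -= int(intron_lens[k])
            intervals = sorted(intervals)
        loci.append(
            GeneLocus(
                gene_id=gene,
                scaffold=scaffold,
                start=g_start,
                end=g_end,
                strand=strand,
                exons=list(intervals),
                cds=list(intervals),
            )
        )
        cursor[scaffold] = max(cursor[scaffold], g_end)

    def pick_scaffold(needed: int) -> str:
        for _ in range(200):
            empty = [s for s in scaffolds if cursor[s] == 0]
            if empty and rng.random() < 0.75:
                s = empty[int(rng.integers(len(empty)))]
            else:
                s = scaffolds[int(rng.integers(len(scaffolds)))]
            gap = config.dispersed_gap_bp if cursor[s] > 0 else int(rng.integers(1_000, 50_000))
            if cursor[s] + gap + needed < config.scaffold_length_bp:
                return s
        raise RuntimeError("could not place gene; scaffolds too small for the config")

    loci: list[GeneLocus] = []
    nontandem_pairs: list[tuple[str, str]] = []
    pair_candidates: list[str] = []
    for sub in config.subfamilies:
        placed_clusters = set()
        for cl in cluster_of_sub[sub.name]:
            s = pick_scaffold(len(cl) * config.tandem_offset_bp)
            gap = config.dispersed_gap_bp if cursor[s] > 0 else int(rng.integers(1_000, 50_000))
            start = cursor[s] + gap
            for idx, gene in enumerate(cl):
                place_gene(gene, s, start)
                placed_clusters.add(gene)
                if idx < len(cl) - 1:
                    prev = loci[-1]
                    spacing = int(
                        rng.integers(prev.end - prev.start + 500, config.tandem_offset_bp)
                    )
                    start = start + spacing
        for gene in genes_by_sub[sub.name]:
            if gene in placed_clusters:
                continue
            s = pick_scaffold(60_000)
            gap = config.dispersed_gap_bp if cursor[s] > 0 else int(rng.integers(1_000, 50_000))
            place_gene(gene, s, cursor[s] + gap)
            pair_candidates.append(gene)

    # plant same-scaffold non-tandem proximity pairs (different subfamilies)
    truth_sub = {
        g: sub.name for sub in config.subfamilies for g in genes_by_sub[sub.name]
    }
    by_id = {locus.gene_id: locus for locus in loci}
    used: set[str] = set()
    for first in pair_candidates:
        if len(nontandem_pairs) >= config.n_nontandem_pairs:
            break
        if first in used:
            continue
        partner = next(
            (
                g
                for g in pair_candidates
                if g not in used and g != first and truth_sub[g] != truth_sub[first]
            ),
            None,
        )
        if partner is None:
            break
        used.update((first, partner))
        locus = by_id[partner]
        anchor = by_id[first]
        new_start = anchor.start + config.nontandem_pair_gap_bp
        shift = new_start - locus.start
        locus.scaffold = anchor.scaffold
        locus.start += shift
        locus.end += shift
        locus.exons = [(a + shift, b + shift) for a, b in locus.exons]
        locus.cds = [(a + shift, b + shift) for a, b in locus.cds]
        nontandem_pairs.append((first, partner))

    # ---- homology hits (family genes + decoys) ---------------------------
    hit_rows = []
    for gene in sorted(truth_sub):
        hit_rows.append(
            (gene, "KD_query", float(f"{10 ** -rng.uniform(15, 60):.3e}"))
        )
    domain_rows = []
    for gene in sorted(architectures):
        arch = architectures[gene]
        for s, e in arch.lrr_repeats:
            domain_rows.append((gene, "LRR", s, e))
        for s, e in arch.tm_spans:
            domain_rows.append((gene, "TM", s, e))
        for s, e in arch.kinase_domains:
            domain_rows.append((gene, "KD", s, e))
    for k in range(config.n_decoys):
        decoy = f"decoy_{k + 1:02d}"
        hit_rows.append((decoy, "KD_query", float(f"{10 ** -rng.uniform(2, 9):.3e}")))
        # decoys that do pass the E-value screen are broken architecturally
        kind = k % 3
        if kind == 0:
            domain_rows.append((decoy, "KD", 300, 589))  # no LRR, no TM
        elif kind == 1:
            domain_rows.append((decoy, "LRR", 31, 54))
            domain_rows.append((decoy, "KD", 300, 589))  # no TM
        # kind == 2: no domain annotation at all
    hit_table = pd.DataFrame(hit_rows, columns=["query_id", "subject_id", "evalue"])
    domain_table = pd.DataFrame(domain_rows, columns=["protein_id", "domain_name", "start", "end"])

    # ---- expression counts -----------------------------------------------
    genes_sorted = sorted(truth_sub)
    lengths = pd.Series(
        {g: sum(e - s + 1 for s, e in by_id[g].exons) for g in genes_sorted},
        name="length_bp",
    )
    lib = pd.Series({t: float(config.library_size) for t in TISSUES}, name="total_fragments")
    counts = {}
    expr_truth: dict[str, dict[str, float]] = {}
    for sub in config.subfamilies:
        expr_truth[sub.name] = dict(sub.expression_fpkm)
    for tissue in TISSUES:
        col = []
        for g in genes_sorted:
            mean_fpkm = expr_truth[truth_sub[g]].get(tissue, 1.0)
            mu = mean_fpkm * lengths[g] * lib[tissue] / 1e9
            if mu <= 0:
                col.append(0)
                continue
            n = 1.0 / config.nb_dispersion
            p = n / (n + mu)
            col.append(int(rng.negative_binomial(n, p)))
        counts[tissue] = col
    counts_df = pd.DataFrame(counts, index=pd.Index(genes_sorted, name="gene_id"))

    truth = GroundTruth(
        subfamily=truth_sub,
        origin=origin,
        tandem_clusters=tandem_clusters,
        nontandem_pairs=nontandem_pairs,
        tree_newick=tree_newick,
        site_omegas=site_omegas,
        expression_fpkm=expr_truth,
    )
    return SimulatedFamily(
        config=config,
        loci=loci,
        architectures=architectures,
        proteins=proteins,
        cds=cds,
        alignments=alignments,
        subfamily_trees=subfamily_trees,
        tree_newick=tree_newick,
        reference_labels=ref_labels,
        motif_table=motif_table,
        hit_table=hit_table,
        domain_table=domain_table,
        counts=counts_df,
        gene_lengths=lengths,
        library_sizes=lib,
        truth=truth,
    )


def fixture_study_scale(seed: int = 0) -> SimulatedFamily:
    """The default study-shaped dataset (94 genes, 60 scaffolds, 18
    subfamilies, five tandem clusters) for a given seed."""
    return simulate_family(FamilySimConfig(seed=seed))


def write_gff3(loci: list[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in sorted(loci, key=lambda g: (g.scaffold, g.start, g.gene_id)):
            base = (locus.scaffold, "lrrfam_sim")
            fh.write(
                "\t".join(
                    map(str, base + ("gene", locus.start, locus.end, ".", locus.strand, ".",
                        f"ID={locus.gene_id}"))
                )
                + "\n"
            )
            mrna = f"{locus.gene_id}.1"
            fh.write(
                "\t".join(
                    map(str, base + ("mRNA", locus.start, locus.end, ".", locus.strand, ".",
                        f"ID={mrna};Parent={locus.gene_id}"))
                )
                + "\n"
            )
            for kind, ivs in (("exon", locus.exons), ("CDS", locus.cds)):
                phase_iter = _cds_phases(ivs, locus.strand) if kind == "CDS" else ["."] * len(ivs)
                for (s, e), ph in zip(ivs, phase_iter):
                    fh.write(
                        "\t".join(
                            map(str, base + (kind, s, e, ".", locus.strand, ph,
                                f"Parent={mrna}"))
                        )
                        + "\n"
                    )


def _cds_phases(intervals, strand):
    ordered = intervals if strand == "+" else list(reversed(intervals))
    phases, acc = {}, 0
    for s, e in ordered:
        phases[(s, e)] = (3 - acc % 3) % 3
        acc += e - s + 1
    return [phases[iv] for iv in intervals]


def _write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")
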