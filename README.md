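# lrrfam

A gene-family evolution toolkit for plant receptor-like kinase families,
built around the analysis stages of a genome-wide LRR-RLK survey in the
basal angiosperm *Amborella trichopoda*. It is a library: you import the
modules from Python, and the `examples/` scripts show one capability each.

LRR-RLKs (leucine-rich-repeat receptor-like kinases) are plant receptors
with extracellular LRR repeats, a transmembrane span (TM), and an
intracellular kinase domain (KD). Surveys of this family ask the same set
of questions in every genome: which gene models are real family members,
how the family expanded (tandem vs dispersed duplication), how members
group into subfamilies on a kinase-domain phylogeny, how conserved their
domain/motif/intron structure is within subfamilies, whether selection has
acted on particular codon sites, and how members are expressed across
tissues. `lrrfam` implements each stage as a tested, reusable function,
and ships a synthetic-data generator so every stage can be validated
against known ground truth.

## What each module does

| module | analysis stage |
| --- | --- |
| `lrrfam.family_screen` | E-value filter (< 1e-10), LRR→TM→KD architecture rule, duplicate/defective-sequence removal |
| `lrrfam.genome_map` | 200-kb proximity clustering on scaffolds, tandem validation by clade monophyly, tandem fraction, expansion rates N_ref/N_query |
| `lrrfam.phylo_classify` | midpoint rooting, reference-guided subfamily assignment with bootstrap-support and monophyly (asterisk) flags |
| `lrrfam.domain_motifs` | LRR-count summaries, motif presence matrices, per-column information content and consensus rendering |
| `lrrfam.gene_structure` | intron counts/positions (CDS offsets + phase) from GFF3, structural-conservation measures |
| `lrrfam.selection` | GY94 codon models: site models M0/M1a/M2a/M3/M7/M8, ML fitting, LRTs at P < 0.01, NEB positive-site calls, codon simulation |
| `lrrfam.expression` | FPKM, low/moderate/high categories, per-subfamily roll-ups |
| `lrrfam.simulate` | complete synthetic study inputs with ground truth |
| `lrrfam.reference` | published summary tables of the *A. trichopoda* LRR-RLK survey (copy numbers, site-model estimates, LRT statistics) |

## The core model

Selection on codon sites is modelled with a GY94-style Markov chain on the
61 sense codons. The rate from codon *i* to *j* (single-nucleotide changes
only) is

```
q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]
```

with ω = dN/dS. The site models differ in how ω varies across sites:
M0 (one ω), M1a (ω0 < 1 and ω1 = 1), M2a (adds ω2 ≥ 1), M3 (three free
classes), M7 (ω ~ Beta(p, q)), M8 (beta plus one class ωs ≥ 1). Likelihoods
are computed by Felsenstein pruning per ω class and mixed over classes;
nested pairs (M0⊂M3, M1⊂M2, M7⊂M8) are compared with likelihood-ratio
tests, `2ΔlnL ~ chi²(df)`, significant at P < 0.01; sites under positive
selection are those whose naive-empirical-Bayes (NEB) posterior for an
ω > 1 class exceeds 0.95.

## Worked example

```python
import numpy as np
from lrrfam.selection import neb_positive_sites, random_tree, simulate_alignment
from lrrfam.selection.fit import fit_nested_pair

nwk = random_tree(5, rng=8, total_length=2.0)
aln, truth = simulate_alignment(nwk, kappa=2.0, omegas=[0.1, 1.0, 6.0],
                                proportions=[0.6, 0.25, 0.15], n_sites=200,
                                rng=np.random.default_rng(8))
f1, f2, test = fit_nested_pair(aln, nwk, "M1", "M2", codon_freq="equal")
print(test.two_delta_lnl, test.p_value, test.significant)
print(len(neb_positive_sites(f2, cutoff=0.95)))
```

prints (run as `examples/05_site_selection.py`):

```
M2 vs M1: lnL -1762.24 vs -1784.02, 2dlnL = 43.55 (df 2), P = 3.50e-10 -> significant
NEB > 95% sites: 27 called, 23 coincide with the true omega>1 class
```

The LRT rejects the nearly-neutral model because 15% of sites were
simulated with ω = 6, and the NEB calls land almost entirely on those
sites. The other examples cover screening (`01`), genome mapping and
tandem calls (`02` — prints `tandem genes: 11/94 = 11.7%` on the default
synthetic family, alongside expansion rates such as `I: 41/5 = 8.2`),
subfamily classification (`03`), motif/structure summaries (`04`),
expression roll-ups (`06`), and dataset generation (`07`).

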