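# Methods

## Family screening

A candidate is accepted as an LRR-RLK only if it (1) has at least one
annotated LRR repeat, (2) at least one transmembrane span, (3) exactly one
kinase domain, and (4) satisfies the receptor topology: every LRR interval
ends before the first TM span begins and the kinase domain starts after
the last TM span ends. The topology condition operationalizes "LRRs in the
extracellular domain with an intracellular kinase"; because domain
annotations can be noisy it is a separate, relaxable check
(`require_topology=False`) with its own reason code. Candidates reach the
architecture check as the union of E-value-passing homology hits
(strict `evalue < 1e-10`) and proteins carrying domain annotations, since
the two discovery routes are complementary. "Defective" sequences are
operationalized as an internal stop symbol or length below `min_aa`
(default 100 aa); exact duplicates collapse to the lexicographically
smallest identifier so the outcome never depends on input order.

## Genome mapping and tandem duplication

Genes are chained per scaffold by start-to-start distance: consecutive
genes at most `window_bp` apart (default 200,000, boundary inclusive) join
one proximity cluster; chains of two or more genes are reported. Chaining
(single linkage) rather than total-span limiting was chosen because a
"region containing two or more genes within 200 kb" is naturally read as a
pairwise-adjacency rule; the window is a parameter, so the other reading
is one call away. A cluster is called tandem only if its members form a
clade: the MRCA of the members has exactly the members as leaf
descendants. A lenient mode (`mode="subfamily"`) accepts shared subfamily
assignment instead, for trees whose fine structure is unreliable. Clusters
of three or more genes must be monophyletic as a whole; monophyletic
sub-pairs of failed clusters are available separately
(`tandem_subpairs`). Expansion rates are reference/query copy-number
ratios rounded half-up to one decimal, matching how such tables are
printed.

## Subfamily classification

Trees are midpoint-rooted: the root is placed halfway along the maximal
patristic leaf-to-leaf path, with ties broken by the lexicographic order
of the leaf pair so rooting is deterministic; all pairwise patristic
distances are preserved. Rooting is undefined (and refused) when every
branch length is zero.

Assignment is reference-guided: for each subfamily label the maximal clade
containing only that label's reference leaves (and at least one) donates
the label to all query leaves inside it. A call is `supported` when that
clade's bootstrap support is strictly above the threshold (default 80).
When a label's references are not monophyletic, no such clade exists for
it; affected queries fall back to the majority label among the reference
leaves of their smallest reference-containing ancestor, and every call
involving that label carries the `monophyly_uncertain` (asterisk) flag.
Queries inside no labelled clade are `unclassified`. Subdivided subfamily
labels (e.g. VI-1 vs VI-2) must be supplied in the reference table; the
classifier never invents subdivisions.

## Domain, motif, and intron conservation

Per-column information content of an amino-acid alignment column is
`bits = log2(20) − H`, with H the Shannon entropy of residue frequencies
over the non-gap symbols and no small-sample correction. Gaps are excluded
by default (`gap_as_symbol=True` adds the gap as a 21st symbol). The
consensus rendering maps bits to emphasis as a step function with
breakpoints exactly at 1, 2, and 3 bits: x / lowercase / uppercase / bold
capital; the consensus residue is the modal residue, ties broken
lexicographically. Motif presence per (subfamily, motif) is categorized
all / most (> 50%, configurable) / some / none, and a motif is
subfamily-specific when exactly one subfamily carries it at all/most while
every other subfamily is at none.

Intron positions are coding-nucleotide offsets: the cumulative CDS length
before each intron in transcription order (minus-strand gene models are
traversed right to left), with phase = offset mod 3. UTR introns are not
counted, since positions are compared over coding sequences. Genes
without CDS intervals are skipped with a logged warning. Structural
similarity between two profiles is the maximum order-preserving matching
under an offset tolerance (default 0 nt, exact) with equal phases,
computed by dynamic programming, summarized as a Jaccard index. The
order-preserving restriction makes the measure symmetric and
deterministic; crossing matches are biologically implausible for
homologous intron positions.

## Codon site models

The substitution model is GY94-style: rates are nonzero only for
single-nucleotide codon changes, proportional to the target codon's
stationary frequency, multiplied by κ for transitions and by ω for
non-synonymous changes. Matrices are normalized so the expected number of
substitutions per codon per unit time is 1 at the class-mixture level (one
shared scaling factor across classes, so branch lengths keep their usual
units). Stationary frequencies are F3x4 by default — position-specific
nucleotide frequencies estimated from the alignment, multiplied and
renormalized over the 61 sense codons — with `equal` as an option; κ is
always estimated (initial value 2.0), even though published tables rarely
print it.

Likelihoods use Felsenstein pruning with per-node rescaling and site
pattern compression; gaps and ambiguous codons are missing data (partial
likelihood 1 over all codons). Reversibility is exploited throughout: the
symmetrized rate matrix is diagonalized once per parameter vector and
reused for every branch.

Fitting maximizes lnL over κ, the class parameters, and all branch lengths
jointly with box-constrained L-BFGS-B. Proportion simplices use a
stick-breaking map so every free parameter lives in a box; ω2 (M2) and ωs
(M8) are constrained to [1, 50], so boundary estimates are reported as
exactly 1. The beta models discretize Beta(p, q) into 10 equal-probability
categories represented by their conditional means. Multi-start fitting
(default 3 seeded starts, the first deterministic) mitigates local optima;
non-convergence is flagged on the returned fit, never silent. For nested
pairs, `fit_nested_pair` additionally starts the alternative model at the
exact embedding of the fitted null — which guarantees
lnL(alt) ≥ lnL(null) by optimizer monotonicity — paired with a free start,
because the embedding sits on a stationary ridge of the richer model
(e.g. all-equal ω classes in M3) that a gradient method cannot leave.

LRTs use `2(lnL_alt − lnL_null)` floored at zero against the chi-square
upper tail (df 4 for M0/M3, 2 for M1/M2 and M7/M8), significant at
P < 0.01. NEB posteriors are the per-site class responsibilities at the
fitted parameters; positive-site calls require an ω strictly above 1 and
posterior above 0.95.

## Synthetic data

The generator emits a complete, mutually consistent input set whose
defaults mirror the study system's shape: 94 genes in 18 subfamilies with
the published size spectrum on 60 scaffolds of 3 Mb, five tandem clusters
(sizes 3,2,2,2,2) placed within 50 kb start-to-start (well inside the
200-kb window; boundary behaviour is tested separately), dispersed genes
at least 600 kb apart, and two same-scaffold pairs from different
subfamilies that form proximity clusters without being tandem. Gene trees
are built directly from the duplication history (tandem duplicates are
cherries/clades), subfamily crown groups get support 95 and deep backbone
nodes low support, and two reference-labelled leaves per subfamily emulate
the labelled comparator species; a `plant_paraphyly` option moves one
reference outside its clade. Codon sequences evolve under per-subfamily
M0-style ω (the five selection-analysed subfamilies carry their published
estimates, others ω = 0.2, κ = 2); proteins are translations of the
simulated CDS, so all sequence files agree. Intron counts are the
subfamily's modal published value; expression counts are negative binomial
(dispersion 0.1) around planted per-subfamily, per-tissue FPKM means with
fixed library sizes of 2×10⁷.

What the generator does not emulate: alignment gaps and alignment error,
rate variation among lineages, annotation errors in domain tables, UTRs
and alternative splicing, intergenic sequence content, and read-level
noise (counts are drawn directly, not mapped). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated models, not robustness to real-data artefacts.

## Recovery experiments and problem sizes

The parameter-recovery experiments simulate 20 replicate alignments on
fresh random trees (8 taxa, total length 2 expected substitutions/codon,
equal codon frequencies, κ = 2): 300 codons per replicate for the M0
experiment and 500 for the M1 experiment, sizes at which the mean estimate
is comfortably stable while a full run stays in the minutes range on one
CPU. Each replicate's randomness is spawned from a single base seed via
`SeedSequence`, so experiments are reproducible from one integer. Fits in
these experiments use a single deterministic start; the nesting-inequality
checks use four-to-five-taxon alignments of 100–150 codons for the same
reason.

## Known limitations

* Only site models are implemented — no branch or branch-site models, and
  only NEB (not BEB) site identification.
* The midpoint-rooting tie-break and the consensus-residue tie-break are
  conventions; other tools may resolve ties differently.
* F3x4 frequencies are clamped away from zero (1e-6) to keep the chain
  irreducible on sparse alignments.
* The published summary tables stored in `lrrfam.reference` contain one
  internally inconsistent cell (the subfamily-I one-ratio log-likelihood);
  the value consistent with the published likelihood-ratio statistic is
  stored, with the discrepancy documented at the definition site.
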