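"""FPKM normalization and per-subfamily expression categories.

Computes FPKM from the synthetic count table, bins genes into
low/moderate/high per tissue (cutoffs 1 and 10), and rolls the categories
up per subfamily.
"""

from lrrfam.expression import categorize, fpkm_matrix, subfamily_rollup
from lrrfam.simulate import fixture_study_scale

family = fixture_study_scale(seed=1)
matrix = fpkm_matrix(family.counts, family.gene_lengths, family.library_sizes)
print("FPKM (first genes):")
print(matrix.head(4).round(2).to_string())

categories = categorize(matrix)  # low < 1 <= moderate <= 10 < high
rollup = subfamily_rollup(categories, family.truth.subfamily)
print("\nper-subfamily roll-up (whole plant):")
wp = rollup[rollup.tissue == "whole_plant"]
print(wp.head(8).round(2).to_string(index=False))
# fractions sum to 1 per subfamily; the planted high-expression subfamilies
# (e.g. I and II in whole plant) show frac_high near 1.
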