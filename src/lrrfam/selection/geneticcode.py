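"""Universal genetic code tables used by the codon substitution machinery.

The codon state space is the 61 sense codons of the standard (universal)
code; the three stop codons (TAA, TAG, TGA) are excluded. Precomputed pair
classifications (single-nucleotide difference, transition vs transversion,
synonymous vs non-synonymous) drive the GY94-style rate matrix.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons, in lexicographic (A<C<G<T) order
CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in _STANDARD.stop_codons
)
N_CODONS = len(CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: amino acid (one-letter) encoded by each sense codon
AMINO_ACIDS: tuple[str, ...] = tuple(_STANDARD.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, transition, nonsyn


SINGLE_DIFF, IS_TRANSITION, IS_NONSYNONYMOUS = _pair_tables()

AMINO_ACID_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def codon_of(index: int) -> str:
    """Codon string for a 0-based sense-codon index."""
    return CODONS[index]
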