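"""LRR-count summaries, motif-presence matrices, and consensus rendering.

Per-column information content of an amino-acid alignment column is
``bits = log2(20) − H`` with ``H`` the Shannon entropy of the residue
frequencies over the 20 amino acids (gaps excluded by default). The
consensus-rendering rule maps bits to emphasis: below 1 bit the position is
written as 'x', [1, 2) lowercase, [2, 3) uppercase, and >= 3 bold capital.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .family_screen import DomainArchitecture

MAX_BITS = math.log2(20)

EMPHASIS_X = "x"
EMPHASIS_LOWER = "lowercase"
EMPHASIS_UPPER = "uppercase"
EMPHASIS_BOLD = "bold"

MOTIF_VOCABULARY = tuple(f"M{i}" for i in range(1, 16))

#: static annotation: which of the 12 kinase subdomains each motif maps to
#: (None for motifs outside the known subdomains); descriptive, not computed
MOTIF_SUBDOMAIN: dict[str, str | None] = {
    "M1": "I",
    "M2": "II",
    "M3": "III",
    "M4": "IV",
    "M5": "V",
    "M6": "V",
    "M7": "VIa",
    "M8": None,
    "M9": None,
    "M10": "VIb&VII",
    "M11": "VIII",
    "M12": "IX",
    "M13": None,
    "M14": None,
    "M15": "XI",
}


@dataclass(frozen=True)
class MotifOccurrence:
    protein_id: str
    motif_id: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}/{self.motif_id}: start > end")


@dataclass(frozen=True)
class ConsensusColumn:
    residue: str
    bits: float
    emphasis: str


def read_motif_table(path: str | Path) -> list[MotifOccurrence]:
    """MEME-style occurrence TSV: protein_id motif_id start end score."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "motif_id", "start", "end", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"motif table must have columns {sorted(required)}")
    return [
        MotifOccurrence(str(r.protein_id), str(r.motif_id), int(r.start), int(r.end), float(r.score))
        for r in df.itertuples(index=False)
    ]


def _range_summary(values: list[int]) -> tuple[int, int, tuple[int, ...]]:
    counts = Counter(values)
    top = max(counts.values())
    modes = tuple(sorted(v for v, c in counts.items() if c == top))
    return min(values), max(values), modes


def lrr_range_by_subfamily(
    architectures: dict[str, DomainArchitecture], calls: dict[str, str]
) -> pd.DataFrame:
    """Per-subfamily (min, max, mode) of LRR-repeat counts.

    Every protein needs a subfamily call; the mode column lists all tied
    modal values (comma-joined).
    """
    missing = sorted(set(architectures) - set(calls))
    if missing:
        raise ValueError(f"proteins without a subfamily call: {missing}")
    groups: dict[str, list[int]] = {}
    for pid, arch in architectures.items():
        groups.setdefault(calls[pid], []).append(len(arch.lrr_repeats))
    rows = []
    for sub in sorted(groups):
        lo, hi, modes = _range_summary(groups[sub])
        rows.append((sub, lo, hi, ",".join(str(m) for m in modes)))
    return pd.DataFrame(rows, columns=["subfamily", "min_lrr", "max_lrr", "mode_lrr"])


CATEGORY_ALL = "all"
CATEGORY_MOST = "most"
CATEGORY_SOME = "some"
CATEGORY_NONE = "none"


def motif_presence(
    occurrences: list[MotifOccurrence],
    calls: dict[str, str],
    most_threshold: float = 0.5,
    vocabulary: tuple[str, ...] = MOTIF_VOCABULARY,
) -> tuple[pd.DataFrame, list[str]]:
    """Subfamily × motif presence categories and subfamily-specific motifs.

    Categories per (subfamily, motif): ``all`` — every member has at least
    one occurrence; ``most`` — more than ``most_threshold`` but not all;
    ``some`` — above zero and at most the threshold; ``none``. A motif is
    subfamily-specific if exactly one subfamily carries it at all/most.
    """
    unknown = sorted({o.motif_id for o in occurrences} - set(vocabulary))
    if unknown:
        raise ValueError(f"motif ids outside vocabulary: {unknown}")
    members: dict[str, set[str]] = {}
    for pid, sub in calls.items():
        members.setdefault(sub, set()).add(pid)
    carriers: dict[tuple[str, str], set[str]] = {}
    for occ in occurrences:
        sub = calls.get(occ.protein_id)
        if sub is None:
            continue
        carriers.setdefault((sub, occ.motif_id), set()).add(occ.protein_id)

    rows = []
    for sub in sorted(members):
        n = len(members[sub])
        for motif in vocabulary:
            k = len(carriers.get((sub, motif), ()))
            if k == 0:
                cat = CATEGORY_NONE
            elif k == n:
                cat = CATEGORY_ALL
            elif k / n > most_threshold:
                cat = CATEGORY_MOST
            else:
                cat = CATEGORY_SOME
            rows.append((sub, motif, k, n, cat))
    matrix = pd.DataFrame(
        rows, columns=["subfamily", "motif_id", "n_carriers", "n_members", "category"]
    )
    specific = []
    for motif in vocabulary:
        present = matrix[
            (matrix.motif_id == motif)
            & matrix.category.isin([CATEGORY_ALL, CATEGORY_MOST])
        ]
        absent_elsewhere = matrix[
            (matrix.motif_id == motif) & (matrix.category == CATEGORY_NONE)
        ]
        if len(present) == 1 and len(present) + len(absent_elsewhere) == len(members):
            specific.append(motif)
    return matrix, specific


def column_bits(column: list[str], gap_as_symbol: bool = False) -> float:
    """Information content (bits) of one amino-acid alignment column.

    ``bits = log2(20) − H`` with frequencies over the non-gap residues (no
    small-sample correction). With ``gap_as_symbol=True`` the gap character
    counts as a 21st symbol and the ceiling becomes log2(21).
    """
    symbols = [c.upper() for c in column]
    if not gap_as_symbol:
        symbols = [c for c in symbols if c not in "-."]
    if not symbols:
        raise ValueError("column has no non-gap symbols")
    n_alpha = 21 if gap_as_symbol else 20
    counts = Counter(symbols)
    freqs = np.array(list(counts.values()), dtype=float)
    freqs /= freqs.sum()
    entropy = -(freqs * np.log2(freqs)).sum()
    return float(math.log2(n_alpha) - entropy)


def consensus_code(residue: str, bits: float) -> ConsensusColumn:
    """Map a consensus residue and its bits value to the emphasis category."""
    if bits < 0:
        raise ValueError("bits must be >= 0")
    if bits < 1:
        emphasis = EMPHASIS_X
    elif bits < 2:
        emphasis = EMPHASIS_LOWER
    elif bits < 3:
        emphasis = EMPHASIS_UPPER
    else:
        emphasis = EMPHASIS_BOLD
    return ConsensusColumn(residue=residue, bits=bits, emphasis=emphasis)


def render_consensus(columns: list[list[str]], gap_as_symbol: bool = False) -> str:
    """Plain-text consensus of an alignment block.

    Per column the modal residue (ties broken lexicographically) is rendered
    as 'x' (uninformative), lowercase, uppercase, or *bold* (asterisk-markup)
    according to its information content.
    """
    out = []
    for col in columns:
        bits = column_bits(col, gap_as_symbol)
        residues = [c.upper() for c in col if c not in "-." or gap_as_symbol]
        counts = Counter(residues)
        top = max(counts.values())
        residue = sorted(r for r, c in counts.items() if c == top)[0]
        cc = consensus_code(residue, bits)
        if cc.emphasis == EMPHASIS_X:
            out.append("x")
        elif cc.emphasis == EMPHASIS_LOWER:
            out.append(cc.residue.lower())
        elif cc.emphasis == EMPHASIS_UPPER:
            out.append(cc.residue.upper())
        else:
            out.append(f"*{cc.residue.upper()}*")
    return "".join(out)
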