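"""Intron profiles from gene models and structural-conservation summaries.

Intron positions are expressed as coding-nucleotide offsets: the cumulative
CDS length (in transcription order, strand-normalized) before each intron,
with the phase being that length mod 3. This makes positions comparable
between genes regardless of scaffold strand or UTR content.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome_map import GeneLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronProfile:
    gene_id: str
    n_introns: int
    positions: tuple[tuple[int, int], ...]  # (coding offset before intron, phase)

    def __post_init__(self) -> None:
        if self.n_introns != len(self.positions):
            raise ValueError("n_introns must equal len(positions)")
        offsets = [p for p, _ in self.positions]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("intron offsets must be strictly increasing")


def introns_from_gff(locus: GeneLocus) -> IntronProfile:
    """Intron count/positions from the CDS intervals of a gene model.

    Introns are the gaps between consecutive CDS intervals in transcription
    order (reverse-complement logic on the minus strand); UTR introns are
    not counted. Raises on overlapping CDS intervals.
    """
    cds = sorted(locus.cds)
    if not cds:
        raise ValueError(f"{locus.gene_id}: no CDS intervals")
    for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
        if s2 <= e1:
            raise ValueError(f"{locus.gene_id}: overlapping CDS intervals")
    if locus.strand == "-":
        ordered = list(reversed(cds))
    else:
        ordered = cds
    positions = []
    coding = 0
    for interval in ordered[:-1]:
        coding += interval[1] - interval[0] + 1
        positions.append((coding, coding % 3))
    return IntronProfile(
        gene_id=locus.gene_id,
        n_introns=len(positions),
        positions=tuple(positions),
    )


def profiles_from_loci(loci: list[GeneLocus]) -> list[IntronProfile]:
    """Intron profiles for a list of gene loci; genes without CDS intervals
    are skipped with a warning (mirroring genes whose structures are
    unavailable in the annotation)."""
    out = []
    for locus in loci:
        if not locus.cds:
            logger.warning("%s: gene structure unavailable; skipped", locus.gene_id)
            continue
        out.append(introns_from_gff(locus))
    return out


def structure_mode_by_subfamily(
    profiles: list[IntronProfile], calls: dict[str, str]
) -> pd.DataFrame:
    """Per-subfamily (min, max, mode) of intron counts.

    Subfamilies with calls but no profiled member are omitted with a warning.
    """
    groups: dict[str, list[int]] = {}
    for profile in profiles:
        sub = calls.get(profile.gene_id)
        if sub is None:
            raise ValueError(f"{profile.gene_id} has no subfamily call")
        groups.setdefault(sub, []).append(profile.n_introns)
    for sub in sorted(set(calls.values()) - set(groups)):
        logger.warning("subfamily %s has no profiled members; omitted", sub)
    rows = []
    for sub in sorted(groups):
        values = groups[sub]
        counts = Counter(values)
        top = max(counts.values())
        modes = ",".join(str(v) for v in sorted(v for v, c in counts.items() if c == top))
        rows.append((sub, min(values), max(values), modes))
    return pd.DataFrame(rows, columns=["subfamily", "min_introns", "max_introns", "mode_introns"])


def shared_structure(
    profile_a: IntronProfile, profile_b: IntronProfile, tolerance_nt: int = 0
) -> tuple[int, float]:
    """Shared-intron count and Jaccard index between two intron profiles.

    Introns match when their coding offsets differ by at most
    ``tolerance_nt`` and their phases are equal; the matching is the maximum
    order-preserving (non-crossing) matching, computed by dynamic
    programming. Symmetric in its arguments.
    """
    if tolerance_nt < 0:
        raise ValueError("tolerance must be >= 0")
    a, b = profile_a.positions, profile_b.positions
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0, 1.0
    # LCS-style DP on the match predicate
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            off_a, ph_a = a[i - 1]
            off_b, ph_b = b[j - 1]
            match = abs(off_a - off_b) <= tolerance_nt and ph_a == ph_b
            dp[i][j] = max(
                dp[i - 1][j],
                dp[i][j - 1],
                dp[i - 1][j - 1] + (1 if match else 0),
            )
    shared = dp[n][m]
    union = n + m - shared
    return shared, (shared / union if union else 1.0)


def profiles_to_frame(profiles: list[IntronProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.gene_id,
                p.n_introns,
                ";".join(f"{off}:{ph}" for off, ph in p.positions),
            )
            for p in profiles
        ],
        columns=["gene_id", "n_introns", "positions"],
    )
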