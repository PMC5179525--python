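"""FPKM computation and expression-category summaries.

FPKM (fragments per kilobase of transcript per million mapped fragments)
normalizes a fragment count by transcript length and library size:

    FPKM = count × 10^9 / (length_bp × total_fragments)

Genes are then binned into low / moderate / high expression per tissue by
FPKM cutoffs (defaults 1 and 10), with per-subfamily roll-ups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LOW = 1.0
DEFAULT_HIGH = 10.0

CATEGORIES = ("low", "moderate", "high")


def fpkm(counts, length_bp, total_fragments):
    """FPKM for scalar or array counts.

    ``length_bp`` is the effective transcript length (summed exon length of
    the representative transcript); ``total_fragments`` the library's total
    mapped fragments. Invariant to joint rescaling of counts and totals.
    """
    length_bp = np.asarray(length_bp, dtype=float)
    total_fragments = np.asarray(total_fragments, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("gene length must be > 0")
    if np.any(total_fragments <= 0):
        raise ValueError("total mapped fragments must be > 0")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    result = counts * 1e9 / (length_bp * total_fragments)
    return float(result) if result.ndim == 0 else result


def fpkm_matrix(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> pd.DataFrame:
    """Genes × tissues FPKM from a count matrix, per-gene lengths, and
    per-tissue library sizes."""
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing length for genes: {list(lengths[lengths.isna()].index)}")
    if totals.isna().any():
        raise ValueError(f"missing library size for tissues: {list(totals[totals.isna()].index)}")
    values = fpkm(
        counts.to_numpy(),
        lengths.to_numpy()[:, None],
        totals.to_numpy()[None, :],
    )
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def categorize(
    fpkm_values: pd.DataFrame,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    mode: str = "cutoff",
) -> pd.DataFrame:
    """Genes × tissues expression categories.

    ``cutoff`` mode: low if FPKM < ``low``, high if FPKM > ``high``,
    moderate between. ``tertile`` mode bins each tissue into its empirical
    tertiles instead (ignores the cutoffs).
    """
    if mode == "cutoff":
        if not low < high:
            raise ValueError("thresholds must satisfy low < high")
        values = fpkm_values.to_numpy()
        cats = np.full(values.shape, "moderate", dtype=object)
        cats[values < low] = "low"
        cats[values > high] = "high"
        return pd.DataFrame(cats, index=fpkm_values.index, columns=fpkm_values.columns)
    if mode == "tertile":
        out = {}
        for tissue in fpkm_values.columns:
            col = fpkm_values[tissue]
            q1, q2 = col.quantile([1 / 3, 2 / 3])
            out[tissue] = np.where(col <= q1, "low", np.where(col <= q2, "moderate", "high"))
        return pd.DataFrame(out, index=fpkm_values.index)
    raise ValueError("mode must be 'cutoff' or 'tertile'")


def subfamily_rollup(categories: pd.DataFrame, calls: dict[str, str]) -> pd.DataFrame:
    """Fraction of each subfamily's members per category per tissue.

    Fractions sum to 1 within every (subfamily, tissue) pair.
    """
    missing = sorted(set(categories.index) - set(calls))
    if missing:
        raise ValueError(f"genes without subfamily calls: {missing}")
    rows = []
    sub_of = pd.Series({g: calls[g] for g in categories.index})
    for sub in sorted(set(sub_of)):
        members = categories.loc[sub_of[sub_of == sub].index]
        for tissue in categories.columns:
            counts = members[tissue].value_counts()
            n = len(members)
            rows.append(
                (sub, tissue, n)
                + tuple(counts.get(cat, 0) / n for cat in CATEGORIES)
            )
    return pd.DataFrame(
        rows,
        columns=["subfamily", "tissue", "n_members", "frac_low", "frac_moderate", "frac_high"],
    )


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes × tissues count table (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
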