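"""Family-membership screening from homology hits and domain annotations.

A candidate joins an LRR-RLK family only if its domain architecture shows
the receptor-kinase layout: one or more extracellular leucine-rich repeats
(LRRs), at least one transmembrane span (TM), and exactly one intracellular
kinase domain (KD), arranged LRRs → TM → KD along the protein. Candidates
are pre-filtered by homology-search E-value; exact-duplicate and defective
protein sequences are dropped before architecture screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_MIN_AA = 100

Interval = tuple[int, int]


@dataclass(frozen=True)
class HitRecord:
    """One homology search hit (query, subject, E-value)."""

    query_id: str
    subject_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query_id}: {self.evalue}")


@dataclass
class DomainArchitecture:
    """Ordered domain annotations for one protein (1-based inclusive intervals)."""

    protein_id: str
    lrr_repeats: list[Interval] = field(default_factory=list)
    tm_spans: list[Interval] = field(default_factory=list)
    kinase_domains: list[Interval] = field(default_factory=list)
    extra_domains: list[tuple[str, Interval]] = field(default_factory=list)
    protein_length: int | None = None

    def __post_init__(self) -> None:
        for name, ivs in (
            ("lrr_repeats", self.lrr_repeats),
            ("tm_spans", self.tm_spans),
            ("kinase_domains", self.kinase_domains),
        ):
            ivs.sort()
            prev_end = 0
            for start, end in ivs:
                if start < 1 or start > end:
                    raise ValueError(f"{self.protein_id}: bad {name} interval ({start}, {end})")
                if self.protein_length is not None and end > self.protein_length:
                    raise ValueError(
                        f"{self.protein_id}: {name} interval ({start}, {end}) "
                        f"exceeds protein length {self.protein_length}"
                    )
                if start <= prev_end:
                    raise ValueError(f"{self.protein_id}: overlapping {name} intervals")
                prev_end = end


@dataclass(frozen=True)
class MembershipDecision:
    protein_id: str
    accepted: bool
    reasons: tuple[str, ...] = ()  # empty iff accepted


REASON_NO_LRR = "no_LRR"
REASON_NO_TM = "no_TM"
REASON_KD_COUNT = "kinase_domain_count"
REASON_TOPOLOGY = "topology"


def filter_hits(
    hits, cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> set[str]:
    """Query ids with at least one hit at E-value strictly below ``cutoff``.

    ``hits`` is an iterable of :class:`HitRecord` (or a DataFrame with
    columns query_id/subject_id/evalue). Deduplicated; order-independent.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if isinstance(hits, pd.DataFrame):
        hits = [
            HitRecord(str(r.query_id), str(r.subject_id), float(r.evalue))
            for r in hits.itertuples(index=False)
        ]
    return {h.query_id for h in hits if h.evalue < cutoff}


def read_hit_table(path: str | Path, blast_outfmt6: bool = False) -> list[HitRecord]:
    """Read a hit TSV: either ``query_id subject_id evalue`` with header, or
    (``blast_outfmt6=True``) headerless tabular BLAST where the E-value is
    column 11."""
    records: list[HitRecord] = []
    if blast_outfmt6:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 11:
            raise ValueError("outfmt6 table needs at least 11 columns")
        rows = df[[0, 1, 10]].itertuples(index=False)
    else:
        df = pd.read_csv(path, sep="\t")
        required = {"query_id", "subject_id", "evalue"}
        if not required <= set(df.columns):
            raise ValueError(f"hit table must have columns {sorted(required)}")
        rows = df[["query_id", "subject_id", "evalue"]].itertuples(index=False)
    for i, row in enumerate(rows, start=2 if not blast_outfmt6 else 1):
        try:
            records.append(HitRecord(str(row[0]), str(row[1]), float(row[2])))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed hit-table row {i}: {exc}") from exc
    return records


_DOMAIN_KIND = {"LRR": "lrr_repeats", "TM": "tm_spans", "KD": "kinase_domains"}


def read_domain_table(path: str | Path) -> dict[str, DomainArchitecture]:
    """Read a domain TSV (``protein_id domain_name start end``, 1-based
    inclusive) into architectures. Domain names LRR/TM/KD fill the three core
    slots; anything else (e.g. a malectin-like domain) goes to extra_domains."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_name", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"domain table must have columns {sorted(required)}")
    archs: dict[str, DomainArchitecture] = {}
    rows: dict[str, dict[str, list]] = {}
    for r in df.itertuples(index=False):
        slot = rows.setdefault(
            str(r.protein_id),
            {"lrr_repeats": [], "tm_spans": [], "kinase_domains": [], "extra_domains": []},
        )
        iv = (int(r.start), int(r.end))
        kind = _DOMAIN_KIND.get(str(r.domain_name))
        if kind:
            slot[kind].append(iv)
        else:
            slot["extra_domains"].append((str(r.domain_name), iv))
    for pid, slots in rows.items():
        archs[pid] = DomainArchitecture(protein_id=pid, **slots)
    return archs


def classify_membership(
    arch: DomainArchitecture, require_topology: bool = True
) -> MembershipDecision:
    """Accept iff the architecture is LRR(s) → TM(s) → exactly one KD.

    Conditions, each with its own reason code on failure: at least one LRR
    repeat; at least one TM span; exactly one kinase domain; and (unless
    ``require_topology=False``) every LRR ends before the first TM starts
    while the KD starts after the last TM ends.
    """
    reasons: list[str] = []
    if not arch.lrr_repeats:
        reasons.append(REASON_NO_LRR)
    if not arch.tm_spans:
        reasons.append(REASON_NO_TM)
    if len(arch.kinase_domains) != 1:
        reasons.append(REASON_KD_COUNT)
    if require_topology and not reasons:
        first_tm_start = arch.tm_spans[0][0]
        last_tm_end = max(end for _, end in arch.tm_spans)
        lrr_ok = all(end < first_tm_start for _, end in arch.lrr_repeats)
        kd_ok = arch.kinase_domains[0][0] > last_tm_end
        if not (lrr_ok and kd_ok):
            reasons.append(REASON_TOPOLOGY)
    return MembershipDecision(arch.protein_id, accepted=not reasons, reasons=tuple(reasons))


def drop_redundant(
    sequences: dict[str, str], min_aa: int = DEFAULT_MIN_AA
) -> dict[str, str]:
    """Remove exact duplicates and defective protein sequences.

    Exact duplicates collapse to the lexicographically smallest identifier.
    A sequence is defective if it contains an internal stop symbol ('*') or
    is shorter than ``min_aa`` residues; a single terminal '*' is tolerated.
    """
    survivors: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    for name in sorted(sequences):
        seq = sequences[name].strip().upper()
        core = seq[:-1] if seq.endswith("*") else seq
        if "*" in core or len(core) < min_aa:
            continue
        if core not in by_seq:
            by_seq[core] = name
            survivors[name] = core
    return survivors


def screen_family(
    hits,
    architectures: dict[str, DomainArchitecture],
    sequences: dict[str, str] | None = None,
    *,
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_aa: int = DEFAULT_MIN_AA,
    require_topology: bool = True,
) -> pd.DataFrame:
    """Full screen: E-value filter, duplicate/defect removal, architecture rule.

    Candidates are the union of E-value-passing queries and proteins with
    domain annotations (merging the homology and domain-annotation routes).
    Returns a membership report with one row per candidate and reason codes.
    """
    passed = filter_hits(hits, cutoff)
    candidates = sorted(passed | set(architectures))
    kept = (
        drop_redundant({c: sequences[c] for c in candidates if c in sequences}, min_aa)
        if sequences is not None
        else None
    )
    rows = []
    for cand in candidates:
        if kept is not None and cand not in kept:
            rows.append((cand, False, "redundant_or_defective"))
            continue
        arch = architectures.get(cand)
        if arch is None:
            rows.append((cand, False, "no_domain_annotation"))
            continue
        decision = classify_membership(arch, require_topology)
        rows.append((cand, decision.accepted, ";".join(decision.reasons)))
    return pd.DataFrame(rows, columns=["protein_id", "accepted", "reasons"])
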