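"""Gap-aware codon alignments over the 61 sense codons."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .geneticcode import CODON_INDEX, CODONS, STOP_CODONS

MISSING = -1  # code for gap / ambiguous codon (treated as missing data)


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences.

    ``codons`` is an (n_sequences, n_sites) integer matrix of sense-codon
    indices; gaps and ambiguous codons are stored as ``MISSING`` and treated
    as missing data in likelihood computations. Internal stop codons are
    rejected at construction.
    """

    ids: list[str]
    codons: np.ndarray

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2:
            raise ValueError("codon matrix must be 2-D")
        if len(self.ids) != self.codons.shape[0]:
            raise ValueError("number of ids must match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")

    @property
    def n_sequences(self) -> int:
        return self.codons.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, named_seqs: list[tuple[str, str]]) -> "CodonAlignment":
        """Build from (id, nucleotide string) pairs; length must be a multiple of 3."""
        ids: list[str] = []
        rows: list[list[int]] = []
        length = None
        for name, seq in named_seqs:
            seq = seq.upper().replace("U", "T")
            if len(seq) % 3 != 0:
                raise ValueError(f"{name}: sequence length {len(seq)} not divisible by 3")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(f"{name}: aligned rows must have equal length")
            row: list[int] = []
            n_codons = len(seq) // 3
            for k in range(n_codons):
                codon = seq[3 * k : 3 * k + 3]
                if codon in STOP_CODONS:
                    if k != n_codons - 1:
                        raise ValueError(f"{name}: internal stop codon {codon} at codon {k + 1}")
                    row.append(MISSING)  # terminal stop: not part of the state space
                elif codon in CODON_INDEX:
                    row.append(CODON_INDEX[codon])
                elif set(codon) <= set("ACGT-N"):
                    row.append(MISSING)
                else:
                    raise ValueError(f"{name}: unrecognized codon {codon!r}")
            ids.append(name)
            rows.append(row)
        if not rows:
            raise ValueError("empty alignment")
        return cls(ids=ids, codons=np.array(rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls.from_sequences(records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.codons):
                seq = "".join(CODONS[c] if c >= 0 else "---" for c in row)
                fh.write(f">{name}\n{seq}\n")

    def row(self, name: str) -> np.ndarray:
        return self.codons[self.ids.index(name)]

    def sequence(self, name: str) -> str:
        return "".join(CODONS[c] if c >= 0 else "---" for c in self.row(name))

    def translate(self, name: str) -> str:
        """Amino-acid translation of one row (gaps dropped)."""
        nt = self.sequence(name).replace("---", "")
        return str(Seq(nt).translate())

    def f3x4_frequencies(self) -> np.ndarray:
        """F3x4 codon frequencies: per-position nucleotide frequencies
        multiplied and renormalized over the 61 sense codons."""
        pos_freq = np.zeros((3, 4))
        base_index = {b: i for i, b in enumerate("ACGT")}
        for row in self.codons:
            for c in row:
                if c < 0:
                    continue
                for pos, base in enumerate(CODONS[c]):
                    pos_freq[pos, base_index[base]] += 1
        if pos_freq.sum() == 0:
            raise ValueError("alignment has no unambiguous codons")
        pos_freq /= pos_freq.sum(axis=1, keepdims=True)
        # avoid exact zeros so the stationary distribution stays positive
        pos_freq = np.maximum(pos_freq, 1e-6)
        pos_freq /= pos_freq.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos_freq[0, base_index[c[0]]]
                * pos_freq[1, base_index[c[1]]]
                * pos_freq[2, base_index[c[2]]]
                for c in CODONS
            ]
        )
        return pi / pi.sum()
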