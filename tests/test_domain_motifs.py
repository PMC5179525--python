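"""LRR summaries, motif presence, information content, consensus coding."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import entropy as scipy_entropy

from lrrfam.domain_motifs import (
    EMPHASIS_BOLD,
    EMPHASIS_LOWER,
    EMPHASIS_UPPER,
    EMPHASIS_X,
    MAX_BITS,
    MotifOccurrence,
    column_bits,
    consensus_code,
    lrr_range_by_subfamily,
    motif_presence,
    render_consensus,
)
from lrrfam.family_screen import DomainArchitecture

AA = "ACDEFGHIKLMNPQRSTVWY"


def _arch(pid, n_lrr):
    lrrs = [(31 + i * 24, 31 + (i + 1) * 24 - 1) for i in range(n_lrr)]
    return DomainArchitecture(pid, lrrs, [(900, 922)], [(950, 1200)])


class TestLrrRange:
    def test_published_style_summary(self):
        archs = {f"p{i}": _arch(f"p{i}", n) for i, n in enumerate([3, 3, 3, 3, 4])}
        calls = {p: "I" for p in archs}
        row = lrr_range_by_subfamily(archs, calls).iloc[0]
        assert (row.min_lrr, row.max_lrr, row.mode_lrr) == (3, 4, "3")

    def test_single_member(self):
        out = lrr_range_by_subfamily({"p": _arch("p", 6)}, {"p": "IV"}).iloc[0]
        assert (out.min_lrr, out.max_lrr, out.mode_lrr) == (6, 6, "6")

    def test_tied_modes_all_reported(self):
        archs = {f"p{i}": _arch(f"p{i}", n) for i, n in enumerate([3, 3, 4, 4])}
        out = lrr_range_by_subfamily(archs, {p: "II" for p in archs}).iloc[0]
        assert out.mode_lrr == "3,4"

    def test_random_matches_brute_force(self, rng):
        archs = {f"p{i}": _arch(f"p{i}", int(rng.integers(1, 10))) for i in range(60)}
        calls = {p: f"S{rng.integers(4)}" for p in archs}
        table = lrr_range_by_subfamily(archs, calls).set_index("subfamily")
        groups = {}
        for p, arch in archs.items():
            groups.setdefault(calls[p], []).append(len(arch.lrr_repeats))
        for sub, values in groups.items():
            assert table.loc[sub, "min_lrr"] == min(values)
            assert table.loc[sub, "max_lrr"] == max(values)
            counts = Counter(values)
            top = max(counts.values())
            assert table.loc[sub, "mode_lrr"] == ",".join(
                str(v) for v in sorted(v for v, c in counts.items() if c == top)
            )

    def test_uncalled_protein_errors(self):
        with pytest.raises(ValueError):
            lrr_range_by_subfamily({"p": _arch("p", 3)}, {})


def _occ(pid, motif):
    return MotifOccurrence(pid, motif, 950, 964, 30.0)


class TestMotifPresence:
    def test_categories(self):
        calls = {f"p{i}": "II" for i in range(6)} | {f"q{i}": "V" for i in range(4)}
        occs = [_occ(f"p{i}", "M1") for i in range(6)]  # all of II
        occs += [_occ(f"p{i}", "M9") for i in range(4)]  # most of II
        occs += [_occ("p0", "M3")]  # some of II
        occs += [_occ(f"q{i}", "M1") for i in range(4)]
        matrix, specific = motif_presence(occs, calls)
        m = matrix.set_index(["subfamily", "motif_id"]).category
        assert m[("II", "M1")] == "all"
        assert m[("II", "M9")] == "most"
        assert m[("II", "M3")] == "some"
        assert m[("II", "M2")] == "none"
        assert "M9" in specific and "M1" not in specific

    def test_subfamily_specific_from_generator(self, family):
        occs = [
            MotifOccurrence(r.protein_id, r.motif_id, r.start, r.end, r.score)
            for r in family.motif_table.itertuples(index=False)
        ]
        _, specific = motif_presence(occs, family.truth.subfamily)
        assert "M9" in specific  # planted only in subfamily II
        assert "M1" not in specific  # core motif, everywhere

    def test_random_matches_counting_oracle(self, rng):
        calls = {f"p{i}": f"S{rng.integers(3)}" for i in range(30)}
        occs = [
            _occ(f"p{i}", f"M{rng.integers(1, 16)}")
            for i in range(30)
            for _ in range(int(rng.integers(0, 3)))
        ]
        matrix, _ = motif_presence(occs, calls)
        for row in matrix.itertuples(index=False):
            members = [p for p, s in calls.items() if s == row.subfamily]
            k = len({o.protein_id for o in occs
                     if o.motif_id == row.motif_id and o.protein_id in members})
            n = len(members)
            expected = (
                "none" if k == 0 else "all" if k == n else "most" if k / n > 0.5 else "some"
            )
            assert row.category == expected

    def test_unknown_motif_id_rejected(self):
        with pytest.raises(ValueError):
            motif_presence([_occ("p", "M99")], {"p": "I"})


class TestColumnBits:
    def test_constant_column(self):
        assert column_bits(["L"] * 12) == pytest.approx(math.log2(20))

    def test_uniform_column(self):
        assert column_bits(list(AA)) == pytest.approx(0.0, abs=1e-12)

    def test_gaps_excluded_by_default(self):
        assert column_bits(["L", "-", "L", "-"]) == pytest.approx(math.log2(20))

    def test_all_gap_errors(self):
        with pytest.raises(ValueError):
            column_bits(["-", "-"])

    def test_random_columns_match_entropy_oracle(self, rng):
        for _ in range(25):
            col = list(rng.choice(list(AA), size=int(rng.integers(2, 40))))
            counts = Counter(col)
            probs = np.array([counts[a] / len(col) for a in sorted(counts)])
            expected = math.log2(20) - scipy_entropy(probs, base=2)
            assert column_bits(col) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.sampled_from(AA), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_bounds_and_permutation_invariance(self, col):
        bits = column_bits(col)
        assert -1e-12 <= bits <= MAX_BITS + 1e-12
        assert column_bits(list(reversed(col))) == pytest.approx(bits)


class TestConsensusCode:
    @pytest.mark.parametrize(
        "bits,emphasis",
        [
            (0.0, EMPHASIS_X),
            (0.5, EMPHASIS_X),
            (0.999999, EMPHASIS_X),
            (1.0, EMPHASIS_LOWER),
            (1.9, EMPHASIS_LOWER),
            (2.0, EMPHASIS_UPPER),
            (2.999, EMPHASIS_UPPER),
            (3.0, EMPHASIS_BOLD),
            (MAX_BITS, EMPHASIS_BOLD),
        ],
    )
    def test_breakpoints(self, bits, emphasis):
        assert consensus_code("L", bits).emphasis == emphasis

    def test_monotone_sweep(self):
        order = [EMPHASIS_X, EMPHASIS_LOWER, EMPHASIS_UPPER, EMPHASIS_BOLD]
        last = -1
        for bits in np.linspace(0.0, MAX_BITS, 200):
            idx = order.index(consensus_code("A", bits).emphasis)
            assert idx >= last
            last = idx

    def test_negative_bits_rejected(self):
        with pytest.raises(ValueError):
            consensus_code("A", -0.1)

    def test_render_markup(self):
        # constant column -> bold; near-uniform -> x
        cols = [["L"] * 20, list(AA), ["K"] * 10 + ["R"] * 4 + ["E", "D"]]
        text = render_consensus(cols)
        assert text.startswith("*L*")
        assert text[3] == "x"
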