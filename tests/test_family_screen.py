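"""Membership screening: E-value filter, architecture rule, redundancy removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrfam.family_screen import (
    DomainArchitecture,
    HitRecord,
    REASON_KD_COUNT,
    REASON_NO_LRR,
    REASON_NO_TM,
    REASON_TOPOLOGY,
    classify_membership,
    drop_redundant,
    filter_hits,
    read_domain_table,
    read_hit_table,
    screen_family,
)


class TestFilterHits:
    def test_strict_inequality_at_cutoff(self):
        hits = [HitRecord("g1", "s", 1e-12), HitRecord("g2", "s", 1e-9),
                HitRecord("g3", "s", 1e-10)]
        assert filter_hits(hits, 1e-10) == {"g1"}  # 1e-10 itself is excluded

    def test_empty_table(self):
        assert filter_hits([], 1e-10) == set()

    def test_matches_exhaustive_scan(self, rng):
        hits = [
            HitRecord(f"g{rng.integers(6)}", "s", 10.0 ** -rng.uniform(0, 20))
            for _ in range(10)
        ]
        cutoff = 1e-10
        oracle = set()
        for h in hits:  # literal scan of the table
            if h.evalue < cutoff:
                oracle.add(h.query_id)
        assert filter_hits(hits, cutoff) == oracle

    @given(st.permutations(list(range(8))))
    @settings(deadline=None)
    def test_order_independent_and_idempotent(self, perm):
        base = [HitRecord(f"g{i}", "s", 10.0 ** -(i + 5)) for i in range(8)]
        shuffled = [base[i] for i in perm]
        result = filter_hits(shuffled, 1e-10)
        assert result == filter_hits(base, 1e-10)
        again = [h for h in base if h.query_id in result]
        assert filter_hits(again, 1e-10) == result

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            HitRecord("g", "s", -1.0)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([], 0.0)


def _arch(pid="p", lrrs=((20, 43), (50, 73), (80, 90)), tms=((200, 222),), kds=((300, 560),)):
    return DomainArchitecture(
        protein_id=pid,
        lrr_repeats=list(lrrs),
        tm_spans=list(tms),
        kinase_domains=list(kds),
    )


class TestClassifyMembership:
    def test_canonical_architecture_accepted(self):
        decision = classify_membership(_arch())
        assert decision.accepted and decision.reasons == ()

    def test_missing_tm_rejected_with_reason(self):
        decision = classify_membership(_arch(tms=()))
        assert not decision.accepted
        assert REASON_NO_TM in decision.reasons

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            ({"lrrs": ()}, REASON_NO_LRR),
            ({"kds": ()}, REASON_KD_COUNT),
            ({"kds": ((300, 400), (450, 560))}, REASON_KD_COUNT),
            ({"lrrs": ((250, 280),)}, REASON_TOPOLOGY),  # LRR after TM
            ({"kds": ((100, 150),)}, REASON_TOPOLOGY),  # KD before TM
        ],
    )
    def test_each_condition_has_its_reason(self, kwargs, reason):
        decision = classify_membership(_arch(**kwargs))
        assert not decision.accepted
        assert reason in decision.reasons

    def test_topology_rule_can_be_relaxed(self):
        arch = _arch(lrrs=((250, 280),))
        assert not classify_membership(arch).accepted
        assert classify_membership(arch, require_topology=False).accepted

    def test_random_architectures_match_condition_recheck(self, rng):
        for k in range(50):
            n_lrr = int(rng.integers(0, 4))
            n_tm = int(rng.integers(0, 3))
            n_kd = int(rng.integers(0, 3))
            pos = 1
            lrrs = []
            for _ in range(n_lrr):
                lrrs.append((pos, pos + 20))
                pos += 25
            pos = int(rng.integers(pos, pos + 100))
            tms = []
            for _ in range(n_tm):
                tms.append((pos, pos + 22))
                pos += 30
            kds = []
            for _ in range(n_kd):
                start = int(rng.integers(pos, pos + 50)) + (
                    -pos + 5 if rng.random() < 0.2 and pos > 10 else 0
                )
                start = max(1, start)
                kds.append((start, start + 200))
                pos = start + 210
            try:
                arch = DomainArchitecture(f"r{k}", lrrs, tms, sorted(kds))
            except ValueError:
                continue
            decision = classify_membership(arch)
            # literal re-check of the four named conditions
            ok = bool(arch.lrr_repeats) and bool(arch.tm_spans) and len(arch.kinase_domains) == 1
            if ok:
                first_tm = arch.tm_spans[0][0]
                last_tm = max(e for _, e in arch.tm_spans)
                ok = all(e < first_tm for _, e in arch.lrr_repeats) and (
                    arch.kinase_domains[0][0] > last_tm
                )
            assert decision.accepted == ok
            if not decision.accepted:
                assert decision.reasons

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            DomainArchitecture("p", [(10, 5)], [], [])
        with pytest.raises(ValueError):
            DomainArchitecture("p", [(10, 30), (20, 40)], [], [])


class TestDropRedundant:
    def test_exact_duplicate_keeps_smallest_id(self):
        seqs = {"B": "M" * 120, "A": "M" * 120, "C": "ML" * 60}
        kept = drop_redundant(seqs)
        assert set(kept) == {"A", "C"}

    def test_internal_stop_removed(self):
        kept = drop_redundant({"a": "MKV*" + "A" * 120, "b": "M" * 120})
        assert set(kept) == {"b"}

    def test_terminal_stop_tolerated(self):
        kept = drop_redundant({"a": "M" * 120 + "*"})
        assert set(kept) == {"a"}

    def test_short_sequences_are_defective(self):
        assert drop_redundant({"a": "MKV"}, min_aa=100) == {}
        assert set(drop_redundant({"a": "MKV"}, min_aa=3)) == {"a"}

    def test_empty_input(self):
        assert drop_redundant({}) == {}

    def test_random_with_planted_duplicates_matches_hash_oracle(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        pool = ["".join(rng.choice(alphabet, 120)) for _ in range(40)]
        seqs = {f"s{i:03d}": pool[int(rng.integers(len(pool)))] for i in range(100)}
        kept = drop_redundant(seqs)
        groups = {}
        for name in seqs:  # oracle: group by sequence hash, keep min id
            groups.setdefault(hash(seqs[name]), []).append(name)
        oracle = {min(names) for names in groups.values()}
        assert set(kept) == oracle
        assert len(set(kept.values())) == len(kept)  # pairwise distinct


class TestTables:
    def test_hit_table_roundtrip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("query_id\tsubject_id\tevalue\ng1\ts\t1e-12\ng2\ts\t2e-9\n")
        records = read_hit_table(p)
        assert filter_hits(records, 1e-10) == {"g1"}

    def test_blast_outfmt6(self, tmp_path):
        p = tmp_path / "hits.tsv"
        row = ["g1", "s", "98.0", "200", "1", "0", "1", "200", "5", "204", "3e-50", "400"]
        p.write_text("\t".join(row) + "\n")
        records = read_hit_table(p, blast_outfmt6=True)
        assert records[0].evalue == pytest.approx(3e-50)

    def test_malformed_row_reported_with_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("query_id\tsubject_id\tevalue\ng1\ts\tnot_a_number\n")
        with pytest.raises(ValueError, match="row 2"):
            read_hit_table(p)

    def test_domain_table_and_full_screen(self, tmp_path):
        p = tmp_path / "domains.tsv"
        p.write_text(
            "protein_id\tdomain_name\tstart\tend\n"
            "good\tLRR\t20\t43\ngood\tTM\t200\t222\ngood\tKD\t300\t560\n"
            "good\tMalectin\t100\t180\n"
            "no_tm\tLRR\t20\t43\nno_tm\tKD\t300\t560\n"
        )
        archs = read_domain_table(p)
        assert [name for name, _ in archs["good"].extra_domains] == ["Malectin"]
        hits = [HitRecord("good", "s", 1e-30), HitRecord("no_tm", "s", 1e-30)]
        report = screen_family(hits, archs)
        by_id = report.set_index("protein_id")
        assert bool(by_id.loc["good", "accepted"])
        assert not bool(by_id.loc["no_tm", "accepted"])


def test_screen_recovers_planted_family(family):
    """End-to-end screen on generator output: exactly the family genes pass."""
    hits = [
        HitRecord(r.query_id, r.subject_id, r.evalue)
        for r in family.hit_table.itertuples(index=False)
    ]
    report = screen_family(hits, family.architectures, sequences=family.proteins)
    accepted = set(report[report.accepted].protein_id)
    assert accepted == set(family.truth.subfamily)
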