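"""Screen candidate proteins for LRR-RLK family membership.

Builds a tiny homology-hit table and domain-annotation set, then applies
the three-part architecture rule (LRRs -> TM -> exactly one kinase domain)
after the E-value filter. The report lists one row per candidate with a
reason code for every rejection.
"""

from lrrfam.family_screen import DomainArchitecture, HitRecord, screen_family

hits = [
    HitRecord("candidate_ok", "AthKD_query", 3e-45),
    HitRecord("candidate_no_tm", "AthKD_query", 1e-30),
    HitRecord("candidate_weak_hit", "AthKD_query", 5e-9),  # fails the 1e-10 cutoff
]

architectures = {
    "candidate_ok": DomainArchitecture(
        "candidate_ok",
        lrr_repeats=[(31, 54), (55, 78), (79, 102)],
        tm_spans=[(200, 222)],
        kinase_domains=[(260, 549)],
    ),
    "candidate_no_tm": DomainArchitecture(
        "candidate_no_tm",
        lrr_repeats=[(31, 54)],
        tm_spans=[],
        kinase_domains=[(260, 549)],
    ),
}

report = screen_family(hits, architectures)
print(report.to_string(index=False))
# 'accepted' is True only for the complete receptor-kinase architecture;
# candidate_no_tm is rejected with reason no_TM, and the weak hit never
# reaches the architecture check (E-value 5e-9 is above the 1e-10 cutoff).
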