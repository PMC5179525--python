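"""Codon rate matrices, pruning likelihoods, and the alignment simulator."""

import numpy as np
import pytest

from lrrfam.selection import (
    CodonAlignment,
    SiteModelSpec,
    TreeIndex,
    build_class_matrices,
    build_rate_matrix,
    discretize_beta,
    equal_frequencies,
    random_tree,
    simulate_alignment,
    site_likelihoods,
)
from lrrfam.selection.geneticcode import (
    AMINO_ACIDS,
    CODONS,
    IS_NONSYNONYMOUS,
    N_CODONS,
    SINGLE_DIFF,
)
from lrrfam.selection.ratematrix import SpectralMatrix


def _random_pi(rng):
    pi = rng.dirichlet(np.full(N_CODONS, 5.0))
    return pi / pi.sum()


class TestRateMatrix:
    def test_symmetric_neutral_case(self):
        q = build_rate_matrix(1.0, 1.0, equal_frequencies())
        off = q[SINGLE_DIFF]
        assert np.allclose(off, off[0])  # all single-step rates equal

    def test_omega_zero_kills_nonsynonymous(self):
        q = build_rate_matrix(2.0, 0.0, equal_frequencies())
        assert np.all(q[IS_NONSYNONYMOUS & SINGLE_DIFF] == 0)
        assert np.any(q[~IS_NONSYNONYMOUS & SINGLE_DIFF] > 0)

    def test_rows_sum_to_zero_and_unit_rate(self, rng):
        pi = _random_pi(rng)
        q = build_rate_matrix(3.0, 0.4, pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        assert -float(pi @ np.diag(q)) == pytest.approx(1.0)

    def test_detailed_balance(self, rng):
        for _ in range(5):
            pi = _random_pi(rng)
            kappa = float(rng.uniform(0.5, 8))
            omega = float(rng.uniform(0.01, 3))
            q = build_rate_matrix(kappa, omega, pi)
            flux = pi[:, None] * q
            assert np.abs(flux - flux.T).max() < 1e-12

    def test_unnormalized_pi_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.5, np.full(N_CODONS, 1.0))

    def test_mixture_scaling_is_shared(self):
        pi = equal_frequencies()
        qs = build_class_matrices(2.0, [0.1, 1.0, 4.0], [0.5, 0.3, 0.2], pi)
        rates = np.array([-float(pi @ np.diag(q)) for q in qs])
        assert np.array([0.5, 0.3, 0.2]) @ rates == pytest.approx(1.0)
        # classes are NOT individually unit-rate
        assert not np.allclose(rates, 1.0)


class TestTransitionMatrices:
    def test_rows_stochastic(self, rng):
        pi = _random_pi(rng)
        sp = SpectralMatrix.from_rate_matrix(build_rate_matrix(2.0, 0.5, pi), pi)
        for t in [0.0, 0.01, 0.3, 2.0]:
            p = sp.transition_matrix(t)
            assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-10
            assert p.min() >= 0

    def test_long_time_limit_is_stationary(self, rng):
        pi = _random_pi(rng)
        sp = SpectralMatrix.from_rate_matrix(build_rate_matrix(2.0, 0.5, pi), pi)
        p = sp.transition_matrix(500.0)
        assert np.abs(p - pi[None, :]).max() < 1e-8

    def test_negative_time_rejected(self):
        pi = equal_frequencies()
        sp = SpectralMatrix.from_rate_matrix(build_rate_matrix(2.0, 0.5, pi), pi)
        with pytest.raises(ValueError):
            sp.transition_matrix(-0.1)


def _brute_force_lnl_2taxon(aln, t1, t2, kappa, omega, pi):
    q = build_rate_matrix(kappa, omega, pi)
    sp = SpectralMatrix.from_rate_matrix(q, pi)
    p1, p2 = sp.transition_matrix(t1), sp.transition_matrix(t2)
    total = 0.0
    for s in range(aln.n_sites):
        i, j = aln.codons[0, s], aln.codons[1, s]
        total += np.log(sum(pi[r] * p1[r, i] * p2[r, j] for r in range(N_CODONS)))
    return total


def _brute_force_lnl_3taxon(aln, lengths, kappa, omega, pi):
    # tree ((a:t1,b:t2):t3,c:t4); enumerate root and internal states
    t1, t2, t3, t4 = lengths
    sp = SpectralMatrix.from_rate_matrix(build_rate_matrix(kappa, omega, pi), pi)
    p1, p2, p3, p4 = (sp.transition_matrix(t) for t in (t1, t2, t3, t4))
    total = 0.0
    for s in range(aln.n_sites):
        a, b, c = aln.codons[:, s]
        site = 0.0
        for root in range(N_CODONS):
            inner = 0.0
            for anc in range(N_CODONS):
                inner += p3[root, anc] * p1[anc, a] * p2[anc, b]
            site += pi[root] * inner * p4[root, c]
        total += np.log(site)
    return total


class TestPruningAgainstEnumeration:
    def test_two_taxon(self, rng):
        pi = equal_frequencies()
        aln, _ = simulate_alignment("(a:0.3,b:0.1);", 2.0, [0.5], [1.0], 20, rng)
        _, _, lnl = site_likelihoods(
            aln, "(a:0.3,b:0.1);", 2.0, np.array([0.5]), np.array([1.0]), pi
        )
        expected = _brute_force_lnl_2taxon(aln, 0.3, 0.1, 2.0, 0.5, pi)
        assert abs(lnl - expected) < 1e-10

    def test_three_taxon(self, rng):
        pi = equal_frequencies()
        nwk = "((a:0.2,b:0.15):0.1,c:0.3);"
        aln, _ = simulate_alignment(nwk, 2.5, [0.8], [1.0], 10, rng)
        _, _, lnl = site_likelihoods(
            aln, nwk, 2.5, np.array([0.8]), np.array([1.0]), pi
        )
        expected = _brute_force_lnl_3taxon(aln, (0.2, 0.15, 0.1, 0.3), 2.5, 0.8, pi)
        assert abs(lnl - expected) < 1e-10

    def test_zero_branches_identical_sequences(self):
        pi = equal_frequencies()
        row = np.arange(10)
        aln = CodonAlignment(ids=["a", "b"], codons=np.stack([row, row]))
        _, site_log, lnl = site_likelihoods(
            aln, "(a:0.0,b:0.0);", 2.0, np.array([0.5]), np.array([1.0]), pi
        )
        assert np.allclose(site_log, np.log(pi[row]))

    def test_degenerate_mixture_equals_single_class(self, rng):
        pi = equal_frequencies()
        nwk = "((a:0.2,b:0.15):0.1,c:0.3);"
        aln, _ = simulate_alignment(nwk, 2.0, [0.4], [1.0], 30, rng)
        _, _, single = site_likelihoods(aln, nwk, 2.0, np.array([0.4]), np.array([1.0]), pi)
        _, _, mixture = site_likelihoods(
            aln, nwk, 2.0, np.array([0.4, 0.4, 0.4]), np.array([0.5, 0.3, 0.2]), pi
        )
        assert mixture == pytest.approx(single, abs=1e-9)

    def test_gaps_are_missing_data(self, rng):
        pi = equal_frequencies()
        aln, _ = simulate_alignment("(a:0.2,b:0.2);", 2.0, [0.5], [1.0], 8, rng)
        gapped = CodonAlignment(
            ids=aln.ids, codons=np.where([[False] * 8, [True] * 8], -1, aln.codons)
        )
        # with one row all-missing, each site's likelihood is the stationary
        # probability of the remaining observed codon
        _, site_log, _ = site_likelihoods(
            gapped, "(a:0.2,b:0.2);", 2.0, np.array([0.5]), np.array([1.0]), pi
        )
        assert np.allclose(site_log, np.log(pi[aln.codons[0]]))


class TestAlignmentContainer:
    def test_fasta_roundtrip(self, tmp_path, rng):
        aln, _ = simulate_alignment("(a:0.2,b:0.2);", 2.0, [0.5], [1.0], 15, rng)
        p = tmp_path / "aln.fna"
        aln.to_fasta(p)
        back = CodonAlignment.from_fasta(p)
        assert back.ids == aln.ids
        assert np.array_equal(back.codons, aln.codons)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment.from_sequences([("a", "ATGTAAATG")])

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CodonAlignment.from_sequences([("a", "ATGC")])

    def test_gap_codon_is_missing(self):
        aln = CodonAlignment.from_sequences([("a", "ATG---AAA")])
        assert aln.codons[0, 1] == -1

    def test_f3x4_matches_position_frequencies(self):
        aln = CodonAlignment.from_sequences([("a", "ATGATGAAA"), ("b", "ATGAAAAAA")])
        pi = aln.f3x4_frequencies()
        assert pi.sum() == pytest.approx(1.0)
        assert pi.min() > 0
        # A dominates first positions, so A-starting codons outweigh G-starting
        a_mass = sum(pi[i] for i, c in enumerate(CODONS) if c[0] == "A")
        g_mass = sum(pi[i] for i, c in enumerate(CODONS) if c[0] == "G")
        assert a_mass > g_mass


class TestSimulator:
    def test_omega_zero_never_changes_amino_acid(self, rng):
        nwk = random_tree(6, rng, total_length=3.0)
        aln, _ = simulate_alignment(nwk, 2.0, [0.0], [1.0], 120, rng)
        translations = {aln.translate(name) for name in aln.ids}
        assert len(translations) == 1

    def test_deterministic_given_seed(self):
        nwk = "((a:0.2,b:0.15):0.1,c:0.3);"
        a1, l1 = simulate_alignment(nwk, 2.0, [0.2, 1.5], [0.7, 0.3], 50, 99)
        a2, l2 = simulate_alignment(nwk, 2.0, [0.2, 1.5], [0.7, 0.3], 50, 99)
        assert np.array_equal(a1.codons, a2.codons)
        assert np.array_equal(l1, l2)

    def test_stationary_frequencies_on_long_branches(self, rng):
        aln, _ = simulate_alignment("(a:60.0,b:60.0);", 2.0, [1.0], [1.0], 4000, rng)
        freqs = np.bincount(aln.codons.ravel(), minlength=N_CODONS) / aln.codons.size
        # total-variation distance to the uniform stationary distribution
        assert 0.5 * np.abs(freqs - equal_frequencies()).sum() < 0.05

    def test_transition_bias_tracks_kappa(self, rng):
        def ts_fraction(kappa, seed):
            aln, _ = simulate_alignment("(a:0.15,b:0.15);", kappa, [1.0], [1.0], 3000,
                                        np.random.default_rng(seed))
            ts = tv = 0
            from lrrfam.selection.geneticcode import IS_TRANSITION
            for i, j in zip(aln.codons[0], aln.codons[1]):
                if i != j and SINGLE_DIFF[i, j]:
                    if IS_TRANSITION[i, j]:
                        ts += 1
                    else:
                        tv += 1
            return ts / max(tv, 1)

        assert ts_fraction(8.0, 5) > 2.5 * ts_fraction(1.0, 5)

    def test_class_labels_match_proportions(self, rng):
        _, labels = simulate_alignment(
            "(a:0.1,b:0.1);", 2.0, [0.1, 1.0], [0.8, 0.2], 5000, rng
        )
        assert np.mean(labels == 0) == pytest.approx(0.8, abs=0.03)


class TestBetaDiscretization:
    @pytest.mark.parametrize("p,q", [(0.5, 1.5), (2.0, 2.0), (0.2, 0.3)])
    def test_category_means_reproduce_beta_mean(self, p, q):
        ncat = 10
        omegas = discretize_beta(p, q, ncat)
        assert np.all((omegas >= 0) & (omegas <= 1))
        assert np.all(np.diff(omegas) >= 0)
        # equal-probability categories: the average of the category means is
        # the distribution mean, exactly
        assert omegas.mean() == pytest.approx(p / (p + q), abs=1e-9)

    def test_spec_class_distribution_m8(self):
        spec = SiteModelSpec("M8", codon_freq="equal")
        omegas, props = spec.class_distribution(
            {"kappa": 2.0, "p": 0.5, "q": 1.5, "p0": 0.9, "omega_s": 2.5}
        )
        assert len(omegas) == 11
        assert props.sum() == pytest.approx(1.0)
        assert props[-1] == pytest.approx(0.1)
        assert omegas[-1] == 2.5
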