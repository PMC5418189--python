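"""Likelihood core: rate matrices, transition kernels, class mixture, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgscan.alignment import CodonAlignment
from psgscan.codon_model import (
    BranchSiteLikelihood,
    BranchSiteParams,
    branch_site_class_mixture,
    build_codon_rate_matrix,
    codon_frequencies,
    stationary_rate,
    transition_probabilities,
)
from psgscan.fit import lrt_pvalue
from psgscan.phylo import Tree

from conftest import brute_force_loglik


def _uniform_pi(space):
    return np.full(space.n_states, 1.0 / space.n_states)


class TestRateMatrix:
    def test_dimension_and_zero_row_sums(self, space):
        Q = build_codon_rate_matrix(2.0, 0.5, _uniform_pi(space), space)
        assert Q.shape == (61, 61)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_neutral_uniform_rates_equal_by_enumeration(self, space):
        """kappa=1, omega=1, uniform pi: every single-step rate is equal,
        verified against direct enumeration of the codon neighbor graph."""
        Q = build_codon_rate_matrix(1.0, 1.0, _uniform_pi(space), space, normalize=False)
        offdiag = Q[space.single_step]
        assert offdiag.size > 0
        assert np.allclose(offdiag, offdiag[0])
        # neighbor graph: rate must be zero iff codons differ at != 1 position
        for i in (0, 17, 42):
            for j in range(space.n_states):
                ndiff = sum(a != b for a, b in zip(space.codons[i], space.codons[j]))
                assert (Q[i, j] != 0) == (ndiff == 1) or i == j

    def test_multi_nucleotide_changes_forbidden(self, space):
        Q = build_codon_rate_matrix(3.0, 2.0, _uniform_pi(space), space)
        assert np.all(Q[~space.single_step & ~np.eye(61, dtype=bool)] == 0)

    def test_normalized_rate_is_one(self, space):
        pi = np.random.default_rng(0).dirichlet(np.ones(61))
        Q = build_codon_rate_matrix(2.5, 0.3, pi, space, normalize=True)
        assert stationary_rate(Q, pi) == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self, space):
        with pytest.raises(ValueError):
            build_codon_rate_matrix(-1.0, 0.5, _uniform_pi(space), space)
        with pytest.raises(ValueError):
            build_codon_rate_matrix(2.0, -0.1, _uniform_pi(space), space)


class TestTransitionProbabilities:
    def test_zero_time_identity(self, space):
        Q = build_codon_rate_matrix(2.0, 0.5, _uniform_pi(space), space)
        P = transition_probabilities(Q, 0.0)
        assert np.allclose(P, np.eye(61), atol=1e-12)

    def test_stochastic_and_matches_expm(self, space):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61))
        Q = build_codon_rate_matrix(1.7, 0.4, pi, space)
        P = transition_probabilities(Q, 0.5, pi=pi)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0)
        from scipy.linalg import expm

        assert np.allclose(P, expm(Q * 0.5), atol=1e-10)

    def test_detailed_balance(self, space):
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(61))
        Q = build_codon_rate_matrix(2.0, 0.7, pi, space)
        P = transition_probabilities(Q, 0.3, pi=pi)
        flux = pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_negative_time_rejected(self, space):
        Q = build_codon_rate_matrix(2.0, 0.5, _uniform_pi(space), space)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


class TestClassMixture:
    def test_no_class_two_when_weights_fill_simplex(self):
        assert branch_site_class_mixture(0.6, 0.4) == pytest.approx((0.6, 0.4, 0.0, 0.0))

    def test_worked_example(self):
        p0, p1, p2a, p2b = branch_site_class_mixture(0.5, 0.25)
        assert p2a == pytest.approx(1 / 6)
        assert p2b == pytest.approx(1 / 12)

    @given(st.floats(0.01, 0.98), st.floats(0.01, 0.98))
    @settings(max_examples=50, derandomize=True)
    def test_weights_sum_to_one(self, p0, p1):
        total = p0 + p1
        if total > 1:
            p0, p1 = p0 / total, p1 / total
        assert sum(branch_site_class_mixture(p0, p1)) == pytest.approx(1.0, abs=1e-14)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            branch_site_class_mixture(0.0, 0.0)


class TestPruningLikelihood:
    def _params(self, engine, lengths=None, **kw):
        defaults = dict(kappa=2.0, omega0=0.3, omega2=4.0, p0=0.5, p1=0.3)
        defaults.update(kw)
        return BranchSiteParams(
            branch_lengths=lengths if lengths is not None else engine.initial_branch_lengths,
            pi=engine.pi,
            **defaults,
        )

    def test_single_taxon_is_log_stationary(self, space):
        aln = CodonAlignment.from_sequences([("A", "ATGAAACCC")])
        tree = Tree.parse("A;")
        pi = np.random.default_rng(3).dirichlet(np.ones(61))
        eng = BranchSiteLikelihood(aln, tree, pi=pi)
        params = self._params(eng, lengths=np.array([]))
        expected = sum(np.log(pi[c]) for c in aln.codes[0])
        assert eng.log_likelihood(params) == pytest.approx(expected, abs=1e-10)

    def test_three_taxon_star_matches_enumeration(self, space):
        tree = Tree.parse("(A #1:0.3,B:0.2,C:0.4);")
        aln = CodonAlignment.from_sequences([("A", "ATGAAA"), ("B", "ATGCCC"), ("C", "ATGAAG")])
        pi = _uniform_pi(space)
        eng = BranchSiteLikelihood(aln, tree, pi=pi)
        params = self._params(eng)
        assert eng.log_likelihood(params) == pytest.approx(
            brute_force_loglik(aln, tree, params), abs=1e-8
        )

    def test_duplicated_columns_double_loglik(self, space):
        tree = Tree.parse("(A:0.1,B:0.2,(C:0.1,D:0.1) #1:0.15);")
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 61, size=(4, 20))
        aln = CodonAlignment(list("ABCD"), codes)
        dup = CodonAlignment(list("ABCD"), np.hstack([codes, codes]))
        eng1 = BranchSiteLikelihood(aln, tree)
        eng2 = BranchSiteLikelihood(dup, tree, pi=eng1.pi)
        p1 = self._params(eng1)
        p2 = self._params(eng2)
        assert eng2.log_likelihood(p2) == pytest.approx(2 * eng1.log_likelihood(p1), rel=1e-12)

    def test_taxon_order_invariance(self, space):
        tree = Tree.parse("(A:0.1,B:0.2,(C:0.1,D:0.1) #1:0.15);")
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 61, size=(4, 30))
        codes[2, 5] = -1  # missing data must not break the invariance
        aln = CodonAlignment(list("ABCD"), codes)
        perm = [2, 0, 3, 1]
        aln_p = CodonAlignment([aln.taxa[i] for i in perm], codes[perm])
        e1 = BranchSiteLikelihood(aln, tree)
        e2 = BranchSiteLikelihood(aln_p, tree, pi=e1.pi)
        assert e1.log_likelihood(self._params(e1)) == pytest.approx(
            e2.log_likelihood(self._params(e2)), rel=1e-12
        )

    def test_gaps_are_missing_data(self, space):
        """An all-gap column contributes zero to the log-likelihood."""
        tree = Tree.parse("(A:0.1,B:0.2,C:0.3 #1);")
        base = CodonAlignment.from_sequences([("A", "ATG"), ("B", "ACG"), ("C", "ATT")])
        gapped = CodonAlignment.from_sequences(
            [("A", "ATG---"), ("B", "ACG---"), ("C", "ATT---")]
        )
        e1 = BranchSiteLikelihood(base, tree)
        e2 = BranchSiteLikelihood(gapped, tree, pi=e1.pi)
        assert e1.log_likelihood(self._params(e1)) == pytest.approx(
            e2.log_likelihood(self._params(e2)), rel=1e-12
        )

    def test_missing_taxon_rejected(self, space):
        tree = Tree.parse("(A:0.1,B:0.2,C:0.3 #1);")
        aln = CodonAlignment.from_sequences([("A", "ATG"), ("Z", "ACG")])
        with pytest.raises(ValueError):
            BranchSiteLikelihood(aln, tree)


class TestCodonFrequencies:
    def test_f3x4_sums_to_one_and_positive(self):
        aln = CodonAlignment.from_sequences([("A", "ATGAAACCCGGG"), ("B", "ATGAAGCCAGGC")])
        for mode in ("f3x4", "f1x4", "uniform"):
            pi = codon_frequencies(aln, mode)
            assert pi.sum() == pytest.approx(1.0)
            assert np.all(pi > 0)

    def test_uniform_mode(self):
        aln = CodonAlignment.from_sequences([("A", "ATG")])
        assert np.allclose(codon_frequencies(aln, "uniform"), 1 / 61)


class TestLRTPvalue:
    def test_equal_likelihoods_give_one(self):
        assert lrt_pvalue(-100.0, -100.0) == 1.0

    def test_alpha_point_of_chi2(self):
        # 2*delta = 3.841459 is the 5% point of chi-square(1)
        assert lrt_pvalue(-100.0, -100.0 - 3.841459 / 2) == pytest.approx(0.05, abs=1e-6)

    def test_negative_statistic_clamped(self):
        assert lrt_pvalue(-101.0, -100.0) == 1.0

    def test_boundary_mixture_halves_tail(self):
        p_plain = lrt_pvalue(-100.0, -102.0)
        p_mix = lrt_pvalue(-100.0, -102.0, mixture=True)
        assert p_mix == pytest.approx(p_plain / 2)
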