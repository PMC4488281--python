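"""Spectral representation, constraint regimes, and the class-M sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutopt import (
    EigenvalueConstraint,
    SpectralForm,
    StationaryDistribution,
    TransitionMatrix,
    assemble,
    detailed_balance_residual,
    draw_free_eigenvalues,
    random_pi_orthonormal_basis,
    sample_class_m,
    spectral_decompose,
    stationary_of,
    stationary_substitution_probability,
    synth_empirical_matrix,
    ts_tv_ratio,
)
from mutopt.errors import (
    DegenerateChainError,
    InfeasibleConstraintError,
    ReversibilityError,
    SamplingError,
)

from conftest import random_reversible_matrix


def power_iteration_stationary(M, iters=10_000, tol=1e-12):
    """Independent oracle: iterate the left action of the chain."""
    v = np.full(4, 0.25)
    for _ in range(iters):
        nxt = v @ M
        if np.max(np.abs(nxt - v)) < tol:
            return nxt / nxt.sum()
        v = nxt
    return v / v.sum()


class TestStationary:
    def test_uniform_matrix_gives_uniform_pi(self):
        P = TransitionMatrix(np.full((4, 4), 0.25))
        assert np.allclose(stationary_of(P).pi, 0.25, atol=1e-12)

    def test_matches_power_iteration_oracle(self):
        M = np.array([
            [0.70, 0.10, 0.15, 0.05],
            [0.20, 0.60, 0.10, 0.10],
            [0.05, 0.25, 0.55, 0.15],
            [0.10, 0.20, 0.30, 0.40],
        ])
        pi = stationary_of(TransitionMatrix(M)).pi
        assert np.allclose(pi, power_iteration_stationary(M), atol=1e-10)

    def test_assembled_matrix_returns_construction_pi(self, hky_problem):
        rng = np.random.default_rng(11)
        pi = StationaryDistribution.from_values((0.32, 0.49, 0.14, 0.06),
                                                renormalize=True)
        constraint = EigenvalueConstraint(regime="equal", lambda3=0.3, lambda4=0.1)
        P, _ = sample_class_m(pi, 0.5, constraint, rng)
        assert np.allclose(stationary_of(P).pi, pi.pi, atol=1e-8)

    def test_periodic_chain_rejected(self):
        # deterministic 4-cycle: irreducible but periodic
        M = np.roll(np.eye(4), 1, axis=1)
        with pytest.raises(DegenerateChainError):
            stationary_of(TransitionMatrix(M))

    def test_reducible_chain_rejected(self):
        M = np.zeros((4, 4))
        M[:2, :2] = 0.5
        M[2:, 2:] = 0.5
        with pytest.raises(DegenerateChainError):
            stationary_of(TransitionMatrix(M))


class TestDecomposeAssemble:
    def test_identity_has_unit_spectrum(self, uniform_pi):
        form = spectral_decompose(TransitionMatrix(np.eye(4)), uniform_pi)
        assert np.allclose(form.eigenvalues, 1.0, atol=1e-12)
        assert np.allclose(form.basis[:, 0], 1.0)

    def test_round_trip_decompose_then_assemble(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            P, pi = random_reversible_matrix(rng)
            form = spectral_decompose(P, pi)
            assert np.max(np.abs(assemble(form).entries - P.entries)) < 1e-8

    def test_round_trip_assemble_then_decompose(self, ecoli_pi):
        rng = np.random.default_rng(4)
        constraint = EigenvalueConstraint(regime="equal", lambda3=0.4, lambda4=-0.2)
        P, form = sample_class_m(ecoli_pi, 0.7, constraint, rng)
        form2 = spectral_decompose(P, ecoli_pi)
        assert np.allclose(form2.eigenvalues, form.eigenvalues, atol=1e-8)
        assert np.max(np.abs(form2.assemble_array() - P.entries)) < 1e-8

    def test_eigenvalues_match_symmetrized_oracle(self):
        rng = np.random.default_rng(5)
        P, pi = random_reversible_matrix(rng)
        # oracle: eigenvalues of the pi-symmetrized conjugate
        d = np.sqrt(pi.pi)
        S = (d[:, None] * P.entries) / d[None, :]
        oracle = np.sort(np.linalg.eigvalsh(0.5 * (S + S.T)))
        ours = np.sort(spectral_decompose(P, pi).eigenvalues)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_non_reversible_matrix_raises_with_residual(self, uniform_pi):
        M = np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.2, 0.6, 0.1, 0.1],
            [0.1, 0.1, 0.7, 0.1],
            [0.1, 0.2, 0.1, 0.6],
        ])
        with pytest.raises(ReversibilityError) as err:
            spectral_decompose(TransitionMatrix(M), uniform_pi)
        assert err.value.residual > 1e-8

    def test_rank_one_spectrum_gives_stationary_rows(self, ecoli_pi):
        basis = random_pi_orthonormal_basis(ecoli_pi, np.random.default_rng(6))
        form = SpectralForm(basis, np.array([1.0, 0.0, 0.0, 0.0]), ecoli_pi)
        P = assemble(form)
        assert np.allclose(P.entries, np.tile(ecoli_pi.pi, (4, 1)), atol=1e-12)

    def test_trace_equals_eigenvalue_sum(self, ecoli_pi):
        rng = np.random.default_rng(7)
        constraint = EigenvalueConstraint(regime="equal", lambda3=0.5, lambda4=0.2)
        P, form = sample_class_m(ecoli_pi, 0.8, constraint, rng)
        assert abs(np.trace(P.entries) - form.eigenvalues.sum()) < 1e-10


class TestRandomBasis:
    def test_columns_pi_orthonormal_over_many_draws(self, ecoli_pi):
        rng = np.random.default_rng(8)
        for _ in range(100):
            A = random_pi_orthonormal_basis(ecoli_pi, rng)
            gram = A.T @ (ecoli_pi.pi[:, None] * A)
            assert np.max(np.abs(gram - np.eye(4))) < 1e-10
            assert np.allclose(A[:, 0], 1.0)

    def test_uniform_pi_reduces_to_scaled_euclidean_orthonormality(self, uniform_pi):
        A = random_pi_orthonormal_basis(uniform_pi, np.random.default_rng(9))
        assert np.max(np.abs(A.T @ A / 4.0 - np.eye(4))) < 1e-10

    def test_different_seeds_give_different_bases(self, ecoli_pi):
        A1 = random_pi_orthonormal_basis(ecoli_pi, np.random.default_rng(1))
        A2 = random_pi_orthonormal_basis(ecoli_pi, np.random.default_rng(2))
        assert np.max(np.abs(A1 - A2)) > 1e-3


class TestFreeEigenvalues:
    def test_equal_regime_passes_through(self):
        c = EigenvalueConstraint(regime="equal", lambda3=0.3, lambda4=0.1)
        assert draw_free_eigenvalues(c, 0.9, np.random.default_rng(0)) == (0.3, 0.1)

    def test_trace_regime_preserves_sum(self):
        c = EigenvalueConstraint(regime="trace", eigenvalue_sum=0.4)
        rng = np.random.default_rng(10)
        for _ in range(1000):
            l3, l4 = draw_free_eigenvalues(c, 0.9, rng)
            assert abs(l3 + l4 - 0.4) < 1e-12
            assert abs(l3) <= 0.9 and abs(l4) <= 0.9

    def test_trace_regime_infeasible_sum(self):
        c = EigenvalueConstraint(regime="trace", eigenvalue_sum=1.5)
        with pytest.raises(InfeasibleConstraintError):
            draw_free_eigenvalues(c, 0.5, np.random.default_rng(0))

    def test_constant_regime_flux_enforced_after_assembly(self, hky_problem):
        pi, emp = hky_problem["pi"], hky_problem["empirical"]
        target = stationary_substitution_probability(emp, pi)
        c = EigenvalueConstraint.from_matrix("constant", emp, pi)
        rng = np.random.default_rng(12)
        for _ in range(20):
            P, _ = sample_class_m(pi, hky_problem["lambda2"], c, rng)
            assert abs(stationary_substitution_probability(P, pi) - target) < 1e-8


class TestSampler:
    @pytest.mark.parametrize("regime", ["equal", "trace", "constant"])
    def test_invariant_sweep(self, hky_problem, regime):
        pi, emp = hky_problem["pi"], hky_problem["empirical"]
        lam2 = hky_problem["lambda2"]
        c = EigenvalueConstraint.from_matrix(regime, emp, pi)
        rng = np.random.default_rng(13)
        for _ in range(200):
            P, form = sample_class_m(pi, lam2, c, rng)
            assert np.all(P.entries >= 0)
            assert np.max(np.abs(P.entries.sum(axis=1) - 1.0)) < 1e-10
            assert detailed_balance_residual(P, pi) < 1e-8
            assert form.eigenvalues[0] == 1.0
            if regime != "constant":
                assert abs(form.eigenvalues[1] - lam2) < 1e-8

    def test_rank_one_request_gives_stationary_rows(self, uniform_pi):
        c = EigenvalueConstraint(regime="equal", lambda3=0.0, lambda4=0.0)
        P, _ = sample_class_m(uniform_pi, 0.0, c, np.random.default_rng(14))
        assert np.allclose(P.entries, 0.25, atol=1e-10)

    def test_retry_exhaustion_raises(self, ecoli_pi):
        # lambda3 = -lambda2 with lambda2 near 1 is essentially never valid
        c = EigenvalueConstraint(regime="equal", lambda3=-0.999, lambda4=0.999)
        with pytest.raises(SamplingError):
            sample_class_m(ecoli_pi, 0.999, c, np.random.default_rng(15),
                           max_retries=50)


class TestSummaries:
    def test_all_equal_offdiagonals_give_half(self, uniform_pi):
        M = np.full((4, 4), 0.05)
        np.fill_diagonal(M, 0.85)
        assert ts_tv_ratio(TransitionMatrix(M), uniform_pi) == 0.5

    def test_zero_transitions_give_zero(self, uniform_pi):
        M = np.full((4, 4), 0.05)
        np.fill_diagonal(M, 0.0)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            M[i, j] = 0.0
        M[np.diag_indices(4)] = 1.0 - M.sum(axis=1)
        assert ts_tv_ratio(TransitionMatrix(M), uniform_pi) == 0.0

    @pytest.mark.parametrize("kappa", [1.0, 2.0, 4.0, 8.0])
    def test_hky_ratio_is_kappa_over_two(self, uniform_pi, kappa):
        P = synth_empirical_matrix(uniform_pi, kappa=kappa, mu=0.05)
        assert ts_tv_ratio(P, uniform_pi) == pytest.approx(kappa / 2.0, rel=1e-12)

    def test_zero_transversions_undefined(self, uniform_pi):
        M = np.eye(4)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            M[i, j] = 0.1
        M[np.diag_indices(4)] = 1.0 - (M.sum(axis=1) - np.diag(M))
        np.fill_diagonal(M, 0.9)
        with pytest.raises(ZeroDivisionError):
            ts_tv_ratio(TransitionMatrix(M), uniform_pi)

    def test_substitution_probability_identity_and_uniform(self, uniform_pi):
        assert stationary_substitution_probability(
            TransitionMatrix(np.eye(4)), uniform_pi) == 0.0
        rows_pi = TransitionMatrix(np.tile(uniform_pi.pi, (4, 1)))
        assert stationary_substitution_probability(rows_pi, uniform_pi) == \
            pytest.approx(0.75, abs=1e-12)

    def test_substitution_probability_brute_force(self):
        rng = np.random.default_rng(16)
        P, pi = random_reversible_matrix(rng)
        brute = sum(pi.pi[i] * (1.0 - P.entries[i, i]) for i in range(4))
        assert stationary_substitution_probability(P, pi) == pytest.approx(
            brute, abs=1e-14)


@st.composite
def stationary_vectors(draw):
    raw = draw(st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4))
    arr = np.array(raw)
    return StationaryDistribution(arr / arr.sum())


@given(pi=stationary_vectors(),
       lam2=st.floats(0.05, 0.9),
       frac3=st.floats(-1.0, 1.0), frac4=st.floats(-1.0, 1.0),
       seed=st.integers(0, 2**20))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_sampled_class_member_properties(pi, lam2, frac3, frac4, seed):
    """Any sampled class member is a valid reversible matrix with the
    requested stationary distribution and second eigenvalue."""
    c = EigenvalueConstraint(regime="equal", lambda3=frac3 * lam2,
                             lambda4=frac4 * lam2)
    rng = np.random.default_rng(seed)
    try:
        P, form = sample_class_m(pi, lam2, c, rng, max_retries=3000)
    except SamplingError:
        return  # some extreme spectra admit (almost) no valid matrix
    assert np.all(P.entries >= 0)
    assert detailed_balance_residual(P, pi) < 1e-8
    assert np.allclose(stationary_of(P).pi, pi.pi, atol=1e-8)
    assert abs(np.trace(P.entries) - form.eigenvalues.sum()) < 1e-10
    back = spectral_decompose(P, pi)
    assert np.max(np.abs(back.assemble_array() - P.entries)) < 1e-8
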