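import numpy as np
import pytest

from mutopt import (
    EigenvalueConstraint,
    GeneticCode,
    StationaryDistribution,
    TransitionMatrix,
    spectral_decompose,
    synth_empirical_matrix,
    table1_stationary,
)


@pytest.fixture(scope="session")
def code():
    return GeneticCode.standard()


@pytest.fixture
def uniform_pi():
    return StationaryDistribution(np.full(4, 0.25))


@pytest.fixture
def ecoli_pi():
    return table1_stationary("Escherichia coli", "leading")


@pytest.fixture
def hky_problem(ecoli_pi):
    """A synthetic empirical matrix plus its spectral anchors (kappa=4)."""
    emp = synth_empirical_matrix(ecoli_pi, kappa=4.0, mu=0.1)
    form = spectral_decompose(emp, ecoli_pi)
    return {
        "pi": ecoli_pi,
        "empirical": emp,
        "lambda2": float(form.eigenvalues[1]),
        "form": form,
    }


@pytest.fixture
def equal_constraint(hky_problem):
    return EigenvalueConstraint.from_matrix(
        "equal", hky_problem["empirical"], hky_problem["pi"]
    )


def random_reversible_matrix(rng, pi=None, scale=0.3):
    """Generic reversible matrix built from a symmetric exchange matrix."""
    if pi is None:
        pi = rng.dirichlet(np.ones(4) * 5)
    S = rng.uniform(0.1, 1.0, size=(4, 4))
    S = 0.5 * (S + S.T)
    M = scale * S * pi[None, :]
    np.fill_diagonal(M, 0.0)
    M[np.diag_indices(4)] = 1.0 - M.sum(axis=1)
    assert np.all(np.diag(M) > 0)
    return TransitionMatrix(M), StationaryDistribution(pi)
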