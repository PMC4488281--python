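"""Time-reversible nucleotide substitution matrices and their spectral form.

A discrete-time substitution process over the ordered alphabet (A, T, G, C)
is described by a 4x4 row-stochastic matrix P.  Every reversible P with
stationary distribution pi admits the representation

    P = A diag(lambda) A^T Pi,        Pi = diag(pi),

where the columns of A are right eigenvectors, orthonormal under the
pi-weighted inner product <u, v>_pi = sum_i pi_i u_i v_i (equivalently
A^-1 = A^T Pi), the first column is the all-ones vector with eigenvalue 1,
and the remaining eigenvalues are real with modulus at most 1.  The family
of matrices sharing a given pi and second eigenvalue (the eigenvalue that
governs the speed of convergence to stationarity) is the reference class
against which an empirical matrix is judged; its free parameters are the
three non-trivial eigenvectors and the third and fourth eigenvalues.

This module provides the representation, decomposition, constraint handling
and rejection sampling for that class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    DegenerateChainError,
    InfeasibleConstraintError,
    ReversibilityError,
    SamplingError,
)

#: Fixed nucleotide order used throughout the package.
ALPHABET: tuple[str, ...] = ("A", "T", "G", "C")
NUC_INDEX = {n: i for i, n in enumerate(ALPHABET)}

#: Index pairs (i, j) of the four transition substitutions A<->G, T<->C.
TRANSITION_PAIRS = ((0, 2), (2, 0), (1, 3), (3, 1))
#: The eight transversion index pairs (all other off-diagonal pairs).
TRANSVERSION_PAIRS = tuple(
    (i, j)
    for i in range(4)
    for j in range(4)
    if i != j and (i, j) not in TRANSITION_PAIRS
)

_ROW_SUM_TOL = 1e-10
_DETAILED_BALANCE_TOL = 1e-8
_NEGATIVE_CLAMP = 1e-12


def _as_vec4(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected a length-4 vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class StationaryDistribution:
    """Probability vector (pi_A, pi_T, pi_G, pi_C) invariant under the chain."""

    pi: np.ndarray

    def __post_init__(self):
        arr = _as_vec4(self.pi)
        if np.any(arr <= 0):
            raise ValueError("stationary distribution entries must be > 0")
        if abs(arr.sum() - 1.0) > _ROW_SUM_TOL:
            raise ValueError(f"stationary distribution sums to {arr.sum()!r}, not 1")
        object.__setattr__(self, "pi", arr)

    @classmethod
    def from_values(cls, values, renormalize: bool = False) -> "StationaryDistribution":
        arr = _as_vec4(values)
        if renormalize:
            arr = arr / arr.sum()
        return cls(arr)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ALPHABET, self.pi.tolist()))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 nucleotide substitution probability matrix."""

    entries: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.entries, dtype=float)
        if arr.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {arr.shape}")
        # floating slack: clamp negligible negatives produced by assembly
        tiny = (arr < 0) & (arr > -_NEGATIVE_CLAMP)
        if tiny.any():
            arr = arr.copy()
            arr[tiny] = 0.0
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsum = arr.sum(axis=1)
        if np.max(np.abs(rowsum - 1.0)) > 1e-9:
            raise ValueError(f"row sums deviate from 1: {rowsum}")
        object.__setattr__(self, "entries", arr)

    def is_reversible(self, pi: StationaryDistribution, tol: float = _DETAILED_BALANCE_TOL) -> bool:
        return detailed_balance_residual(self, pi) <= tol


def detailed_balance_residual(P: TransitionMatrix, pi: StationaryDistribution) -> float:
    """Max |pi_i p_ij - pi_j p_ji| over all pairs."""
    flux = pi.pi[:, None] * P.entries
    return float(np.max(np.abs(flux - flux.T)))


@dataclass(frozen=True)
class SpectralForm:
    """Generative representation (A, lambda, pi) of a reversible matrix.

    ``basis`` columns are right eigenvectors, pi-orthonormal, first column
    all ones; ``eigenvalues`` are sorted so the leading entry is 1 and the
    rest descend in absolute value.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    pi: StationaryDistribution

    def __post_init__(self):
        A = np.asarray(self.basis, dtype=float)
        lam = _as_vec4(self.eigenvalues)
        if A.shape != (4, 4):
            raise ValueError("basis must be 4x4")
        if np.max(np.abs(A[:, 0] - 1.0)) > 1e-8:
            raise ValueError("first basis column must be the all-ones vector")
        gram = A.T @ (self.pi.pi[:, None] * A)
        if np.max(np.abs(gram - np.eye(4))) > 1e-8:
            raise ValueError("basis columns are not pi-orthonormal")
        if abs(lam[0] - 1.0) > 1e-10:
            raise ValueError("leading eigenvalue must be 1")
        if np.max(np.abs(lam)) > 1.0 + 1e-10:
            raise ValueError("eigenvalue modulus exceeds 1")
        object.__setattr__(self, "basis", A)
        object.__setattr__(self, "eigenvalues", lam)

    def assemble_array(self) -> np.ndarray:
        """Raw A diag(lambda) A^T Pi product; entries may be slightly negative."""
        A, lam, pi = self.basis, self.eigenvalues, self.pi.pi
        return (A * lam) @ (A.T * pi)


def assemble(form: SpectralForm) -> TransitionMatrix:
    """Assemble the transition matrix from its spectral form.

    Row sums are automatically 1 (the all-ones eigenvector); entries may be
    negative for an arbitrary form, in which case ``TransitionMatrix``
    validation raises -- callers sampling at random should use
    :func:`sample_class_m` which retries instead.
    """
    return TransitionMatrix(form.assemble_array())


def stationary_of(P: TransitionMatrix, tol: float = 1e-10) -> StationaryDistribution:
    """Stationary distribution: the left eigenvector of the unit eigenvalue.

    Requires the chain to be irreducible and aperiodic (some power of P is
    strictly positive); otherwise the distribution is not unique and a
    :class:`DegenerateChainError` is raised.
    """
    M = P.entries
    # regular chain test: (I + P)^4 > 0 catches reducibility; aperiodicity
    # is then checked via the subdominant eigenvalue modulus
    reach = np.linalg.matrix_power(np.eye(4) + M, 4)
    if np.any(reach <= 0):
        raise DegenerateChainError("chain is reducible")
    w, v = np.linalg.eig(M.T)
    order = np.argsort(-np.abs(w))
    if abs(np.abs(w[order[1]]) - 1.0) < 1e-12:
        raise DegenerateChainError("chain is periodic or has multiple closed classes")
    k = order[0]
    vec = np.real(v[:, k])
    vec = vec / vec.sum()
    if np.any(vec < -tol):
        raise DegenerateChainError("stationary eigenvector has negative entries")
    vec = np.clip(vec, 1e-300, None)
    return StationaryDistribution(vec / vec.sum())


def spectral_decompose(P: TransitionMatrix, pi: Optional[StationaryDistribution] = None) -> SpectralForm:
    """Decompose a reversible matrix into its pi-orthonormal spectral form.

    The decomposition conjugates P with diag(sqrt(pi)), which is symmetric
    exactly when detailed balance holds, and diagonalizes the symmetrized
    matrix; eigenvalues are therefore real.  The unit eigenvector sqrt(pi)
    is deflated explicitly so the first column of the returned basis is the
    exact all-ones vector even for degenerate spectra (e.g. the identity).
    """
    if pi is None:
        pi = stationary_of(P)
    residual = detailed_balance_residual(P, pi)
    if residual > _DETAILED_BALANCE_TOL:
        raise ReversibilityError(residual)
    sqrt_pi = np.sqrt(pi.pi)
    S = (sqrt_pi[:, None] * P.entries) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    # Householder rotation taking e1 -> sqrt_pi (a unit vector since sum pi = 1)
    e1 = np.zeros(4)
    e1[0] = 1.0
    u = sqrt_pi - e1
    nrm = np.linalg.norm(u)
    if nrm < 1e-14:
        Q = np.eye(4)
    else:
        u /= nrm
        Q = np.eye(4) - 2.0 * np.outer(u, u)  # symmetric, Q @ e1 = sqrt_pi
    Sp = Q.T @ S @ Q  # block-diagonal: Sp[0,0] ~ 1, Sp[0,1:] ~ 0
    B = 0.5 * (Sp[1:, 1:] + Sp[1:, 1:].T)
    w, V = np.linalg.eigh(B)
    order = _sort_free_eigenvalues(w)
    w, V = w[order], V[:, order]
    U = np.zeros((4, 4))
    U[0, 0] = 1.0
    U[1:, 1:] = V
    U = Q @ U
    A = U / sqrt_pi[:, None]
    A[:, 0] = 1.0  # exact: column is sqrt_pi / sqrt_pi up to rounding
    lam = np.concatenate(([1.0], np.clip(w, -1.0, 1.0)))
    return SpectralForm(basis=A, eigenvalues=lam, pi=pi)


def _sort_free_eigenvalues(w: np.ndarray) -> np.ndarray:
    """Order by |lambda| descending, ties broken by signed value descending."""
    return np.lexsort((-w, -np.abs(w)))


@dataclass(frozen=True)
class EigenvalueConstraint:
    """Constraint regime tying the free eigenvalues to an empirical matrix.

    regime ``equal``  : lambda3, lambda4 equal the empirical values.
    regime ``trace``  : lambda3 + lambda4 equals the empirical sum.
    regime ``constant``: the stationary substitution probability
    sum_i pi_i (1 - p_ii) equals the empirical value; enforced after
    assembly by jointly rescaling (lambda2, lambda3, lambda4).
    """

    regime: str
    lambda3: Optional[float] = None
    lambda4: Optional[float] = None
    eigenvalue_sum: Optional[float] = None
    stationary_flux: Optional[float] = None

    def __post_init__(self):
        if self.regime not in ("constant", "equal", "trace"):
            raise ValueError(f"unknown regime {self.regime!r}")
        need = {
            "equal": ("lambda3", "lambda4"),
            "trace": ("eigenvalue_sum",),
            "constant": ("stationary_flux",),
        }[self.regime]
        for name in need:
            val = getattr(self, name)
            if val is None or not np.isfinite(val):
                raise ValueError(f"regime {self.regime!r} requires finite {name}")

    @classmethod
    def from_matrix(cls, regime: str, P: TransitionMatrix,
                    pi: Optional[StationaryDistribution] = None) -> "EigenvalueConstraint":
        """Extract the reference quantities a regime needs from an empirical matrix."""
        if pi is None:
            pi = stationary_of(P)
        form = spectral_decompose(P, pi)
        lam = form.eigenvalues
        return cls(
            regime=regime,
            lambda3=float(lam[2]),
            lambda4=float(lam[3]),
            eigenvalue_sum=float(lam[2] + lam[3]),
            stationary_flux=stationary_substitution_probability(P, pi),
        )


def random_pi_orthonormal_basis(pi: StationaryDistribution, rng: np.random.Generator) -> np.ndarray:
    """Random basis with all-ones first column, pi-orthonormal columns.

    The three free columns are drawn i.i.d. standard normal and
    orthogonalized by pi-weighted Gram-Schmidt against the ones vector and
    each other; a near-collinear draw is rejected and redrawn internally.
    Rotational symmetry of the Gaussian makes the resulting frame uniform
    over the orthogonal group of the pi-complement of span{1}.
    """
    while True:
        cols = rng.standard_normal((4, 3))
        A = np.empty((4, 4))
        A[:, 0] = 1.0
        A[:, 1:] = cols
        ok, A = _gram_schmidt_pi(A, pi.pi)
        if ok:
            return A


def _gram_schmidt_pi(A: np.ndarray, pi: np.ndarray, min_norm: float = 1e-6):
    """pi-weighted Gram-Schmidt on the columns of A (first column fixed to 1).

    Returns (ok, Q); ok is False when a column becomes numerically collinear.
    Two orthogonalization passes keep the residual below 1e-12.
    """
    Q = A.copy()
    Q[:, 0] = 1.0
    for k in range(1, 4):
        v = Q[:, k]
        for _ in range(2):  # reorthogonalize for numerical safety
            for j in range(k):
                v = v - np.dot(pi * Q[:, j], v) * Q[:, j]
        nrm = np.sqrt(np.dot(pi * v, v))
        if nrm < min_norm:
            return False, Q
        Q[:, k] = v / nrm
    return True, Q


def draw_free_eigenvalues(constraint: EigenvalueConstraint, lambda2: float,
                          rng: np.random.Generator) -> tuple[float, float]:
    """Draw (lambda3, lambda4) under the given regime.

    Free values are restricted to [-|lambda2|, |lambda2|] so lambda2 remains
    the convergence-governing eigenvalue.  Under ``constant`` the pair is
    drawn freely here; the flux condition is enforced after assembly (see
    :func:`enforce_constant_flux`).
    """
    if abs(lambda2) > 1.0 + 1e-12:
        raise ValueError("|lambda2| must be <= 1")
    a = abs(lambda2)
    if constraint.regime == "equal":
        return float(constraint.lambda3), float(constraint.lambda4)
    if constraint.regime == "trace":
        s = float(constraint.eigenvalue_sum)
        lo, hi = max(-a, s - a), min(a, s + a)
        if lo > hi + 1e-15:
            raise InfeasibleConstraintError(
                f"eigenvalue sum {s} unattainable with |lambda| <= {a}"
            )
        l3 = float(rng.uniform(lo, hi))
        return l3, s - l3
    # constant regime
    return float(rng.uniform(-a, a)), float(rng.uniform(-a, a))


def enforce_constant_flux(form: SpectralForm, target_flux: float) -> Optional[SpectralForm]:
    """Rescale the non-unit eigenvalues so the assembled matrix has the
    target stationary substitution probability sum_i pi_i (1 - p_ii).

    Because p_ii = sum_k lambda_k A_ik^2 pi_i, the flux is affine in the
    eigenvalues:  flux = 1 - c1 - sum_{k>=2} lambda_k c_k with
    c_k = sum_i pi_i^2 A_ik^2, so a single scalar alpha applied jointly to
    (lambda2, lambda3, lambda4) matches the target exactly.  Returns None
    when the rescaled spectrum leaves [-1, 1] (caller should redraw).
    """
    A, lam, pi = form.basis, form.eigenvalues, form.pi.pi
    c = (pi**2)[:, None] * A**2  # (4, 4): contributions per state/eigenvector
    ck = c.sum(axis=0)
    denom = float(np.dot(lam[1:], ck[1:]))
    if abs(denom) < 1e-14:
        return None
    alpha = (1.0 - ck[0] - target_flux) / denom
    new_lam = lam.copy()
    new_lam[1:] *= alpha
    if np.max(np.abs(new_lam)) > 1.0:
        return None
    return SpectralForm(basis=A, eigenvalues=new_lam, pi=form.pi)


def sample_class_m(pi: StationaryDistribution, lambda2: float,
                   constraint: EigenvalueConstraint, rng: np.random.Generator,
                   max_retries: int = 10_000) -> tuple[TransitionMatrix, SpectralForm]:
    """Rejection-sample a valid matrix from the constrained reversible class.

    Each attempt draws a fresh random pi-orthonormal basis and free
    eigenvalues, applies the regime, assembles, and accepts only a
    nonnegative matrix.  The class has no closed-form acceptance region,
    so rejection is the method itself.
    """
    for attempt in range(max_retries):
        A = random_pi_orthonormal_basis(pi, rng)
        l3, l4 = draw_free_eigenvalues(constraint, lambda2, rng)
        lam = np.array([1.0, lambda2, l3, l4])
        form = SpectralForm(basis=A, eigenvalues=lam, pi=pi)
        if constraint.regime == "constant":
            form = enforce_constant_flux(form, constraint.stationary_flux)
            if form is None:
                continue
        M = form.assemble_array()
        if np.min(M) < -_NEGATIVE_CLAMP:
            continue
        return TransitionMatrix(M), form
    raise SamplingError(max_retries)


def ts_tv_ratio(P: TransitionMatrix, pi: StationaryDistribution,
                flux_weighted: bool = True) -> float:
    """Transition/transversion ratio.

    By default each substitution i->j is weighted by its stationary flux
    pi_i p_ij; with ``flux_weighted=False`` raw matrix entries are summed.
    The ratio is 1:2 = 0.5 when all twelve substitutions are equally
    probable under a uniform stationary distribution.
    """
    W = pi.pi[:, None] * P.entries if flux_weighted else P.entries
    # pairwise np.sum keeps the all-equal case exact (4x vs 8x of one value)
    ts = float(np.sum(np.array([W[i, j] for i, j in TRANSITION_PAIRS])))
    tv = float(np.sum(np.array([W[i, j] for i, j in TRANSVERSION_PAIRS])))
    if tv <= 0:
        raise ZeroDivisionError("transversion flux is zero; ratio undefined")
    return float(ts / tv)


def stationary_substitution_probability(P: TransitionMatrix,
                                        pi: StationaryDistribution) -> float:
    """Overall substitution probability at stationarity, sum_i pi_i (1 - p_ii)."""
    return float(np.dot(pi.pi, 1.0 - np.diag(P.entries)))
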