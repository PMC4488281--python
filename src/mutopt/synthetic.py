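"""Synthetic study inputs: surrogate empirical matrices and coding genes.

The analysis needs two inputs that are external in real studies: a per
genome/strand "empirical" nucleotide transition-probability matrix, and
the protein-coding genes of that strand.  This module generates realistic
stand-ins for both:

* :func:`synth_empirical_matrix` builds an HKY-style reversible matrix
  with a chosen stationary distribution and transition/transversion rate
  multiplier kappa -- real mutational spectra are transition-biased, with
  transitions observed several times more often than transversions, so
  kappa in the 3-6 range emulates a realistic pressure.
* :func:`synth_coding_genes` samples coding genes whose codon usage is the
  independence distribution pi x pi x pi conditioned on sense codons,
  recalibrated by iterative proportional fitting so that the positionwise
  nucleotide composition still matches the strand's pi.
* :func:`table1_stationary` returns the published per-genome leading and
  lagging strand stationary distributions used as realistic compositions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import MutoptError, ValidationError
from .fitness import ALL_CODONS, GeneticCode
from .spectral import (
    ALPHABET,
    NUC_INDEX,
    TRANSITION_PAIRS,
    StationaryDistribution,
    TransitionMatrix,
)

logger = logging.getLogger(__name__)

#: Published stationary distributions (A, T, G, C) per genome and strand,
#: stored exactly as printed (two decimals; some rows sum to 0.99 or 1.01
#: through rounding and are renormalized at load time).
STATIONARY_TABLE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "Borrelia burgdorferi": {
        "leading": (0.32, 0.49, 0.14, 0.06),
        "lagging": (0.49, 0.32, 0.06, 0.14),
    },
    "Chlamydia muridarum": {
        "leading": (0.24, 0.25, 0.28, 0.22),
        "lagging": (0.22, 0.23, 0.29, 0.26),
    },
    "Chlamydia trachomatis": {
        "leading": (0.23, 0.21, 0.29, 0.26),
        "lagging": (0.25, 0.25, 0.25, 0.24),
    },
    "Escherichia coli": {
        "leading": (0.25, 0.33, 0.25, 0.18),
        "lagging": (0.27, 0.31, 0.21, 0.22),
    },
    "Rickettsia species": {
        "leading": (0.30, 0.31, 0.21, 0.19),
        "lagging": (0.33, 0.27, 0.24, 0.16),
    },
    "Staphylococcus aureus": {
        "leading": (0.41, 0.39, 0.12, 0.08),
        "lagging": (0.35, 0.45, 0.09, 0.11),
    },
    "Streptococcus pyogenes": {
        "leading": (0.33, 0.42, 0.12, 0.13),
        "lagging": (0.30, 0.40, 0.09, 0.20),
    },
}


def table1_stationary(genome_name: str, strand: str) -> StationaryDistribution:
    """Stationary distribution for one of the seven study genomes.

    Values are stored as printed and renormalized to sum exactly to 1;
    the (sub-percent) rounding deviation is logged.
    """
    try:
        row = STATIONARY_TABLE[genome_name]
    except KeyError:
        raise KeyError(
            f"unknown genome {genome_name!r}; known: "
            + ", ".join(sorted(STATIONARY_TABLE))
        ) from None
    if strand not in ("leading", "lagging"):
        raise KeyError(f"strand must be 'leading' or 'lagging', got {strand!r}")
    vals = np.array(row[strand], dtype=float)
    dev = vals.sum() - 1.0
    if abs(dev) > 1e-12:
        logger.debug("renormalizing %s/%s stationary vector (printed sum off by %+.3f)",
                     genome_name, strand, dev)
    return StationaryDistribution(vals / vals.sum())


def synth_empirical_matrix(pi: StationaryDistribution, kappa: float, mu: float,
                           rng: np.random.Generator | None = None,
                           jitter: float = 0.0) -> TransitionMatrix:
    """HKY-style reversible surrogate for an unpublished empirical matrix.

    Off-diagonal entries are p_ij = mu * pi_j * (kappa for transitions,
    1 for transversions); the diagonal takes the remainder.  The matrix is
    reversible with stationary distribution pi by construction, and its
    flux-weighted transition/transversion ratio increases strictly with
    kappa.  Optional multiplicative lognormal ``jitter`` (sd on log scale)
    roughens the pattern away from exact HKY while preserving
    reversibility; it requires ``rng``.
    """
    if kappa < 0 or mu <= 0:
        raise ValidationError("kappa must be >= 0 and mu > 0")
    p = pi.pi
    rate = np.ones((4, 4))
    for i, j in TRANSITION_PAIRS:
        rate[i, j] = kappa
    if jitter > 0:
        if rng is None:
            raise ValidationError("jitter requires an rng")
        noise = np.exp(rng.normal(0.0, jitter, size=(4, 4)))
        noise = np.sqrt(noise * noise.T)  # symmetric -> keeps reversibility
        rate *= noise
    M = mu * rate * p[None, :]
    np.fill_diagonal(M, 0.0)
    diag = 1.0 - M.sum(axis=1)
    if np.any(diag < 0):
        raise ValidationError(
            f"mu={mu} too large: diagonal would reach {diag.min():.3f}"
        )
    M[np.diag_indices(4)] = diag
    return TransitionMatrix(M)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome (both strands)."""

    pi_leading: StationaryDistribution
    pi_lagging: StationaryDistribution
    kappa: float = 4.0
    mu: float = 0.1
    n_genes: int = 500
    mean_codons: float = 300.0
    sd_codons: float = 100.0
    min_codons: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.min_codons < 10:
            raise ValidationError("genes must be at least 10 codons")
        if self.n_genes < 1:
            raise ValidationError("need at least one gene per strand")


def _sense_codon_distribution(pi: np.ndarray, code: GeneticCode,
                              n_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Sense-codon distribution with positionwise base marginals equal to pi.

    Starts from the independence product pi(x) pi(y) pi(z) restricted to
    non-stop codons and rebalances per-position base weights by iterative
    proportional fitting, so that excluding the three stop codons does not
    bias the achievable composition.
    """
    sense = [c for c in ALL_CODONS if not code.is_stop(c)]
    idx = np.array([[NUC_INDEX[b] for b in c] for c in sense])  # (61, 3)
    w = np.tile(pi, (3, 1))  # per-position weights
    prob = None
    for _ in range(n_iter):
        prob = w[0, idx[:, 0]] * w[1, idx[:, 1]] * w[2, idx[:, 2]]
        prob = prob / prob.sum()
        max_gap = 0.0
        for pos in range(3):
            marg = np.bincount(idx[:, pos], weights=prob, minlength=4)
            max_gap = max(max_gap, float(np.max(np.abs(marg - pi))))
            w[pos] *= pi / marg
        if max_gap < tol:
            break
    if prob is None or np.any(~np.isfinite(prob)):
        raise MutoptError("codon-composition fitting failed for this pi")
    return prob


@dataclass(frozen=True)
class SyntheticGene:
    name: str
    strand: str
    sequence: str

    def fasta_header(self) -> str:
        return f"{self.name} strand={self.strand}"


def synth_coding_genes(spec: SyntheticGenomeSpec, strand: str,
                       rng: np.random.Generator,
                       code: GeneticCode | None = None) -> list[SyntheticGene]:
    """Sample a strand's gene set: ATG start, sense body, single terminal stop.

    Body codons are drawn i.i.d. from the composition-matched sense-codon
    distribution (stop codons excluded by construction, so no internal
    stops can occur); the terminal stop codon is drawn with probability
    proportional to the independence weight of each stop under pi.  Gene
    lengths are normal (mean, sd in codons) truncated at the minimum.
    """
    if code is None:
        code = GeneticCode.standard()
    pi = (spec.pi_leading if strand == "leading" else spec.pi_lagging).pi
    sense = [c for c in ALL_CODONS if not code.is_stop(c)]
    probs = _sense_codon_distribution(pi, code)
    stops = list(code.stop_codons)
    stop_w = np.array([
        np.prod([pi[NUC_INDEX[b]] for b in s]) for s in stops
    ])
    stop_w = stop_w / stop_w.sum()
    genes = []
    for g in range(spec.n_genes):
        n_body = max(spec.min_codons,
                     int(round(rng.normal(spec.mean_codons, spec.sd_codons))))
        body = rng.choice(len(sense), size=n_body, p=probs)
        stop = stops[rng.choice(len(stops), p=stop_w)]
        seq = "ATG" + "".join(sense[k] for k in body) + stop
        genes.append(SyntheticGene(f"{strand[:4]}_gene_{g:05d}", strand, seq))
    return genes
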