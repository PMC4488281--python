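"""Mutational-cost fitness functions on protein-coding sequences.

The fitness of a substitution matrix P with respect to a set of coding
sequences is the expected per-event burden of a single nucleotide
substitution hitting a random codon position:

    F(P) = sum_c f(c) sum_{c' in N1(c)} (1/3) p_{x y} w(c, c'),

where f(c) is the empirical frequency of sense codon c, N1(c) is the set
of codons differing from c at exactly one position, x -> y is that
nucleotide change, and the weight w is

* 1 for non-synonymous changes and 0 for synonymous ones
  (mode ``nonsynonymous_probability``), or
* the amino-acid replacement cost of the encoded change
  (mode ``amino_cost``), with sense -> stop changes costed at the
  scheme's stop cost.

Whether nonsense (sense -> stop) events count at all is controlled by
``include_stops`` in both modes.  The 1/3 factor is the uniform choice of
the mutated codon position; it is a global scale that cancels in any
normalized comparison of matrices.

Because F is linear in the entries of P, the whole double sum collapses to
a fixed 4x4 weight matrix W with F(P) = sum_ij W_ij p_ij; ``CodonFitness``
precomputes W so evaluating a matrix costs a single elementwise product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .costs import CostScheme
from .errors import ValidationError
from .spectral import ALPHABET, NUC_INDEX, TransitionMatrix

ALL_CODONS = tuple("".join(c) for c in itertools.product(ALPHABET, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid mapping; stops encoded as '*'."""

    table: dict[str, str]

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValidationError("genetic code must map exactly 64 codons")
        stops = {c for c, a in self.table.items() if a == "*"}
        if len(stops) != 3:
            raise ValidationError("expected exactly 3 stop codons")
        if len({a for a in self.table.values() if a != "*"}) != 20:
            raise ValidationError("expected 20 reachable amino acids")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard code (NCBI table 1; identical to the bacterial code
        in codon -> amino acid assignments)."""
        t = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(t.forward_table)
        for stop in t.stop_codons:
            mapping[stop] = "*"
        return cls({c: mapping[c] for c in ALL_CODONS})

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == "*"

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] == "*")


@dataclass(frozen=True)
class CodonFrequencyTable:
    """Relative frequencies of sense codons observed in a coding-sequence set."""

    frequencies: dict[str, float]
    total_codons: int

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-10:
            raise ValidationError(f"codon frequencies sum to {total!r}, not 1")
        for c, f in self.frequencies.items():
            if len(c) != 3 or any(b not in NUC_INDEX for b in c):
                raise ValidationError(f"invalid codon {c!r}")
            if f < 0:
                raise ValidationError(f"negative frequency for {c!r}")

    def get(self, codon: str) -> float:
        return self.frequencies.get(codon, 0.0)


def codon_frequencies(sequences: Iterable[str],
                      code: Optional[GeneticCode] = None) -> CodonFrequencyTable:
    """Count in-frame codons over a set of coding sequences.

    Codons containing N are skipped; stop codons (normally only terminal
    ones in well-formed genes) are excluded because fitness treats stops as
    mutation targets, never sources.  Every sequence length must be a
    multiple of 3.
    """
    if code is None:
        code = GeneticCode.standard()
    counts: dict[str, int] = {}
    total = 0
    for idx, seq in enumerate(sequences):
        s = seq.upper()
        if len(s) % 3 != 0:
            raise ValidationError(
                f"sequence #{idx} length {len(s)} is not a multiple of 3"
            )
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValidationError(f"sequence #{idx} contains invalid characters {bad}")
        for k in range(0, len(s), 3):
            codon = s[k:k + 3]
            if "N" in codon:
                continue
            if code.is_stop(codon):
                continue
            counts[codon] = counts.get(codon, 0) + 1
            total += 1
    if total == 0:
        raise ValidationError("no codons retained from input sequences")
    freqs = {c: n / total for c, n in counts.items()}
    return CodonFrequencyTable(freqs, total)


def codon_change_probability(c: str, c2: str, P: TransitionMatrix) -> float:
    """Probability that a single substitution event turns codon c into c2.

    The event picks one of the three positions uniformly and substitutes
    the nucleotide there according to P; codons differing at zero or more
    than one position therefore have probability 0.
    """
    diff = [k for k in range(3) if c[k] != c2[k]]
    if len(diff) != 1:
        return 0.0
    k = diff[0]
    return P.entries[NUC_INDEX[c[k]], NUC_INDEX[c2[k]]] / 3.0


@dataclass(frozen=True)
class FitnessSpec:
    """What a fitness evaluation measures.

    mode ``nonsynonymous_probability`` needs no scheme; mode ``amino_cost``
    weights each change by the scheme's replacement cost.  ``include_stops``
    toggles whether nonsense (sense -> stop) events contribute.
    """

    mode: str
    scheme: Optional[CostScheme] = None
    include_stops: bool = False

    def __post_init__(self):
        if self.mode not in ("nonsynonymous_probability", "amino_cost"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")
        if (self.scheme is not None) != (self.mode == "amino_cost"):
            raise ValueError("scheme must be present iff mode is amino_cost")

    def label(self) -> str:
        tag = self.scheme.name if self.scheme else "nonsyn"
        return f"{tag}{'+stops' if self.include_stops else ''}"


class CodonFitness:
    """Precompiled fitness function F(P) = sum_ij W_ij p_ij.

    The 4x4 weight matrix W accumulates, over every sense codon and every
    single-nucleotide neighbor that the spec counts, the codon frequency
    times 1/3 times the change's weight, binned by the underlying
    nucleotide substitution.  W has zero diagonal, so F(identity) = 0.
    """

    def __init__(self, freqs: CodonFrequencyTable, code: GeneticCode,
                 spec: FitnessSpec):
        if not freqs.frequencies:
            raise ValidationError("empty codon frequency table")
        self.spec = spec
        self.code = code
        W = np.zeros((4, 4))
        for codon, f in freqs.frequencies.items():
            if f == 0.0 or code.is_stop(codon):
                continue
            aa = code.translate(codon)
            for pos in range(3):
                x = NUC_INDEX[codon[pos]]
                for y, nuc in enumerate(ALPHABET):
                    if y == x:
                        continue
                    neighbor = codon[:pos] + nuc + codon[pos + 1:]
                    aa2 = code.translate(neighbor)
                    if aa2 == aa:
                        continue  # synonymous
                    if aa2 == "*":
                        if not spec.include_stops:
                            continue
                        w = spec.scheme.stop_cost if spec.scheme else 1.0
                    else:
                        w = spec.scheme.pair_cost(aa, aa2) if spec.scheme else 1.0
                    W[x, y] += f * w / 3.0
        self.weights = W

    def __call__(self, P) -> float:
        entries = P.entries if isinstance(P, TransitionMatrix) else np.asarray(P)
        return float(np.sum(self.weights * entries))


def fitness(freqs: CodonFrequencyTable, P: TransitionMatrix,
            code: GeneticCode, spec: FitnessSpec) -> float:
    """One-shot fitness evaluation (see module docstring for the model)."""
    return CodonFitness(freqs, code, spec)(P)
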