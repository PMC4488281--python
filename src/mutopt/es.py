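"""Evolutionary Strategy search for extreme-fitness matrices.

The optimizer works directly in the spectral parameterization: an
individual is a (basis, eigenvalues) pair over a fixed stationary
distribution, mutation adds Gaussian N(0, sigma) shifts to the three free
eigenvector columns and/or the free eigenvalues, re-orthonormalizes by
pi-weighted Gram-Schmidt, re-applies the eigenvalue-constraint regime and
keeps only perturbations that assemble into a valid (nonnegative)
transition matrix.  Selection each generation deletes the worse half of
the population and refills it with mutated copies of the surviving half, a
(mu + mu) scheme whose elitism makes the best-so-far fitness monotone.

Defaults follow the study conditions: population 100, sigma = 0.3,
10,000 generations (the fitness trace typically stabilizes within the
first ~500).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import MutoptError
from .fitness import CodonFitness, CodonFrequencyTable, FitnessSpec, GeneticCode
from .spectral import (
    EigenvalueConstraint,
    SpectralForm,
    StationaryDistribution,
    TransitionMatrix,
    _NEGATIVE_CLAMP,
    _gram_schmidt_pi,
    enforce_constant_flux,
    sample_class_m,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ESConfig:
    """Run parameters of the Evolutionary Strategy."""

    population_size: int = 100
    generations: int = 10_000
    sigma: float = 0.3
    direction: str = "minimize"
    seed: int = 0
    elitism: bool = True
    strict_literal: bool = False  # mutate everyone first, then select
    mutation_retries: int = 100
    sampling_retries: int = 10_000

    def __post_init__(self):
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be 'minimize' or 'maximize'")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass(frozen=True)
class Individual:
    """A candidate matrix with its spectral form and cached fitness."""

    form: SpectralForm
    matrix: TransitionMatrix
    fitness_value: float


@dataclass
class ESTrace:
    """Per-generation population fitness summary (min, mean, max)."""

    generation: list[int] = field(default_factory=list)
    min_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    max_fitness: list[float] = field(default_factory=list)

    def record(self, gen: int, values: np.ndarray) -> None:
        self.generation.append(gen)
        self.min_fitness.append(float(values.min()))
        self.mean_fitness.append(float(values.mean()))
        self.max_fitness.append(float(values.max()))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "generation": self.generation,
            "min_fitness": self.min_fitness,
            "mean_fitness": self.mean_fitness,
            "max_fitness": self.max_fitness,
        })


def _make_fitness(fitness_spec, freqs, code) -> Callable:
    if callable(fitness_spec) and freqs is None:
        return fitness_spec
    if code is None:
        code = GeneticCode.standard()
    return CodonFitness(freqs, code, fitness_spec)


def initialize_population(pi: StationaryDistribution, lambda2: float,
                          constraint: EigenvalueConstraint, config: ESConfig,
                          rng: np.random.Generator,
                          fitness_fn: Callable) -> list[Individual]:
    """Independent rejection samples from the constrained class, with fitness."""
    population = []
    for _ in range(config.population_size):
        matrix, form = sample_class_m(pi, lambda2, constraint, rng,
                                      max_retries=config.sampling_retries)
        population.append(Individual(form, matrix, float(fitness_fn(matrix))))
    return population


def mutate(ind: Individual, sigma: float, constraint: EigenvalueConstraint,
           rng: np.random.Generator, fitness_fn: Callable,
           retries: int = 100) -> Individual:
    """Gaussian perturbation of an individual, kept only if valid.

    Each attempt perturbs the basis, the free eigenvalues, or both (one of
    the three cases uniformly, so that at least one applies -- under the
    ``equal`` regime the eigenvalues are frozen and only the basis moves),
    then re-orthonormalizes and re-applies the regime.  On exhausting the
    retry budget the parent is returned unchanged.
    """
    pi = ind.form.pi
    lam_parent = ind.form.eigenvalues
    a = abs(lam_parent[1])
    for _ in range(retries):
        if constraint.regime == "equal":
            do_basis, do_eigen = True, False
        else:
            which = rng.integers(3)  # 0: basis, 1: eigenvalues, 2: both
            do_basis = which != 1
            do_eigen = which != 0
        basis = ind.form.basis.copy()
        if do_basis:
            basis[:, 1:] += rng.normal(0.0, sigma, size=(4, 3))
            ok, basis = _gram_schmidt_pi(basis, pi.pi)
            if not ok:
                continue
        lam = lam_parent.copy()
        if do_eigen:
            if constraint.regime == "trace":
                l3 = lam[2] + rng.normal(0.0, sigma)
                l4 = constraint.eigenvalue_sum - l3
                if abs(l3) > a or abs(l4) > a:
                    continue
                lam[2], lam[3] = l3, l4
            elif constraint.regime == "constant":
                l3 = lam[2] + rng.normal(0.0, sigma)
                l4 = lam[3] + rng.normal(0.0, sigma)
                if abs(l3) > a or abs(l4) > a:
                    continue
                lam[2], lam[3] = l3, l4
        form = SpectralForm(basis=basis, eigenvalues=lam, pi=pi)
        if constraint.regime == "constant":
            form = enforce_constant_flux(form, constraint.stationary_flux)
            if form is None:
                continue
        M = form.assemble_array()
        if M.min() < -_NEGATIVE_CLAMP:
            continue
        matrix = TransitionMatrix(M)
        return Individual(form, matrix, float(fitness_fn(matrix)))
    logger.debug("mutation retry budget (%d) exhausted; keeping parent", retries)
    return ind


def select(population: list[Individual], direction: str) -> list[Individual]:
    """Replace the worse half with copies of the surviving half.

    Survivors are ordered best-first; survivor k's copy fills removed slot
    k, so the returned list is [survivors..., copies...] and the best
    individual always survives.
    """
    reverse = direction == "maximize"
    ranked = sorted(population, key=lambda ind: ind.fitness_value, reverse=reverse)
    half = len(ranked) // 2
    survivors = ranked[:half]
    return survivors + list(survivors)


def run_es(pi: StationaryDistribution, lambda2: float,
           constraint: EigenvalueConstraint, fitness_spec,
           freqs: Optional[CodonFrequencyTable], config: ESConfig,
           code: Optional[GeneticCode] = None) -> tuple[Individual, ESTrace]:
    """Full ES run; returns the best individual found and the fitness trace.

    ``fitness_spec`` may be a :class:`FitnessSpec` (with ``freqs``) or any
    callable on transition matrices (with ``freqs=None``).  Deterministic
    given ``config.seed``.
    """
    fitness_fn = _make_fitness(fitness_spec, freqs, code)
    rng = np.random.default_rng(config.seed)
    sign = 1.0 if config.direction == "minimize" else -1.0
    population = initialize_population(pi, lambda2, constraint, config, rng,
                                       fitness_fn)
    best = min(population, key=lambda ind: sign * ind.fitness_value)
    trace = ESTrace()
    half = config.population_size // 2
    for gen in range(config.generations):
        if config.strict_literal:
            mutated = [mutate(ind, config.sigma, constraint, rng, fitness_fn,
                              config.mutation_retries) for ind in population]
            population = select(mutated, config.direction)
        else:
            ranked = select(population, config.direction)
            survivors = ranked[:half]
            offspring = [mutate(ind, config.sigma, constraint, rng, fitness_fn,
                                config.mutation_retries)
                         for ind in ranked[half:]]
            population = survivors + offspring
        gen_best = min(population, key=lambda ind: sign * ind.fitness_value)
        if sign * gen_best.fitness_value < sign * best.fitness_value or not config.elitism:
            best = gen_best
        values = np.array([ind.fitness_value for ind in population])
        trace.record(gen, values)
    return best, trace


def find_extremes(pi: StationaryDistribution, lambda2: float,
                  constraint: EigenvalueConstraint, fitness_spec,
                  freqs: Optional[CodonFrequencyTable], config: ESConfig,
                  code: Optional[GeneticCode] = None):
    """Minimize and maximize the fitness over the constrained class.

    Runs the ES twice with derived seeds (seed for the minimization,
    seed + 1 for the maximization) and returns
    (f_min, f_max, argmin Individual, argmax Individual).
    """
    cfg_min = replace(config, direction="minimize", seed=config.seed)
    cfg_max = replace(config, direction="maximize", seed=config.seed + 1)
    best_min, _ = run_es(pi, lambda2, constraint, fitness_spec, freqs, cfg_min, code)
    best_max, _ = run_es(pi, lambda2, constraint, fitness_spec, freqs, cfg_max, code)
    f_min, f_max = best_min.fitness_value, best_max.fitness_value
    if f_min > f_max:
        raise MutoptError(
            f"internal inconsistency: F_min {f_min} > F_max {f_max}"
        )
    return f_min, f_max, best_min, best_max
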