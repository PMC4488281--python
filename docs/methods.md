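# Methods

## The matrix class and its spectral parameterization

The object of study is a discrete-time nucleotide substitution process
over the ordered alphabet (A, T, G, C), described by a row-stochastic
matrix *P*. We restrict attention to time-reversible chains — the standard
assumption in substitution modelling, and the one that makes the spectrum
real — and parameterize them generatively:

    P = A Λ Aᵀ Π,   Π = diag(π),

with *A* π-orthonormal (A⁻¹ = Aᵀ Π), first column all ones, Λ =
diag(1, λ₂, λ₃, λ₄). Row sums are automatically 1; reversibility and the
stationary distribution π are built in. Any reversible *P* decomposes
uniquely into this form (up to eigenvector sign/ordering), which we
compute by conjugating with diag(√π): the conjugate is symmetric exactly
under detailed balance, and its eigendecomposition is performed after
explicitly deflating the known unit eigenvector √π with a Householder
rotation. The deflation matters for degenerate spectra (e.g. the identity
matrix), where a generic symmetric eigensolver would not return the ones
vector as an eigenvector.

The reference class for an empirical matrix fixes π and λ₂ (the
convergence-governing eigenvalue by the Perron–Frobenius argument) and
constrains (λ₃, λ₄) by one of three regimes:

* **equal** — λ₃, λ₄ exactly equal the empirical values;
* **trace** — λ₃ + λ₄ equals the empirical sum, λ₃ drawn uniformly in the
  feasible interval;
* **constant** — the stationary substitution probability
  s(P) = Σᵢ πᵢ(1 − pᵢᵢ) equals the empirical value. Since
  pᵢᵢ = Σₖ λₖ A²ᵢₖ πᵢ, s is affine in the eigenvalues; we draw (λ₃, λ₄)
  freely, then rescale (λ₂, λ₃, λ₄) jointly by the unique scalar matching
  the target exactly. This is one consistent reading of a regime that
  cannot fix both λ₂ and s when eigenvectors vary; the achieved λ₂ is
  recorded, and the joint rescaling preserves the eigenvalue ordering.

Free eigenvalues are restricted to [−|λ₂|, |λ₂|] so λ₂ remains second in
modulus. "Second eigenvalue" means second-largest in absolute value, ties
broken by signed value descending.

Sampling the class is by rejection: draw three standard-normal columns,
π-orthonormalize by Gram–Schmidt against the ones vector (two passes, for
numerical hygiene; near-collinear draws are redrawn), draw the free
eigenvalues, assemble, and accept only nonnegative matrices. Entries in
(−10⁻¹², 0) are clamped to zero as floating slack; anything more negative
is a rejection. There is no closed-form acceptance region — rejection *is*
the sampler — and the default retry budget is 10,000 attempts. Acceptance
is comfortable in practice for realistic spectra (hundreds of samples per
second for the equal and trace regimes; the constant regime is a few-fold
slower because the rescaled spectrum must also stay inside [−1, 1]).

## Fitness functions

The burden of a matrix on a coding-sequence set is the expected cost of a
single substitution event hitting a random codon position:

    F(P) = Σ_c f(c) Σ_{c' ∈ N₁(c)} ⅓ p_{x→y} w(c, c').

*f* is the empirical sense-codon frequency (in-frame count; codons with N
skipped; stop codons excluded — they are mutation targets, never sources).
The ⅓ is the uniform choice of mutated position within the codon. It is a
global scale: it divides out of F_norm exactly (verified by a property
test asserting invariance of F_norm under joint affine rescaling), so its
value cannot affect any normalized conclusion.

Weights *w*: 1 for non-synonymous changes in probability mode, or the
amino-acid replacement cost in cost mode; sense→stop changes are included
only when requested and always carry the scheme's maximum pairwise cost.
Whether non-synonymous probability should itself count nonsense events is
genuinely ambiguous, so both variants are exposed through the same
`include_stops` switch.

F is linear in the entries of *P*, so the 64-codon double loop collapses
to a precomputed 4×4 weight matrix with F(P) = Σ W ∘ P. The optimized path
is checked against an independent full-enumeration oracle to 10⁻¹² on 50
random draws.

### Cost schemes

Schemes are packaged as TSV fixtures in AAindex-style layout; indices
(20-vectors) become pairwise costs |vₐ − v_b|, matrices are used directly;
the stop cost is always the table maximum.

* `grantham_chemical_distance` — computed from Grantham's 1974
  composition/polarity/volume properties with his weights (α = 1.833,
  β = 0.1018, γ = 0.000399, mean pair distance normalized to 100); the
  values agree with the published integer table within rounding (±1).
* `kd_hydropathy`, `polar_requirement` — the published Kyte–Doolittle and
  Woese indices.
* `aa_pair_distance`, `empar` — **synthetic stand-ins** (so labelled in
  filename and header): the dissimilarity transform
  d(a,b) = s(aa) + s(bb) − 2s(ab) of PAM250 and BLOSUM62 respectively.
  They are proper symmetric zero-diagonal dissimilarities capturing
  empirical replaceability, used where the original matrices are cited
  only by reference number and could not be pinned to accessions.
* `unit` — all pair costs 1; under it cost-mode fitness equals the
  non-synonymous probability exactly, a consistency identity used in tests.

## The Evolutionary Strategy

Individuals are spectral forms; fitness is evaluated on the assembled
matrix. Defaults: population 100, σ = 0.3, 10,000 generations.

* **Mutation** perturbs the basis columns and/or the free eigenvalues —
  one of the three cases with probability ⅓ each, so at least one applies;
  under the equal regime only the basis can move. Perturbed bases are
  repaired by π-weighted Gram–Schmidt, the regime re-applied, and the
  result kept only if the assembled matrix is valid; up to 100 fresh
  attempts, after which the parent is retained (logged at debug level).
* **Selection** deletes the worse half and refills with copies of the
  surviving half in rank order. We mutate the copies and keep survivors
  intact — a (μ + μ) elitist scheme under which the best-so-far fitness is
  provably monotone (and is asserted per-generation in tests). A
  `strict_literal` flag instead mutates everyone before selection.
* **Reproducibility**: one `numpy` Generator seeded from the config drives
  initialization and mutation; identical configs give bit-identical
  traces. `find_extremes` runs minimization with `seed` and maximization
  with `seed + 1`.

On the synthetic study problem the population fitness stabilizes within a
few hundred generations; five independent seeds at 1,000 generations agree
on the minimum to a relative spread of ~10⁻⁶, and the range of fitness
among fresh random class members is ≥ 4 orders of magnitude wider than the
spread among converged solutions.

## Comparative analysis

F_norm = (F_emp − F_min)/(F_max − F_min) is reported exactly, including
values outside [0, 1] (the empirical matrix can beat the search).
Supporting comparisons:

* **ts/tv ratio** — stationary-flux weighted (Σ πᵢ pᵢⱼ over the four
  transition pairs divided by the eight transversion pairs); equals ½ when
  all twelve substitutions are equally likely. A raw-entry variant is
  available; both coincide at 0.5 in the uniform case.
* **PCA** of the 12 off-diagonal entries (fixed order A→T … C→G) uses the
  covariance matrix — raw matrix elements, not flux — with component signs
  fixed so the G→A loading on PC1 is nonnegative, and loadings reported as
  feature–component correlations.
* **Kruskal–Wallis** per substitution across matrix groups, tie-corrected,
  chi-square p-values; raw p-values are primary and Holm-adjusted values
  are added in a separate clearly-labelled column as an extension. The
  chi-square approximation is accurate to a few hundredths against the
  exact permutation null at very small n (the exact null is discrete in
  steps of 1/C(n, n₁)), which is the tolerance the unit test uses.
* **Rankings** use π-weighted flux ("most frequent substitutions"), ties
  broken by the fixed feature order.

`compare_genome` runs the full grid of (fitness measure × regime)
conditions with per-condition derived seeds and reports per-condition rows
plus the fractions of conditions with F_norm < 0.5 and < 0.25. The
condition grid is fully configurable and recorded in the run manifest.

## Synthetic data

The two study inputs that are external in real analyses are emulated:

* **Surrogate empirical matrices** are HKY-style: pᵢⱼ = μ πⱼ κ^{[i→j is a
  transition]}, reversible with stationary π by construction; ts/tv is
  strictly increasing in κ (κ/2 exactly under uniform π). Real mutational
  spectra are transition-biased several-fold, so the study default is
  κ = 4 with μ = 0.1 (per-event substitution probability ≈ 0.1–0.15,
  comfortably inside the valid-diagonal region for all seven published
  compositions). An optional symmetric lognormal jitter roughens the
  pattern away from exact HKY without breaking reversibility.
* **Gene sets**: ATG start, i.i.d. sense-codon body, one terminal stop.
  The body codon distribution starts from the independence product
  π×π×π restricted to sense codons and is rebalanced by iterative
  proportional fitting so the positionwise base marginals equal π to
  10⁻¹² despite the stop-codon exclusion. Default 500 genes of 300 ± 100
  codons (minimum 10) per strand, matching typical bacterial coding
  statistics at a size where codon-frequency noise is negligible.
* **Published compositions**: the seven genomes' leading/lagging-strand
  stationary vectors are stored exactly as printed (two decimals; some
  rows sum to 0.99–1.01) and renormalized at load with the deviation
  logged.

What the synthetic data does *not* emulate: real codon usage bias beyond
base composition, codon autocorrelation within genes, operonic structure,
non-HKY exchangeability structure in the empirical matrix, and
selection-filtered inference noise in empirical matrices. Consequently,
passing end-to-end tests demonstrates that the machinery recovers the
designed signal (a transition-biased pressure scores F_norm well below
0.5 against its own composition-matched genes), not that any particular
real genome does so.

## Scaled-down study sizes

The packaged end-to-end checks run the full pipeline at: 500 genes, κ = 4,
equal regime, population 100, 1,000 generations, 5 seeds (the fitness
trace stabilizes within a few hundred generations at these sizes, so
longer runs only tighten an already ~10⁻⁶ seed-to-seed spread). The
acceptance script uses 120 genes and a 150-generation search, sizes at
which the normalization anchor points and stationary-vector round trips
are already exact to well beyond the reported precision.

## Numerical choices and edge cases

* Row-sum tolerance 10⁻¹⁰ in memory, 10⁻⁶ on file input (files are
  renormalized after validation to strip printed rounding).
* Detailed-balance residual tolerance 10⁻⁸; the reversibility error
  reports the max residual.
* Assembly entries in (−10⁻¹², 0) are clamped to 0; more negative values
  reject the candidate.
* `stationary_of` requires a regular chain ((I + P)⁴ > 0 and subdominant
  modulus < 1) and raises a degenerate-chain error otherwise.
* All-identical observations in the rank test return H = 0, p = 1 rather
  than raising.
* Exact ties in rankings and tied fitness in selection resolve by fixed
  order (feature order; stable sort), keeping runs deterministic.

## Known limitations

* The constant regime does not hold λ₂ exactly fixed (see above); the
  equal and trace regimes do.
* The ES uses a fixed σ; no self-adaptation or covariance adaptation, by
  design — matching the simple fixed-σ scheme the analysis is defined
  with.
* Cost schemes `aa_pair_distance` and `empar` are synthetic stand-ins, not
  the original published matrices; conclusions that depend on a specific
  scheme's absolute scale should use the three exactly-sourced schemes.
* Complex-eigenvalue (non-reversible) chains, context-dependent mutation,
  and continuous-time rate matrices are out of scope.
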