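# Methods

## Model and optimization

`cemodule` factorizes three sample-matched non-negative expression
matrices X₁ (S×N₁, lncRNA), X₂ (S×N₂, miRNA), X₃ (S×N₃, mRNA) as
Xᵢ ≈ W Hᵢᵀ with a single shared basis W (S×K) and non-negative
coefficient matrices Hᵢ (Nᵢ×K).  The objective combines, per layer, a
Frobenius reconstruction term and an orthogonality penalty
(α/2)‖HᵢᵀHᵢ − I‖²_F; three network attraction terms
−λ₁Tr(H₂ᵀAH₁) − λ₂Tr(H₂ᵀBH₃) − λ₃Tr(H₃ᵀCH₃) rewarding co-loading of
interacting molecules; and sparsity penalties γ₁‖W‖²_F + γ₂Σ‖Hᵢ‖₁.
A and B are binary (miRNA–lncRNA, miRNA–mRNA); C is symmetric,
non-negatively weighted with zero diagonal (gene–gene).

Optimization uses the KKT-derived multiplicative updates.  One sweep
updates W, then H₁, H₂, H₃, each rule using the most recently updated
factors (Gauss–Seidel order; fixed and documented, since sweeps in
Jacobi order would change iterates but not the model).  In the H₃
numerator the gene–gene term carries coefficient λ₃ — not λ₃/2 — because
C enters the objective quadratically, so its gradient contributes a
factor 2.  The entrywise L1 penalty on the non-negative Hᵢ appears as the
constant γ₂/2 in each H denominator.

Assumptions worth keeping in mind: one shared sample basis means all
three layers are driven by the same K latent sample patterns; the
network terms assume interactions are enriched *within* modules; all
inputs must be non-negative, which the preprocessing guarantees.

## Numerical choices

- **Initialization.** All factor entries i.i.d. uniform on (0, 1]
  (strictly positive — a zero entry can never revive under multiplicative
  updates), then W is rescaled so ‖W H₁ᵀ‖_F matches ‖X₁‖_F (first
  non-empty layer).  Seeded with `numpy.random.default_rng`; identical
  seeds give bit-identical results.
- **Denominator guard.** ε = 1e-10 added to every update denominator;
  fixed points are preserved to within ε.
- **Negative numerators.** The network terms appear only in numerators
  with non-negative matrices, so numerators stay ≥ 0; this is asserted at
  run time rather than clipped, so a violation surfaces as a
  `NumericalError` instead of being masked.
- **Convergence.** |objₜ − objₜ₋₁| / max(1, |objₜ₋₁|) < tol, default
  tol = 1e-6, default cap max_iter = 500.  Reaching the cap warns rather
  than errors and sets `converged=False`.  The recovery experiments in
  the test suite and acceptance script raise the cap to 3000 so the
  solver actually reaches its tolerance: on the default planted
  conditions convergence typically needs 1500–2800 sweeps, and stopping
  at 500 leaves partially mixed factors.
- **Default weights.** α = 1, λ₁ = λ₂ = λ₃ = 0.01, γ₁ = γ₂ = 0.1.  These
  are pragmatic defaults of the expected order of magnitude, not values
  tied to any particular dataset; correctness properties (descent,
  non-negativity, fixed points) are tested across a grid of weights
  around them.

## Preprocessing

Raw expression tables (samples on rows, molecules on columns) pass
through, in order: all-zero molecule removal (miRNA layer), a variance
filter and a low-magnitude filter (lncRNA/mRNA layers, cutoffs applied to
raw values), then v → log2(v + 1) on all layers.  The percentile filters
use the linear-interpolation percentile of the per-molecule summary;
molecules strictly below the cut are removed and ties at the cut survive,
which makes a percentile of 0 an exact identity and the single-molecule
case deterministic.  "Overall magnitude" defaults to the per-molecule
mean of absolute values (`method="max"` is available).  log2(v+1) is
strictly monotone, maps 0 to 0 and guarantees the non-negativity the
factorization requires; inputs that may contain negatives (already
normalized data) can opt into a per-molecule min-shift first.
Interaction edge lists are filtered to molecules present in the layers;
duplicate binary edges collapse by OR, duplicate weighted edges by
maximum (conservative and idempotent), C is symmetrized with zero
diagonal and self-loops dropped.

## Module extraction

Within each Hᵢ, column j is standardized over molecules:
zᵢⱼ = (hᵢⱼ − μⱼ)/σⱼ with the sample standard deviation (ddof = 1,
configurable).  Molecule i joins module j iff zᵢⱼ > T, strict, with
default T = 2 (a conventional two-sigma cut).  A constant column yields
all-zero z-scores plus a warning.  Membership is intentionally
overlapping: hub molecules join many modules.  Extraction is invariant
to positive rescaling of any column and monotone in T.  The z-scores are
computed column-wise (across the molecules of one factor) rather than
row-wise; the row-wise reading of "average value of molecule i" would
standardize each molecule across factors instead, and is not
implemented.

Recovered-vs-planted comparison uses greedy maximum-Jaccard 1-1 matching
on the layer-tagged union of member sets — simple, deterministic and
adequate at K ≤ 100; an optimal assignment would only matter when many
pairings have near-equal overlap.

## Evaluation statistics

- **Correlation score.** S(Cᵥ) = mean |Pearson r| over all cross-layer
  member pairs (N = n₁n₂ + n₂n₃ + n₁n₃).  Computed from centered blocks
  with r = cov/√(ss_a·ss_b), identical to the explicit covariance
  formula down to floating point.  Members with variance < 1e-15
  contribute r = 0 with a warning; a module non-empty in fewer than two
  layers gets a flagged NaN.
- **Permutation null.** Each permutation redraws every module's members
  uniformly from the layer's full registry, without replacement within a
  slot, independently across modules and layers, preserving slot sizes.
  Per-module empirical p = (#{null ≥ observed} + 1)/(n_perm + 1) — the
  +1 correction never returns 0.  A pooled Wilcoxon rank-sum statistic
  (all observed scores vs all null scores) gives one global p; the
  per-module empirical p and the pooled global test are reported as
  distinct quantities rather than conflated.
- **Enrichment.** One-sided hypergeometric tail P(X ≥ k) for the overlap
  of a module's mRNA members with each gene set; the universe is the
  post-filter mRNA layer.  Gene sets lose members with evidence codes
  NAS/ND/EA (when annotated) and are dropped below 5 members within the
  universe.  Benjamini–Hochberg correction is applied per module across
  terms; for known-molecule overlap it is applied across modules.

## Module network topology

An edge joins two molecules iff they share at least one module **and**
their interaction exists (A, B, or C > 0; C weights are used only as an
existence threshold).  Nodes are layer-tagged tuples, so identifier
namespaces cannot collide; isolated members stay in the node set flagged
`has_edge=False`.  Centralities are computed on the unweighted merged
network: degree, betweenness both raw (each unordered pair counted once)
and normalized, and closeness per connected component as
(n_reachable − 1)/Σdistances with isolated nodes scoring 0 — this avoids
infinite distances on disconnected graphs.  Top-k rankings sort
descending with lexicographic tie-break.

## Synthetic data: what it does and does not emulate

The generator draws exactly the structure the model assumes: W* with
i.i.d. uniform(0,1) entries, sparse loadings whose support encodes
K_true disjoint planted modules with planted entries ~
uniform(s, 2s) (s = `signal_strength`), observations
Xᵢ = W*Hᵢ*ᵀ + N(0, noise_sd²) truncated at 0, and interaction edges drawn
with `within_module_edge_prob` (default 0.9) for co-module cross-layer
pairs and `background_edge_prob` (default 0.01) otherwise; gene–gene
weights are uniform on (0.5, 1].

Default conditions: S = 60 samples, 150/60/150 molecules, K_true = 5
modules of 10/4/10 members, signal 1.0, noise 0.1.  The layer sizes are
chosen so a planted column has ≈ 7% support: with loadings on (s, 2s)
the *weakest* planted entry then sits ≈ 2.4 column standard deviations
above the column mean, comfortably above the default T = 2, whereas at
20% support (e.g. 10 members in a 50-molecule layer) even noiseless
loadings straddle z = 2 and extraction would be limited by the threshold
rather than by the factorization.

What the generator does **not** emulate: TCGA-like marginal
distributions, library-size or batch effects, overlapping planted
modules, hub molecules spanning modules, or realistic interaction-network
degree distributions.  Passing recovery tests therefore demonstrates that
the optimization and extraction machinery works when the model's
assumptions hold — not that modules of this quality will be recovered
from real tumour compendia, where signal fractions are far smaller and
the model is misspecified.

## Problem sizes used in the automated experiments

Recovery runs use the default conditions above with the solver cap at
3000 sweeps (a run takes ~1 s); descent and non-negativity diagnostics
use 20 instances at S = 40, N = 30/15/30, K = 5 across a 3×3 grid of
(α, λ) × (γ₁, γ₂); permutation calibration uses 40 size-6/3/6 random
modules at 500 permutations.  These sizes give stable statistics while
keeping a full run in seconds.

## Known limitations

- Multiplicative updates find a local optimum; different seeds can land
  on different factorizations.  `fit` is deterministic per seed, and
  restarts are the caller's loop (no built-in multi-start).
- Monotone descent is an empirical guarantee verified across the tested
  weight grid; very large network weights λ relative to the
  reconstruction scale can in principle break the majorization and are
  not part of the tested envelope.
- K must be chosen by the user.  A practical heuristic is to set K near
  the number of miRNA clusters expected in the data; there is no
  automatic selection.
- The enrichment machinery assumes identifier systems already match
  between expression and annotation inputs; no ID mapping is provided.
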