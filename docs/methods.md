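# Methods

## Scope and data model

`herbiscreen` covers the statistics and decision analysis of an
in-silico herbicide-substitute screening campaign. The physical
simulation layers — ligand docking, molecular dynamics / MMPBSA binding
energies, DFT reaction barriers — are treated strictly as inputs, read
from CSV/TSV tables or emulated by the seeded synthetic generators. The
central containers are a compounds × criteria `ScoreMatrix` (each
criterion tagged positive or negative), a `QsarDataset` (descriptor
blocks + activity + train/test split), a `DesignMatrix`/`ResponseTable`
pair for two-level designs, and ordered `EnergyProfile`s of positive
step barriers.

## Composite ranking (AHP-TOPSIS with minimum-entropy fusion)

Normalization is min-max per criterion, direction-dispatched by the
indicator tag so that a larger normalized value always means "better":
positive criteria map through (X−min)/(max−min), negative ones through
(max−X)/(max−min). Constant columns are rejected by name rather than
silently imputed, since a zero range makes every later quantity
undefined.

Subjective weights W₁ are the normalized principal eigenvector of a
positive reciprocal pairwise-judgment matrix, with Saaty's consistency
ratio CR = ((λ_max−n)/(n−1))/RI(n) reported (warning above 0.10, never
enforced; CR is defined as 0 for orders 1 and 2). The judgment matrix is
user input; the default shipped matrix is a *consistent stand-in* with
the herbicidal criterion weighted twice the others (W₁ = 0.5, 0.25,
0.25). It is not a reconstruction of any published judgment table — the
published campaign's final fused weights (≈49.3 : 25.2 : 25.5) are
echoed in documentation as a reference point only, because the judgments
behind them are not available to re-derive.

Objective weights come from a TOPSIS-style construction: per criterion,
the relative-error vectors against the ideal value a⁺ and anti-ideal
value a⁻ (each divided by the column range, hence bounded by 1 in
magnitude), and the cosine θ_j of the angle between them, summed over
compounds. Three printed-source ambiguities had to be resolved, and the
resolutions are part of this package's definition of the method:

1. the ideal/worst vectors are the standard TOPSIS pair (max/min for
   positive criteria, min/max for negative) — the degenerate alternative
   of identical best and worst vectors would zero out the construction;
2. θ_j can legitimately be negative (a three-point column with
   normalized values 0, 0.5, 1 gives θ = −0.2), so the objective weight
   uses |θ_j|/Σ|θ_j|; the raw signed cosine is still reported;
3. the cosine's summation index runs over compounds.

Fusion of W₁ and W₂ follows the minimum-entropy principle
min Σ w ln(w/W₁) + Σ w ln(w/W₂) on the simplex. Its exact Lagrange
solution is w ∝ √(W₁W₂) (`entropy-sqrt` mode). The product form
w = W₁W₂/ΣW₁W₂ is nevertheless the default (`printed-product`), for
fidelity with how the method is commonly printed; the two agree only
when W₁ = W₂ is uniform, and both are exposed and logged. Note the
product form is *not* a fixed point at W₁ = W₂ (it sharpens weights
toward the larger entries); the sqrt form is.

The comprehensive value is CV_i = Σ_j w(j)Z_ij, optionally (default on)
min-max renormalized across compounds so the report scale is [0, 1].
Ranking is descending with ties broken by input order. Because every
ingredient is range-normalized, the full ranking is invariant under any
positive affine rescaling of a raw criterion column; this is enforced by
property test.

## QSAR validation statistics

The regression engine is NIPALS PLS1 with column mean-centering and no
autoscaling (similarity-field blocks share units, so variance scaling
would distort field contributions). Coefficients on the original
descriptors are B = W(PᵀW)⁻¹q. Component extraction stops early when the
residual covariance ‖Xᵀy‖ is numerically zero, which happens exactly on
low-rank data; this makes q² plateau instead of fluctuating at machine
precision and lets component selection (first-occurrence argmax of q²
over 1..max_n, capped at 10 by default) return the smallest optimal
count. Zero-variance descriptors are dropped with a warning and get zero
coefficients.

- q² = 1 − PRESS/TSS with PRESS from genuine leave-one-out refits (the
  implementation is the refit loop; the test oracle is an independent
  reference PLS implementation).
- R², SEE = √(RSS/(n_train−k−1)) and F = (R²/k)/((1−R²)/(n_train−k−1))
  use the k-component degrees-of-freedom convention of the classic 3D-QSAR
  software stack.
- r²_pred = (SD−PRESS)/SD with SD about the **training** mean (the
  classic external-validation convention); the test-mean variant is
  available behind a flag.
- Overfit ratio = 100·(R²−q²)/R².
- Validation gates: pass iff q² > 0.5 AND r²_pred > 0.6 AND overfit
  ratio < 30 %, all strict, with every failed gate named.

One documented source discrepancy: the published campaign's prose quotes
q² = 0.751, n = 10, R² = 0.998 for its comprehensive model while its
summary table prints 0.789 / 8 / 0.993 for the same row; the table
values are treated as authoritative here. Printed SEE/F magnitudes
depend on the unpublished descriptor tables and are not targeted.

Field contributions of block k are Σ_{j∈k} |b_j|·s_j over its columns
(coefficient times training standard deviation), normalized over all
blocks — nonnegative and summing to 1 by construction, invariant to
column order, and splitting mass evenly across duplicated blocks.

The similarity-field generator is a deliberately simplified stand-in for
a molecular-field calculation: descriptor at grid point q for field k is
w_probe,k · Σ_i w_ik exp(−α r²_iq), defaulting to 2 Å grid spacing,
α = 0.3 Å⁻² and unit probes. It produces field-blocked descriptor tables
of the right shape and smoothness for the PLS layer; it does not model
real force fields.

## Experimental designs and effects

Orthogonal arrays use the Sylvester–Hadamard construction: for n runs (a
power of two), drop the all-ones column of H_n, map ±1 to 1/0, and take
the first n_factors columns in Yates order. Any such selection is an
OA(n, 2^k, strength 2); balance (16/16 per column at n = 32) and
pairwise orthogonality (all four level pairs equally often) are verified
by brute force in tests rather than by matching any particular
commercial package's proprietary run order, which is not reproducible.

Full factorials are generated in Yates standard order with run 1 the
all-zeros blank scheme. Effects recode levels to ±1 and compute
high-contrast mean minus low-contrast mean, with interaction contrasts
as elementwise products; the regression coefficient (half the effect) is
reported alongside. The responses are |binding energy| in kJ/mol; a more
negative binding energy (larger response) is read as stronger
substrate–enzyme association and hence better microbial accessibility.
On that response scale, positive main effects are classified as
promoting degradation, positive interactions as synergistic, negative as
antagonistic, and a positive third-order effect as the three factors
jointly suppressing lower-order antagonism. Screening reports, for every
run, the percent reduction 100·(|E_run|−|E_blank|)/|E_blank| vs the
blank (the all-zeros run by convention, overridable), and selects the
run with minimum binding energy, ties to the earliest run.

## Degradation bookkeeping

Step barriers must be strictly positive (an activation energy); stage
totals are plain sums, change rates are signed percentages
100·(candidate−reference)/reference, negative meaning the candidate's
step is easier. Report output rounds to 3 decimals for energies and 2
for percentages, matching common reporting precision, while full
precision is retained internally. The fish-antioxidant composite is the
unweighted sum of the SOD and CAT docking scores (1:1), higher meaning
stronger predicted enzyme inhibition, i.e. more toxic.

## Synthetic generators: what they emulate and what they don't

All generators are pure functions of (config, seed); sub-streams are
derived per generator so the stages are independently reproducible.

- **Docking scores**: a single latent quality per compound with
  per-criterion loadings (positive for herbicidal function and
  degradability, negative for toxicity) plus Gaussian noise, scaled into
  a plausible docking-score range (~60–160). Defaults: 26 compounds × 3
  criteria, loadings (20, 15, −12) around baselines (110, 100, 110),
  unit quality spread, noise SD 2 score units — a signal-to-noise ratio
  at which ranking recovery is good but not trivial. The single-factor
  structure is the simplest model under which the composite ranking has
  a recoverable ground truth; real docking scores have multi-factor
  structure and heavier tails, so passing tests show the machinery is
  correct, not that real rankings are this clean.
- **Design responses**: planted effects are specified on the ±1 contrast
  scale (so the factorial analysis recovers them exactly at zero noise,
  effect = planted value) with an additive offset fixing the blank run
  at exactly −93.414 kJ/mol, the published control binding energy. The
  default planted set (mains 24, 14, 12; interactions 4, 3, −2; 4.479
  three-way) reproduces the published screening geometry: all mains
  promoting, one pairwise antagonism, and the all-additives scheme
  58.32 % below the control. Default response noise SD is 1 kJ/mol.
- **QSAR data**: latent factors × loadings + noise for descriptors,
  activity linear in the factors; default 28 compounds, rank 3, 60
  descriptors cycled through five field-block labels, noise SD 0.05.
  The 3:1 train/test split is stratified by activity quartile with the
  template compound (the first) pinned to the training set — a split
  tag cannot place one compound in both sets, so "template available to
  both evaluations" is honored on the training side where the model is
  built.
- **Energy profiles**: defaults are the published two-step hydrolysis
  barrier pair (160.893, 39.913 vs 60.147, 34.386 kJ/mol) used as a
  fixture; configurable multipliers derive the candidate from the
  reference instead.

## Numerical choices

- Weight vectors validate to sum 1 within 1e-12 and strict positivity.
- AHP uses the dense eigendecomposition; the CR is clamped at 0 against
  eigenvalue round-off on exactly consistent matrices.
- Tie-breaking everywhere is the stable order of input ids.
- Machine outputs (CSV/JSON) carry full precision; only human-readable
  report text is rounded.
- The pipeline's reports are byte-identical across reruns of the same
  config and seed.

## Problem sizes

Tests and the acceptance script run on the study-scale problems: 26 × 3
score matrices, 32-run/18-factor arrays checked by exhaustive pair
counts, 2³ factorials, 10–28-compound QSAR datasets with LOO refit
loops, and 20-permutation sanity ensembles. The whole suite and the
acceptance script each complete in seconds on one CPU.

## Known limitations

- No docking, MD or DFT is performed; garbage scores in, garbage
  ranking out.
- The AHP default matrix is a documented stand-in; campaign-specific
  judgments must be supplied to reproduce any particular published
  weighting.
- The entropy-fusion product form and sqrt form disagree whenever
  W₁ ≠ W₂; results quoting "compound weights" should state the mode
  (the run log always does).
- LOO is the only cross-validation granularity implemented;
  leave-group-out would need a trivial extension of the refit loop.
- The similarity-field generator is geometric plumbing, not chemistry:
  no alignment, no force-field physics, no contour rendering.
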