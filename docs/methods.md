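# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data generator behind `voxelstack`, including the places where the
design was genuinely open and a choice had to be made.

## First-level encoders

Each feature space `x_j` (n samples × d_j features) gets an independent ridge
encoder per voxel. Features and responses are mean-centered per training
split; no intercept column is added or penalized; feature columns are not
rescaled by default (a `standardize` flag exists for feature sets on
heterogeneous scales). The penalty `λ_jv` is selected independently per
feature space and voxel by 5-fold inner cross-validation over the fixed grid
`{10^-6, 10^-5, …, 10^9}` (16 values), minimizing validation squared error;
ties are broken toward the larger penalty, preferring the more regularized
model at equal evidence.

Fitting shares one spectral factorization per training split across all
penalties and voxels: with `XᵀX = V diag(w) Vᵀ`, the coefficients at penalty
λ are `V diag(1/(w+λ)) Vᵀ Xᵀ Y` for every voxel simultaneously; when
`d > n` the dual (Gram) form `Xᵀ(XXᵀ+λI)^{-1}Y` is used. The test suite
asserts agreement with a naive per-voxel solve to 1e-8 across the whole
grid. Constant response columns are legal inputs: their centered solution is
identically zero and a warning is logged.

## Stacking

Per voxel, the stacked prediction is a convex combination of the first-level
predictions. The weights minimize the combination's squared error computed
from *out-of-fold* first-level predictions: the training set is split into 5
stacking folds; for each fold, first-level models (penalties re-selected by
inner CV inside the 80%) predict the held-out 20%; concatenating folds gives
each space one prediction per training sample from a model that never saw
that sample. The k×k residual-product matrix `R` (the Gram matrix of
out-of-fold residual vectors) defines the per-voxel QP

    min_α αᵀ(R + εI)α   s.t. α ≥ 0, Σα = 1,
    ε = jitter · trace(R)/k,  jitter = 1e-9.

The relative jitter makes the objective strictly convex, so the optimum is
unique and redundant predictors split weight evenly — a deterministic,
solver-independent tie-break (two identical feature spaces each get exactly
0.5). The QP is solved exactly by support enumeration: for each nonempty
support `S`, the equality-constrained stationary point is
`α_S ∝ Q_SS^{-1} 1` with objective `1/(1ᵀQ_SS^{-1}1)`; the feasible candidate
with the smallest objective is the global optimum (the KKT system of the
true optimum appears among the candidates). With `k ≤ 12` feature spaces the
2^k−1 supports are enumerated directly; layer hierarchies in practice have
k ≤ 10. An all-zero `R` (perfect predictors) has a degenerate optimum and
returns uniform weights, logged. Weights that come out of the solver a
round-off below zero are clipped and the vector renormalized on export.

After the weights are found, the first-level models are refit on the entire
training split (penalties re-selected) and carried in the exported model.
`R` is computed once from the full set of pooled out-of-fold predictions,
not averaged per fold. The optional `include_concat_space` flag appends the
column-concatenation of all spaces as an extra stacking input (off by
default; it is a remedy for regimes where concatenation alone would win on
raw prediction, not part of the core method).

Known misspecification: if two spaces predict *disjoint* signal components,
the simplex constraint Σα = 1 caps the stacked model below the sum of the
parts. This is inherent to convex-combination stacking; in exchange the
weights stay interpretable as a split of the prediction and the stacked
model is essentially never worse than the best single space on held-out
data — the property variance partitioning relies on.

## Evaluation protocol

All performance numbers are pooled outer cross-validation estimates: 5 outer
folds (seeded shuffled partition by default; contiguous blocks behind a
flag), the full pipeline trained on 80%, predictions on the held-out 20%
pooled so each sample is predicted exactly once per model, per-voxel
`R² = 1 − SS_res/SS_tot` computed on the pooled predictions. `R = √R²` is
reported only where `R² > 0` and is missing (NaN) otherwise, never zero.
Negative held-out R² is reported as-is. The three-way comparison (stacked
vs. concatenated vs. each individual space) shares the identical folds.

## Variance partitioning and sweeps

The unique variance of space `j` is `U(all) − U(all \ j)` with both unions
estimated by stacked joint models under the same outer-CV protocol. The
forward sweep computes the cumulative prefix performances `U({1..j})` for
`j = 1..k`; the forward index is the *smallest* prefix whose performance
reaches `threshold × U(all)` (threshold 0.95 by default, configurable). The
backward sweep computes suffix performances `U({j..k})`; the backward index
is the *largest* suffix start retaining the threshold. A literal "max j"
reading of the forward rule (and "min j" backward) would always return `k`
(and 1) for monotone series; the crossing rule implemented here is the one
that matches the questions the sweeps answer — the latest layer that must be
included, the earliest layer that must be included. Voxels whose total
performance is not positive get missing indices (a 95%-of-nonpositive
threshold is meaningless), never zeros.

Cumulative series are stored raw; near-monotonicity is an empirical property
of stacked unions, tested, not enforced. A `monotone_envelope` flag applies
a running maximum before thresholding for users who want the guarantee.

Cost sharing: the sweeps need up to 2k−1 subset models, but all of them
reuse the same first-level machinery. The per-outer-fold out-of-fold
predictions and full-train refits are computed once per space
(`build_first_level_cv`); each subset model then only extracts the relevant
sub-block of `R` and re-solves the per-voxel QP. Subset results are
identical to fitting each subset from scratch, by construction.

Attribution maps label each voxel by its largest stacking weight (variant A)
or by its best individually-performing space (variant B); ties break toward
the earliest space. The second-largest-weight label and early/middle/late
group-mean weights are exported as convenience columns.

## The synthetic-data generator

The generator emulates a multi-feature-space encoding experiment with a
known ground truth:

1. All `D = Σd_j` feature dimensions are drawn jointly from `MVN(0, Σ)` with
   the Toeplitz kernel `Σ(u,v) = exp(−(u−v)²/(s·D))` (unit diagonal; the
   alternative grouping `exp(−(u−v)²·s/D)` is available as `kernel="alt"`).
2. Adjacent blocks get a shared correlated component of strength `c`: on the
   overlapping columns, `X_j ← √(1−c)·Z_j + √c·S`, with `S` a standard
   normal latent shared between blocks `j` and `j+1`, and `Z_j` the block's
   own pre-mixing draw. The pre-mixing block 1 is stored so the true unique
   variance of space 1 is well defined.
3. A weight vector `w ~ MVN(0, Σ)` is split into per-space pieces.
4. Component signals `f_j = standardize(X_j w_j)` (zero mean, unit sd).
5. `y = Σ_j α_j f_j + σ·ε`, `ε ~ N(0,1)`, with hand-set simplex weights α.

RNG consumption order is fixed (features, shared latents, weights, noise),
so one seed pins the dataset exactly; the stored components reconstruct `y`
bit-for-bit. `m_voxels > 1` yields a bank of voxels sharing the feature
matrices with independent weights and noise per voxel.

The true unique variance of space 1 is the R² of the oracle predictor
`α₁ · standardize(X₁_initial w₁)` against `y` — the standardized form is the
one consistent with the generative pipeline; at `c = 0, σ = 0` with
decorrelated blocks it reduces to the analytic share `α₁²/Σα_j²`.

Defaults: `dims = (256, 256, 256, 256)` (D = 1024 total, matching the
dimensionality budget of PCA-reduced network-layer features), `n = 1000`,
`σ = 1`, `c = 0.2`, `α` uniform, `s = 0.004`. The scale `s` is set so the
correlation length `√(s·D)` is about two features at the default
dimensionality: PCA-derived features are close to decorrelated, and at
`s = 1` the kernel would make adjacent features 99.9% correlated, collapsing
the effective dimensionality to a few dozen and removing the
over-parameterization (D ≥ n) that makes joint-model estimation genuinely
hard — the regime this benchmark exists to probe.

What the generator does **not** emulate: temporal autocorrelation of fMRI
noise, voxel-to-voxel noise correlation, hemodynamic convolution,
session/run structure, and nonlinearity between features and response.
Passing benchmarks here show the estimators behave correctly under the
generative model's assumptions; they do not certify performance on real
data, where those violations apply.

## Benchmark experiment

`run_experiment` repeats, per parameter setting: draw a fresh dataset
(all variables resampled each repetition, one voxel per repetition), run the
outer-CV three-way comparison, estimate the unique variance of space 1 by
stacking and by concatenation, and record both absolute errors against the
ground truth. Rows are paired by repetition, so stacked-vs-concatenated
contrasts are paired comparisons. Per-repetition seeds derive from a master
seed via `SeedSequence`. The identical all-spaces concatenation pipeline
appears in both the evaluation report and the concat unique-variance
estimate and is computed once.

The acceptance-grade runs in the test suite use 20 repetitions at
`α₁ ∈ {0.5, 0.7}` with the default generator conditions above; the
structured-sweep recovery check uses a lighter chain (`dims = (32,)×4`,
`n = 800`, `σ = 0.5`, 40 voxels) where exactly spaces 1–2 carry signal.
Problem sizes were chosen as the smallest at which the phenomena under test
are stably expressed.

## Numerical details and edge cases

- Fold assignment: seeded permutation split into near-equal blocks;
  deterministic given (n, folds, seed). Every nested level derives its seed
  from the run seed by fixed offsets.
- QP feasibility tolerances: support candidates with components below
  −1e-12 (relative) are rejected; exported weights satisfy Σα = 1 to 1e-6.
- `r2_score` returns NaN for constant true responses (undefined), and
  negative values on held-out data are legitimate.
- Sparse feature inputs are densified with a warning; non-finite entries are
  rejected with their location before any fit runs.
- HDF5 round-trips are bit-exact; TSV exports render floats at full
  `repr` precision (read back with `float_precision="round_trip"` for
  bit-exactness).

## Known limitations

- Support enumeration is exponential in k; guarded at k ≤ 12. Larger
  ensembles would need an iterative QP solver.
- The simplex misspecification above means raw stacked R² can trail the
  concatenation baseline when n comfortably exceeds D and spaces carry
  disjoint signal; the `include_concat_space` flag is the documented remedy.
- Sweeps assume a chain hierarchy; other dependence structures (e.g.
  V-structures) would need different subset families, for which
  `joint_performance` over arbitrary subsets is the building block.
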