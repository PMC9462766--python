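# Methods

This note documents the models, numerical choices and known limitations of
`pgropt`. The package analyzes designed factorial experiments in plant
tissue culture: four plant-growth-regulator doses (BA, Kin, NAA, GA₃, mg/L)
in, three growth responses (shoot number SN, shoot length SL in cm, callus
weight CW in g) out. The packaged wallflower dataset is a full 4×4×2×2
factorial of treatment means ± SE (64 cells, 4 replicates per cell).

## Data handling

**Modeling unit.** The modeling unit is the treatment mean (64 rows), not
the replicate observation. Replicate-level expansion from the printed SEs is
available (`replicate_expand`, `RunConfig.replicate_mode`) but off by
default: pseudo-replicates generated from a normal around the mean add no
information beyond inflating n, and the printed table provides only means
and SEs.

**Normalization.** All inputs and targets are affinely mapped to [−1, 1]
(`RangeScaler`, the mapminmax convention): the observed minimum maps to −1
and the maximum to +1. The scaler is fitted on the **full** table before
splitting, mirroring the normalize-then-split order of the original
workflow. This leaks the test set's range into training; with a designed
factorial whose extremes are fixed by the design this is immaterial, but it
is a deliberate, documented choice rather than an oversight.

**Splitting.** 80/20 random split; the test partition gets ⌈0.2·N⌉ records
(13 of 64), so the training set has 51. Deterministic per seed.

**Outlier screen.** Correlation-matrix PCA on the 7 numeric columns;
Hotelling T² of the scores on the components explaining ≥ 95% of variance,
compared to the F-distribution critical value at a **family-wise** (Bonferroni)
level of α = 0.05. A raw per-record level would flag ≈ α·N points of any
clean sample by chance, which defeats a screen; with the family-wise level
the packaged dataset yields zero flags, consistent with the original
analysis. The screen only reports flags; it never removes records.

## Surrogate models

Each response gets its own 4-input, m-hidden, 1-output perceptron with
tansig (hyperbolic tangent) hidden units and a purelin (identity) output.
Single-output networks are used deliberately — the three responses have very
different scales and noise levels, and independent networks let each choose
its own complexity.

**Training** minimizes F = β·E_D + α·E_W by Levenberg–Marquardt:
solve (2β·JᵀJ + (2α+μ)·I)δ = −∇F, accept the step if F decreases
(μ ← μ/10) else raise μ (×10, start 0.005, give up at 10¹⁰). After each
accepted step the hyperparameters are re-estimated by the evidence
approximation (Foresee–Hagan):

    H = 2β·JᵀJ + 2α·I,   γ = P − 2α·tr(H⁻¹)
    α ← γ / (2·E_W),     β ← (K − γ) / (2·E_D)

with γ clipped to [10⁻⁶, P] and denominators floored to avoid division by
zero on (near-)interpolating fits. Stopping: 1000 epochs, gradient ∞-norm
below 10⁻⁷, mean squared error below 10⁻¹⁰, or an unacceptable step at
μ = 10¹⁰. Weights initialize uniformly in [−0.5, 0.5] from the run seed;
training is bit-for-bit deterministic given (data, config). A fixed-decay
mode (constant α, β = 1) exists for debugging and for the
regularization-effect tests.

**Hidden width** is selected per output by trial and error: grid 1–12, five
seeds (each seed fixes both the split and the initialization), pick the
width with the smallest median test RMSE, ties to the smaller network. On
the packaged table this typically selects small networks (SN: 2, SL: 3,
CW: 5) — with 51 training points and Bayesian shrinkage, small-m networks
generalize best. A fixed width can be forced via `RunConfig.n_hidden`.

**Metrics.** R² = 1 − SS_res/SS_tot, RMSE, and mean bias error
MBE = mean(y − ŷ), all reported in original units. RMSE in scaled units
maps to original units by half the target range; R² is scale-invariant
(verified by test). A constant target makes R² undefined: the error raised
still carries RMSE and MBE.

## Multi-objective medium design

NSGA-II is implemented from scratch (it is part of the package's
contribution, not delegated): fast non-dominated sort (vectorized pairwise
dominance), crowding distance with infinite boundary distance and
all-infinite fronts of size ≤ 2, binary tournament on (rank, crowding), SBX
crossover (η_c = 15) with polynomial mutation (η_m = 20, per-gene
probability 0.01 by default), bounds clipping, and (μ+λ) elitist
environmental selection with crowding-based truncation (descending
crowding, stable order on ties). Maximization is handled by sign-flipping
into minimization-native dominance. Defaults follow the study protocol:
population 50, 800 generations, crossover rate 0.8, mutation rate 0.01.
Termination is the fixed generation count; no early stopping.

**Ideal-point selection.** Objectives are scaled by the observed per-output
min/max (values outside the observed range are not clipped, so the
surrogate may legitimately score above 1). The ideal point assembles the
best observed values — (max SN, max SL, min CW), for the packaged table
(6.50, 3.99, 0.00) — and the front member with the smallest Euclidean
distance E wins; ties break to smaller predicted CW, then lexicographic
doses. Observed-range scaling (rather than front-range) keeps E comparable
across runs and seeds.

**A documented discrepancy.** The originally published recommendation for
this dataset (SN 7.12, SL 3.99, CW 0.21 at BA 1.41) is *not* the minimizer
of this selection rule on any Pareto front that spans the shoot/callus
trade-off: its CW term alone contributes 0.70 to E while mid-front
compromises (SN ≈ 4.6, CW ≈ 0.06) score E ≈ 0.40 — and even among the 64
printed cells the rule prefers other cells. Front-range and utopia-corner
scaling variants select compromises as well. The published point is only
consistent with a front concentrated near the maximum-SN corner. `pgropt`
therefore reproduces the published fit quality and sensitivity rankings but
deliberately reports the compromise medium its own selection rule actually
implies; `compare_to_published` makes the difference visible instead of hiding
it. A related consequence: because BA and Kin are partially interchangeable
cytokinins, the compromise region has two near-equivalent branches (BA-rich
and Kin-rich), and the median recommended BA over seeds is bimodal.

## Sensitivity analysis

"Input not available" is operationalized as mean substitution: the column is
replaced by its training-set mean and the model is **not** retrained — fast,
deterministic, and the conventional reading of ablation sensitivity for
small networks. VSE is the model RMSE (original units, full table) under
ablation; VSR = VSE / baseline RMSE. An input the network provably ignores
gives VSR = 1 exactly. A retraining policy (drop the column, refit) is
available behind a flag for comparison; absolute VSE/VSR magnitudes depend
strongly on that choice, so only rank orders should be compared across
implementations. Ranks are recomputed from median VSR when aggregating over
seeds.

## Synthetic data generator

The generator emulates the structure of the real experiment, not its
biology: full factorial over the real dose grids; per-output response
surfaces y = clip₀(ceiling · tanh(b·z + Σqᵢzᵢ² + Σcᵢⱼzᵢzⱼ − offset)) on
doses z normalized to [0, 1]; Gaussian replicate noise with
SD = noise_sd/√n_reps clipped at zero. Defaults are calibrated once to the
real table: ceilings give SN ≈ 0–6, SL ≈ 0–3.6, CW ≈ 0–0.27, and noise SDs
equal the median printed SE × √4 (SN 0.33, SL 0.012, CW 0.005 per
observation). The negative quadratic and BA×Kin interaction terms reproduce
the observed rise-then-decline at high cytokinin (an interior optimum); CW
rises monotonically with a threshold. Surface curvature is chosen strong
enough that the multi-objective optimum is sharply identified in every
dose — on a flat ridge, gene-space recovery scores would be meaningless no
matter how good the optimizer is.

Ground truth shipped with each dataset: the planted optimum (dense grid
search of the true-surface ideal-point distance, the exact analog of the
pipeline's selection step) and the planted importance order, defined as
main-effect strength (SD of per-level conditional means of the true surface
on the factorial grid) — with curvature present this, not the raw linear
coefficient, is what ablation sensitivity measures.

What passing synthetic tests do **not** show: real dose-response surfaces
are not exactly saturating quadratics, real replicate noise is not Gaussian
(counts, truncation), and real experiments have batch effects the generator
omits. Recovery results certify the pipeline's machinery, not its biology.

## Pipeline and reproducibility

The pipeline repeats split → fit → optimize → rank over `n_seeds` seeds
(default 10) and reports medians. Every stochastic stage draws its sub-seed
from the master seed through a counter-based splitter
(`SeedSequence(master, spawn_key=(stage, k))`), so the training streams are
unaffected by, say, changing the number of GA repeats. Problem sizes used
by the test suite are scaled to the method, not the data: property tests
use populations ≤ 40 and 150–300 generations, which suffice for the
constructed problems they solve; headline comparisons use the full
50 × 800 protocol.

## Known limitations

- Single-response networks only; no multi-output or deeper architectures.
- Box bounds only in the optimizer; no general constraints, no integer doses.
- VSE/VSR magnitudes are ablation-policy-dependent; compare ranks only.
- The ideal-point rule is sensitive to objective scaling; only
  observed-range scaling is exposed, for cross-run comparability.
- Exact reproduction of any single published run is impossible without its
  seeds; all comparisons are distributional (medians over seeds).
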