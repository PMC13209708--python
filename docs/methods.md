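# Methods

## Scope and data model

The package predicts butyrylcholinesterase inhibition (pIC50, molar
convention: pIC50 = −log10(IC50·10⁻⁹) for IC50 in nM) from six molecular
descriptors: nRot, Flex (= nRot/nRig), Fsp3, logD(7.4), log Caco-2
permeability, and PPB (%). Descriptor computation is upstream; compound
tables enter as CSV with an `id` column, optional `smiles`, and descriptor
columns (Unicode minus signs are normalized on read; rows missing a
modeling descriptor are retained but flagged incomplete and excluded from
model stages). Records may carry the wider ADMET vocabulary (MW, TPSA,
nHA, …); only the six modeling descriptors are mandatory for modeling.

Splitting is by seeded shuffle; every non-train split gets
round(fraction·n) records and the remainder goes to train, so the
reference-scale split of 121 compounds at fractions 100/121, 21/121 always
yields exactly 100 train / 21 test.

## The frozen linear model

The published six-descriptor equation is shipped as a frozen
`LinearModel` with its printed coefficients, standard errors, and fit
statistics, and is applied to raw (unstandardized) descriptors — verified
by the fact that it reproduces the full 16-row printed prediction table
within ±0.02, the rounding slack of the printed coefficients. Printed-table
comparisons use half-up rounding to 2 decimals.

## Refitting machinery

* **OLS** via least squares with classical SEs from the unbiased residual
  variance; rank-deficient designs are rejected naming the collinear
  columns (QR diagnostic).
* **Q² (LOO)** = 1 − PRESS/TSS with TSS about the training mean, PRESS via
  the hat-matrix shortcut e/(1 − h); tested equal to an explicit
  refit-per-left-out-point oracle to 1e−8. This convention is consistent
  with Q² < R² as printed (0.667 < 0.706).
* **Tolerance** of a descriptor against a candidate subset is 1 − R² of
  the OLS of that descriptor on the other members — the standard
  multivariable generalization of the pairwise 1 − r² rule, to which it
  reduces for two-variable subsets. Default admission threshold 0.1; the
  stricter 0.25 level is reported as an advisory flag. A duplicated column
  yields tolerance 0 and subset rejection rather than an error, since a
  screen must be able to *fail* exactly-collinear candidates.
* **Best-subset search** enumerates all subsets of size kmin..kmax
  (default 2..6), screens each at tolerance 0.1, and ranks admissible
  subsets by adjusted R² (the selection criterion used by the original
  tooling is not documented; adjusted R² is the conventional default, with
  R² and LOO-Q² available). Ranking uses correlation-matrix algebra
  (R² = r'R⁻¹r on standardized complete-case data — exact, and ~100×
  faster than refitting); full models with SEs are fit for the top
  `fit_models` subsets. Note that with pure-noise decoys adjusted R²
  legitimately admits a decoy whose |t| exceeds 1, so recovery claims are
  phrased per subset size or with the size range capped.
* The model p-value is the F tail with (k, n−k−1) degrees of freedom.

## Neural-network engine

One hidden layer; activations for hidden and output drawn independently
from {identity, logistic, tanh, exponential}; loss is the sum of squares
(SOS). Inputs and response are min–max scaled to [0, 1] internally (the
response scaling also keeps bounded output activations feasible). Training
is scipy BFGS with analytic gradients, iteration cap 200 (configurable),
gradient tolerance 1e−6, weights initialized U(−0.5, 0.5) from a seeded
generator — deterministic per seed; non-convergence returns the best
iterate flagged. The architecture search samples hidden sizes 3–13 and
activation pairs uniformly, trains each candidate, and retains the best by
validation-set SOS. The desk-scale default is 40 trained / 5 retained;
the conventional large-scale search (500/50) is a parameter away and not
run in tests purely as a matter of problem sizing. ANN splits default to
70/15/15 train/test/validation.

**GSA** scores input j as SOS(model with input j frozen at its training
mean) / SOS(full model), ranked descending; a score ≤ 1 marks an input the
network does no better with. Mean-substitution without retraining is the
implemented convention (an input with zero outgoing weights therefore
scores exactly 1); a retraining variant exists behind `retrain=True` but
makes no fidelity claim, since the original tool's reduced-model definition
is not documented. If the full-model SOS is exactly 0 the ratio is
degenerate; scores are defined as +∞ where ablation raises the error and 1
otherwise, and the report is flagged.

## SVR engine

scikit-learn ε-SVR behind the module surface. Kernel menu: linear,
quadratic (= polynomial of degree 2, the nomenclature of the original
tooling), RBF, sigmoid. Descriptors are z-scored on training statistics
inside the engine — SVR is scale-sensitive and raw-unit fitting would let
the percent-scale PPB dominate. Defaults C = 1, ε = 0.1 with a small log
grid (C ∈ {0.1, 1, 10}, ε ∈ {0.01, 0.1, 0.3}) searched per kernel by
test-set MSE; ties break by kernel list order. The solver is
deterministic; a seed argument exists only for interface symmetry.

## Applicability domain

Reference descriptors are z-scored; PCA is the eigendecomposition of their
correlation matrix (not covariance — the descriptors have incommensurate
units), with the sign of each loading fixed so its largest-magnitude entry
is positive (reproducible scores). The domain is an ellipse in (PC1, PC2)
score space sharing the orientation of the 2D score covariance. Its radius
is the smallest Mahalanobis radius containing ceil(coverage·n) reference
scores, which (i) guarantees at-least-coverage on the reference set by
construction, with overshoot at most 1/n, and (ii) converges to the
chi-square(2) quantile radius for Gaussian scores (both radii are kept on
the model; they agree to <1% at n = 10⁵). Verdicts report a radial
distance with 1.0 at the boundary. Classification is invariant to affine
per-descriptor unit changes. Default descriptor set: the six modeling
descriptors (the "key properties" choice is configurable).

## Atomic contributions

Morgan fingerprints: radius 2, 2048 hashed bits, binary by default
(counted vectors optional), computed with RDKit's Morgan generator keeping
the bit → (center atom, radius) environment map. PLS (6 components,
scikit-learn) regresses pIC50 on the bit matrix; the response is z-scored,
the bit columns stay binary (whether the original tool standardized
fingerprint columns is undocumented; binary X is the conservative choice).
Split 75/25 by seeded shuffle; 5-fold CV Q² on the training portion.
The fitted latent model is collapsed to an explicit bit-weight vector plus
intercept, so prediction = Σ(set-bit weights) + intercept.

Back-projection: each set bit's weight is divided equally among all
(environment, atom) slots of the environments that set it in that molecule
(atoms of an environment = atoms within its radius of the center atom;
heavy atoms only). This makes the conservation identity — Σ atom
contributions = prediction − intercept — exact by construction, and gives
symmetric atoms identical contributions. Hash collisions mean unrelated
environments can share a bit and hence a weight; that is inherent to
hashed fingerprints and documented rather than corrected.

## Synthetic reference generator

The 121-compound experimental reference set is external. The generator
emulates what is publicly pinned down about it:

* **correlation structure** — the published 6×6 descriptor correlation
  block, imposed through a Gaussian copula (eigenfactor of the PSD-repaired
  matrix; the published block is itself PSD, minimum eigenvalue 0.125, so
  repair is a no-op). `nearest_psd` clips negative eigenvalues and restores
  the unit diagonal; generation refuses matrices whose repair moves any
  entry by more than 0.05.
* **marginals** — truncated Gaussians: nRot rounded to a nonnegative
  integer, Flex ≥ 0, Fsp3 ∈ [0, 1], PPB ∈ [0, 100]. Means/SDs are anchored
  on the dispersions implied by the published coefficient standard errors
  (SE_j = σ/(sd_j·√(tol_j·n)) with σ = 0.59, n = 100 and tolerances from
  the published correlations gives sd ≈ {nRot 2.3, Flex 0.16, Fsp3 0.18,
  logD 0.58, caco2 0.32, PPB 7.8}) and inflated ~1.6× — defaults
  {3.8, 0.27, 0.30, 1.0, 0.55, 13.5} about means
  {7.5, 0.60, 0.45, 3.5, −4.9, 78} — so the reference cloud brackets the
  bulk of the 16 sunscreen queries while truncation tails stay ≤ ~7% per
  descriptor and the correlation structure survives truncation (empirical
  error < 0.01 at n = 10⁵).
* **response** — pIC50 from the frozen equation evaluated on the
  *post-truncation* descriptors (so at σ = 0 the equation is exactly
  identifiable by OLS) plus N(0, σ²) noise, σ = 0.59 by default — the
  published prediction RMSE, the best available error-scale estimate.

What the generator does *not* emulate: real inhibitor chemistry (SMILES
come from an explicitly synthetic toy library and are unrelated to the
descriptor draws), non-Gaussian marginal shapes, and any structure in the
residuals. Consequently, passing tests demonstrate that the *machinery* is
correct and well-calibrated under the published statistical conditions —
not that the published models generalize to new chemistry. Two visible
consequences: fingerprint-PLS on synthetic data has no predictive power
(its conservation and symmetry properties are what the tests assert), and
the refit MLR/ANN/SVR predictions for the sunscreens differ from the
printed ones (only the frozen equation reproduces those).

## Pipeline

Stages run in dependency order (screen → mlr/ann/svr → predict → ad →
atoms) with per-stage seeds spawned deterministically (numpy SeedSequence,
kept below 2³¹) from one global seed; a stage failure is recorded and
skips dependents while independent stages continue. Outputs are CSV tables
plus a markdown report and a JSON manifest; reruns with the same config
are byte-identical apart from the manifest's timing block. Prediction
tables carry full precision and are displayed at 2 decimals; Mean(1)
averages MLR/ANN1/SVR, Mean(2) additionally includes ANN2–ANN5 and is
emitted only when five networks are retained (never imputed).

Inhibition-strength bands for display: < 2 weak; [2, 4) moderate; [4, 5)
comparable to reference drugs (donepezil/rivastigmine/galantamine,
pIC50 ≈ 4.9–5.5); [5, 6] strong (closed on both ends, honoring the
"between 5 and 6" phrasing for the borderline compounds); > 6 very high,
flagged for an applicability-domain check. Purely presentational.

## Problem sizes in tests

The test and validation suites size their simulations to the study
conditions: reference-scale datasets are n = 121 (split 100/21),
coefficient-recovery uses 200 replicates at n = 100, subset-recovery 100
seeds, correlation and ellipse-coverage calibration n = 10⁵, and the
network search runs at the 40/5 desk scale. The whole suite completes in
well under a minute of CPU.

## Known limitations

* The exact random split, ANN weights, and SVR hyperparameters behind the
  published per-model predictions are unpublished; ANN1–ANN5 and SVR
  columns of the printed table are therefore not reproduction targets —
  only the frozen linear equation and the mean arithmetic are.
* The published correlation table was computed on all 121 compounds while
  the regression used 100; the screening module computes on whatever set
  it is given and does not resolve that ambiguity.
* The published tolerance claim ("> 0.25") is slightly optimistic for the
  nRot/Flex pair, whose multivariable tolerances from the published
  correlations are ≈ 0.23; the screen's operative threshold (0.1) is what
  the package enforces, and 0.25 is an advisory flag.
* The ellipse construction (covariance ellipse vs. drawn boundary) in the
  original analysis is not documented; the confidence-ellipse construction
  here is a standard choice, and the outlier *ranking* — ET and DOBT
  farthest outside — is the reproduced claim, not coordinates.
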