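# Methods

This note documents the models, conventions and design choices behind
`qradbrain`, in the spirit of the methods documentation of established
scientific packages.  It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Two classes of contrast-enhancing brain lesions are to be distinguished
from 3-D imaging: metastasis-like (label −1) and glioma-like (label +1).
The package's pipeline is: radiomic feature extraction over a tumor mask
and a 5-mm peritumoral ring → tabular preprocessing → two-stage primary
feature selection → QUBO mutual-information subset selection → a 2-qubit
variational classifier → Shapley-value interpretation.  The reference
cohort is not public, so all stages are developed and validated against
synthetic data whose generative structure is part of the package.

## Synthetic data

**Volumes.**  A lesion is the sub-level set ρ(v) ≤ 1 + ι·η(v) of a
normalised ellipsoidal radius ρ, where η is a smoothed (σ = 4 voxels),
unit-variance Gaussian field and ι ≥ 0 is the *shape irregularity*; ι = 0
yields a digital ellipsoid.  Semi-axis ratios are (1, 0.95, 0.9) for the
metastasis-like class and (1.2, 0.9, 0.7) for the glioma-like class, with
base radius 11 mm (the generator enforces a > 20 mm largest diameter and
errors out if lesion plus ring cannot fit the volume; default 64³ voxels
at 1 mm isotropic spacing).  The interior intensity is
1 + 0.1·rough + 0.3·h·corr, where *rough* is a short-range field
(σ = 1.2 voxels), *corr* a correlated field (σ = 3 voxels), and h ≥ 0 the
*texture heterogeneity*; h = 0 exactly yields a constant interior
(documented convention).  Raising the variance of the correlated field
spreads the gray-level run-length distribution and raises GLRLM run
entropy monotonically (verified empirically in the tests).  Class
defaults — metastasis-like: ι = 0.05, h = 1.0; glioma-like: ι = 0.35,
h = 0.35 — plant the association the interpretation stage is expected to
recover: the −1 class is rounder and has higher run-entropy texture.  The
ring is the set of voxels within 5 mm (physical distance, anisotropy
handled by the Euclidean distance transform) of the tumor surface,
excluding the tumor.

**Tables.**  Features are planted as: *informative* — mean shifted by
±d/2 per class (effect size d = 1.0 by default: a moderately
discriminative radiomic feature); *redundant* — an informative parent
plus Gaussian noise calibrated through the bivariate-normal relation
r = 2 sin(π ρ_s/6) to a target Spearman ρ_s = 0.9, so correlation pruning
at 0.8 must remove one member; *interacting* — pairs (a, b) with
independent half-normal magnitudes and signs coupled so that
sign(a)·sign(b) equals the label with probability 0.95, making each
member marginally independent of the label but the pair jointly
predictive (XOR structure); *noise* — standard normal.  The default spec
is n = 4000 samples at 36% minority (the 129:72 cohort imbalance), 5
informative + 1 interacting pair + 10 noise features.  Ground-truth
relevance is recorded with the table.  The generator does not emulate MRI
physics, scanner effects, bias fields or feature distributions of real
radiomics; passing tests demonstrate correctness of the algorithms under
the planted statistical structure, not clinical performance.

## Radiomics

Preprocessing per image type is fixed: z-score normalisation over the
region mask (an affine map, so the result is invariant to affine
intensity changes), then the filter, then fixed-bin-number discretization
(32 equal-width bins over the masked range; the maximum maps to the top
bin; a constant region maps to bin 1).  The filter bank is the original
image, one Laplacian-of-Gaussian at σ = 1 mm (truncation 6σ keeps the
discrete kernel's zero-sum property tight), and the 8 sub-bands of a
single-level stationary (undecimated) 3-D Haar transform with periodic
boundary, normalised so that sub-band energies sum to the input energy;
sub-bands keep the input size, so region masks apply unchanged.  The Haar
choice is the simplest orthogonal wavelet; family and level are exposed
nowhere because the manifest names only the L/H sub-band structure.

Texture matrices: GLCM at distance 1 over the 13 unique 3-D directions,
symmetric, matrices summed before normalisation; GLRLM aggregated the
same way; GLSZM zones by 26-connectivity.  Entropies are base 2 with
0·log 0 ≡ 0.  A naive triple-loop counter in the test suite serves as the
independent oracle for all three matrices.

Sphericity is (36π V²)^(1/3)/A.  The mask is lightly smoothed (Gaussian,
σ = 0.7 voxels) before marching cubes so large compact lesions are not
penalised by voxel stair-stepping; the smoothed mesh is accepted only if
its enclosed volume matches the voxel-count volume to 3% (V is then the
voxel-count volume).  Otherwise the raw binary mask is meshed and both V
and A are taken from that mesh, which keeps the statistic
isoperimetrically bounded for thin or scattered masks.  The value is
invariant to isotropic spacing rescaling.

The feature manifest enumerates 7 classes with cardinalities
13/17/22/16/16/14/5 over 10 image types and both regions (shape only for
the tumor on the original image): 913 tumor + 900 ring descriptors.  The
name lists use standard IBSI-style naming trimmed to those cardinalities;
the counts, not the exact membership, are the tested contract.  Only a
subset is computable (sphericity; first-order mean/variance/entropy; GLCM
contrast and cluster prominence; GLRLM run entropy; GLSZM zone entropy);
requesting any other descriptor raises an explicit error rather than
returning NaN.

## Tabular preprocessing

Standardisation parameters, the correlation-pruning decisions, the linear
selector and the MI ranking are all fitted on training rows only;
resampling applies to the training split after the split.  The stratified
split draws round(0.7·class size) training rows per class.  Imbalance
handling combines SMOTE (convex interpolation towards one of k = 5
nearest minority neighbours, uniform t ∈ [0, 1]) with random
undersampling under meet-in-the-middle sizing: the minority grows to at
most twice its size (capped by the ratio target) and the majority shrinks
to minority/target_ratio — e.g. 100:30 at ratio 1.0 becomes 60:60.
Correlation pruning greedily keeps, within any pair with |Spearman ρ| >
0.8, the column with the higher marginal MI with the label, so the
informative member of a redundant pair survives.  The primary linear
stage is an L1-penalised hinge-loss max-margin model solved by proximal
subgradient descent (step 0.5/√t, soft-thresholding, patience-based
stopping), implemented in-house so the stage is self-contained; columns
with |w| > 1e-5 are kept, topped up by |w| order if fewer than the QUBO
cardinality survive.

## QUBO mutual-information selection

MI and CMI are plug-in estimates from joint histograms, base-2 logs,
negatives clipped at 0.  Continuous variables are discretized into 4
equal-frequency bins — few enough that 3-way tables remain populated at
n ≈ 10².  Q has marginal MIs on the diagonal and Q_ij = I(X_i; Y | X_j)
off it; since the quadratic form's i<j coefficient is (Q_ij + Q_ji), that
symmetrised sum is used.  The cardinality penalty enters the minimisation
as +α(Σx − k)²; α = "auto" sets it just above the objective's total range
(Σ diag + Σ|Q_ij + Q_ji| plus a strictness epsilon), which provably pins
the optimum at cardinality k.  The Ising mapping substitutes
x = (1 − s)/2 and is verified exhaustively in the tests.

Solvers: exact enumeration up to p = 22 (chunked, lexicographically
smallest tie-break; optionally over the C(p, k) feasible states only),
and best-of-reads single-spin-flip Metropolis simulated annealing with a
geometric temperature schedule scaled to the coefficient magnitudes (100
sweeps of p proposed flips per read).  Each read owns a random stream
derived from (seed, read index), so results are reproducible and
best-of-reads is monotone in the read count.  The annealing sampler
stands in for quantum-annealing hardware behind the same problem
interface; minor-embedding and hardware execution are out of scope.

## Variational classifier

The 10 selected features are centered and projected onto the top 3
principal components (component signs fixed so the largest-|loading|
coordinate is positive), min-max scaled to [0, 1] with fit-row ranges
(transform rows clipped), padded with the constant 0.3 — any fixed
nonzero pad carries the per-sample normalisation information — and
L2-normalised into a non-negative amplitude 4-vector.  State preparation
uses the reversed controlled-R_y cascade with angles

    β₁² = 2 asin√(α₃²+α₄²),  β₁¹ = 2 asin(α₂/√(α₁²+α₂²)),
    β₂¹ = 2 asin(α₄/√(α₃²+α₄²)),   0/0 ≡ 0,

each controlled rotation realised by the standard half-angle 2-CNOT
decomposition (control-on-0 by X conjugation).  Basis order is
|q₁q₂⟩ = 00, 01, 10, 11.  The round-trip property (prepared state equals
the amplitude vector to 1e-10) pins the construction; the batched
training path exploits that identity directly while the explicit gate
path remains the tested reference.

The ansatz is 6 layers of [Rot(φ, θ, ω) on each qubit, CNOT(1→2)] with
Rot = RZ(ω)RY(θ)RZ(φ); the readout is ⟨Z⟩ on qubit 1.  The score is
⟨Z⟩ + b with a trainable classical bias; a score of exactly 0 predicts
+1.  Training minimises the mean squared error between score and ±1
label with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, lr 0.01), gradients by
the exact parameter-shift rule (verified against central differences),
angles initialised from a seeded N(0, 0.01²), full-batch by default.
Squared-error loss with a trainable bias mirrors the standard
variational-classifier design; the simulator is a generic dense n-qubit
statevector with 2 qubits as the default configuration.

## Shapley interpretation

The value of a coalition is the background-averaged score with absent
features replaced by background rows (interventional masking).  The exact
oracle enumerates all coalitions (M ≤ 15) with permutation weights;
Kernel SHAP solves the weighted least-squares problem with the Shapley
kernel w(s) = (M−1)/(C(M,s)·s·(M−s)), the boundary coalitions imposed
exactly through the efficiency constraint (eliminating the last feature
from the regression; ridge λ = 1e-8 on singular designs).  When the
budget covers all 2^M − 2 interior coalitions they are enumerated and the
estimate coincides with the exact oracle.  Attribution targets the
real-valued score, not the thresholded label, so local accuracy is
meaningful.  The default background is 50 seeded training rows; the
pipeline explains up to 64 test rows by default.  Summaries report
mean |φ| ranking, and mean φ with mean feature value per predicted class
and per prediction correctness.

## Metrics and orchestration

ROC-AUC is the Mann-Whitney rank statistic with midranks for ties; bACC
is the mean of per-class recalls; precision/recall/F1 come from the
thresholded confusion matrix.  All metrics are computed in-house (and
cross-checked against scikit-learn in the tests) so the evaluation path
has no model-library dependency.  The pipeline chains
split → standardize(train-fit) → resample(train) → prune → linear select
→ MI top-17 → QUBO k = 10 → classifier → SHAP → metrics, logs every stage
as line-delimited JSON, and is bit-reproducible under a fixed config;
whether resampling should precede the split is undocumented in the
method's sources, and the leakage-safe post-split placement is used.
Baseline gradient-boosting / neural-network comparisons are deliberately
out of the core path.

## Problem sizes and numerical choices

The test and acceptance workloads use: 100 random vectors for the
encoding round trip; 50 random QUBOs at p ≤ 16 with 200 annealing reads;
n = 4000 tables for interaction recovery; 10 seeds for planted-feature
recovery; 5 seeds × 200 samples × 100 epochs for classifier
trainability; M = 10 with full coalition enumeration for the attribution
oracle; and the default n = 4000 planted table (with 3 redundant copies
added) for the end-to-end run.  These sizes were chosen so the full
validation remains a desk-scale computation while keeping estimator noise
well below the tested margins.  Notable numerical conventions: MI/CMI
estimates clipped at 0; exhaustive-solver ties broken lexicographically;
annealer acceptance uses exp(−ΔE/T) with ΔE clipped for overflow; PCA
sign convention as above; zero-variance columns dropped with a warning.

## Known limitations

- The radiomic extractor computes only the named feature subset; the full
  1813-value computation parity with reference extractors is a non-goal.
- The plug-in MI/CMI estimators are positively biased at small n (the
  usual (K−1)(L−1)/(2N ln 2) scale); the bias is roughly uniform across
  the Q matrix and does not affect subset ranking in the tested regimes.
- Simulated annealing is a classical stand-in: it validates the QUBO
  formulation and solution quality against enumeration, not any claim
  about quantum hardware behaviour.
- Synthetic volumes contain no bias fields, motion, multi-sequence
  contrast or anatomical context; synthetic tables are Gaussian-based and
  cannot certify performance on real cohorts.
- The classifier's capacity is intentionally small (3 encoded components
  + pad on 2 qubits); strongly nonlinear decision boundaries in 10-D are
  representable only insofar as they survive the PCA reduction.
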