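# Methods

This note records the models implemented by `sczscreen`, the defaults and
why they were chosen, what the synthetic phantom does and does not
emulate, and the numerical decisions that matter for reproducibility.

## Pipeline model

Each 2D axial slice is processed as: skull stripping → tri-level
thresholding → MRF refinement → GM/WM texture features + whole-brain LBP →
fusion with deep features → binary classification.  The positive class is
SCZ throughout.

### Skull stripping

The "threshold filter" is realized as: Otsu binarization of the slice,
hole-filling of the bright set to obtain the head outline, erosion of the
filled head by a configurable radius (default 6 px at 224×224) to define a
core the cranial rim cannot reach, and retention of the largest bright
component that touches the core, holes filled.  The erosion radius only
needs to exceed the rim thickness; because membership is decided by
component connectivity rather than by the eroded set itself, the operation
is idempotent on already-stripped slices (the brain component always
touches its own core).  An image with no foreground after thresholding is
an error ("no head found").

### Tri-level Otsu by mayfly search

Thresholds `(t1, t2)` maximize the standard between-class variance of the
three classes `[0,t1], (t1,t2], (t2,255]` over the 256-bin histogram of
brain-mask pixels only — including background zeros would dominate the
histogram.  Empty classes contribute zero.  The search space is the
continuous box `[1, 254]²`; positions are rounded and sorted at evaluation,
and a degenerate rounded pair is nudged (`t2 = t1 + 1`) so the objective
stays finite.  An exhaustive vectorized search over all ~32k integer pairs
is provided as an independent oracle; on phantom histograms the swarm (16
flies, 60 iterations) reaches the exhaustive maximum within 0.5% in
essentially every run, so the default per-slice budget is kept small.

### Mayfly optimizer

Maximization convention.  Defaults follow the standard parameterization:
C1 = 1, C2 = 1.5, β = 2, nuptial dance d = 5, 30 flies per sex, 3000
iterations.  Choices made where the algorithm is conventionally
under-specified:

* The inertia coefficient on the previous velocity is 1 (the velocity
  update uses the bare previous velocity).
* The current best male skips attraction and only dances; the dance step
  is `d·R` with `R ~ U[−1,1]` drawn per dimension.
* The female random-walk step uses the same scale and decay as the dance;
  a female is attracted only when her rank-paired male is *strictly*
  better, so ties take the walk branch.
* The dance/walk scale decays geometrically (0.99 per iteration): an
  undamped jitter of 5 prevents convergence on unit-scale problems.
* Box bounds are enforced by clamping, with velocity zeroed on clamped
  dimensions.
* Mating is rank-paired uniform crossover (`off = L·male + (1−L)·female`
  and its mirror, `L ~ U(0,1)` per dimension); offspring replace the worst
  same-sex individuals only when strictly better, which preserves elitism
  and makes the best-so-far trace monotone.

### MRF refinement

Energy: `Σ_p [(I_p − μ_{l_p})²/(2σ_{l_p}²) + log σ_{l_p}] +
λ·#{neighboring pairs with different labels}` over in-mask pixels, with
λ = 1 and a 4-neighborhood by default.  The unary term is the full
Gaussian negative log-likelihood — keeping the `log σ` normalization makes
per-sweep re-estimation of `(μ_k, σ_k)` a constrained maximum-likelihood
step that can never increase the energy.  ICM runs in checkerboard
(red-black) order: all pixels of one parity are updated simultaneously
given the fixed opposite parity, so each update is an exact conditional
mode and the whole sweep is vectorizable; the energy trace is therefore
non-increasing by construction.  σ is floored at 0.5 intensity units so
noiseless classes remain well-posed; a class that empties keeps its last
parameters (logged).  Convergence: fewer than 0.1% of labels changing, or
50 sweeps.

Tissue identity is assigned by ordering the class means (dark → CSF/
background, middle → GM, bright → WM), the T1-weighted convention.

### GLCM descriptors

The 25-descriptor list is fixed and named (contrast, correlation, energy,
homogeneity, entropy, dissimilarity, maximum probability, sum average,
sum variance, sum entropy, difference variance, difference entropy,
autocorrelation, cluster shade, cluster prominence, inverse difference,
IDMN, IDN, IMC1, IMC2, variance, mean index, joint max row mean, trace,
marginal uniformity), computed on 8-level uniform quantization of the
fixed [0, 255] range, distance 1, averaged over the four standard
directions.  Masked computation uses a sentinel level so only pairs with
both pixels in the tissue mask are counted.  Degenerate conventions:
correlation of a zero-variance matrix is 1; `0·log 0 = 0`.  Every
descriptor is checked against a pair-enumeration oracle on 4×4 toys.

### Weighted LBP

For each interior brain pixel the 8 neighbors (order E, NE, N, NW, W, SW,
S, SE, bit q = 2^q) are compared against a threshold blending the local
average `ALGL = (Σ neighbors + 8·center)/9` with the global weighted gray
level `g_W = W·(μ+σ)`: `thr = (ALGL + g_W)/2`, ties count as 1.  The ALGL
denominator 9 with the center counted 8 times follows the printed form of
the local-average definition.  The blend uses every defined quantity,
reduces to near-plain LBP at small W, and makes the per-pixel bit count
monotonically non-increasing in W — matching the expectation that higher
weights produce sparser codes.  Codes map onto the standard 59-bin
uniform-pattern histogram (58 codes with ≤2 circular transitions in
ascending order, one pooled bin), normalized by default.

### Deep features and fusion

The backbone contract is "224×224 grayscale in, 1024 finite floats out,
deterministic".  Pretrained network weights are deliberately not bundled;
the shipped `FixtureBackbone` is a fixed random projection of multi-scale
block means (intensity and gradient magnitude at 32², 16², 8²) plus global
moments — deterministic, linear in its statistics, zero image ↦ documented
bias vector.  The supervised 1024 → 512 reduction ranks dimensions by
absolute two-sample t-statistic on training folds (zero-variance rules:
equal means → rank last, different means → rank first; ties to the lower
index).  Fusion is always DF(512) then HF(103), total 615.

### Wrapper selection

The selection fitness is `‖gap[mask]‖₂/√k` where `gap` is the difference
of class centroids on z-scored training features.  Centroids are the
minimal realization of a between-class distance over many slices, and the
√k normalization removes the trivial incentive to select everything.
Mayfly positions live in `[0,1]^286` and decode by thresholding at 0.5;
the final mask is coerced to exactly k = 103 (default) by |gap| ranking —
a deterministic, testable mechanism for the fixed output size.
Zero-variance features get unit scale and are flagged.

### Cross-validation and metrics

Stratified 5-fold at slice level is the default; subject-grouped folding
is provided because slices of one subject straddling train/validation
inflates accuracy — consumers of real data should prefer it.  All stage
transformers (DF ranking, HF z-scoring + mask) are fit per fold on the
training indices only, record their fit fold, and the harness asserts the
fit fold matches before transforming validation data.  The per-run report
marks the best fold by ACC (ties by F1) and carries the pooled fold mean.
Metrics are exact rational percentages rounded half-up to 4 decimals via
decimal arithmetic; ratios with zero denominators are NaN with a warning,
never silently 0.  Classifier tiers are fixed in a registry (decision
trees with 4/20/100 max leaves, KNN with k = 100/10/1, depth-3 gradient
boosting with 30 rounds, multinomial logistic "softmax", Gaussian naive
Bayes, linear SVM).

## Synthetic phantom

The phantom is a 2-ellipse-plus-ribbon cartoon: elliptical skull annulus
(intensity 230), a dark subarachnoid gap, a GM ribbon (130) around a WM
core (200) with ventricular CSF pockets (50), optional Gaussian noise
(default σ = 4), clipped to [0, 255].  All randomness flows from one seed
through per-(class, index) seed sequences, so every image is bit
reproducible independent of generation order.  The SCZ class effect is a
controllable texture perturbation — spatially correlated noise (Gaussian
field, correlation length 2 px) of standard deviation `class_effect`
added to the GM ribbon — or alternatively a GM-fraction change
(`effect_mode="gm_fraction"`).  The discriminative image property of real
SCZ scans is not established, so the generator exposes the effect as a
free parameter instead of asserting one.

What the phantom does *not* emulate: MRI physics (bias fields, Rician
noise, partial-volume averaging), anatomical variability, or realistic
cortical geometry.  Passing phantom tests therefore demonstrates that the
pipeline machinery is correct, leakage-free, and sensitive to planted
texture differences of known magnitude — not that any particular accuracy
transfers to clinical cohorts.

## Problem sizes used by tests and the acceptance script

End-to-end experiments run on 128×128 phantoms, 10 slices per class, 5
seeds, with reduced swarm budgets (16×60 for thresholds, 15×60 or 30×200
for selection); these sizes were chosen as the smallest at which the
planted effects are comfortably detectable while keeping the runs quick
at a desk.  The optimizer defaults (30 flies, 3000 iterations) remain the
recommended setting for real data.

## Known limitations

* ICM is a greedy solver; it refines threshold initializations but cannot
  escape poor ones (no graph cuts or annealing).
* The fixture backbone is a texture-statistics projection, not a trained
  network; accuracy comparisons across backbones require the adapter plus
  external weights.
* Slice-level folding (the default) is optimistic whenever multiple
  slices per subject are present; use `grouping="subject"`.
* Selection cardinality k is enforced post hoc rather than penalized in
  the objective; with very small training sets the |gap| ranking used for
  coercion dominates the swarm's contribution.
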