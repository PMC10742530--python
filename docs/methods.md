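# Methods

This note documents the models implemented in `fishcut`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Synthetic fish scans

### Population model

Four body measures (head length *a*, total length *b*, maximum width *c*,
maximum thickness *d*, all mm) are drawn from a truncated multivariate
normal whose marginal means, standard deviations and min/max bounds match
a measured sample of 204 crucian carp
(a: 54.6 ± 2.5 in [50.1, 63.1]; b: 223.6 ± 8.9 in [200.8, 239.4];
c: 100.9 ± 2.2 in [94.6, 103.7]; d: 47.49 ± 1.85 in [45.3, 51.54]).
Truncation is by rejection, so the marginals respect the bounds exactly.

Cross-correlations come from a one-factor ("overall size") model with
loadings 0.995 (total length), 0.99 (thickness), 0.95 (width); the head
loading is set so that corr(head, total) equals a configurable target,
default 0.8.  The near-unit length/thickness loadings encode almost
isometric co-scaling, appropriate for a size-graded single-species batch
(the emulated sample spans less than 20% in weight).  This matters
downstream: once a demarcation line is resampled to relative positions its
only absolute-scale channel is the height amplitude, so the achievable
prediction accuracy is capped by how tightly thickness tracks length.
With these loadings the cap sits near R² ≈ 0.95 — the regime the emulated
study reports — and it does **not** go to 1 even for noiseless scans.

### Body geometry

A fish occupies x ∈ [0, L] and presents the surface

    z(x, y) = t(x) · (1 − |y / w(x)|^e)^(1/e)

with thickness envelope t(x), footprint half-width w(x) and cross-section
exponent e.  The envelope is a C¹ unimodal bump: from a blunt snout at
30% of the maximum thickness it rises with a power law (exponent 2.2) to
the maximum at x = q·L, then declines (exponent 1.8) to a caudal peduncle
at 25%, with both one-sided slopes vanishing at the peak; at the snout and
tail the profile drops to zero over a 1 mm silhouette ramp, the
near-vertical wall the laser actually sees at the body extremities.  The
half-width follows the same bump at half power (a blunter outline).

The thickness peak is anchored just behind the gill cover:
q = 1.365 · (head length / total length), which puts it near one-third of
the body length.  This anchoring is the geometric channel through which
the demarcation line carries the head-cut signal, as it does in real fish;
its offset factor is treated as fixed anatomy.  Real fish vary in the
peak-to-gill offset, so this is an idealization — see Limitations.

The default cross-section exponent is e = 50: a slab-like flank, flat to
~1% over 90% of the section with a narrow rim.  Two considerations fix
this.  A deep-bodied fish lying on its side does present a nearly flat
flank; and the downstream Kalman filter, with the prescribed covariances,
has a ~30-sample response lag (see below), so it can only track sections
whose interior varies slowly.  Rounder flanks (e ≲ 20) make the causal
filter smear the section rim and *raise* the per-point error above the raw
noise level.  The exponent is a per-fish parameter, so that regime can be
studied deliberately.

### Scanning and noise

Frames sit at x = k·Δx (Δx = 3 mm, giving 70–80 frames per fish, enough to
resample to 60 features) covering the fish plus a 9 mm belt margin; the
scan trigger is taken to align the first frame with the fish arrival, as a
hardware trigger does.  Each frame holds 640 points across a 160 mm
lateral span (laser wider than any fish), belt plane at 250.32 mm in the
sensor frame.  Per point: Gaussian noise (sd 0.3 mm), impulse outliers
(rate 0.01 per point, ±5 mm), and a per-frame sinusoidal vibration offset
(amplitude 0.2 mm, 0.13 cycles/frame, random phase per scan).  All
randomness flows from one seeded generator per call; identical inputs give
bit-identical clouds.

## Preprocessing

### Threshold segmentation

Within a frame, the fish run is the maximal contiguous region bounded by
the first and the last adjacent-point height jump with |Δz| > T (default
T = 5 mm; the body silhouette jumps ≥ 12 mm even at the tail, belt noise
stays below ~1 mm).  Each edge is treated independently; a frame with at
most one super-threshold jump is all belt.

With the default noise an isolated +5 mm impulse on the belt produces two
jumps that straddle the threshold, so roughly every other impulse fakes a
fish edge; with ~6 impulses per 640-point frame, the raw run is stretched
beyond the fish in most frames.  The pipeline therefore refines each raw
run before filtering: the belt level is estimated as the median of the
frame's flanking belt points, and the run is cut back to the contiguous
region exceeding belt + T around the run maximum.  A genuine cross-section
clears the belt by ≥ 12 mm at every interior point, an impulse does not.
Runs narrower than 5 points (a real section is ≥ 100 points wide at this
resolution) are discarded as spurious.  Refining on the *raw* run is
essential: filtering first lets the causal Kalman smear belt level into
the section before any trim can see the boundary.

### Kalman filter

A scalar constant-position (random-walk) model, the model exactly
parameterized by the three prescribed covariances: process q = 10⁻⁴ mm²,
measurement r = 0.1 mm², initial P₀ = 1 mm².  Predict P ← P + q; update
K = P/(P + r), with the state initialized at the first sample.  The gain
sequence depends only on (q, r, P₀) and converges to the Riccati fixed
point K∞ = Pp/(Pp + r) with Pp = (q + √(q² + 4qr))/2 ≈ 0.0032, i.e.
K∞ ≈ 0.031 — an effective averaging window of ~30 samples.  This is why
flat-top sections are the only regime in which the filter helps (above).
The recursion is applied along each radial profile (within-frame); the
gain sequence is shared, so all runs of a cloud are filtered in one
vectorized batch, padded causally and trimmed.

### Median filter

Sliding-window median over index offsets [−2, +1] (the stated "left and
right rank 2 and −1" read as an asymmetric 4-point window; a negative
right rank has no standard meaning, so the magnitudes are used as window
extents — both are configurable, including the symmetric 5-point window).
Edges truncate the window to valid indices rather than padding, so no data
is invented at the fish boundary.  Order is Kalman first, then median.

## Features

The demarcation line is h(x) = max of the frame's filtered heights minus
the frame's own belt-level estimate (which also cancels per-frame
vibration offsets).  Lines have 70–80 points depending on fish length, so
each is linearly interpolated onto p equally spaced positions spanning its
own [min x, max x]; p = 60 by default.  That number is pinned by the
emulated study's own figures: its first eigenvalue 43.031 is printed as
71.718% of total variance, and for correlation-matrix PCA the total is the
variable count — 43.031/0.71718 = 60.0.

PCA conventions: Z-scores use the sample (n−1) standard deviation;
D = ZᵀZ/(n−1); eigenvalues sorted descending (their sum equals p);
the selected count is the smallest m whose cumulative explained-variance
fraction reaches the target (default 0.95).  Coefficient vectors are
Pᵢ/√λᵢ, which makes training scores unit-variance — the convention that
keeps the downstream learning rates meaningful.  (The literal Pᵢ/λᵢ
scaling is available via `coefficient_scaling="lambda"`.)  Component signs
are fixed by making each component's largest-magnitude loading positive;
signs are otherwise arbitrary and irrelevant to the regressors, but
determinism requires a rule.  The pipeline fixes three components (the
count the variance rule selects on this data) so the regressor interfaces
are stable; the rule's own selection is recorded on the PCA model.

## Regressors

All three operate on standardized inputs and targets (training-set
mean/sd), with predictions mapped back to mm.  Training is deterministic
given a seed.

**LS-SVM.**  Dual system [[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y] with RBF
kernel k(u,v) = exp(−‖u−v‖²/2σ²), solved exactly by LU factorization.
Note a naming trap: this package uses the standard convention — γ (`gam`)
regularizes, σ² (`sig2`) is the kernel width — while the emulated study
labels σ² the "penalty" and γ the "kernel" parameter (its printed optimum
even falls outside its own σ² search box, evidence of swapped labels).
Search ranges are mapped by role: penalty ∈ [0.1, 100] → γ, kernel
∈ [0.01, 100] → σ².  Hyperparameters are found by PSO (swarm 20, 100
iterations) in log₁₀-space — both ranges span three decades, which linear
search explores poorly — minimizing 5-fold cross-validated RMSE with folds
fixed from the seed; the model is refit on all data at the optimum.

**PSO.**  Canonical inertia-weighted swarm: v ← ωv + c₁r₁(pbest − x) +
c₂r₂(gbest − x) with c₁ = c₂ = 2, ω decayed linearly 0.9 → 0.3, velocities
and positions clipped to their boxes, fitness history = running global
best (non-increasing by construction).

**PSO-BP.**  One hidden layer of 10 sigmoid units, linear output (the
"ten layers" of the source description read as ten neurons; its own figure
shows a single hidden layer).  All 51 parameters are flattened into
particle positions (positions [−2, 2], velocities [−1, 1], swarm 20, 200
iterations) minimizing training MSE; the best particle initializes
full-batch gradient descent (rate 0.09, up to 1000 iterations, stop at
MSE ≤ 10⁻⁵).  Gradients are analytic and verified against central finite
differences.  The trainer returns the best-loss parameters seen, so
refinement can never end worse than the swarm's solution; a pure-PSO mode
(`refine=False`) is available.

**LSTM.**  The three scores enter as a 3-step univariate sequence through
a standard cell (sigmoid forget/input/output gates, tanh candidate,
c_t = f∘c_{t−1} + i∘g, h_t = o∘tanh c_t) with hidden size 16 (the source
does not state one), zero initial state, forget-gate bias initialized at
1, and a dense layer to one output.  Training is full-batch
backpropagation through time, gradients clipped at global norm 1, learning
rate 0.005, 200 epochs, dropout 0.2 applied to the hidden-to-output path
only (recurrent dropout placement is unstated; output-path dropout is the
conservative reading), disabled at inference.  The parameter updates use
Adam: the stated recipe — an *initial* learning rate, a gradient
threshold, a maximum epoch count — is the signature of standard deep
learning toolchains whose LSTM trainers default to Adam, and plain
gradient descent at rate 0.005 moves the parameters by at most ~1 unit in
200 full-batch steps, far too little to fit; the BPTT gradients themselves
are verified against finite differences independently of the optimizer.

## Evaluation

R² = 1 − SSE/SST, RMSE, MAE, and RPD.  RPD is reported primarily as
SD(observed, n−1)/RMSE; the algebraically related form 1/√(1−R²) is equal
only in expectation and is exposed as a secondary field (on the emulated
study's own tables the two disagree, and SD/RMSE reproduces its printed
values).  Interpretation bands: R² > 0.82 usable, R² > 0.9 excellent,
RPD > 2.5 accurate and reliable.  The split is a uniform random 154/50
partition of 204 samples (not stratified; stratification is not described
for the emulated design).  PCA is fitted on all samples before splitting,
matching the emulated procedure; only the regressors see the split.

## Problem sizes and runtime

The default study — 204 fish × ~78 frames × 640 points (~10M points),
full preprocessing, PCA and all three trained models — runs in under half
a minute on one CPU; the test suite completes in about a minute.  Unit
tests use 40–80 fish and reduced swarm/epoch budgets where the full sizes
add nothing to the property under test.

## Limitations

* The generator is a geometric surrogate, not an optical simulation: no
  speckle, occlusion shadows, surface reflectance, or multi-fish scenes.
  Fish are axis-aligned and trigger-aligned; pose variation is not
  modelled.
* The head-cut signal reaches the surface through two idealized couplings
  — a fixed thickness-peak-to-gill offset and near-isometric allometry.
  Passing the end-to-end tests shows the *pipeline* recovers geometric
  information at realistic noise; it cannot validate those anatomical
  couplings, which on real fish carry extra scatter (the emulated study's
  real-data accuracy, R² ≈ 0.91–0.95, is of the same order as the
  synthetic results here, but that agreement is consistency, not
  validation).
* The prescribed Kalman covariances suit slowly varying sections only;
  per-point error reduction degrades for rounded flanks (cross-section
  exponents below ~20), although the demarcation line itself, being a
  flat-top maximum, is robust to this.
* Degenerate inputs are rejected, not repaired: zero-variance feature
  columns, constant targets, singular LS-SVM systems and diverging network
  fits raise typed errors with diagnostics.
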