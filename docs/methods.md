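# Methods

`cardiomap` plans cardiac voltage-mapping sequences by active learning on a
Gaussian-process (GP) surrogate of the voltage field. This note records the
model, the algorithmic choices that were genuinely open, the numerical
conventions, and what the synthetic benchmark does and does not demonstrate.

## Surrogate model

The voltage field over a candidate set V (a 2D lattice or the vertices of a
triangulated endocardial mesh) is modelled as a zero-mean GP with kernel
K(·,·) and i.i.d. Gaussian observation noise σ². Conditioning on the mapped
set A = (X, y) gives the Gaussian predictive distribution

    μ* = K(X*, X) [K(X,X) + σ²I]⁻¹ y
    Σ* = K(X*, X*) − K(X*, X) [K(X,X) + σ²I]⁻¹ K(X, X*)

Implementation notes:

- Linear systems are solved by Cholesky factorization with an adaptive
  jitter ladder (start 1e−10, escalate ×10, cap 1e−4), never an explicit
  inverse. A Gram matrix that is exactly singular because of duplicated
  points at σ² = 0 is reported as ill-conditioned rather than silently
  regularized, since the jitter would quietly average conflicting values.
- The zero-mean assumption is taken literally; every caller that regresses
  real values (benchmark, mapping-run estimates, CV scoring) subtracts the
  training mean and adds it back to the predictive mean. Predictive
  *variances* are unaffected by this centring.
- Kernel families: linear (with a constant offset, `σ_f²(1 + x·x′/l²)`, so
  affine fields are representable), squared exponential, Matérn, and
  rational quadratic. Matérn smoothness is restricted to ν ∈ {1/2, 3/2,
  5/2} (closed forms); the default is ν = 5/2 — a twice-differentiable
  field matches the smoothness of clinical voltage maps — and is exposed in
  `KernelSpec`. Observation noise defaults to 0.01·var(y) when a caller has
  data but no stated noise level.

## Acquisition: posterior entropy, PE and IE

Candidates are scored one at a time, so the differential entropy
H = ½ log v + ½ log 2πe of the scalar predictive variance v is used
(natural log; only the argmax ranking matters).

- **PE (pure exploitation)** scores every unobserved candidate under the
  fixed prior hyperparameter θ₀. It consumes no randomness: a PE sequence
  is a deterministic function of the field, θ₀ and the start point.
- **IE (implicit exploration)** maintains a particle approximation of the
  hyperparameter posterior p(θ_A) and scores each candidate by the
  *expectation over particles* of the per-particle entropy. The
  alternative — entropy at the posterior-mean hyperparameter — is
  implemented behind `ie_score="mean_theta"`, but the expectation is the
  default because it preserves multimodal hyperparameter uncertainty.
- **Travel cost** divides each score by the Euclidean distance s from the
  current catheter tip and masks candidates closer than s_min (default 5%
  of the domain bounding-box diagonal when travel cost is on). Distances
  are straight-line by default even on meshes; a `geodesic` config option
  switches to shortest-path distances along mesh edges (Dijkstra on the
  Euclidean-weighted edge graph). Note the quotient H/s is taken exactly
  as defined even though H can be negative for very small variances; with
  the default unit-scale priors this regime is not reached.
- Ties are broken by the lowest candidate index, making every selection
  deterministic and testable against exhaustive search.
- Observed points leave the candidate set permanently; re-visits are
  forbidden.

The closed loop (`run_mapping`) needs only the first mapping point: observe
the current point, update the hyperparameter posterior (IE), record the
field estimate and the max/median posterior SD over unobserved points, then
select the next point. The exact step order — weight update, then
resample-move, then selection — is a design choice; reversing update and
move only delays the move's effect by one step.

## Regularized particle filter

p(θ_A) is tracked over (log l, log σ_f²); σ² and ν stay fixed to keep the
particle dimension at 2. The initial cloud is uniform on
[θ₀/(1+spread), θ₀·(1+spread)] per component (symmetric about θ₀ in the log
domain), with spread 0.5 and m = 100 particles by default. Each new
observation multiplies every particle's weight by the one-step GP
predictive density of the observed value under that particle's
hyperparameters — the natural per-particle likelihood, since the marginal
likelihood factorizes over one-step predictives.

The resample-move step runs after every update: systematic resampling, then
a move drawn from the Epanechnikov kernel at the optimal bandwidth
h = A(K)·m^(−1/(d+4)) with A(K) = [8 c_d⁻¹ (d+4)(2√π)^d]^(1/(d+4)) and the
Cholesky factor of the weighted particle covariance (a scale factor on h is
config-exposed, default 1). Two deliberate choices:

- **Kernel-location shrinkage.** At m = 100 and d = 2 the optimal bandwidth
  is h ≈ 1.11, which would inflate the particle covariance by h²/(d+4) ≈
  21% per step — more than a single observation's likelihood can remove, so
  the filter would never concentrate. Resampled particles are therefore
  first contracted towards the weighted mean by √(1 − h²/(d+4)) before the
  kernel move (the classic variance-preserving shrinkage construction for
  kernel-smoothed resampling). With shrinkage the move preserves the first
  two posterior moments exactly, and the filter demonstrably concentrates
  and tracks (see the recovery tests).
- **Move every step, ESS as diagnostic only.** The effective sample size
  1/Σw² is logged but does not gate the move; the move happens in every
  generation.

Sampling from the d-variate Epanechnikov kernel uses the closed-form radius
inverse CDF for d = 2 (r² = 1 − √(1−u)), the median-of-three-uniforms trick
for d = 1, and rejection sampling otherwise.

A residual behaviour worth knowing: the per-step σ_f posterior mean keeps
fluctuating by a few percent (single-observation likelihoods are weakly
informative about scale, and the kernel move re-disperses every step).
Consequently IE's reported median-uncertainty curve declines with
occasional small upticks — about 80–85% of steps are non-increasing in our
synthetic runs — whereas PE's curve is exactly monotone (a theorem for
fixed hyperparameters: every point's variance is non-increasing in
observations, and the removed point is the variance maximum).

## Kernel prior from demonstrations

`fit_kernel` learns θ₀ from concatenated expert mapping sequences
(ordering ignored, position/value pairing preserved; exact duplicates
removed per case). Per family, hyperparameters maximize the log marginal
likelihood via L-BFGS-B on log parameters with analytic gradients
(dL = ½ tr((αα′ − K⁻¹)∂K)), from random restarts: l log-uniform on
[0.05, 5]× the domain diameter, σ_f² log-uniform on [0.1, 10]×var(y), σ²
log-uniform on [1e−3, 0.1]×var(y). Families are then ranked by point-wise
held-out RMSE (5-fold CV over points, seeded folds, fixed hyperparameters —
no per-fold refit; both held-out and training RMSE are reported because the
original protocol does not say which was used). Only an isotropic length
scale is learned; ARD is out of scope.

A caveat established while validating: on data *generated* from a smooth
Matérn GP, the Matérn/SE/RQ families are statistically indistinguishable by
CV-RMSE (differences < 0.005 at n = 200), so "the Matérn family wins" is
not a reproducible event even when Matérn is the generative truth; what is
reproducible is that the length scale recovers within ±30%, that Matérn is
always within noise of the winner, and that the linear family always loses
on nonlinear fields. The tests assert exactly that.

## Geometry-coverage baseline ("baseline-approx")

The comparison planner is a greedy coverage rule: each step selects the
candidate maximizing `ratio·d̂ + (1−ratio)·ĉ`, where d̂ is the min-distance
to the already-selected set and ĉ the per-vertex curvature magnitude, both
min–max normalized over the remaining candidates. ratio = 1 is farthest-
point coverage ("distance only"); ratio = 0.5 mixes in curvature so points
cluster on highly curved anatomy. The rule is an *approximation* anchored
by those two behaviours — the original mesh-decimation pipeline it stands
in for is not reproduced — and all outputs are labelled `baseline-approx`.
The convention that `ratio` weights the distance term is fixed by the
"ratio = 1 ⇒ distance only" anchor. Curvature is the discrete mean-curvature
magnitude from the cotangent Laplacian with barycentric vertex areas
(H = |Σ(cot α + cot β)(x_i − x_j)| / 4A_i), validated on spheres (H → 1/R).

## Domains and preprocessing

- The benchmark lattice places n×n points on [0, extent]² *including both
  boundaries* (spacing extent/(n−1)); the defaults 60×60 over 10×10 give
  3600 candidates. A cell-centred variant is available.
- Meshes load from PLY/OBJ (via trimesh) or legacy ASCII VTK POLYDATA (own
  minimal parser); non-triangular faces are fan-triangulated. Coordinates
  are dimensionless pass-through.
- Duplicate mapping points are removed by a greedy first-kept rule within
  tolerance (default 1e−6, i.e. exact duplicates; exported clinical data
  with near-duplicates should raise it).
- Scattered points project to their Euclidean-nearest mesh vertex
  (point→vertex direction); multiple points on one vertex are averaged.

## Synthetic benchmark and its limits

Ground truth for the 2D benchmark is a sum of k isotropic Gaussian bumps:
centres uniform on the square, σ log-uniform on [extent/20, extent/4],
amplitudes uniform on [0.5, 1.5]; k ∈ {5, 20, 40, 60} with 20 trials per
group, m = 30 points from the grid centre, prior θ₀ = Matérn(l = 1,
σ_f² = 1) and σ² = 1e−3 (the oracle is noiseless; the small σ² is a
conditioning choice). Both methods' observations are GP-regressed onto the
full grid — IE under its final particle-mean hyperparameter, the baseline
under θ₀ — and compared to truth by SSIM (Gaussian 11×11 window, σ = 1.5,
C1 = (0.01L)², C2 = (0.03L)² with L the truth dynamic range, border crop;
verified to 1e−6 against scikit-image). Each trial's field is shared by
both methods.

What this shows: IE's mean SSIM exceeds the geometry baseline's in every
group, with fully reproducible seeded runs. What it does not show: with
all-positive amplitudes, summing more bumps makes the field *relatively
smoother* (a central-limit effect), so SSIM rises with k here rather than
falling as in mapping tasks where complexity grows with component count;
absolute SSIM levels are therefore generator-specific and should not be
read as clinical accuracy. The generator also idealizes reality in other
ways: no measurement noise, no anisotropy, no mesh geometry, and no
low-voltage scar morphology beyond what random bumps produce.

Problem sizes used by the test-suite were chosen to exercise the full
study configuration where it matters (the benchmark runs at its native
4×20×30 scale) and small domains (≤400 points) for the qualitative
uncertainty-curve and recovery properties.

## Known limitations

- Geodesic travel distances are the edge-graph approximation (no exact
  polyhedral geodesics); on coarse meshes they overestimate true surface
  distance.
- The particle filter fixes σ² and ν; fields whose noise level drifts
  during a procedure are not tracked.
- Greedy one-step-ahead selection only; no batch or lookahead planning.
- SSIM requires a regular grid; mesh runs are evaluated by mean-L1 only.
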