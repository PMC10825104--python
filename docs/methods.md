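# Methods

This note documents the models, numerical choices, and limitations of
`mdifkit`, in the order the pipeline runs.

## Compartment model and conventions

The irreversible two-tissue compartment model (2TCM) for [¹⁸F]FDG has rate
constants K₁ (mL/g/min), k₂, k₃ (min⁻¹) and blood volume fraction V_b
(mL/g), with k_f = k₂ + k₃, net clearance K_i = K₁k₃/k_f, and distribution
volume V_d = K₁/k_f. Time is minutes everywhere inside the package; file
interfaces use seconds, the PET convention, with explicit `_s` suffixes.
Activity concentrations are kBq/mL (arbitrary units in simulations). A
brain density of 1.05 g/mL is exposed as a configuration constant for any
mL↔g conversion. Tissue model curves are evaluated at frame mid-times by
default; `twotcm_forward(..., frame_average=True)` instead averages the
model over each frame (Simpson on frame start/mid/end). Mid-time evaluation
is the package default because it is the common practice for frame
schedules this dense; the switch exists to quantify the difference.

## Convolution scheme

Both the forward model and the input-function inversion convolve sums of
decaying exponentials with a sampled curve. Clinical frame schedules are
strongly non-uniform (2 s to 300 s frames), so discrete/FFT convolution
would introduce spacing-dependent bias. Instead, the sampled curve is
treated as piecewise linear between nodes (extended through (0, 0) before
the first mid-time), and the convolution with e^(−λt) is computed exactly
per segment with the stable recursion
y_{i+1} = e^(−λΔ) y_i + closed-form segment integral. Small λΔ uses a
series expansion of the segment integrals to avoid cancellation; λ = 0
yields the exact running integral. When k_f < 10⁻¹² min⁻¹ the tissue kernel
collapses to pure trapping (constant K₁).

## Input-function inversion (MDIF)

The continuous-time inversion expresses the plasma input as the whole-brain
curve plus a two-exponential kernel (decay constants α₁, α₂ with
α₁+α₂ = 2a, α₁α₂ = b) convolved with it. Two numerically equivalent
schemes are implemented:

- **`scheme="exact"` (default).** The sampled forward operator is linear
  and causal in the plasma samples, hence a lower-triangular matrix; the
  plasma curve is recovered by a triangular solve. This makes the inversion
  the *exact* inverse of the forward model on any frame schedule. The
  choice matters for simultaneous estimation: with the closed-form kernel
  alone, the piecewise-linear interpolant of the whole-brain samples
  differs from the true continuous curve between coarse late frames,
  leaving a ~0.5% systematic residual on the 50-frame schedule that biases
  jointly fitted parameters by several percent. The exact discrete inverse
  removes that bias entirely; noiseless identifiability then holds to
  optimizer precision.
- **`scheme="kernel"`.** Direct evaluation of the closed-form expression
  with the same piecewise-linear convolution primitive. It agrees with the
  exact scheme to O(h²) in the frame spacing (<0.1% on a 0.01-min grid,
  <2% on the clinical schedule) and is kept as an independent cross-check
  and as the analytic reference form. When (a²−b)/a² < 10⁻¹⁰ the two decay
  constants are treated as confluent and the analytic limit
  −((k₃−a)t + 1)e^(−at) is substituted; the t·e^(−at) convolution reuses
  the exponential primitive via t·(e∗c) − e∗(t c), with t·c treated as
  piecewise linear (second-order error, measure-zero branch).

V_b = 0 or R = 0 make the inversion singular and are rejected.

## Simultaneous estimation

The joint cost is the unweighted sum of squared region residuals plus
squared anchor residuals (anchor weight 1 in MDIF mode; 10 in IDIF mode,
where the input scale is otherwise weakly constrained). The input function
is evaluated at anchor times by linear interpolation between frame
mid-times. Anchors are treated as plasma concentrations compared directly
to the plasma input function.

Tissue parameters are box-bounded — upper (0.2 mL/g/min, 0.4 min⁻¹,
0.2 min⁻¹, 0.10 mL/g), lower 0.01 — with the distribution-volume constraint
V_d < 1 (K₁ < k₂+k₃) enforced smoothly by fitting the ratio
s = K₁/(k₂+k₃) ∈ (0.01, 0.999) instead of K₁ itself. Because the K₁ box
cannot be expressed as a box on s, it is kept by a hinge penalty residual
(weight 10³) that is identically zero at any interior solution; returned
solutions are verified against the boxes post hoc. IDIF mode fits the
tri-exponential input parameters (A₁, A₂, A₃, λ₁, λ₂, λ₃) with upper
bounds (4000, 100, 50, 25, 1, 0.1) and lower bounds 0, plus a delay boxed
to ±10 s around an a-priori estimate from the whole-brain TAC rise (first
crossing of 5% of the early-2-min maximum, back-interpolated).

Optimization is bound-constrained trust-region-reflective nonlinear least
squares (ftol = xtol = 10⁻⁹, up to 2000 function evaluations per start).
Since no starting values are canonical, a seeded multi-start is used: 8
Latin-hypercube draws inside the box plus the box's geometric midpoint;
the lowest final cost wins. On the noiseless built-in study every start
converges to the same optimum.

Two structural notes. First, with exact anchors and noiseless data the
cost at the generating parameters is identically zero (the exact-inverse
property above), which the tests assert. Second, without anchors the
IDIF-mode cost is invariant under C_p → aC_p with K₁ and V_b rescaled —
the input scale is a gauge freedom, which is precisely why anchors are
required; the tests check the scale-invariant content of the ablation.

## Standalone fitting, Patlak, CMRGlu, CV of K_i

Standalone weighted fits use bounds 0..(0.5, 0.5, 0.2, 1.0) with no
distribution-volume constraint, a single start at (0.1, 0.15, 0.05, 0.05)
(the bounded problem is well behaved on regional TACs), and frame weights
w_i ∝ Δt_i / C_wb(t_i) normalized to max 1, with non-positive whole-brain
frames given zero weight. The weighted residual sum (WRSS) is reported for
the first 3 min and the full 60 min (frames selected by mid-time). The
covariance of (K₁, k₂, k₃) is approximated as (JᵀJ)⁻¹·WRSS/T from the
weighted Jacobian, and CV(K_i) = 100·σ/K_i with σ² propagated through
∇K_i = (k₃/k_f, −K₁k₃/k_f², K₁k₂/k_f²); V_b uncertainty is deliberately
excluded, matching the three-parameter gradient.

Patlak analysis regresses C(t)/C_p(t) on ∫₀ᵗC_p/C_p(t) over frames with
mid-time > t* (default 20 min; at least 3 points required). The plasma
integral is trapezoidal from t = 0 with the left edge closed at (0, 0).
The slope is reported ×100 (mL/100 g/min) and converted to CMRGlu with
CMRGlu = K_i·[glucose]/LC (LC default 0.52). For V_b > 0 the fitted slope
estimates (1−V_b)·K_i — the usual Patlak behavior — so the compartmental
and graphical estimates are expected to differ by a factor (1−V_b).

Input functions are compared by trapezoidal AUC over the windows 0–5,
5–10, 10–30 and 30–60 min (curves interpolated at window edges), the AUC
ratio per window, and the overall percent difference 100|m₁−m₂|/m̄.

## Clustering

Voxel TACs are grouped per tissue class by k-medoids (Euclidean distance
on raw frame values, no normalization), best of 10 random restarts, each a
Voronoi-style iteration (assign to nearest medoid; recompute each medoid as
the in-cluster point with minimal summed distance) capped at 500
iterations. The within-cluster cost is non-increasing per iteration and
the run is bitwise deterministic for a given seed. For clustering *only*,
frames are first denoised with a HYPR-style composite-guided filter:
out_f = C·G(img_f)/(G(C)+ε) with C the duration-weighted frame sum, G a
Gaussian of 3 voxels SD by default, and ε = 10⁻¹² guarding the division; an
all-zero composite is rejected. Cluster mean and medoid TACs are always
extracted from the original image so denoising bias cannot reach
quantification. Selection keeps the n largest clusters per tissue class
(default 3 of 5), grey matter first, ties broken by lower cluster index.
An optional rule drops the cluster whose mean TAC peaks earliest — a
vascular/non-brain signature; this is a logged heuristic for a qualitative
exclusion, not a validated classifier.

## The built-in simulation study

The reference study uses a tri-exponential theoretical input (A₁ = 850
a.u./min, A₂ = 22, A₃ = 21 a.u., λ = 4, 0.12, 0.01 min⁻¹, delay 0),
sampled on the 50-frame, 60-min clinical schedule (15×2 s, 6×5 s, 8×15 s,
4×30 s, 5×60 s, 3×120 s, 8×300 s, 1×240 s), six regional parameter sets
with distinct kinetics, a whole-brain TAC generated from the reported
average parameter set (0.090, 0.117, 0.066, 0.067 — note the reported V_b
exceeds the arithmetic mean of the six regional entries; the reported set
is taken as authoritative since it defines the whole-brain curve), R = 1
with C_b = C_p, and two anchors read from the *analytic* input at 28.5 and
53.5 min (both frame mid-times). The study is noiseless and fully
deterministic.

The general generators add Gaussian frame noise with variance proportional
to value/duration (σ_i = scale·√(C_i/Δt_i), seeded; first frame clipped at
0), and a voxelized phantom that fills contiguous slabs of a small volume
with region TACs plus voxel-level noise, emitting WB/GM/WM masks and a
ground-truth label volume. The default noisy-phantom scale of 0.5 gives
early-frame noise comparable to voxel-level clinical data. What these
synthetic data do *not* emulate: reconstruction noise correlations, partial
volume effects, scanner PSF, motion, or frame-count statistics — so passing
tests demonstrate correctness of the estimators under the model, not
robustness to every real-data artifact.

## Known limitations

- Only the plasma input is recovered; whole-blood recovery and metabolite
  correction are out of scope (R is assumed constant).
- The reversible-tracer and one-tissue variants of the inversion are not
  implemented.
- The SIME fitters assume all TACs share one frame schedule.
- The non-brain-cluster exclusion is a heuristic.
- Voxelwise (parametric-image) estimation is not included; the package
  targets regional quantification.
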