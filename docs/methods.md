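# Methods

This note records the models implemented in `renalseg`, their assumptions,
the parameter defaults and the numerical choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Notation

A volume `g` assigns each voxel `p = (x, y, z)` of the lattice
`R = {0..X−1} × {0..Y−1} × {0..Z−1}` a gray level in `Q = {0..Q−1}`
(default `Q = 256`; real-valued inputs are linearly quantized).  A region
map `m` assigns each voxel a label in `L = {0, 1}` (0 background, 1
kidney).  Arrays are indexed `[x, y, z]`, 0-based, `x` fastest-varying;
voxel spacing is anisotropic (default 1.28 × 1.28 × 4 mm, the acquisition
matrix and section thickness of the emulated protocol).

## Preprocessing

Intensity inhomogeneity is modelled as a smooth multiplicative field:
`g = u · f`.  `correct_bias` estimates `log f` by iterated low-pass
filtering of the log-residual (Gaussian kernel of physical scale
`smoothness_mm`, default 25 mm, 8 iterations), normalized to unit
geometric mean over the foreground.  The iteration acts as a Landweber
refinement, so field components near the cutoff scale are progressively
recovered rather than attenuated once.  The estimator is non-parametric in
the sense that no tissue model enters; only the smoothness scale does.
Histogram equalization (monotone CDF remap on `{0..Q−1}`) follows bias
correction; the bias-then-equalize order is a design choice — equalization
is non-linear, so removing the multiplicative field first keeps the field
model valid.

## First-order appearance: LCDG

The empirical marginal of gray levels is approximated by a signed mixture
of *discrete Gaussians* — Gaussian CDF differences at half-integer bin
boundaries, renormalized over `{0..Q−1}` — with exactly two positive
dominant components (one per class) and up to `max_subordinate` (default 8)
sign-alternating subordinate components.

- Dominant fit: 2-component EM on the histogram, weighted-median moment
  initialization, σ floored at 0.5 gray levels (spike histograms hit the
  floor).
- Subordinates: added greedily from the largest contiguous same-sign mode
  of the residual (empirical − model), weight carrying the residual sign;
  negative weights are capped so the total density stays non-negative at
  every level; a component is kept only if it reduces the L1 fit error by
  more than `tol` (default 1e-4).  A final projected-least-squares pass
  re-solves all weights under the same constraints.  This realizes the
  sign-alternate subordinate behavior without reproducing any particular
  published fitting schedule, which is not specified to this level.
- Class split: each subordinate joins the dominant class that minimizes
  the overlap of the two weighted class submodels; submodels are clipped to
  non-negative and renormalized, so `Pr(q|l)` are proper distributions.
  The threshold `t*` is the crossing of the weighted submodels between the
  dominant means (midpoint fallback, flagged, if no crossing exists).
- Class assignment: which dominant component is "kidney" is configurable.
  The default for a standalone fit is kidney = brighter; the pipeline
  default is `auto`, which picks the assignment whose brightness ordering
  agrees with the mean intensity inside the shape prior's confident region
  (`Pr_sp > 0.75`).  This matters because kidney/background contrast
  reverses between low and high b-values.

## 4th-order spatial MGRF

Label interactions are modelled by a translation-invariant Gibbs
distribution over three groups of clique families inside the
26-neighborhood:

- 13 pair families (one per direction modulo sign),
- 13 collinear triple families (voxel plus both opposite neighbors),
- 9 planar 2×2 quadruple families (three axis-aligned square orientations
  plus six diagonal-plane squares), spanned by offset pairs `(u, v)` with
  the clique `{0, u, v, u+v}`.

The family set is a configuration object; the published description shows
example cliques but does not enumerate the families, so this default was
chosen for full 26-neighborhood coverage and translation invariance.

Only label-equality classes are scored.  For binary labels the quadruple
classes are: all-equal (`eq4`, baseline probability 1/8 under equiprobable
labels), exactly-three-equal (`eq3`, baseline 1/2), and two-and-two
(`eq2`, baseline 3/8).  These baselines are the unique choice consistent
with the centred frequencies `f4 = F_eq4 − 1/8`, `f3 = F_eq3 − 1/2`,
`f2 = F_eq2 − 3/8` and the variance weights `7/64 = (1/8)(7/8)`,
`1/4 = (1/2)(1/2)`, `15/64 = (3/8)(5/8)` in the scale estimator

    lambda* = sum_a (f4² + f3² + f2²) /
              sum_a (7/64 f4² + 1/4 f3² + 15/64 f2²).

Potentials are the analytic plug-in estimates `V2:eq = 4(F_eq − 1/2) =
−V2:ne`, `V3:eq3 = (16/3)(F_eq3 − 1/4) = −V3:eq2`, and `V4 = λ*(f4, f3,
f2)` per quadruple family.  On an equiprobable i.i.d. map all estimates
vanish up to sampling noise (the acceptance suite bounds them by 0.05 on
64³ maps).  Cliques crossing the lattice boundary are skipped, keeping the
frequencies unbiased.

Downstream the model is consumed only through the voxel-wise *conditional*
probabilities `Pr_V:p(l) = exp(E_p(l)) / (exp(E_p(0)) + exp(E_p(1)))`,
where `E_p(l)` sums the potentials of all cliques containing `p` with the
voxel's label replaced by `l`.  The partition function is never computed.
A chromatic Gibbs sampler (27 colours, period 3 per axis, so concurrently
updated sites never share a clique) is provided for estimation-consistency
checks; it is deterministic given its seed.

## Adaptive shape prior

Training pairs (preprocessed b0 scan, expert map) are co-aligned to a
reference subject chosen by maximum normalized cross-correlation with the
test scan (after integer centroid pre-alignment; ties break to the lowest
index).  Registration is a multi-resolution (3 levels) demons-style
scheme: displacement updates follow the normalized SSD gradient, each
update is fluid-smoothed (σ = 1 voxel) and the accumulated field
elastic-smoothed (σ = 1.5 voxels), updates capped at 1.5 voxels/iteration,
30 iterations per level.  The full-resolution field is only accepted when
it lowers the SSD, so `SSD(warped, fixed) ≤ SSD(moving, fixed)` holds by
construction.  The backend is pluggable; maps are always warped with
nearest-neighbor interpolation and stay binary.

For a test image, the reference volume is registered onto it, giving a
field that maps each test voxel into database coordinates.  Around the
mapped (nearest-voxel) location a window — initially 3×3×3, grown by +2
per axis up to 11×11×11 — is searched across *all* aligned training
volumes for voxels within ±10 gray levels (of 256) of the test voxel's
intensity; `Pr_sp:p(1)` is the fraction of kidney labels among the
matches.  If the largest window holds no intensity match, the label
relative occurrence in that window (ignoring intensity) is used, which
guarantees termination with a valid probability.  The window, tolerance
and cap are configuration values; none is dictated by the published
description.  Because the search is appearance-driven, moderate
registration error is absorbed: the acceptance suite checks that a
deliberate 2-voxel misalignment shifts the thresholded prior by at most
0.05 DSC.  The prior's reach is bounded by the maximum window half-width
plus residual alignment error, so "far exterior" in the tests means
more than 8 voxels outside the true kidney.

## Deformable boundary

`Φ` is the signed Euclidean distance (honouring spacing) to the boundary
voxel set (object voxels with a 6-neighbor background voxel): positive
inside, zero on the boundary, negative outside.  Evolution follows

    Φ_{n+1}(p) = Φ_n(p) − τ · F_n(p) · |∇Φ_n(p)|

with Godunov upwind gradients and `F_n(p) = |κ(p)| · ϑ_p`, where

    ϑ_p = −Pr_p(1)  if Pr_p(1) > 0.5,   else  +Pr_p(0),

and `Pr_p(1)` is the joint probability built from the three models
(`Ω_kd = Pr(q|1)·Pr_V:p(1)·Pr_sp:p(1)`, `Ω_bg` its complement-factor
counterpart; when both vanish the voxel defaults to `Pr = 0.5` and the
background branch).  Ties at 0.5 take the background branch (strict
majority rule).

The curvature factor enters through its magnitude.  ϑ alone specifies the
direction of motion — the formulation describes it as carrying "magnitude
and direction" — and a signed curvature factor would reverse the data
force wherever the front is concave (at the renal hilum), which makes the
front erode without bound instead of converging; with `|κ|` the boundary
is everywhere attracted to the `Pr_p(1) = 0.5` interface, fast at sharp or
noisy parts of the front and slow where it is already smooth.  `κ` itself
is the mean curvature `div(∇(−Φ)/|∇(−Φ)|)` by central differences
(positive for convex objects under the positive-inside convention),
clamped to ±1/min(spacing) and zeroed where the gradient vanishes.

Numerical choices: the time step obeys a CFL-style bound
`τ = 0.45·min(spacing)/max|F|` unless fixed in the configuration; updates
are restricted to a narrow band of ±6 voxels around the zero level; Φ is
redistanced every 20 iterations; evolution stops when the zero-level mask
changes by < 0.1 % of its volume for 10 consecutive iterations, or at
`n_max = 120`; an emptied or flooded mask raises an error carrying the
per-iteration change trace.  None of these values is part of the published
method; all are configuration-exposed.

The per-scan pipeline is: fit LCDG → Bayes initial map
(`m_ini(p) = 1` iff `Pr(g_p|1)·Pr_sp:p(1) > Pr(g_p|0)·Pr_sp:p(0)`, ties to
background) → analytic potentials from `m_ini` → joint guidance → evolve
from `m_ini`'s signed distance.  A series is segmented per b-value with
one shared shape prior adapted from the b0 scan.  Two ablations are
wired in: `mgrf_order = 2` (pairwise potentials only) and
`use_shape_prior = False` (uniform prior), mirroring the comparison with
the pairwise-only predecessor model.

## Synthetic phantom cohort

The generator emulates the statistical structure the method assumes, at
the emulated protocol's geometry (1.28 × 1.28 × 4 mm voxels; b-values
from the 0–1000 s/mm² schedule, default subset {0, 500, 1000}):

- a bean-shaped kidney (ellipsoid minus a hilum notch), per-subject
  deformed by smooth random displacement fields (amplitude 3 voxels) for
  inter-subject variability; cortex shell (erosion depth 3) around a
  medulla interior;
- mono-exponential per-tissue decay `S_b = S0·exp(−b·ADC)` with defaults
  cortex 2.0×10⁻³, medulla 1.8×10⁻³ mm²/s, and a smoothly mixed
  background ADC in [1.0, 2.5]×10⁻³ mm²/s with mottled S0 — producing
  high contrast at b0 and heavily overlapping intensities at b1000, the
  regime the method targets;
- Rician magnitude noise (σ = 4 gray levels by default; 8 in the
  high-noise condition), so kidney SNR at b1000 falls below a third of its
  b0 value at the defaults;
- a smooth multiplicative bias field (20 % peak deviation).

Default cohort: 8 subjects of 48³ voxels, which keeps a full
leave-one-subject-out study with ablations within a few CPU-minutes.  All
randomness derives from a single seed; identical seeds give bit-identical
cohorts.

What the phantoms do *not* model: respiratory/cardiac motion between
b-values, eddy-current geometric distortion, k-space artifacts,
multi-organ context (liver, spleen with kidney-like intensities), and
partial-volume mixing beyond quantization.  Passing tests therefore
demonstrate the internal correctness and the designed robustness ordering
of the components (shape prior ≫ spatial model at these conditions), not
clinical-grade accuracy; on phantoms the no-shape-prior ablation collapses
because background tissue shares the kidney's equalized intensity range,
which overstates the prior's dominance relative to real abdominal anatomy.

## Evaluation

DSC = 2|A∩B|/(|A|+|B|) (1.0 when both masks are empty, by convention);
MHD95 = 95th percentile of the *pooled* symmetric boundary-to-boundary
Euclidean distances in mm (pooling both directions before the percentile
is a documented choice; taking the max of directional percentiles is the
main alternative); PKVD = 100·|V_seg − V_gt|/V_gt, deliberately
asymmetric.  Boundary voxels are object voxels with a 6-neighbor
background voxel.  Cohort reports add min/max/mean±SD and a paired
two-sided t-test between two method columns, with zero-variance pairs
flagged rather than tested.

## Known limitations

- The guidance is computed once per scan from the initial map rather than
  re-estimated during evolution; with a grossly wrong initial map the
  spatial model can entrench errors.
- The speed function stalls where the front is exactly flat (|κ| ≈ 0);
  in practice the Bayes initial map places the front close enough that
  this only delays convergence.
- The analytic potential estimator assumes clique-family cardinalities
  close to the lattice cardinality; on very small maps (≲ 8³) the skipped
  boundary cliques bias the frequencies noticeably.
- Registration is intensity-driven SSD; strong bias fields must be removed
  first (the pipeline preprocesses before aligning).
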