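# Methods

This note records the models, estimators, parameter choices and known
limitations of the `ooctrack` pipeline. All lengths are micrometres, times
minutes; chip coordinates use a bottom-left origin with y up (image rows are
flipped on ingest and on rendering).

## 1. Cell detection and population discrimination

Frames are filtered with a Canny edge detector (σ = 1.2 on intensities
scaled to [0, 1]) and fed to a multi-radius circular Hough transform
(scikit-image, perimeter-normalized accumulator). Peaks with score ≥ 0.4
survive a non-maximum suppression processed in descending score: a candidate
is suppressed when its center lies within the radius of an already accepted
detection (one cell cannot contain the center of another; this also removes
small circle candidates supported by arcs of a larger cell's rim).
Populations are assigned by object area `πr²` with the boundary belonging to
the tumor class; the default threshold (120 px² at 1 px/µm) sits between the
default 9 µm immune and 20 µm tumor diameters.

## 2. Constrained proximity tracking

Linking is greedy nearest-neighbour per population with three rules:

* **Reach** — a track links to the closest unclaimed detection within
  `dmax` of its last position (10 px immune, 5 px tumor per frame).
* **Missing** — with no detection in reach the track waits; it may resume
  within the gap budget (10 frames immune, 50 tumor) at the same `dmax`.
* **Conflict** — when two active tracks share the same nearest detection,
  both stop and the detection may seed a new track. Candidate links are
  processed in ascending distance with deterministic tie-breaking, so the
  result does not depend on detection order.

Optional region-of-interest masks — polygon vertex lists in micrometres in
the pipeline config — restrict the detections before linking (chip-region
auto-recognition is out of scope; the masks stand in for it). The `track`
command writes the per-frame detections (after discrimination and masking)
alongside the track CSV.

Tracks spanning fewer than 20 frames are dropped, then fragments of one
population are merged iteratively, closest pair first, to a fixed point:
tumor fragments merge when endpoint-to-start spatial distance ≤ 5 px for any
time gap within the tumor gap budget (a cylinder in `(x, y, t)` — tumor
cells barely move); immune fragments merge when
`sqrt(dx² + dy² + (c·dframes)²) ≤ 5 px` with `c = 1 px/frame` (a sphere —
motile cells drift during gaps). Merges record provenance.

## 3. Random-walk migration descriptors

Per-lapse displacements are pooled over an ensemble; steps across closed
gaps are excluded. For each axis and sign, the step-length magnitudes are
histogrammed (Freedman–Diaconis bins clipped to [5, 200]; trailing bins
with fewer than 5 counts are dropped as sparse tail) and the log-frequency
is fitted linearly in |step| (exponential model) and in step² (half-Gaussian
model). The larger R² selects the model; a difference below 0.01 is
indeterminate. Reported scales are the maximum-likelihood estimates of the
chosen family (mean for exponential, root-mean-square for half-normal).

The motion class maps the four branch models onto phenotypes: exactly one
Gaussian branch per axis on both axes → `drift_xy`; on x only →
`drift_x_only`; all four exponential → `isotropic`; anything else (including
any indeterminate branch) → `indeterminate`.

Turning angles are the signed heading changes of consecutive valid steps
(pairs with a zero-length displacement are skipped and counted).
Histograms use 24 equal bins on (−π, π] normalized to unit sum; the
circular mean and mean resultant length R̄ summarize persistence.

## 4. Encounter stability (Lyapunov coefficients)

Each tumor cell is reduced to a fixed point at its time-mean position (a
warning is emitted when it wanders more than 10 µm from that mean). A PBMC
track is rebased to polar coordinates `(r, θ)` about that point with θ
unwrapped; velocities are central finite differences (one-sided at the
ends); the backward time index sets t = 0 at the closest-approach point.

**Interaction range.** The time-ordered profile `r(θ)` is fitted with one,
two and three least-squares line segments split at candidate time indices
(prefix-sum accumulators make each segment SSE O(1)). A changepoint is
accepted when the 2-segment BIC beats the single line by a margin of 10; a
3-segment model (approach / engaged / leave) supersedes it when it beats the
2-segment BIC by the same margin. The interaction range is `r` at the first
breakpoint. Without a detected changepoint a 50 µm default is used. The
physical interaction range — the contact radius — is defined exactly as
`tc_diameter + pbmc_mean_diameter` (29 µm for the default 20 + 9 µm).

**Linearization window.** Eligible points are the maximal time-contiguous
run containing t = 0 with `r` inside the interaction range. From t = 0 the
window grows one point at a time, choosing at each step the side whose
inclusion keeps the minimum of the two row-fit R² highest; this growth path
is independent of the threshold, and the selected window is the largest one
along the path with both R² ≥ 0.95 (at least 5 points, else the encounter
is indeterminate). Because the path is threshold-independent, window size
is monotone in the R² threshold. When both a detected changepoint and the
default range are available as candidate interaction ranges, the candidate
yielding the larger accepted window is kept.

**Jacobian and classification.** The two rows are fitted affinely,
`v_r ~ 1 + Δr + Δθ` and `v_θ ~ 1 + Δr + Δθ`; the intercepts absorb the
residual drift at the empirical fixed point (with noise, the
closest-approach point need not carry zero velocity), leaving the slope
block — the Jacobian — invariant to that offset. Eigenvalues come from the
trace/determinant formula with first-order standard errors propagated from
the two independent row covariances (for a complex pair, the SE of the
common real part). Classification: both real parts negative → stable, both
positive → unstable, mixed → metastable; any |Re λ| below its standard
error → indeterminate. An eigenvalue time series refits the Jacobian on
growing sub-windows anchored at the window's outer edge.

The polar fit is the primary estimator. A Cartesian cross-check
(`estimate_jacobian_cartesian`) refits the same window in attractor-relative
Cartesian deviations; because the chart change is nonlinear the two
Jacobians agree only for locally linear data, so the cross-check is read for
sign consistency of the stability class, not eigenvalue magnitudes.

## 5. Potential landscape

Each TC with at least one analyzed encounter becomes a truncated parabolic
well `U(x) = −Z_rel · max(0, 1 − d²/R²)` centred on the TC with `R` the
basin (interaction) radius. The default depth policy multiplies `R²` by the
mean |λ₁λ₂| over the TC's stable encounters (curvature × size); alternative
policies use `R²` alone or the number of captured PBMCs. Depths are
normalized so the deepest well has `Z_rel = 1`; a TC with only metastable
encounters is flagged low-confidence; overlapping basins are recorded. The
landscape is the pointwise minimum over wells. This is a heuristic
visualization of the stability results, not an inference of the true
chemokine field.

## 6. Synthetic generators (scope)

* **Phenotype walks** — independent per-axis steps; on a drifted axis the
  step enters the drift half-plane with probability 0.7 and its magnitude is
  half-Gaussian (σ = 2 µm) there, exponential (scale 2 µm) elsewhere;
  unbiased axes are symmetric exponential. These match the distributional
  assumptions of the branch fits by construction.
* **Encounters** — linear dynamics directly in polar phase space about a
  fixed point at contact distance (r₀ = 20 µm, where the polar chart is
  regular), propagated exactly through the per-frame matrix exponential,
  with component-wise multiplicative noise (SD = noise fraction × that
  component's per-frame drift). The validation grid uses eigenvalue pairs
  (−0.5, −0.2), (−0.3, +0.3), (+0.2, +0.5) min⁻¹ with noise fractions drawn
  uniformly from 10–20 %. The frame interval of 0.5 min resolves the
  fastest mode (|λ|·dt ≤ 0.25, central-difference velocity bias ≈ 1 %).
  Initial offsets along unstable directions are set so each mode traverses
  a comparable number of e-folds before its stopping boundary (r > 60 µm or
  |θ − θ₀| > 2.5), giving both eigenvalues an estimable signature in one
  trajectory.
* **Rendering** — cells are anti-aliased disks (coverage-weighted edges) on
  a noisy constant background, 8-bit grayscale, with a ground-truth table
  including an overlap flag. The tracking benchmark scene tethers 20 immune
  cells to a well-separated grid (mean-reverting walks, step SD 1.5 px) with
  3 sub-pixel-jitter tumor cells in a separate column, so every
  ground-truth link is recoverable in principle.

## 7. Numerical choices

* Segment SSE via prefix sums; BIC `n·ln(SSE/n) + k·ln n` with 3 parameters
  per line segment.
* Least squares via `numpy.linalg.lstsq`; R² centered (defined as 1 when
  the response is constant).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every stochastic stage is reproducible.

## 8. Limitations

* Validation is synthetic: the generators satisfy the estimators'
  assumptions by construction. Performance numbers (classification
  accuracy, eigenvalue RMSE, link recovery) characterize the implementation
  under its own model, not accuracy on real microscopy, where cell shape,
  intensity variation, division, and dense crossings violate the model.
* The Jacobian is estimated from a single trajectory; when both modes'
  excitations are strongly correlated in time the slow eigenvalue's
  variance inflates (collinear regressors). The benchmark mitigates this by
  design of the initial conditions; real encounters offer no such control.
* The fixed-point treatment of tumor cells ignores slow TC drift beyond a
  stationarity warning.
* The changepoint model assumes piecewise-linear `r(θ)`; smooth gradual
  transitions yield ambiguous or undetected ranges.
* The potential landscape is a visualization heuristic; well depths depend
  on the chosen depth policy and are relative, not calibrated to any
  physical energy.
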