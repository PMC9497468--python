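# Methods

This note records the models implemented in `bendseg`, the numerical
choices behind them, and what the synthetic experiments do and do not
demonstrate.

## The Bendlet system

A Bendlet is a second-order shearlet: the element family is generated
from a mother waveform by anisotropic scaling
`A_{a,α}(x1,x2) = (a·x1, a^α·x2)` (with `a ∈ (0,1]`, `α ∈ [0,1]`), the
second-order shear map `S_{s,b}(x1,x2) = (x1 + s·x2 + b·x2², x2)`, and
translation.  The shear `s` is a slope (dimensionless); the bend `b` is a
curvature in 1/px.  An element whose curve `x1 = s·x2 + b·x2²` osculates a
boundary responds strongly at every scale, which is what makes local
curvature classifiable: by the osculating-parabola relation, a circle of
radius `r` probed where its tangent is axis-aligned matches `b = 1/(2r)`,
and in general `K = 2|b′|/(1+s′²)^{3/2}`.

### Discrete construction

The discrete system is built per image shape:

* **Mother waveform.**  Ricker (second derivative of a Gaussian) across
  the curve, Gaussian envelope along it — a real, zero-mean curved ridge
  filter.  Base widths default to `width0 = min(shape)/32` across and
  `length0 = min(shape)/8` along; at scale `a_j = 2^-j` the widths scale
  as `a_j·width0` and `a_j^α·length0`.  The across width must remain about
  a pixel at the finest scale; sub-pixel profiles alias into junk bands
  (this caps the useful scale count at 4 for 256-px images).
* **Cones.**  "Horizontal" elements oscillate along x (respond to locally
  vertical edges), "vertical" along y; with slopes `|s| ≤ 1` in each cone
  the two cones cover all orientations.
* **Grids.**  Shears default to `{0, ±0.5, ±1}`.  Bends default to a
  dyadic ladder `{0, ±1/64, ±1/32, ±1/16, ±1/8}` 1/px, covering boundary
  radii of roughly 4–64 px.  Both grids are identical at every scale so
  that decay across scales is read at fixed physical `(s, b)`.
* **Tight frame.**  Each filter is sampled in space, FFT'd, and all
  windows (plus a Gaussian low-pass) are divided by the square root of
  their per-bin energy sum.  By construction `Σ|window|² = 1` at every
  frequency bin (measured defect ~4e-15), so analysis is plain frequency
  multiplication and synthesis with the same windows is exact to rounding
  (round-trip relative error ~1e-15, far inside the 1e-3 contract).
* **Order 1 vs 2.**  With `order=1` (or `b = 0`) the bending term is
  dropped and the construction is a plain cone-adapted shearlet; the
  coefficient planes agree bit-for-bit with the `bend_grid={0}` Bendlet.

### Curvature classification

For each band, the response at the probe is the maximum |coefficient| in
a 5×5 window, tracked across scales.  The score is the **mean
log-response across scales**: the winning band is the one whose response
is sustained at every scale, i.e. decays slowest in absolute terms.  A
least-squares log–log slope was evaluated and rejected: it is invariant
to amplitude, and over the 3–4 octaves a pixel image supports it ranks
uniformly negligible bands as "non-decaying".  Ties break toward smaller
|b|, then smaller |s|, so straight edges report exactly `b* = 0` and
`K = 0`.  Estimates are grid-quantized: with the dyadic ladder, discs of
radius 10/20/40 px classify to +25 % of `1/r`, strictly ordered.  An
off-grid parabolic refinement was prototyped and dropped — raw-response
refinement drifts up (band gain grows with |b|), matched-filter-normalized
refinement overshoots down — the grid argmax is the honest estimate.

### Sparsity comparison

The curved-edge sparsity claim is measured as best n-term approximation:
the number of atoms needed to capture 95 % of the detail (band-pass)
energy.  For the redundant frames this is computed by matching pursuit
(greedy, unit-normalized atoms); for the orthogonal separable wavelet
(`db4`) it is coefficient sorting, which is the same thing in an
orthonormal basis.  Counting raw coefficient energy in an undecimated
frame would penalize redundancy itself and invert the comparison.  On a
128-px disc-edge image (r = 16 px): bendlet 50 ≤ shearlet 75 ≤ wavelet 125.

## Registration

Features are 8-neighborhood maxima of the per-scale max-over-band
response maps above the 0.98 quantile, kept only when re-detected at a
neighboring scale within 2 px, deduplicated across scales.  Descriptors
for feature-set matching are window-averaged band magnitudes at two
scales, L2-normalized.

For warp estimation the package matches each fixed-image feature against
the **dense signed coefficient field** of the moving image within a
10 px search radius (multi-band normalized correlation).  Two choices
matter here and were validated against a brute-force intensity-matching
oracle:

* **Signed coefficients**, not magnitudes: polarity and texture phase are
  what pin a match tangentially along a boundary; magnitude profiles are
  identical under sliding.
* **Ambiguity rejection**: a peak must beat the best score outside its
  2 px surroundings by the Lowe ratio (0.8 on squared descriptor
  distance), which discards aperture-ambiguous ridge maxima.  Accepted
  peaks are refined to sub-pixel by a quadratic fit (skipped for exact
  peaks so self-registration is exactly the identity).

Matched displacements are densified by a thin-plate spline
(`scipy` RBF, smoothing 100 — heavy smoothing wins because match errors
are locally correlated), then refit after dropping matches that deviate
from the fitted field by more than max(1.5 px, 3× median residual); this
removes matches corrupted by genuine content differences (the lesion
itself has no counterpart in the reference).  Registration quality is
reported as the mean feature displacement when the fixed image is
re-matched against the warped result.

## SSIM localization

Blocks are anchored every `stride` px (default 50), the final anchor
clamped to the border so all pixels are covered; the default window is
128 px for 256-px frames.  SSIM uses sample statistics (denominator
`HW−1`) and the conventional constants `C1=(0.01L)², C2=(0.03L)²,
C3=C2/2` with `L=1`.  Scores are computed per aligned block pair; the
argmin (ties to the lowest raster index) is the tumor unit.  With no
anomaly all scores are ~1 — the minimum score, not the block id, is the
caller's no-tumor signal.

## Chan–Vese solver

Region means use the sharp Heaviside (`H = 1` where `φ ≥ 0`); evolution
is smoothed by the Cauchy-kernel `δ_ε` (the asymmetry is deliberate and
follows the model's two defining formulas).  The curvature term is the
central-difference divergence of the normalized gradient with `|∇φ|`
floored at 1e-8.  The data terms enter with the gradient-descent signs
(`−λ1(I−c1)² + λ2(I−c2)²`): with them a point whose intensity is close to
the inside mean gains level-set value, which is the behavior the model
narrative requires.

**Time stepping.**  Between `t_n` and `t_{n+1}` the flow is embedded in a
linear homotopy; truncating the perturbation series at first order gives
the predictor `φ⁰ = φ_n + Δt·F_n` and the corrector
`φ_{n+1} = φ_n + Δt/2·(F_n + F(t_{n+1}, φ⁰))` — a trapezoidal two-stage
scheme, verified second-order on manufactured flows (error ratio 4.1 per
Δt halving).  The CV force is normalized by its sup-norm each step (one
shared factor for both stages), so `Δt = 0.5` reads "at most half a pixel
of level-set change per step" and the contour speed is independent of
image contrast; without this, low-contrast forces stall against the 1-px
quantum restored by periodic re-distancing.  φ is rebuilt as a signed
distance every 50 steps and compressed in the wavelet basis every 10;
convergence is declared when the mask is unchanged for 25 consecutive
steps.  Energy is monitored with the geometric length term (total
variation of the indicator), so reparameterizations of φ leave the energy
of an unchanged contour unchanged; on noiseless two-phase phantoms the
trace is non-increasing.

**Collocation basis.**  The interval Shannon-Cosine basis on dyadic grids
of [0,1] uses the kernel `φ(t) = sinc(t)·(a0 + a1 cos(2πt/N) + a2
cos(4πt/N))` supported on `|t| < N/2` (default `N = 6`).  The three
cosine weights are solved at construction from: interpolation
(`Σa = 1`), vanishing at the support edge, and exact partition of unity
at half-grid points — numerically (0.4152, 0.5, 0.0848), nearly a
Blackman window.  Evenness then gives exact reproduction of linear ramps
at half-grid points, so interpolatory details of (bi)linear functions
vanish identically.  Boundary nodes fold in exterior translates with
linear-extrapolation weights (exterior node `−n` counts as `(1+n)`× node
0 minus `n`× node 1), preserving both reproductions on the closed
interval.  Decomposition is the interpolatory pyramid (details = residual
at the three new-point parity classes per level) down to a coarsest level
of at least 9 nodes per axis; reconstruction inverts it exactly.  Detail
magnitudes concentrate at the interface and provide both the boundary
flags and the compression rule (drop details below 1e-3 of the maximum).

The wavelet-homotopy solver and the plain forward-Euler finite-difference
solver agree on ≥ 99.9 % of pixels across seeded two-phase phantoms at
two contrasts.

**Parameters.**  Defaults `μ = 0.2, λ1 = λ2 = 1, ε = 1, Δt = 0.5,
max_iter = 500`.  μ must be scaled to the squared contrast of the target:
for lesions at ~0.1–0.2 contrast on unit-range images, `μ ≈ 0.02–0.05`
(the pipeline default is 0.05); at `μ = 0.2` the length term dominates a
(0.1)² data term and collapses the contour.

## Pipeline

The tumor image is registered onto the reference, the pair is scanned by
SSIM, and the CV solver runs inside the argmin block.  The level set is
seeded at the hotspot of the smoothed |aligned − reference| difference —
a blind centered circle can be captured by bright anatomy (skull rim)
entering the block edge, which is exactly the failure mode block
localization exists to avoid.  If the two-phase mask splits into several
components, the one explaining most of the reference difference is kept.
The deliverable mask is pushed back through the estimated warp into the
observed image frame, where any manual ground truth would be drawn; this
measures segmentation quality without double-charging residual
registration error to localization.

## Phantoms

`make_phantom` renders a bright elliptical skull rim (0.9), mid-grey
tissue (0.4) with smooth Gaussian texture (amplitude 0.06, correlation
~2 px) over the whole head, dark ventricles, two round internal
structures, background 0.05; the optional lesion is a disc of given
center/radius/contrast with a blurred edge (truth stays sharp).  The
texture covers the skull rim deliberately: a perfectly clean synthetic
rim is self-similar under tangential sliding in a way real tissue is
not, and landmark matching there becomes ill-posed for *any* local
matcher (verified with a brute-force intensity oracle).

Deformations are globally smooth: a 3×3 control grid blown up and
blurred (σ = min(shape)/4) plus a radial mass-effect push centered on the
lesion with a Rayleigh profile (peak at 0.35·min(shape)), blended 50/50
and rescaled to the requested peak displacement (default 6 px,
diffeomorphism guard at half the control spacing).  The earlier, rougher
field (amplitude 6 px at ~90 px wavelength, ~40 % local stretch) defeats
constant-offset patch matching including the intensity oracle; real
mass-effect displacement varies over the whole head.

**What passing tests show and what they do not.**  The phantoms exercise
low contrast, blurred boundaries, texture, curved anatomy, distractor
structures and smooth deformation, but not MR physics (bias fields,
Rician noise), partial-volume effects, pathology heterogeneity, or
multi-lesion cases; single-lesion localization is assumed throughout.
Results on phantoms bound what the pipeline can do under its own model
assumptions, not clinical performance.

## Known limitations

* Curvature estimates are quantized to the bend grid (about ±25 % on a
  dyadic ladder); probing requires a point on or near a boundary.
* Registration needs texture or corner-like structure; on large perfectly
  homogeneous regions matches are (correctly) rejected and the warp
  interpolates, so accuracy degrades over feature-free areas such as the
  lesion interior.
* One tumor unit per image: the locator returns exactly one block.
* The solver's force normalization makes the *path* of descent
  dt-dependent in principle, though the stationary masks agree with the
  unnormalized reference solver.
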