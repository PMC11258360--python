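# Methods

This note records the models, parameter choices and numerical decisions
behind `smtkit`, and what the synthetic-data validation does and does
not establish about real microscope data.

## Imaging model and coordinate conventions

A field of view is a 16-bit movie stack (frames × rows × cols).  Pixel
(i, j) covers the unit square centred on integer coordinates (i, j);
continuous positions are pixel units with the origin at the centre of
pixel (0, 0), row = y, col = x, and micrometre coordinates are pixel
coordinates times the pixel size (default 187.14/1728 ≈ 0.1083 µm/px,
the camera field of view divided by its pixel count).  Acquisition
constants default to 100 Hz (frame interval 0.01 s) with a 407 µs
stroboscopic excitation pulse and 150 frames per movie.  Because the
pulse is ~25× shorter than the frame interval, within-pulse motion is
negligible (RMS displacement √(2·D·t_pulse) < 0.07 px even at
D = 5 µm²/s); the simulator therefore samples positions at the pulse
midpoint and renders no motion blur, and the inference applies no
motion-blur correction.  `rbme_log_likelihood` is the single place a
blur covariance term would enter if longer exposures were modelled.

## Spot detection (GLRT)

The detector compares, for each 11×11 tile, hypothesis A (white
Gaussian noise, free mean and variance) with hypothesis B (noise plus
I·G, G a mean-zero unit-energy Gaussian of width σ_w = 1.5 px).  At the
maximum-likelihood parameter values the log-likelihood ratio reduces to

    LLR = −(w²/2)·log[1 − (ΣXG)² / (ΣX² − (ΣX)²/w²)].

Numerical decisions:

- The three tile sums are computed for all tile positions at once with
  FFT convolution; the frame mean is subtracted first (the statistic is
  offset-invariant since ΣG = 0) to keep the convolutions
  well-conditioned.  Agreement with direct per-tile evaluation is at
  machine precision (~1e-13) on random frames.
- A zero-variance (constant) tile has no evidence of a spot: LLR := 0.
- When the log argument underflows (a tile exactly proportional to the
  kernel is analytically infinite), it is clamped at 1e-12, capping the
  LLR near 1672 — finite and order-preserving.
- Tiles must fit entirely: no detections within w//2 px of the border.
- The map is evaluated densely and detections are its local maxima at
  LLR ≥ 14 (the empirical operating threshold), with a minimum peak
  separation of 3 px to prevent double-counting of one emitter.

## Subpixel localization

The integrated-Gaussian model integrates a σ_w = 1.5 px Gaussian over
each unit pixel (erf differences) so the fit is correct at the
single-pixel scale of these PSFs.  Fitting is damped Levenberg–
Marquardt, θ ← θ + γ(JᵀJ + αI)⁻¹Jᵀ(X − f(θ)) with γ = 0.3, α = 10⁻⁴,
at most 8 iterations, declaring convergence when x₀ and y₀ both move
less than 10⁻⁴ px (pixel units assumed).  The damping gives a linear
contraction of roughly (1 − γ) per iteration near the optimum, so on
noisy spots the 10⁻⁴ px criterion is rarely met within 8 iterations;
the convergence flag is informational and the refined position is used
either way.  Initialization: (x₀, y₀) from the radial-symmetry
estimator (gradient-line intersection on the inter-pixel midpoint grid,
with centre fallback for degenerate gradients); I⁽⁰⁾ = Σ(tile − min);
b⁽⁰⁾ = median of the tile border.  A singular or non-finite step, or a
position leaving the tile, returns the initialization flagged
unconverged.  On noiseless spots the fit lands within ~1e-4 px of a
brute-force grid-search least-squares oracle; at the default simulated
photon budget the empirical 1-D RMSD is ≈ 0.025–0.035 µm, inside the
0.02–0.08 µm range the state-array grid marginalizes over.

## Trajectory linking

Candidate links connect detections separated by ≤ 1.25 µm and 1–3
frames.  Link probabilities are inferred on a factor graph: one binary
variable per candidate link with prior weight equal to the *squared*
2-D Brownian transition density of its displacement (per-axis variance
2·D̂·δ·Δt + 2·σ_loc², σ_loc default 0.035 µm, D̂ the average of the two
spots' current estimates), and one "at most one active link" factor per
detection side whose no-link alternative carries weight
rate × 1/(π·1.25²) µm⁻².  Squaring the link density makes every
detection side contribute exactly one density factor, so configuration
weights are dimensionless up to a global constant.  The rate factor
(default 0.1) encodes that disappearance requires photobleaching or a
missed detection — each a few percent per frame — rather than being
free; with a bare spatial density the no-link alternative outweighs the
Brownian density for the displacement tail of fast molecules
(r ≳ 0.7 µm at D = 5 µm²/s), silently fragmenting ~18% of fast-state
jumps and biasing state occupations toward the bound end.  This was
diagnosed on ground truth (jumps per alive frame 0.79 for fast vs 0.97
for bound emitters; ≈ 0.90 vs 0.99 after the rate factor).

Marginals decompose over connected components of the candidate graph:
components with ≤ 12 links are marginalized exactly by matching
enumeration; larger ones use loopy sum-product belief propagation
(exact on trees, slightly overconfident on frustrated cycles).  An
outer loop alternates marginals with re-estimation of per-spot D̂ from
probability-weighted squared displacements (initial value 0.5 µm²/s, a
unit-weight prior stabilizes spots without confident links; the result
is insensitive to the initial value after iteration).

Selection maximizes the full-configuration objective — the sum of
selected-link log marginals plus log no-link mass for every unmatched
detection side — by deterministic hill-climbing over add/remove/swap
moves after pruning links whose marginal is below 0.5× the local
no-link mass.  (The sum of link log-probabilities alone would be
maximized by the empty matching, since every log p < 0.)  Strictly
improving moves guarantee termination; on instances small enough to
enumerate, the hill-climb attains the global optimum in 100/100 random
cases.  Trajectories are the connected components of the selected
links; feasibility is re-verified post hoc.

Link fidelity depends on emitter density and diffusion speed: in a
dilute field (0.01–0.02 emitters/µm², the regime of 10–40 pM labelling)
≥ 99% of selected links join detections of the same true emitter;
at 0.05 µm⁻² with 70% of molecules at D = 5 µm²/s, identity swaps
during close encounters of two fast molecules — a physical ambiguity no
position-only linker can resolve — cap accuracy near 98%.

## Nuclear segmentation and assignment

The stain movie is mean-projected and segmented classically: Gaussian
smoothing (σ = 2 px) → Otsu threshold → hole filling →
distance-transform watershed to split touching nuclei → removal of
components below 20 µm².  The contract is image → label mask, so a
learned segmenter can replace the classical one without touching the
rest of the pipeline.  Near-constant images yield an empty mask rather
than a degenerate threshold.  Each localization takes the label of the
pixel containing its subpixel position; a trajectory takes the majority
label of its localizations and is excluded from state inference when
that majority is background.

## State-array inference

States form a fixed grid of 100 log-spaced diffusion coefficients on
0.01–100 µm²/s (log spacing: 100 points across four decades) × 31
linear localization errors on 0.02–0.08 µm.  The RBME likelihood of a
trajectory is the joint Gaussian of its observed jumps with per-axis
variance 2·D·δ·Δt + 2·σ² and covariance −σ² between consecutive jumps
(they share the middle localization).  That covariance is essential:
with single-gap jumps treated independently, D and σ are unidentifiable
along the ridge v = 2DΔt + 2σ², and low-D states cannot be placed on
the grid.  The tridiagonal quadratic form and determinant are evaluated
by the Thomas recursion, vectorized over the grid and batched over
trajectories sharing a gap pattern.

Occupations are estimated by maximum-likelihood mixture EM over the
grid, each trajectory weighted by its jump count, uniform
initialization, tolerance 1e-6.  Plain EM crawls along the
near-degenerate ridge, so the fixed-point map is accelerated with
SQUAREM extrapolation (with an EM safeguard step); the budget of 1000
map evaluations then reaches convergence.  The error axis is summed out
to give the 1-D distribution over D per FOV (trajectories are pooled
per FOV).  Reporting conventions: bound = mass at D ≤ 0.1 µm²/s,
fast = mass at D ≥ 1.0 µm²/s (both configurable — the cutoffs are a
convention, not an inference); mean D is the occupation-weighted
arithmetic mean of the grid values.  No defocalization or out-of-plane
loss correction is applied.

## Synthetic data generator

The generator emulates the statistical structure the inference assumes:
elliptical nuclei (semi-axis 4.0 ± 10% µm) placed without overlap;
emitters Poisson-distributed at `emitter_density` (default 0.05 per µm²
of nuclear area — sparse, as dictated by picomolar labelling) with
static state labels drawn from the configured (D, occupancy) list
(default 0.05 µm²/s at 30%, 5.0 µm²/s at 70%); per-axis Brownian steps
of variance 2DΔt, reflected at the nuclear boundary (radial reflection
in ellipse-normalized coordinates — exact for circles, approximate for
the mild eccentricities used); geometric photobleaching (survival 0.98
per frame, mean lifetime ≈ 50 frames); optional two-state blinking
behind config flags (off by default).  Rendering deposits
`photons_per_spot` (default 800) through the integrated-Gaussian PSF,
applies Poisson noise to signal plus background (default 200 counts)
and additive Gaussian read noise (default 5 counts).  The photon and
background defaults were set from the Thompson localization-precision
formula so the empirical 1-D RMSD falls inside the 0.02–0.08 µm
marginalization range while spots remain detectable at LLR 14.

`make_condition_pair` realizes a treatment contrast with common random
numbers: both conditions share nucleus geometry, the candidate emitter
set, the state-assignment uniforms and per-emitter motion noise; the
treatment enters only through the occupancy shift and binomial thinning
by the density multiplier.  Observed differences are therefore
attributable to the effect, and control/treated FOV pairs can be
compared with paired statistics.

What the simulations do **not** model: axial structure and defocus,
motion blur, sCMOS pixel-dependent noise, dye photophysics beyond
bleaching/simple blinking, nucleolar substructure, and non-Brownian
motion (directed or confined-within-domain).  Passing tests on this
generator therefore validate the estimators under their own model
assumptions — detector calibration, fit accuracy, linking optimality,
occupancy recovery — not robustness to every real-microscope artifact.

## Validation problem sizes

The test suite and the acceptance script run desk-scale problems chosen
to keep each check statistically meaningful: 192–384 px fields, 15–100
frames, 2–4 nuclei per FOV; 8–10 coupled condition pairs for the
treatment-signature readout; 500-track (length 16) single-state and
1000-track (length 8) two-state sets for state-array recovery; 8 dilute
sims for link fidelity.  Single-state recovery uses track length 16
because at the photobleaching default trajectories live ~50 frames, and
in the error-dominated regime (D = 0.02 µm²/s) shorter tracks do not
constrain the D–σ decomposition tightly enough for single-cell-level
grid resolution.

## Known limitations

- Linking assumes pure Brownian motion per spot; directed or strongly
  confined motion would bias both link probabilities and D̂.
- Occupations are maximum-likelihood point estimates on the grid, not a
  posterior with an explicit prior; uncertainty is conveyed by spread
  across grid cells, not credible intervals.
- The bound/slow/fast cutoffs are reporting conventions; biological
  interpretation requires calibration against known-bound controls.
- Spot density counts detections (not trajectories) per nuclear area
  per frame; at very high densities NMS merging deflates it.
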