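# Methods

## Coordinate conventions

Visual-field positions are measured in degrees, x right, y up, fixation at
the origin.  A raster (`RasterSpec`) maps the field onto a pixel grid with
pixel (0, 0) top-left and pixel centers at half-integer coordinates; the
field of view is given along the raster diagonal, which fixes one isotropic
degrees-per-pixel scale, so the pixel↔degree map is affine and exactly
invertible.  All conversions go through `RasterSpec`; no other module does
its own geometry.  The library default raster is a professional headset
panel (1440×1600 px per eye, 110° diagonal); the study and calibration
defaults use 256×256 / 192×192 px at 36° diagonal, which resolves the
default kernel sizes (≈ 7–19 px per σ) at a small fraction of the cost —
the distortion model is resolution-independent, and every rasterized
quantity converges with pixel density.

## Distortion model

Metamorphopsia is modeled as a mixture of truncated-Gaussian distortion
kernels (see the README for the formulas).  Choices worth recording:

* **Smooth truncation.** The boundary multiplier α truncates the support at
  r = ασ.  A hard cut would make the displacement discontinuous at the
  boundary, so the Gaussian profile is multiplied by a smoothstep T falling
  from 1 to 0 over [(α−½)σ, ασ].  Contributions are *exactly* zero at and
  beyond ασ, which makes locality testable bit-for-bit.
* **Tangential rotation profile.** "Rotation proportional to the distance to
  the center" is implemented as θ(r) = ρ·(r/σ)·e^{½−r²/2σ²}·T(r): linear
  growth near the center (continuity at r = 0 demands θ(0) = 0), peak value
  exactly ρ at r = σ, Gaussian decay beyond.  A pure θ ∝ r reading would
  rotate the far field without bound and violate locality, so the damped
  form is used.
* **Composition order.** Within a kernel the backward sample point is
  rotate-then-scale, μ + Rot(θ)·v·(1+s·g).  The reverse order differs only
  at second order in the amplitudes; one order had to be fixed and this one
  is documented and frozen.
* **Mixture composition.** Displacements add; luminance gains multiply.
  Addition matches Gaussian-mixture composition of the geometric field;
  multiplication keeps gains in [0, 1] for any number of kernels.  With
  overlapping kernels the gain can drop below 1 − max λₖ (two coincident
  λ = 0.5 kernels give 0.25); the guaranteed lower bound is ∏ₖ(1 − λₖ).
* **Separated amplitudes.** One kernel record carries λ, ρ, s sharing a
  single (μ, σ, α); zeroing two of the three recovers independent
  perceptual-loss / rotational / spatial kernels.

## Warping and inversion

Warping is backward mapping: output pixel p samples the input at
p + d(p) with bilinear interpolation (`scipy.ndimage.map_coordinates`,
order 1), edge-clamped, then multiplies by the luminance gain.  Forward
splatting was rejected (holes).  Integer images are rounded half-to-even
back to their dtype; where d = 0 and gain = 1 the pipeline is bit-exact,
so "no distortion" is literally the identity.

The dense inverse solves d(p + d⁻¹(p)) + d⁻¹(p) = 0 per pixel by
under-relaxed fixed-point iteration (ω = 0.7, residual tolerance 0.05 px,
≤ 200 sweeps).  The plain iteration (ω = 1) diverges where several strong
kernels overlap and push the Jacobian of p ↦ p + d(p) toward singularity;
ω = 0.7 restores contraction for every admissible template we generate
while only modestly slowing easy cases.  Non-convergence raises with the
worst residual rather than returning a silently bad map.

The parametric corrective field minimizes the mean squared residual
displacement of (warp by corrective) ∘ (warp by field) over a strided pixel
sample, by Nelder–Mead seeded from the negated amplitudes of the forward
kernels, with the simplex re-seeded at the incumbent whenever it collapses
early (restarts share one evaluation budget).  Corrective kernels are purely
geometric — lost luminance sensitivity cannot be restored by remapping
light.  The returned objective never exceeds the all-zero corrective's.

**Family limitation.** The exact inverse of a radial-stretch kernel is not a
radial-stretch kernel: expanding 1/(1+s·g) shows the leading error term is
proportional to g², a squared-Gaussian living at σ/√2.  With one corrective
kernel the residual floor is ≈ 7 % of the uncorrected RMS at s ≈ 0.3
(derivative-free search from multiple starts agrees, so it is the family,
not the optimizer).  A two-kernel corrective mixture — the second kernel
seeded at σ/√2 with a small stretch amplitude — drops the residual below
3 % for every default-range single-kernel field; that is the recommended
configuration for stretch-bearing fields and the one the acceptance checks
use.  Rotation, by contrast, inverts exactly within the family (rotation
preserves radius, so negating ρ is the exact inverse).

## Stimuli and random templates

The Amsler grid defaults to the classical geometry: 20°×20°, 0.5° cell
pitch, 1 px black lines on white, optional diagonals through fixation and a
small fixation disk.  A pixel is a line pixel when its center lies within
half a line width of the analytic line locus; the rendering is deterministic
and exactly symmetric under quarter turns on square rasters.

The reading task lays out pronounceable CV/CVC pseudo-Latin nonsense words
(2–4 syllables, seeded) in Pillow's bundled default font, highlighting a
seeded subset with translucent boxes recorded as pixel rectangles.  Nonsense
words remove lexical predictability: a highlighted word can only be read,
never guessed.

Random templates draw every kernel parameter uniformly from
`TemplateRanges`.  The defaults — 1–3 kernels, σ 1.0–2.5°, λ 0.2–0.8,
ρ ±0.5 rad, s −0.25…0.35, center eccentricity 0–4°, α = 3 — describe
moderate para-central distortions of the kind Amsler-grid screening targets:
supports up to ≈ 7.5° radius, within the central grid, strong enough to bend
several grid cells but far from fold-over (which requires s ≤ −1 or extreme
ρ).  The severity presets used as study conditions scale the three amplitude
intervals by m = 1/6 … 1 while sharing the geometry intervals.

What the generator does *not* emulate: irregular (non-circular) scotoma
shapes, spatial correlation between λ and the geometric amplitudes seen in
real lesions, fixation instability, and any temporal dynamics.  Passing
tests therefore certify the computational pipeline, not clinical realism.

## Simulated observer

Perceived grid distortion is geometric: the mean residual displacement
magnitude of grid-line pixels, in units of the cell pitch, with pixels under
the suppression spot contributing zero (the observer cannot see distortion
there) and the average taken over *all* line pixels.  Normalizing by the
full line-pixel count (rather than the visible count) makes the metric
provably non-increasing as the spot grows and exactly zero at full coverage;
it coincides with the naive mean when there is no spot.  Legibility uses the
same residual restricted to highlighted-word pixels.  Luminance loss can be
folded in through a weight (default 0, geometric-only): how human raters
combined dimming with bending into one number is unknown, so the default
refuses to guess.

Metrics map to ratings via score = round(5·min(1, metric/ref)), half-up.
The reference `ref` is calibrated once per task as the metric of the
*strongest admissible template* — a single kernel at fixation with every
amplitude at its interval extreme — viewed without suppression; that
template scores 5 by construction and the empty field scores 0.  The
synthetic participant perturbs ratings with Gaussian noise (sd in score
units) and uniform lapses, and compares percepts with a 2 % relative
indifference dead-band; zero noise makes every response a deterministic
function of the stimulus.

## Suppression

The dark spot is centered on the distortion extent centroid (kernel centers
weighted by max(λ, |ρ|, |s|)) with radius = scale × extent radius, where the
extent radius is the smallest disk radius covering every kernel support.
Consequently scale ≥ 1 covers all distorted pixels — the 120 % level
eliminates perceived distortion identically, which is the geometric content
of the headline result.  The spot is hard-edged pure black, locked to gaze:
the mask translates by exactly the pixel image of any gaze shift.  An
alternative "mass" sizing mode (fraction of Gaussian mass instead of extent
radius) was considered and rejected as the default because 120 % of mass is
undefined; the radius reading makes every protocol level well-defined.

In the binocular composite the healthy eye supplies the suppressed pixels
bit-exactly; outside the spot the distorted percept dominates (worst-case
fusion).  Monocular mode ignores the healthy image entirely, matching a
switched-off contralateral display.

## Calibration procedures

All three procedures treat the participant's report as the only oracle and
count every interrogation.

* **Contralateral reconstruction** is coordinate descent over each candidate
  kernel's (center, σ, λ, ρ, s) from mid-range defaults, accepting only
  moves the participant reports as more similar to the remembered target
  (dissimilarity = RMS displacement difference plus an equally weighted
  luminance-map term, with memory noise).  Initial center steps are large
  (2°) so that a move changes the percept overlap by more than the
  indifference dead-band; steps halve when a sweep yields no accepted move.
* **Corrective assessment** runs on the affected eye only.  Because a
  zero-amplitude corrective gives the center parameters no perceptual
  signal (coordinate descent stalls on that plateau), the loop first probes
  a coarse lattice of centers with a small rotation amplitude of either
  sign — the analogue of the subject dragging the corrective blob around —
  and then hands the best start to a Nelder–Mead simplex whose objective is
  the participant's reported residual, re-seeding a shrunken simplex at the
  incumbent until the query budget is spent.
* **Macular-hole procedure**: (1) the subject directs a dot to the
  distortion center (0.25° steps; terminates within half a step per axis);
  (2) a circle grows in 0.25° steps until reported to cover the distorted
  area, fixing the corrective σ = radius/α; (3) tangential rotation in
  0.05 rad steps, content-clockwise first, reversing direction on the first
  "worse" report; (4) radial contortion in 0.05 steps, inward first, same
  reversal rule.  Stages 3–4 repeat with halved steps until the subject
  reports the distortion imperceptible — the natural examiner fine-tune;
  with the fixed first-pass steps alone the stronger hidden kernels stop
  one quantization level short of rated imperceptibility.  Sign
  conventions, as seen by the viewer: a positive backward-sampling angle
  rotates content clockwise, a positive sampling stretch contorts content
  inward.  If the subject reports no distortion at the outset the procedure
  ends immediately.

With noiseless patients the macular-hole procedure reaches reported score 0
for every default-range hidden kernel and localizes the center within one
step; with rating noise sd 0.5 the median final score stays ≤ 1.

## Study harness and analysis

Each participant, per severity condition, gets one random template in one
random eye and rates both tasks at suppression scales 0, 0.25, 0.90, 1.20
(ascending, repeated measures).  A baseline no-distortion presentation is
checked to rate 0.  Recorded per trial: the first scale at which the task
rating reaches 0 ("first imperceptible") and the first scale at which the
spot overlaps any grid-line pixel — a stated proxy for "suppression first
noticed": the spot becomes visible the moment it occludes stimulus content.
Trial logs round-trip losslessly through a fixed-column CSV.

Scores are analyzed with Pearson's chi-square on the score(0–5) ×
suppression-level contingency table (empty rows/columns dropped, no
continuity correction), plus per-level arithmetic means.  No
multiple-comparison correction is applied; p-values are reported raw.
Six-way ordinal data analyzed by chi-square discards the ordering — the
per-level means are emitted alongside precisely because the test statistic
alone says nothing about direction.

## Known limitations

* The simulated observer's linear metric→score mapping, anchored to the
  strongest admissible template, is more conservative than human raters:
  at 90 % suppression the surviving annulus residual falls below the
  score-1 threshold for essentially all templates, so simulated mean scores
  at 90 % and 120 % are both exactly 0, whereas human cohorts still report
  a mean near 1 at 90 %.  Only the 120 % elimination is
  observer-independent (it is forced by coverage geometry).
* Single-kernel corrective fits bottom out near 7 % residual for strong
  radial stretch (see above); use two corrective kernels.
* Bilateral distortion is supported only as two independent per-eye fields
  calibrated sequentially; no interaction protocol is modeled.
* The spot is circular and hard-edged; feathered or shaped suppression and
  multi-spot layouts are out of scope, as are real-time rendering, optics,
  chromatic effects, and headset/eye-tracker integration (static rasters
  stand in for the camera feed, a fixed gaze vector for the tracker).
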