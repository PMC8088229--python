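# Methods

## The model

A dissected eyecup is modeled as a sphere of radius *R* (mm) whose south
pole is the optic nerve head. Cutting the cup into *n* lobes and pressing
it onto a slide preserves radial arc lengths (the no-stretch assumption
for meridians), so a concentric circle of radius *L* on the flatmount
corresponds to the sphere latitude at polar angle θ = π − L/R. The circle
has perimeter 2πL but carries only 2πR·sin θ of tissue; the remainder is
interlobe gap:

    G(L) = 2π (L − R sin(π − L/R)).            (ideal gap law)

Flattening also deforms the tissue itself. The deformation is modeled as
an additive gap error E = k·sin θ, proportional to the tissue mass on the
circle, with a tissue distortion coefficient *k* (a length, reported to
users as k/2π in mm):

    G(L) = 2π (L − (R − k/2π) sin(π − L/R)).   (corrected gap law)

The corrected law minus the ideal law equals k·sin(π − L/R) identically;
tests assert this algebraic identity to machine precision rather than any
approximate equivalence.

Assumptions worth keeping in mind: the eye is a sphere (no ellipsoidal
axis), arc lengths along meridians are preserved exactly, and the
distortion enters only through the gap law (uniform per-lobe narrowing).
The corneal angle θ_c = π − M_max/R, with M_max the longest lobe
middle-axis length, says how far toward the north pole the tissue extends.

## Measurement

Images are converted to HSV; Otsu's threshold on the saturation channel
separates stained tissue (saturated) from background, and the class with
the lower mean saturation is labeled background. Lobe middle-axis lengths
M_1..M_n are Euclidean distances from the annotated optic-nerve-head
origin to the annotated lobe-tip markers; all model math is done in mm
(px · µm-per-px / 1000 at the boundary), because k is a physical length
that must transfer across images with different scales.

Gap profiles are sampled on 500 concentric circles with radii forming an
arithmetic sequence over [1 px, M_min]. Each circle is rasterized as a
*midpoint ring*: the set of pixels whose distance to the origin is within
half a pixel of the radius. Rings of consecutive integer radii tile the
plane with no gaps or overlaps, membership is provably unambiguous (a
pixel distance can never equal r + 1/2 exactly), and the expected pixel
count equals the annulus area 2πr. The gap length is the *fraction* of
ring pixels on background times the true circumference,
G_i = frac_bg · 2πL_i, rather than the raw pixel count — raw counts would
inherit the ring's quantized size and bias k. Ring pixels outside the
frame count as background (tissue cannot exist outside the image); a
warning is raised when that happens.

Agreement metric. Tests compare measured profiles to the analytic law and
to a brute-force oracle (bin every pixel by rounded distance, background
fraction per bin) using the aggregate relative error Σ|ΔG_i| / Σ G_ref.
A per-point mean of |ΔG_i|/G_i is not usable here: the radius array starts
at 1 px, where the true gap is near zero and a single-pixel flip is a
~100% per-point error (and the ratio is undefined at G = 0). The aggregate
error is ~1.3% at 5 µm/px and ~2% at 10 µm/px against the analytic law on
rendered images.

## Estimation

*k from calibration samples.* Given the true radius, the corrected law is
linear in k, so the least-squares solution is closed form:
k̂ = Σ s_i (G_i − G_ideal,i) / Σ s_i², s_i = sin(π − L_i/R). A generic
iterative least-squares minimizer of the same objective serves as a test
oracle, not as the implementation. Negative estimates are legal (the
model is linear) but flagged, since physical coefficients are positive.
Coefficients from multiple calibration samples are aggregated by their
arithmetic mean (median available as an option).

*R with k fixed.* R̂ minimizes Σ(G_i − G(L_i, R, k))² subject to
R ≥ M_max/π (keeps the corneal angle non-negative). The fit starts at
R_init = 100 working units — far above any plausible radius, which
together with the bound prevents collapse onto the trivial solution
R ≈ 0 — with multi-start fallback from M_max/π·1.1, M_max and 2·M_max, so
the initial value is inert. Convergence tolerances are 1e-10 (relative),
500 function evaluations max. Estimating k and R simultaneously is
deliberately not the default: it is ill-conditioned (k and R trade off
through the shared sine term), and the calibrate-then-estimate order is
the supported workflow.

*Zone experiments.* `exclude_zone` removes round(f·n) points from the
low-latitude (equator-proximal, largest-L) or high-latitude
(pole-proximal, smallest-L) end; on exact model data k̂ is invariant to
any exclusion, while an equator-weighted disturbance moves k̂ much more
under low-zone exclusion — the diagnostic the zone tables encode.

*Cross-validation.* 3-fold (23 → 8/8/7), 5-fold (23 → 5/5/5/4/4) and
leave-one-out. k-fold schemes shuffle with per-repeat generators spawned
from a master seed (default 20 repeats), so fold assignment is
bit-reproducible; LOO is deterministic and ignores `repeats` with a note.
Per-sample radius errors are summarized as ground truth minus estimate
(signed), its absolute value, the relative percentage, and an accuracy
class: 1 for ≤5%, 2 for (5%, 10%], 3 above 10% (boundaries inclusive,
with 1e-9 slack so float round-off cannot flip an exact-boundary class).

## Synthetic data

The generator emulates the calibration study's conditions: 4 lobes on
axes at 45°/135°/225°/315°, lobe middle-axis lengths uniform on
[0.55, 0.75]·πR (lobes extend past the equator), radii uniform on
1.47–1.71 mm (the observed ground-truth range), k/2π normal around
0.1355 mm truncated at zero (sd 0.05 mm for rendered cohorts, matching
the observed 0.05–0.25 mm spread; the benchmark profile cohort uses sd
0.01 mm), 10 µm/px scale, and manifests that record ground truth as a
*diameter* (2R), the convention of whole-eye micrometry.

`simulate_profile` evaluates the corrected law directly and applies
multiplicative Gaussian noise to G, clamped to [0, 2πL]; its radius array
starts at one pixel's length to match the measured profiles.
`render_flatmount` draws the same law as a binary-color image: at every
radius the total tissue angle (2πL − G)/L is split equally among lobes
centered on their axes. Rendering noise is a smooth per-lobe radial
perturbation of the local gap share (interpolated between 40 knots),
emulating irregular cut edges — per-pixel i.i.d. noise cannot represent a
gap-length error in a binary image.

What synthetic data do *not* contain: wrinkles, tears, staining texture,
tile-merge seams, corneal remnants at lobe tips, annotation error, or any
deviation from the spherical gap law other than the injected noise.
Passing the synthetic benchmarks therefore shows that the estimation
machinery is correct and well-conditioned under the study's nominal
conditions, not that real tissue obeys the model; the real-data error
level is an upper benchmark, not a reproduced number.

## Problem sizes and numerical choices

Tests render at 5–20 µm/px (images roughly 350–1500 px square) and use
profile cohorts of 3–23 samples with 100–500 points; the benchmark cohort
is 10 samples at 500 points with 1% gap noise. The rasterization-heavy
checks use one rendered sample shared across tests. Degenerate inputs are
rejected with specific messages: L outside [0, πR], uniform saturation,
markers coincident with the origin, lobes shorter than 10 px, fractions
≥ 1, scheme/sample-count mismatches, k/2π ≥ R at render time.

## Known limitations

- Sphere only; ellipsoidal eyes bias R toward an effective average radius.
- Manual annotations are trusted; no landmark detection or refinement.
- The longitude convention (equal 2π/n sector per lobe, within-lobe
  azimuth rescaled by the local tissue half-width) is this package's
  definition — longitude is not identifiable from the gap model itself.
- Sub-pixel origin placement is rounded to the nearest pixel for ring
  generation.
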