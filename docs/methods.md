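# Methods

## Scene model

A scene is a flat confluent epithelial sheet at a base height, with
fluid domes modelled as **spherical caps**: a dome of footprint radius
*r* and apex height *h* follows the cap of sphere radius
*R = (r² + h²)/2h*, so the surface is continuous, peaks at *h* over the
center and returns to the base at the rim. The cap must not exceed a
hemisphere (*h ≤ r*): a taller cap overhangs and cannot be represented
by a height field. Dome placement keeps footprints disjoint and inside
the field.

Default dome geometry uses **apex = 0.8 × radius** with radii of
25–45 µm. Epithelial fluid domes are blister-like — their height is of
the same order as their footprint radius — and this aspect ratio
matters quantitatively: a much flatter cap has a wide rim band whose
elevation stays below one z-step, which any height-threshold
segmentation must miss. With the default geometry that band is a few
percent of the footprint; the dome-area estimate carries a small,
systematic undershoot of that size (visible in the validation numbers
as a ~5–8% deficit against Σπr²).

The brightfield channel models what focus stacking actually keys on: a
cell sheet has contrast everywhere. It is composed of dark
cell-boundary lines on a Voronoi lattice of ~12 µm cells (edge
strength decays with the difference of the two nearest-seed distances)
plus band-limited intracellular texture — unit-variance Gaussian noise
smoothed at 1 px and scaled to a fixed standard deviation of 25 counts
on a background of 150. Fluorescence channels are binary-ish: nuclei as
discs (radius 3–5 µm), mitochondria as 2:1 ellipses with areas drawn
from a regular range (0.3–1.5 µm²) and, for a configurable fraction,
from a strictly disjoint enlarged range (3–8 µm²), autophagosomes as
discs. Objects are placed by rejection sampling: nuclei at least one
diameter apart, sized objects (mitochondria, puncta) without footprint
overlap, largest first.

## Optics and noise

Rendering a focal plane at height *z* blurs the ideal image per pixel
with an isotropic Gaussian of

    sigma(y, x) = blur_rate × |z − height(y, x)|     [px, rate in px/µm]

with `blur_rate = 0.3 px/µm` by default, so adjacent 5 µm planes differ
by 1.5 px of blur — enough for a 7×7 variance window to rank planes
reliably. No diffraction, phase or chromatic model is attempted; the
linear-sigma Gaussian is the simplest point-spread consistent with
"nearest plane is sharpest", which is the only property the fusion
relies on. For speed the sigma field is quantized onto a monotone
ladder (0.125 px steps up to 2 px, then ×1.25 geometric); the mapping
is monotone in true sigma, so focus ordering across planes is preserved
exactly, and each distinct ladder value costs one separable Gaussian
filter regardless of how many planes use it.

Noise is applied after blurring: Poisson shot noise at a configurable
photons-per-count scale (default 1.0) followed by Gaussian read noise
(default SD 3 counts), clipped at zero. Each channel draws from its own
deterministic substream of the scene seed, so renders are bit-identical
per (parameters, seed).

## EDF fusion and stitching

The focus score is windowed variance (7×7, reflection padding);
tenengrad (Sobel energy) is available by configuration. The raw height
map is the per-pixel argmax over planes with ties resolved to the
lowest index — a stable, documented choice that also fixes the
degenerate all-planes-identical case. A median filter with a 2 px disk
removes isolated argmax noise without rounding dome edges; the
composite then samples each pixel from its smoothed plane, so composite
and height map stay mutually consistent.

Tiles are registered pairwise by phase correlation on their nominal
overlap regions; pairs with near-constant overlap or a shift beyond the
search radius (8 px default) contribute nothing. Per-tile residuals are
reconciled by a breadth-first sweep from the anchor tile (smallest
nominal offset, residual fixed at zero), averaging the estimates from
already-placed neighbours; exact half-pixel averages round toward zero
(the smaller shift). Tiles with no usable estimate fall back to the
nominal grid and are flagged. Offsets are integer pixels — subpixel
registration is deliberately out of scope.

Stitching places tiles at nominal + residual. Composites blend with
linear feathering (weight = distance to tile border) or nearest-tile
assignment; **height maps always use nearest-tile provenance** because
plane indices are categorical — averaging two indices would fabricate a
plane nobody measured. Nearest assignment also makes reassembly of
exactly-cut tiles bit-identical, which the tests exploit as a
round-trip oracle. Residual offsets can leave thin uncovered strips at
the mosaic border; these are trimmed, but never deeper than the largest
residual on that axis — a deeper gap is a genuine coverage error and
raises.

## Segmentation choices

- **Domes** are segmented from the height map alone; intensity plays no
  role. The base plane is the **mode** of the height values (robust as
  long as domes cover less than half the field; a mean would drift with
  dome area). The detection threshold defaults to **one z-step above
  base**: on a height map quantized to planes, that is the first level
  distinguishable from the base at all, and the median smoothing in the
  fusion already removes the single-pixel argmax noise that a higher
  threshold would guard against; a higher threshold discards the entire
  first quantized level of every dome rim and biases areas down.
  Minimum area 500 µm² rejects residual speckle. Both are configurable,
  and total dome area is non-increasing in each.
- **Nuclei**: Gaussian smooth (1 µm) → Otsu → hole fill → distance
  transform → peak markers → watershed → minimum-area filter (12 µm²).
  The watershed splits touching nuclei that overlap by less than about
  a third of a radius.
- **Mitochondria**: either a deterministic threshold (Otsu or fixed) or
  a random-forest pixel classifier over 5 features × n scales
  (Gaussian-smoothed intensity, gradient magnitude, Laplacian, largest
  structure-tensor eigenvalue, local variance). Both routes sit behind
  the same interface and produce mask → components → per-object areas;
  the footprint is foreground pixels over field pixels, so object areas
  sum to footprint × field area exactly. The tests validate the
  deterministic route against generator ground truth and the learned
  route on a separable toy (held-out pixel accuracy ≥ 0.99,
  seed-deterministic).
- **Enlarged mitochondria**: strict area threshold. No biological
  cutoff in µm² is established for this cell system, so the default is
  derived per experiment as the 97.5th percentile of object areas in
  control fields (helper provided); tests use a threshold placed in the
  gap between the generator's disjoint area ranges.
- **Autophagosomes**: intensity-quantile threshold (default 0.99) and a
  minimum area; counts are monotone non-increasing in the area cutoff.
- Reporting units mirror typical acquisition: mitochondrial metrics per
  48 × 48 µm field at 0.1 µm/px, autophagosomes per 331.5 × 331.5 µm
  field, both configurable.

## Assays

Mito Stress parameters follow the vendor cycle convention (last basal,
minimum post-oligomycin, maximum post-FCCP, last rotenone/antimycin-A
cycle); a phase-mean alternative is selectable. The partition
identities `basal = ATP-linked + leak` and `spare = maximal − basal`
hold exactly by construction for any trace. OCR values are not
cell-number-normalized: the assay design holds cell numbers constant
across groups, and no normalization is applied by default.
`spare_pct = 100 × maximal / basal` is reported as NaN with a warning
when basal respiration is not positive.

Biopsy Z-scores subtract the per-fluorophore no-primary background mean
(clipping at zero, clipped tubules flagged), normalize each complex
marker by the same tubule's corrected VDAC1 (mitochondrial mass), and
standardize against control tubules using the sample (n−1) SD. By
construction control Z-scores have mean 0 and SD 1 per marker, and the
whole computation is invariant to a common positive rescaling of any
fluorophore. A zero control SD raises rather than silently dividing.

The ATP standard curve is an ordinary least-squares line, inverted at
the sample luminescence; duplicate standards do not change the fit, and
samples outside the standard range are flagged as extrapolated.

## Metabolite quantification

Monoisotopic masses use the lightest-isotope table (H 1.0078250319,
C 12 exact, N 14.0030740052, O 15.9949146221, P 30.97376151,
S 31.97207069 Da); the only supported adduct is [M−H]⁻ at
mass − 1.007276 Da, a convention that reproduces the reference m/z
values for tenofovir and both phosphates at 4 decimal places (the
electron mass is folded into the proton-mass constant). The extraction
window is half-open `[lo, hi)` for deterministic boundary behaviour — a
peak exactly at +tolerance is excluded, one exactly at −tolerance is
included. XICs contain every distinct retention time of the series
(zero where no peak falls in-window) so integration bounds are well
defined. Peak bounds are the contiguous run of samples strictly above
the baseline (zero, or the line through the first and last samples)
containing the global apex; integration is trapezoidal with no
smoothing and no multi-peak deconvolution — co-eluting isobars within
the window are deliberately summed.

## What the generator does and does not establish

The synthetic scenes give exact object-level ground truth, which is the
point: every pipeline stage is checked against quantities known by
construction (counts, Σπr², injected jitter, injected XIC areas).
They do not emulate photobleaching, illumination gradients, chromatic
aberration, realistic intracellular texture statistics, overlapping
organelles in 3D, or dome shapes other than spherical caps. Passing
tests therefore demonstrate that the algorithms are correct and
well-calibrated under the stated optical model — not that the defaults
transfer unchanged to any particular microscope; thresholds are
expected to be re-tuned on real data, which is why every one is a
configuration value.

## Problem sizes

Validation uses 512×512 px scenes (1 µm/px) with 20 planes at 5 µm for
height-map fidelity, 540×540 scenes cut into 2×2 tiles at 12.5%
overlap with ≤3 px stage jitter for the end-to-end dome recovery
(5 seeds each), 288×288 noise-free scenes for the bit-exact stitching
oracle, and 480×480 px organelle fields at 0.1 µm/px. These sizes keep
the full suite and the acceptance script fast while leaving every
quantity measurable at the tolerances stated in the tests.
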