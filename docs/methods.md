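# Methods

## Shape model

A single spheroid in a brightfield micrograph is modeled as a simply
connected dark region on a bright background. Its boundary is reduced to
polar form about the center of a least-squares reference circle: border
point `i` at distance `r_i` from the center contributes a normalized
radius `ρ_i = r_i / r_c`. All shape statistics are functionals of `{ρ_i}`
and are therefore dimensionless — independent of magnification and, to
first order, of spheroid size.

The discrepancy of a point set is its population standard deviation
`σ = sqrt(mean((ρ_i − s)²))` about the reference level `s`. Two readings
of `s` are implemented:

- `set_mean` (default): `s` is the mean of `ρ` over the summation set —
  globally for R, per sector for χ. This makes σ a pure spread measure:
  R captures total divergence from circularity, and χ, computed with
  sector-local means, is insensitive to global elongation, which is what
  a "local smoothness" statistic should be.
- `circle_reference`: `s ≡ 1`, i.e. deviation from the fitted circle
  itself. Provided for sensitivity analysis; with it, a sector sitting
  wholly outside the fitted circle contributes its offset as well as its
  texture, so χ partially re-absorbs global shape.

The default reading is the one consistent with the intended semantics
("global and local circularity"); the printed source formula for σ is
degenerate as written, so the choice is documented here rather than
hidden.

χ uses 32 half-open sectors of π/16 starting at the positive x-axis about
the fitted center. Sectors with fewer than two points are excluded from
the average (not zero-filled) and the number of valid sectors is reported.
The sector average is unweighted by point count. Contour vertices are used
as-is rather than resampled by arc length; for the near-circular contours
this pipeline accepts, vertex density along the boundary is close to
uniform and resampling changes χ by far less than rasterization does.

## Circle fit

Pratt's algebraic least squares: minimize the algebraic residual
`A(x²+y²)+Bx+Cy+D` under the constraint `B²+C²−4AD = 1`, solved as a 4×4
generalized eigenproblem. Coordinates are centered and scaled to unit RMS
radius first — at raw pixel scale the `x²+y²` column dwarfs the others
and the eigenproblem becomes numerically unreliable. The fit is
non-iterative and deterministic; collinear input raises a degenerate-fit
error. On a mildly eccentric boundary the Pratt radius settles between
the semi-axes, which depresses measured R by a few percent relative to
the mean-radius reference (see "accuracy" below).

## Segmentation

Gaussian pre-smoothing (σ = 2 px) → global Otsu threshold (polarity
`dark_object` by default, matching brightfield) → morphological closing
(disk, radius 3 px) → hole filling → largest connected component. Each
step is parameter-free or has a fixed, configurable default; the pipeline
is fully deterministic.

Guards:

- *No-spheroid guard.* Otsu always returns a threshold, even on a blank
  noisy frame, and thresholded smooth noise can percolate into one giant
  component. The stage therefore requires the Otsu split's between-class
  variance to exceed 0.75 of the total variance: a unimodal Gaussian
  scores ≈ 0.64 at its optimal split, while any real spheroid scene with
  contrast well above noise scores > 0.95. Below the bound the stage
  reports "no spheroid found".
- *Clipped spheroids* (main component touching the image border) are an
  error, never a silently truncated measurement.
- *Satellites.* Discarded components with area ≥ 10 % of the main
  component (configurable) are counted as satellite aggregates and
  reported, so downstream consumers can filter spheroids whose
  single-border metrics are not meaningful. Components below the ratio
  are treated as debris.

The border is traced at the 0.5 iso-level of the binary mask (marching
squares), giving subpixel vertices. Components anywhere thinner than 2 px
or with self-intersecting boundaries are rejected as degenerate.

## Synthetic scenes and ground truth

The generator produces boundaries `r(θ) = r0·(1 + e·cos 2(θ−φ) +
Σ a_k·cos(kθ+ψ_k))`: a mode-2 term for global elongation plus a band of
higher modes for margin texture. Defaults emulate the imaging conditions
the pipeline targets: 512² px, r0 = 140 px, dark aggregate (15000) on
bright background (40000) on a 16-bit scale, 1 px optical blur, additive
Gaussian noise of sd 500 (2 % of contrast). The default roughness band is
modes 8–24 — straddling the 32-sector frequency so that both the global
(R) and local (χ) statistics are exercised.

`rough_spec(amplitude, seed)` splits the roughness as
`a_k = amplitude/√m` over the `m` modes of the band, making `amplitude`
an RMS-scale knob: true χ grows linearly with it (≈ 0.47·amplitude for
the default band) and stays well above the contour-quantization floor
(χ ≈ 0.0016 at r0 = 140 px) from amplitude 0.02 upward. A uniform split
`amplitude/m` would push the smallest nonzero rung into that floor.

True R, χ and area are evaluated on ≥ 4096 analytic boundary samples by
deliberately naive loop-level sums (`math.fsum`), independent of the
vectorized implementation; this is the oracle the test suite compares
against (agreement to 1e−12 when the morphometry functions are fed the
same samples and circle). Samples are taken at angular midpoints so none
sits exactly on a sector boundary, where floor-based assignment would be
sensitive to last-ulp differences. The polar angles the oracle bins by
are recomputed from the sample coordinates with `atan2`, exactly as the
measurement does — the *sums* are independent, the *data* are identical.

Satellites are rendered as filled disks with satellite/main *area* ratio
drawn from (0.12, 0.25) — above the 10 % detection threshold with margin
— placed by rejection sampling outside a clearance band (12 px + 2·blur)
so that blur and closing cannot merge them with the main body.

Reproducibility: each spec's integer seed derives two fixed RNG streams
(boundary phases + satellite placement; render noise), so the same spec
always renders a bit-identical image while `make_boundary` and `render`
remain independently callable.

### What the generator does not emulate

Real micrographs have uneven illumination, out-of-focus halos, internal
intensity structure (necrotic cores), debris, and non-Gaussian sensor
noise; spheroids deviate from star-shaped (radially single-valued)
boundaries when cells sprout. Passing the synthetic suite therefore
demonstrates correctness of the *statistics* and robustness to blur,
noise and rasterization — not segmentation robustness on arbitrary real
images. Absolute R/χ values from other border-extraction procedures are
not comparable; rankings are.

## Accuracy of the end-to-end pipeline (study conditions)

Measured on the default conditions (512² scenes, 1 px blur, 2 % noise),
from the validation suite:

- perfect circle: R, χ ≈ 0.0016 — the quantization floor;
- χ recovery within ~7 % of truth for amplitudes ≥ 0.02 (15 % bound);
- ellipse (e = 0.1): R within ~5 % of truth (Pratt-radius effect, see
  above), χ/R ≈ 0.11;
- invariances: exact under 90° rotation; ≤ ~0.3 % under whole-pixel
  translation (residual comes from the noise field, which does not
  translate with the object); ≤ ~3 % under 2× radius scaling.

Sector-count robustness: with roughness entirely above every sector
frequency (wavelengths shorter than the narrowest sector), χ at 16/32/64
sectors agrees within ~10 % and rank-orders scenes identically. With the
default 8–24 band the *values* of χ depend systematically on sector count
(modes below the sector frequency are partially global and contribute
less in narrower sectors) but scene *rankings* are preserved — which is
the property that matters for comparative use.

## Quantification

- Size normalization: group means per (cell type, seeding density),
  divided by the same cell type's 5,000-cell group mean, × 100. A cell
  type without a reference group is an error, not a silent skip.
- Invasion: the experimental unit is the well; field counts are averaged
  within well before any statistics, since fields are pseudo-replicates.
  The default test is the classic pooled-variance unpaired two-tailed
  t-test (Welch behind a flag). Degenerate cases (single-well conditions,
  zero variance) report the fold change but mark the p-value unavailable.
- χ-vs-invasion: Spearman rank correlation — the association claim is
  ordinal and group counts are tiny; no p-value is attached below n = 5.

## Numerical and interface choices

- Coordinates: x = column, y = row, origin at the top-left pixel center;
  contours are counter-clockwise by shoelace sign in this frame.
- Physical units are never guessed: areas are px², with µm² added only
  when a µm/pixel scale is supplied.
- RGB input collapses by Rec. 601 luma; intensities are never rescaled.
- Segmentation re-applied to its own binarized output reproduces the mask
  up to ≤ 0.1 % of the area (staircase pixels whose smoothed value
  straddles the threshold); all shape statistics are insensitive to this
  at the documented tolerances.
- Validation problem sizes (5-rung × 3-seed ladder, 10 scenes for sector
  robustness, 20 satellite scenes, 100 random count tables) were chosen
  as the smallest sets that exercise every code path with stable
  statistics.

## Known limitations

- Star-shaped boundaries only: a margin that folds back on itself (true
  sprouting) makes the polar representation multivalued; such contours
  are not detected specifically and will be smoothed over by the radial
  statistics.
- Global Otsu assumes bimodal intensity; faint spheroids on textured
  backgrounds need a different segmentation front-end (the morphometry
  accepts any externally produced contour).
- χ at 32 sectors is tuned to margin texture at scales near r0·π/16;
  much finer texture is attenuated by optical blur before it reaches the
  contour.
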