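# spheroshape

Quantitative shape analysis of multicellular tumor spheroids from
single-spheroid brightfield micrographs.

Spheroids — self-assembled 3-D aggregates of tumor cells, optionally mixed
with endothelial cells — are a standard ex vivo micro-tumor model. Their
outline carries biology: hybrid spheroids with higher endothelial content
develop rougher margins, and margin roughness tracks invasive potential.
`spheroshape` turns a micrograph of one spheroid into two dimensionless
shape statistics, plus the downstream summaries an invasion-assay workflow
needs.

## The statistics

The spheroid border `{M_i}` is segmented and traced at subpixel precision,
and a least-squares circle (Pratt algebraic fit, center `c`, radius `r_c`)
is fitted to it. For any set of border points `{n_i}` with distances `r_i`
from `c`, normalized radii `ρ_i = r_i / r_c` and set mean
`s = ⟨ρ⟩`, the *discrepancy* of the set is the population standard
deviation

    σ({n_i}) = sqrt( (1/N{n_i}) · Σ (ρ_i − s)² )

- **Roundness `R = σ({M_i})`** over *all* border points: global divergence
  from circularity. Smaller R, rounder spheroid.
- **Smoothness `χ`**: the border is divided into 32 angular sectors of
  π/16 about `c`; σ is evaluated per sector (sector-local mean) and χ is
  the unweighted average over sectors with ≥ 2 points. Smaller χ, smoother
  margin. A smooth ellipse has large R but small χ; a ragged circle has
  χ ≈ R — the two statistics separate global from local circularity.

Also included: spheroid-size normalization across seeding densities
(percent of the 5,000-cells-per-spheroid group mean), transwell invasion
summaries (field → well → condition averaging, fold changes, unpaired
two-tailed Student t-test on per-well means), the χ-vs-invasion Spearman
correlation, satellite-aggregate detection (the failure mode that makes
highly disperse spheroids unanalyzable), and a synthetic micrograph
generator with analytic ground truth for end-to-end validation.

## Worked example

```python
import spheroshape as sp

spec = sp.rough_spec(amplitude=0.06, seed=11, ellipticity=0.03)
truth = sp.make_boundary(spec)       # analytic boundary + true metrics
img = sp.render(spec, truth)         # 16-bit brightfield-style image
metrics = sp.analyze(img)            # segment -> contour -> circle -> R, chi
```

prints (see `examples/01_shape_metrics_of_one_spheroid.py`):

```
fitted circle : center=(255.8, 255.4) r=140.3 px
roundness  R  : measured 0.0460   true 0.0474
smoothness chi: measured 0.0247   true 0.0262
area          : 61713 px^2 (analytic 61714)
```

The measured R and χ recover the analytic ground truth of the generating
boundary within a few percent despite 1 px optical blur, 2 % sensor noise
and rasterization. `examples/02_roughness_ladder.py` shows χ rising
strictly with roughness amplitude — the synthetic surrogate for increasing
endothelial content:

```
amplitude  true chi measured chi  rel err
     0.00    0.0000       0.0016       --
     0.02    0.0094       0.0094    +0.7%
     0.04    0.0187       0.0182    -3.0%
     0.06    0.0281       0.0269    -4.2%
     0.08    0.0374       0.0352    -6.0%
```

A thin CLI wraps the same pipeline for batch use:

```bash
spheroshape simulate --ladder 0,0.04,0.08 --seeds 1,2 --out scenes/
spheroshape analyze --input scenes/ --out metrics.csv
spheroshape quantify --counts counts.csv --metrics metrics.csv --out results/
```

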