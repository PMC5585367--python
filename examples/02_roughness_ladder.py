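"""Roughness ladder: chi tracks margin roughness monotonically.

Renders scenes with increasing boundary-roughness amplitude (the synthetic
stand-in for increasing endothelial-cell content of hybrid spheroids) and
shows that measured chi rises strictly with the amplitude while recovering
the analytic ground truth within a few percent.
"""

import spheroshape as sp

print(f"{'amplitude':>9} {'true chi':>9} {'measured chi':>12} {'rel err':>8}")
for amplitude in sp.DEFAULT_LADDER:
    spec = sp.rough_spec(amplitude, seed=3)
    truth = sp.make_boundary(spec)
    metrics = sp.analyze(sp.render(spec, truth))
    rel = (
        f"{(metrics.chi / truth.true_chi - 1) * 100:+.1f}%"
        if truth.true_chi
        else "  --"
    )
    print(f"{amplitude:>9.2f} {truth.true_chi:>9.4f} {metrics.chi:>12.4f} {rel:>8}")

print()
print("Rougher margins (higher amplitude) give strictly higher chi; at zero"
      " amplitude the small residual chi is the contour-quantization floor"
      " of the rasterized image.")
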