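"""Satellite detection and pipeline failure modes.

Some cell types form many small secondary aggregates ("semi-spheroids")
around the main body, which makes shape analysis of a single border
meaningless. The segmentation stage counts such satellites and the
analysis errors out cleanly on blank or clipped scenes instead of
returning numbers.
"""

import numpy as np

import spheroshape as sp

# scene with three satellite aggregates around the main spheroid
spec = sp.rough_spec(0.03, seed=21, n_satellites=3)
metrics = sp.analyze(sp.render(spec))
print(f"satellite scene: satellite_count={metrics.satellite_count} "
      f"(generated 3), chi={metrics.chi:.4f}")

# blank image: no spheroid to analyze
try:
    sp.analyze(sp.GrayImage(np.full((512, 512), 40000.0)))
except sp.NoSpheroidFoundError as exc:
    print(f"blank scene   : {exc}")

print()
print("A nonzero satellite_count flags spheroids whose morphology metrics"
      " should be interpreted with care or excluded, mirroring how highly"
      " disperse cell types resist single-border analysis.")
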