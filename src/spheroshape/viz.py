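"""Debug overlay rendering: border contour and fitted circle on the image.

Visual QC only — the quantitative pipeline never depends on plotting.
"""

from __future__ import annotations

import numpy as np

from .io import GrayImage
from .morphometry import FittedCircle
from .segmentation import BorderContour


def save_overlay(
    img: GrayImage,
    contour: BorderContour,
    circle: FittedCircle,
    path: str,
    dpi: int = 120,
) -> None:
    """Save the micrograph with the traced border (white) and the fitted
    reference circle (yellow) — the standard visual check that the
    segmentation and the circle fit are sane."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.pixels, cmap="gray", interpolation="nearest")
    xy = np.vstack([contour.xy, contour.xy[:1]])
    ax.plot(xy[:, 0], xy[:, 1], color="white", lw=1.0, label="border")
    t = np.linspace(0, 2 * np.pi, 512)
    ax.plot(
        circle.cx + circle.r * np.cos(t),
        circle.cy + circle.r * np.sin(t),
        color="yellow",
        lw=1.0,
        label="fitted circle",
    )
    ax.set_axis_off()
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
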