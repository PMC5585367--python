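import math

import numpy as np
import pytest

import spheroshape as sp

LADDER_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def ladder_results():
    """Measured vs true metrics for the roughness-amplitude ladder.

    One entry per (amplitude, seed): the Fig.-3-style surrogate where
    roughness amplitude stands in for endothelial-cell content. Rendered
    once per session; several tests read it.
    """
    rows = []
    for seed in LADDER_SEEDS:
        for amplitude in sp.DEFAULT_LADDER:
            spec = sp.rough_spec(amplitude, seed=seed)
            truth = sp.make_boundary(spec)
            metrics = sp.analyze(sp.render(spec, truth))
            rows.append(
                {
                    "amplitude": amplitude,
                    "seed": seed,
                    "true_R": truth.true_R,
                    "true_chi": truth.true_chi,
                    "true_area_px": truth.true_area_px,
                    "R": metrics.R,
                    "chi": metrics.chi,
                    "area_px": metrics.area_px,
                }
            )
    return rows


@pytest.fixture(scope="session")
def satellite_scenes():
    """20 seeded scenes with a known number of satellite aggregates."""
    scenes = []
    for i in range(20):
        n_sat = i % 4
        spec = sp.rough_spec(0.03, seed=300 + i, n_satellites=n_sat)
        metrics = sp.analyze(sp.render(spec))
        scenes.append((n_sat, metrics))
    return scenes


@pytest.fixture(scope="session")
def smooth_scene():
    spec = sp.rough_spec(0.0, seed=1)
    truth = sp.make_boundary(spec)
    return spec, truth, sp.render(spec, truth)


def analytic_contour(r_of_theta, n=2000, center=(0.0, 0.0)):
    """Dense polygonal samples of a polar boundary, for oracle-level tests."""
    theta = (np.arange(n) + 0.5) * (2 * math.pi / n)
    r = r_of_theta(theta)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
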