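"""Circle fitting and the roundness/smoothness statistics.

The shape of a spheroid is summarized by how its border deviates from a
least-squares reference circle. For a set of border points with distances
``r_i`` from the fitted center, normalized radii ``rho_i = r_i / r_c``
(``r_c`` the fitted radius) and set mean ``s = <rho>``, the *discrepancy*
of the set is the population standard deviation

    sigma = sqrt( (1/N) * sum_i (rho_i - s)^2 ).

Two statistics are built from it:

* **Roundness R** — sigma over *all* border points. A global measure of
  divergence from circularity; smaller R means a rounder spheroid. An
  ellipse with large eccentricity has large R even if its margin is
  perfectly smooth.
* **Smoothness chi** — the border is divided into ``n_sectors`` angular
  sectors (default 32, each pi/16 wide) about the fitted center; sigma is
  computed per sector with the *sector-local* mean, and chi is the
  unweighted average over sectors holding at least two points. chi is a
  local texture measure: a smooth ellipse has small chi, a ragged margin
  has large chi, regardless of global elongation.

Both statistics are dimensionless (radii are normalized by ``r_c``), hence
invariant to magnification. ``sigma_mode="circle_reference"`` replaces the
set mean by ``s = 1`` — deviation from the fitted circle itself — for
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    DegenerateCircleFitError,
    InsufficientPointsError,
    SpheroShapeError,
    ValidationError,
)
from .io import GrayImage
from .segmentation import BorderContour, SpheroidMask, extract_contour, mask_area, segment

SET_MEAN = "set_mean"
CIRCLE_REFERENCE = "circle_reference"


@dataclass(frozen=True)
class FittedCircle:
    """Least-squares circle: center ``(cx, cy)`` and radius ``r`` in px."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cx) and math.isfinite(self.cy)):
            raise ValidationError("circle center must be finite")
        if not self.r > 0:
            raise ValidationError(f"circle radius must be positive, got {self.r}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


@dataclass(frozen=True)
class RadialProfile:
    """Normalized radial distances of a border-point set.

    ``rho[i] = r_i / r_c`` for each point, ``s`` the reference level the
    discrepancy is measured about (the set mean by default, 1.0 in
    circle-reference mode).
    """

    rho: np.ndarray
    s: float

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, np.float64)
        if rho.ndim != 1:
            raise ValidationError("rho must be one-dimensional")
        if rho.size and rho.min() <= 0:
            raise ValidationError("normalized radii must be positive")
        object.__setattr__(self, "rho", rho)

    @property
    def n_points(self) -> int:
        return int(self.rho.size)


@dataclass(frozen=True)
class SectorPartition:
    """Partition of [0, 2pi) into equal half-open angular sectors.

    Sector ``k`` covers ``[k*d, (k+1)*d)`` with ``d = 2pi/n_sectors``,
    measured about the fitted-circle center from the positive x-axis.
    """

    n_sectors: int = 32

    def __post_init__(self) -> None:
        if not (isinstance(self.n_sectors, (int, np.integer)) and self.n_sectors >= 1):
            raise ValidationError(f"n_sectors must be a positive int, got {self.n_sectors}")

    @property
    def sector_angle(self) -> float:
        return 2.0 * math.pi / self.n_sectors

    def assign(self, points: np.ndarray, circle: FittedCircle) -> np.ndarray:
        """Sector index of each point's polar angle about the circle center."""
        pts = _as_points(points)
        theta = np.arctan2(pts[:, 1] - circle.cy, pts[:, 0] - circle.cx)
        theta = np.mod(theta, 2.0 * math.pi)
        idx = np.floor(theta / self.sector_angle).astype(np.intp)
        return np.minimum(idx, self.n_sectors - 1)  # guard theta == 2pi round-off


@dataclass
class ShapeMetrics:
    """Per-spheroid analysis record produced by :func:`analyze`."""

    R: float
    chi: float
    n_sectors: int
    n_valid_sectors: int
    area_px: int
    area_um2: float | None
    satellite_count: int
    circle: FittedCircle
    source_id: str = ""


def _as_points(points) -> np.ndarray:
    if isinstance(points, BorderContour):
        return points.xy
    pts = np.asarray(points, np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected an (N, 2) point array, got shape {pts.shape}")
    return pts


def fit_circle(points) -> FittedCircle:
    """Fit a circle to 2-D points by Pratt's algebraic least squares.

    Minimizes the algebraic residual ``A(x^2+y^2) + Bx + Cy + D`` subject
    to ``B^2 + C^2 - 4AD = 1``, solved as a generalized eigenproblem.
    Non-iterative, deterministic, and essentially unbiased for the
    near-circular contours this pipeline produces.

    Raises
    ------
    DegenerateCircleFitError
        Fewer than 3 points, collinear points, or a vanishing curvature
        coefficient (the best algebraic fit is a line).
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateCircleFitError("degenerate circle fit: need >= 3 points")
    x = pts[:, 0]
    y = pts[:, 1]
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    # collinearity: second singular value of the centered coordinates
    sv = np.linalg.svd(np.column_stack([u, v]), compute_uv=False)
    if sv[1] / max(sv[0], 1e-30) < 1e-9:
        raise DegenerateCircleFitError("degenerate circle fit: collinear points")

    # scale to unit RMS radius: the generalized eigenproblem is badly
    # conditioned at raw pixel scale (z ~ r^2 dwarfs the other columns)
    scale = math.sqrt(float(np.mean(u * u + v * v)))
    u = u / scale
    v = v / scale
    z = u * u + v * v
    W = np.column_stack([z, u, v, np.ones_like(u)])
    M = (W.T @ W) / len(u)
    B = np.array(
        [
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ]
    )
    vals, vecs = scipy.linalg.eig(M, B)
    best = None
    best_res = np.inf
    for val, vec in zip(vals, vecs.T):
        if not np.isfinite(val.real) or abs(val.imag) > 1e-8 * (1 + abs(val.real)):
            continue
        vec = vec.real
        norm = vec[1] ** 2 + vec[2] ** 2 - 4.0 * vec[0] * vec[3]
        if norm <= 0:
            continue
        res = float(vec @ M @ vec) / norm
        if res < best_res:
            best_res = res
            best = vec / math.sqrt(norm)
    if best is None or abs(best[0]) < 1e-12:
        raise DegenerateCircleFitError("degenerate circle fit: no circular solution")
    A, Bc, Cc, D = best
    cx = -Bc / (2.0 * A) * scale
    cy = -Cc / (2.0 * A) * scale
    r = scale / (2.0 * abs(A))  # sqrt(B^2+C^2-4AD)=1 after normalization
    return FittedCircle(cx + xm, cy + ym, r)


def radial_profile(points, circle: FittedCircle, sigma_mode: str = SET_MEAN) -> RadialProfile:
    """Normalized radial distances of points about a fitted circle."""
    pts = _as_points(points)
    r = np.hypot(pts[:, 0] - circle.cx, pts[:, 1] - circle.cy)
    rho = r / circle.r
    if sigma_mode == SET_MEAN:
        s = float(rho.mean()) if rho.size else 1.0
    elif sigma_mode == CIRCLE_REFERENCE:
        s = 1.0
    else:
        raise ValidationError(f"unknown sigma_mode {sigma_mode!r}")
    return RadialProfile(rho=rho, s=s)


def discrepancy_sigma(profile: RadialProfile) -> float:
    """Root-mean-square deviation of normalized radii about the reference.

    ``sigma = sqrt( (1/N) * sum (rho_i - s)^2 )`` — zero iff every point
    sits at the reference level; needs at least two points.
    """
    if profile.n_points < 2:
        raise InsufficientPointsError(
            f"insufficient points for discrepancy: {profile.n_points}"
        )
    dev = profile.rho - profile.s
    return float(np.sqrt(np.mean(dev * dev)))


def roundness(points, circle: FittedCircle, sigma_mode: str = SET_MEAN) -> float:
    """Global roundness R: discrepancy over *all* border points."""
    return discrepancy_sigma(radial_profile(points, circle, sigma_mode))


def smoothness(
    points,
    circle: FittedCircle,
    partition: SectorPartition | int = 32,
    sigma_mode: str = SET_MEAN,
) -> tuple[float, int]:
    """Local smoothness chi and the number of valid sectors.

    Per sector holding >= 2 points, the discrepancy is computed with the
    sector-local reference; chi is the unweighted mean over those sectors.
    Sparse sectors are excluded, not zero-filled.
    """
    if isinstance(partition, int):
        partition = SectorPartition(partition)
    pts = _as_points(points)
    idx = partition.assign(pts, circle)
    sigmas = []
    for k in range(partition.n_sectors):
        sel = pts[idx == k]
        if len(sel) < 2:
            continue
        sigmas.append(discrepancy_sigma(radial_profile(sel, circle, sigma_mode)))
    if not sigmas:
        raise InsufficientPointsError("contour too sparse for chi: no valid sector")
    return float(np.mean(sigmas)), len(sigmas)


def analyze(
    img: GrayImage,
    polarity: str = "dark_object",
    min_area_px: int = 200,
    sigma_px: float = 2.0,
    closing_radius_px: int = 3,
    satellite_ratio: float = 0.10,
    n_sectors: int = 32,
    sigma_mode: str = SET_MEAN,
) -> ShapeMetrics:
    """Run the full pipeline on one micrograph.

    segment -> extract_contour -> fit_circle -> R, chi, areas, satellites.
    Deterministic; stage failures propagate with the stage name attached.
    """

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except SpheroShapeError as exc:
            exc.stage = exc.stage or name
            raise

    mask = _stage(
        "segment",
        segment,
        img,
        polarity=polarity,
        min_area_px=min_area_px,
        sigma_px=sigma_px,
        closing_radius_px=closing_radius_px,
        satellite_ratio=satellite_ratio,
    )
    contour = _stage("extract_contour", extract_contour, mask)
    circle = _stage("fit_circle", fit_circle, contour)
    r_value = _stage("roundness", roundness, contour, circle, sigma_mode)
    chi, n_valid = _stage(
        "smoothness", smoothness, contour, circle, SectorPartition(n_sectors), sigma_mode
    )
    area_px, area_um2 = mask_area(mask, img.pixel_size_um)
    return ShapeMetrics(
        R=r_value,
        chi=chi,
        n_sectors=n_sectors,
        n_valid_sectors=n_valid,
        area_px=area_px,
        area_um2=area_um2,
        satellite_count=mask.satellite_count,
        circle=circle,
        source_id=img.source_id,
    )
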