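"""MSAC outlier rejection and least-squares plane fitting for leaf point clouds.

A cabbage leaf seen from above is close to planar; its depth pixels, however,
carry SfM speckle and occasional gross outliers (matching failures, pixels from
an overlapping leaf). The two-step treatment mirrors standard robust practice:

1. MSAC — an M-estimator sample consensus, i.e. RANSAC whose candidate score is
   the truncated squared residual Σ min(r², tol²) rather than an inlier count —
   selects the dominant planar subset.
2. An ordinary multiple linear regression of z on (x, y) over the inliers gives
   the final plane in graph form z = a·x + b·y + c.

Scoring uses orthogonal point-plane distances (the MSAC convention); the final
refit minimises vertical residuals (the regression formulation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import DegenerateGeometryError
from .io_formats import LeafPointCloud


@dataclass(frozen=True)
class Plane:
    """Plane in graph form z = a·x + b·y + c (slopes mm/mm, offset mm)."""

    a: float
    b: float
    c: float
    inlier_count: int = 3

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("plane coefficients must be finite")
        if self.inlier_count < 3:
            raise ValueError("a plane needs at least 3 supporting points")

    def z_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c


@dataclass(frozen=True)
class MsacConfig:
    """MSAC parameters.

    distance_tolerance is the orthogonal residual (mm) beyond which a point
    stops contributing evidence; 10 mm is on the order of leaf thickness plus
    SfM depth noise. min_inlier_fraction below which the result is flagged
    low-support rather than rejected.
    """

    distance_tolerance: float = 10.0
    max_iterations: int = 500
    min_inlier_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_tolerance <= 0:
            raise ValueError("distance_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if not (0 < self.min_inlier_fraction <= 1):
            raise ValueError("min_inlier_fraction must lie in (0, 1]")


def _plane_through_three(p: np.ndarray) -> Plane | None:
    """Exact plane through 3 points, or None if degenerate/vertical."""
    v1, v2 = p[1] - p[0], p[2] - p[0]
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    if norm < 1e-12 or abs(n[2]) < 1e-12 * norm:
        return None  # collinear, or plane vertical (no graph form)
    a = -n[0] / n[2]
    b = -n[1] / n[2]
    c = p[0, 2] - a * p[0, 0] - b * p[0, 1]
    return Plane(a=a, b=b, c=c)


def plane_residual(
    plane: Plane,
    point: np.ndarray,
    mode: Literal["vertical", "orthogonal"] = "orthogonal",
) -> float | np.ndarray:
    """Distance (mm) from point(s) to the plane.

    Vertical: |z − a·x − b·y − c|. Orthogonal: the vertical residual divided by
    sqrt(a² + b² + 1), the true point-plane distance.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    r = np.abs(pts[:, 2] - plane.z_at(pts[:, 0], pts[:, 1]))
    if mode == "orthogonal":
        r = r / np.sqrt(plane.a**2 + plane.b**2 + 1.0)
    elif mode != "vertical":
        raise ValueError(f"unknown residual mode {mode!r}")
    return float(r[0]) if np.ndim(point) == 1 else r


def msac_filter(cloud: LeafPointCloud, config: MsacConfig | None = None) -> LeafPointCloud:
    """Return the inlier subset of the MSAC-best plane.

    Candidate planes come from random 3-point samples; each is scored by
    Σ min(orthogonal_residual², tolerance²) over the whole cloud and the
    minimum-score plane wins. Deterministic given ``config.rng_seed``. The
    result carries ``low_support=True`` when the winning inlier fraction falls
    below ``config.min_inlier_fraction``.
    """
    config = config or MsacConfig()
    pts = cloud.points
    n = len(pts)
    rng = np.random.default_rng(config.rng_seed)
    tol2 = config.distance_tolerance**2

    best_score = np.inf
    best_inliers: np.ndarray | None = None
    n_degenerate = 0
    for _ in range(config.max_iterations):
        idx = rng.choice(n, size=3, replace=False)
        plane = _plane_through_three(pts[idx])
        if plane is None:
            n_degenerate += 1
            continue
        r2 = np.square(plane_residual(plane, pts, mode="orthogonal"))
        score = float(np.minimum(r2, tol2).sum())
        if score < best_score:
            best_score = score
            best_inliers = r2 <= tol2
    if best_inliers is None:
        raise DegenerateGeometryError(
            f"leaf {cloud.leaf_id}: all {n_degenerate} candidate samples were "
            "collinear; cannot fit a plane"
        )
    inliers = pts[best_inliers]
    low = best_inliers.mean() < config.min_inlier_fraction
    return LeafPointCloud(
        points=inliers,
        leaf_id=cloud.leaf_id,
        plant_id=cloud.plant_id,
        low_support=bool(low),
    )


def fit_plane_lsq(cloud: LeafPointCloud) -> Plane:
    """Least-squares plane z = a·x + b·y + c minimising vertical residuals.

    Solved by QR-based ``lstsq`` on the design matrix [x, y, 1]; raises
    DegenerateGeometryError when the (x, y) footprint is collinear.
    """
    pts = cloud.points
    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, np.abs(design).max())) < 3:
        raise DegenerateGeometryError(
            f"leaf {cloud.leaf_id}: (x, y) footprint is collinear; plane is "
            "not identifiable from vertical residuals"
        )
    coef, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    return Plane(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]), inlier_count=len(pts))


def fit_leaf_plane(cloud: LeafPointCloud, config: MsacConfig | None = None) -> tuple[Plane, LeafPointCloud]:
    """Consensus-then-refit: MSAC inliers, then the regression plane on them."""
    inliers = msac_filter(cloud, config)
    plane = fit_plane_lsq(inliers)
    return plane, inliers
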