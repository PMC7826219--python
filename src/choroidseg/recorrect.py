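"""Candidate recorrection: RANSAC outlier rejection plus the anatomical
shape constraint (the choroid always lies below Bruch's membrane).

The heat-map candidates contain misdetections from vessel shadows and
speckle; RANSAC repeatedly fits a low-order polynomial to random minimal
subsets and keeps the largest consensus of points within a pixel
threshold.  The shape constraint is applied afterwards as an independent
hard filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heatmap import CandidatePoints
from .trace import BoundaryTrace


@dataclass
class RansacConfig:
    """Consensus-model settings: cubic polynomial, 5-px inlier threshold,
    500 seeded iterations (the anatomy is smooth, so a cubic consensus
    matches the fallback fitting degree)."""

    model_degree: int = 3
    inlier_threshold: float = 5.0
    iterations: int = 500
    seed: int = 0

    @property
    def min_samples(self) -> int:
        return self.model_degree + 1

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.inlier_threshold <= 0:
            raise ValueError("inlier_threshold must be positive")


def ransac_filter(points: CandidatePoints, cfg: RansacConfig | None = None) -> CandidatePoints:
    """Largest-consensus subset of the candidates (x order preserved).

    Ties on inlier count break toward the smaller inlier residual sum.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or RansacConfig()
    m = len(points)
    if m < cfg.min_samples:
        raise ValueError(f"need at least {cfg.min_samples} points for RANSAC, got {m}")
    x = points.x.astype(float)
    y = points.y.astype(float)
    rng = np.random.default_rng(cfg.seed)
    span = [float(x.min()), float(x.max())] if x.min() < x.max() else [0.0, 1.0]

    best_mask = None
    best_count = -1
    best_resid = np.inf
    for _ in range(cfg.iterations):
        idx = rng.choice(m, size=cfg.min_samples, replace=False)
        try:
            poly = np.polynomial.Polynomial.fit(x[idx], y[idx], cfg.model_degree, domain=span)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate sample
            continue
        resid = np.abs(poly(x) - y)
        mask = resid <= cfg.inlier_threshold
        count = int(mask.sum())
        rsum = float(resid[mask].sum())
        if count > best_count or (count == best_count and rsum < best_resid):
            best_mask, best_count, best_resid = mask, count, rsum
    return points.subset(best_mask)


def shape_constraint_filter(points: CandidatePoints, bm: BoundaryTrace,
                            margin: float = 0.0) -> CandidatePoints:
    """Drop every candidate at or above the BM curve (plus ``margin`` px).

    Keeps points with y > bm(x) + margin; idempotent, order preserved.
    """
    if len(points) == 0:
        return points
    keep = points.y > bm(points.x) + margin
    return points.subset(keep)
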