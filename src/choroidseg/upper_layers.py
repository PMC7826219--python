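"""RPE and Bruch's-membrane detection from image physics.

The RPE is the brightest layer in a retinal B-scan after light reflection,
so its curve is anchored on per-column intensity maxima.  The BM is the
lower boundary of the ~5-px-thick RPE complex and is located as the
strongest vertical intensity edge in the 5-pixel band below the RPE curve.
Both point sets are smoothed by a cubic least-squares fit.
"""

from __future__ import annotations

import numpy as np

from .trace import BoundaryTrace, round_half_up

#: assumed RPE complex thickness in pixels; sets the BM search band height
RPE_THICKNESS_PX = 5


def fit_cubic(x: np.ndarray, values: np.ndarray, width: int) -> BoundaryTrace:
    """Least-squares cubic polynomial through (x, values), evaluated on 0..width-1.

    Uses a scaled fitting domain so the Vandermonde system stays
    well-conditioned at 600-pixel widths.
    """
    poly = np.polynomial.Polynomial.fit(x, values, deg=3, domain=[0, width - 1])
    return BoundaryTrace.from_polynomial(poly, width)


def detect_rpe(img: np.ndarray) -> BoundaryTrace:
    """Locate the RPE curve from per-column intensity maxima.

    For each column the row of the maximum intensity is taken (ties go to
    the smallest row index); the returned trace is the cubic least-squares
    fit through those points.  Invariant to adding a constant to all
    intensities.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 4:
        raise ValueError("expected a 2-D image with at least 4 rows")
    if img.max() == img.min():
        raise ValueError("no distinguishable RPE: image is constant")
    peaks = np.argmax(img, axis=0)  # first occurrence = smallest row
    x = np.arange(img.shape[1])
    return fit_cubic(x, peaks.astype(float), img.shape[1])


def detect_bm(img: np.ndarray, rpe: BoundaryTrace) -> BoundaryTrace:
    """Segment Bruch's membrane below the RPE curve.

    In each column the candidate row maximizes the absolute vertical
    forward difference |I(r+1) - I(r)| over the band of RPE_THICKNESS_PX
    rows starting at the (rounded) RPE row — the BM is the strong edge at
    the bottom of the bright RPE complex.  Ties go to the smallest row.
    Columns whose band falls outside the image are skipped; if more than
    half the columns are skipped the detection fails.
    """
    img = np.asarray(img, dtype=float)
    H, W = img.shape
    if rpe.width != W:
        raise ValueError("RPE trace width does not match image width")
    diff = np.abs(np.diff(img, axis=0))  # diff[r, i] = |I(r+1,i) - I(r,i)|
    top = round_half_up(rpe.rows)
    xs, qs = [], []
    for i in range(W):
        lo = max(top[i], 0)
        hi = min(top[i] + RPE_THICKNESS_PX, H - 2)  # forward diff needs row r+1
        if lo > hi:
            continue
        band = diff[lo : hi + 1, i]
        xs.append(i)
        qs.append(lo + int(np.argmax(band)))
    if len(xs) < W / 2:
        raise ValueError("BM band outside image for more than half the columns")
    return fit_cubic(np.asarray(xs), np.asarray(qs, dtype=float), W)


def bm_error(pred: BoundaryTrace, truth: BoundaryTrace) -> float:
    """Mean absolute per-column error between two traces, in pixels."""
    if pred.width != truth.width:
        raise ValueError("trace widths differ")
    return float(np.mean(np.abs(pred.rows - truth.rows)))


def crop_above_bm(img: np.ndarray, bm: BoundaryTrace) -> np.ndarray:
    """Zero every pixel above the (rounded) BM row; dimensions preserved.

    Removes the retina above Bruch's membrane so the patch classifier only
    sees choroid-relevant structure.  Idempotent.
    """
    img = np.asarray(img)
    H, W = img.shape
    if bm.width != W:
        raise ValueError("BM trace width does not match image width")
    bm_px = round_half_up(bm.rows)
    mask = np.arange(H)[:, None] < bm_px[None, :]
    out = img.copy()
    out[mask] = 0
    return out
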