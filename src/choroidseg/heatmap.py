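"""Prediction heat map and per-column CSI candidate extraction.

The trained classifier is slid over the BM-cropped image at stride 3;
each 32x32 patch writes 255*p into its central 6x6 recognition area of the
heat-map matrix M, and cells covered by several patches hold the average.
One candidate interface point per column is then read off as the center of
the best three-consecutive-row window of M.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .patching import CENTER_HI, CENTER_LO, INFER_STRIDE, extract_patches, make_grid

#: heat-map value of a p=0.5 prediction; columns below it yield no candidate
DEFAULT_PEAK_THRESHOLD = 255.0 / 2.0


@dataclass
class HeatMap:
    """Accumulated prediction matrix M (values in [0, 255]) and coverage counts."""

    M: np.ndarray
    counts: np.ndarray

    def to_png(self, path) -> None:
        Image.fromarray(np.clip(np.rint(self.M), 0, 255).astype(np.uint8), mode="L").save(path)


@dataclass
class CandidatePoints:
    """At most one candidate (x, y) per column, x strictly increasing."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise ValueError("candidate columns must be strictly increasing")
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def points(self) -> list:
        return list(zip(self.x.tolist(), self.y.tolist()))

    def subset(self, mask: np.ndarray) -> "CandidatePoints":
        return CandidatePoints(self.x[mask], self.y[mask])

    def to_csv(self, path) -> None:
        np.savetxt(Path(path), np.column_stack([self.x, self.y]), fmt="%d,%.3f",
                   header="x,y", comments="")


def build_heatmap(img: np.ndarray, model, stride: int = INFER_STRIDE,
                  batch_size: int = 256) -> HeatMap:
    """Accumulate classifier predictions over a stride-3 patch grid.

    ``model`` is either a trained network with ``predict_proba`` or any
    callable mapping a (N, 32, 32) stack of [0, 1] patches to N
    probabilities (an oracle predictor, for instance).  Each patch's
    central 6x6 block of M receives 255*p; overlapping patches average.
    """
    img = np.asarray(img)
    H, W = img.shape
    grid = make_grid(H, W, stride=stride)
    patches = extract_patches(img, grid)
    predict = model.predict_proba if hasattr(model, "predict_proba") else model
    p = np.empty(len(patches), dtype=np.float64)
    for s in range(0, len(patches), batch_size):
        p[s : s + batch_size] = predict(patches[s : s + batch_size])

    sums = np.zeros((H, W), dtype=np.float64)
    counts = np.zeros((H, W), dtype=np.int64)
    span = CENTER_HI - CENTER_LO + 1
    for (top, left), pk in zip(grid.coords, p):
        r0, c0 = top + CENTER_LO, left + CENTER_LO
        sums[r0 : r0 + span, c0 : c0 + span] += pk
        counts[r0 : r0 + span, c0 : c0 + span] += 1
    M = np.zeros_like(sums)
    covered = counts > 0
    M[covered] = 255.0 * sums[covered] / counts[covered]
    return HeatMap(M=M, counts=counts)


def extract_column_candidates(hm: HeatMap,
                              peak_threshold: float = DEFAULT_PEAK_THRESHOLD) -> CandidatePoints:
    """One candidate row per column: center of the best 3-consecutive-row window.

    For each column the row r (interior rows only) maximizing
    M[r-1]+M[r]+M[r+1] is the candidate — the "center element of three
    continuous largest elements".  Ties break to the smallest row; columns
    whose best window mean falls below ``peak_threshold`` contribute no
    point, so the output may cover fewer than W columns.
    """
    M = hm.M
    H, W = M.shape
    if H < 3:
        raise ValueError("heat map needs at least 3 rows")
    win = M[:-2, :] + M[1:-1, :] + M[2:, :]  # win[r-1] = sum over rows r-1..r+1
    best = np.argmax(win, axis=0)  # first max = smallest row
    rows = best + 1
    keep = win[best, np.arange(W)] / 3.0 >= peak_threshold
    return CandidatePoints(np.flatnonzero(keep), rows[keep].astype(float))
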