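"""Patch grids and the 6x6 recognition-area labeling rule.

Images are cut into 32x32 patches on a regular grid, left-to-right then
top-to-bottom.  A patch is a positive ("on-line") sample only when the CSI
ground truth passes through its central 6x6 recognition area — not merely
through the patch — which keeps boundary features centered and makes the
class ratio roughly 1:11 on 150x600 B-scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import GroundTruth
from .trace import BoundaryTrace, round_half_up

log = logging.getLogger(__name__)

PATCH_SIZE = 32
TRAIN_STRIDE = 8
INFER_STRIDE = 3
#: 0-based offsets of the central 6x6 recognition area inside a 32x32 patch
CENTER_LO, CENTER_HI = 13, 18


@dataclass(frozen=True)
class PatchGrid:
    """Regular grid of fully-contained patch positions (row-major order)."""

    patch_size: int
    stride: int
    n_rows: int
    n_cols: int

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of (top_row, left_col), left-to-right, top-to-bottom."""
        tops = np.arange(self.n_rows) * self.stride
        lefts = np.arange(self.n_cols) * self.stride
        rr, cc = np.meshgrid(tops, lefts, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def __len__(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class LabeledPatch:
    pixels: np.ndarray
    coord: tuple
    label: int


def make_grid(H: int, W: int, patch: int = PATCH_SIZE, stride: int = TRAIN_STRIDE) -> PatchGrid:
    """Enumerate fully-contained patch positions; partial edge patches are
    discarded (a 150x600 image at stride 3 yields 40 x 190 = 7600 patches)."""
    if patch > H or patch > W:
        raise ValueError("patch size exceeds image dimensions")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n_rows = (H - patch) // stride + 1
    n_cols = (W - patch) // stride + 1
    return PatchGrid(patch_size=patch, stride=stride, n_rows=n_rows, n_cols=n_cols)


def label_patch(coord: tuple, truth_csi: BoundaryTrace, patch: int = PATCH_SIZE) -> int:
    """1 iff the CSI curve passes through the patch's central 6x6 area.

    The recognition area of a 32x32 patch is rows/cols 13..18 relative to
    its top-left corner; the curve "passes through" when its rounded row at
    some center column lands inside the center rows.
    """
    top, left = int(coord[0]), int(coord[1])
    cols = np.arange(left + CENTER_LO, left + CENTER_HI + 1)
    cols = cols[(cols >= 0) & (cols < truth_csi.width)]
    if cols.size == 0:
        return 0
    rows = round_half_up(truth_csi(cols))
    lo, hi = top + CENTER_LO, top + CENTER_HI
    return int(np.any((rows >= lo) & (rows <= hi)))


def grid_labels(grid: PatchGrid, truth_csi: BoundaryTrace) -> np.ndarray:
    """Vectorized ``label_patch`` over a whole grid (same rule)."""
    labels = np.zeros(len(grid), dtype=np.int8)
    coords = grid.coords
    csi_px = round_half_up(truth_csi(np.arange(truth_csi.width)))
    for k, (top, left) in enumerate(coords):
        cols = np.arange(left + CENTER_LO, left + CENTER_HI + 1)
        cols = cols[(cols >= 0) & (cols < truth_csi.width)]
        rows = csi_px[cols]
        labels[k] = int(np.any((rows >= top + CENTER_LO) & (rows <= top + CENTER_HI)))
    return labels


def extract_patches(img: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """(N, patch, patch) float32 stack of patch pixels, scaled to [0, 1]."""
    img = np.asarray(img, dtype=np.float32) / 255.0
    p = grid.patch_size
    s = grid.stride
    windows = np.lib.stride_tricks.sliding_window_view(img, (p, p))[::s, ::s]
    return windows.reshape(-1, p, p).copy()


def build_training_set(
    images: list,
    truths: list[GroundTruth],
    stride: int = TRAIN_STRIDE,
    augment_flip: bool = False,
) -> list[LabeledPatch]:
    """Label stride-8 patches of BM-cropped images by the recognition-area rule.

    Images are expected to be cropped above the BM already.  Optional
    horizontal-flip augmentation doubles the set; off by default.
    """
    if len(images) == 0 or len(images) != len(truths):
        raise ValueError("need a non-empty, aligned list of images and truths")
    out: list[LabeledPatch] = []
    for img, truth in zip(images, truths):
        H, W = np.asarray(img).shape
        grid = make_grid(H, W, stride=stride)
        patches = extract_patches(img, grid)
        labels = grid_labels(grid, truth.csi)
        for pix, (top, left), lab in zip(patches, grid.coords, labels):
            out.append(LabeledPatch(pixels=pix, coord=(int(top), int(left)), label=int(lab)))
            if augment_flip:
                out.append(
                    LabeledPatch(pixels=pix[:, ::-1].copy(), coord=(int(top), int(left)), label=int(lab))
                )
    n_pos = sum(p.label for p in out)
    n_neg = len(out) - n_pos
    log.info("training set: %d patches, positive:negative = %d:%d", len(out), n_pos, n_neg)
    return out


def patch_arrays(dataset: list[LabeledPatch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a labeled-patch list into (X, y) arrays for training."""
    X = np.stack([p.pixels for p in dataset]).astype(np.float32)
    y = np.array([p.label for p in dataset], dtype=np.int64)
    return X, y


def save_patch_dataset(directory, dataset: list[LabeledPatch],
                       image_ids: list | None = None) -> None:
    """Persist a labeled-patch set: pixel stack plus a CSV manifest
    (image_id, top_row, left_col, label)."""
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X, y = patch_arrays(dataset)
    np.save(directory / "patches.npy", X)
    pd.DataFrame(
        {
            "image_id": image_ids if image_ids is not None else [0] * len(dataset),
            "top_row": [p.coord[0] for p in dataset],
            "left_col": [p.coord[1] for p in dataset],
            "label": y,
        }
    ).to_csv(directory / "manifest.csv", index=False)


def load_patch_dataset(directory) -> list[LabeledPatch]:
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    X = np.load(directory / "patches.npy")
    manifest = pd.read_csv(directory / "manifest.csv")
    return [
        LabeledPatch(pixels=X[i], coord=(int(r.top_row), int(r.left_col)), label=int(r.label))
        for i, r in enumerate(manifest.itertuples())
    ]
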