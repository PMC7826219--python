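"""Synthetic OCT-like B-scan phantoms with known layer ground truth.

Real EDI-OCT choroid data is restricted, so the pipeline is exercised on
phantoms that emulate the image structure the method assumes: a bright
retinal-pigment-epithelium (RPE) complex whose peak dominates every column,
a sharp Bruch's-membrane (BM) step a few pixels below the RPE peak, a
choroid band of intermediate intensity, and a lower-contrast
choroidal-scleral interface (CSI) following a smooth polynomial.  Speckle
noise and vertical vessel-shadow artifacts supply the misdetections the
RANSAC stage must survive.

Conventions: row 0 is the top of the image; the BM ground-truth row is the
last bright RPE-complex row, so the choroid starts at ``bm + 1`` and the
largest vertical forward difference in the sub-RPE band falls exactly on
the BM row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .trace import BoundaryTrace, round_half_up

#: intensity drop per row away from the RPE peak inside the RPE complex
_RPE_SHOULDER_DROP = 10.0
#: multiplicative intensity dip inside a vessel shadow
_SHADOW_FACTOR = 0.45


@dataclass
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    Polynomials are coefficient lists in ascending order of the column
    coordinate x (``c0 + c1*x + c2*x**2 + ...``) and give the row position
    of the curve.  Intensities are on the 8-bit [0, 255] scale.
    """

    seed: int = 0
    width: int = 600
    height: int = 150
    rpe_poly: tuple = (38.0, 0.02, -3.0e-5)
    rpe_brightness: float = 220.0
    rpe_halfwidth: int = 2
    bm_offset: int = 5
    csi_poly: tuple = (95.0, 0.03, -5.0e-5)
    choroid_mean: float = 110.0
    sclera_mean: float = 60.0
    vitreous_mean: float = 25.0
    speckle_sigma: float = 8.0
    n_shadows: int = 2
    shadow_width: int = 18

    def _curve(self, coeffs) -> np.ndarray:
        x = np.arange(self.width, dtype=float)
        return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))

    def rpe_rows(self) -> np.ndarray:
        return self._curve(self.rpe_poly)

    def bm_rows(self) -> np.ndarray:
        return self.rpe_rows() + self.bm_offset

    def csi_rows(self) -> np.ndarray:
        return self._curve(self.csi_poly)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        rpe, bm, csi = self.rpe_rows(), self.bm_rows(), self.csi_rows()
        floor = 4.0 * self.speckle_sigma
        for name, mean in (
            ("vitreous_mean", self.vitreous_mean),
            ("choroid_mean", self.choroid_mean),
            ("sclera_mean", self.sclera_mean),
        ):
            if not self.rpe_brightness > mean + floor:
                raise ValueError(
                    f"brightness ordering violated: rpe_brightness must exceed "
                    f"{name} + 4*speckle_sigma ({mean + floor:.1f})"
                )
        if self.bm_offset < 1:
            raise ValueError("bm_offset must be >= 1 (BM lies below the RPE peak)")
        if not np.all(csi > bm):
            raise ValueError("curve ordering violated: csi row must exceed bm row in every column")
        if np.any(rpe - self.rpe_halfwidth < 0) or np.any(csi > self.height - 1) or np.any(
            bm > self.height - 1
        ):
            raise ValueError("curves out of bounds: all bands must lie inside [0, height-1]")


@dataclass
class GroundTruth:
    """Known boundary curves of a phantom (exact generating polynomials)."""

    bm: BoundaryTrace
    csi: BoundaryTrace
    rpe: BoundaryTrace | None = field(default=None)

    def __post_init__(self):
        if not np.all(self.csi.rows > self.bm.rows):
            raise ValueError("ground truth requires csi(x) > bm(x): choroid lies below the BM")


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom B-scan and its exact ground truth.

    Deterministic given ``spec.seed``; returns an ``(H, W)`` uint8 image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width

    rpe = spec.rpe_rows()
    bm = spec.bm_rows()
    csi = spec.csi_rows()
    r0 = round_half_up(rpe)
    bm_px = r0 + spec.bm_offset
    csi_px = round_half_up(csi)

    rows = np.arange(H)[:, None]  # (H, 1) broadcast against columns
    img = np.full((H, W), spec.vitreous_mean, dtype=float)
    img[rows > csi_px[None, :]] = spec.sclera_mean
    in_choroid = (rows > bm_px[None, :]) & (rows <= csi_px[None, :])
    img[in_choroid] = spec.choroid_mean
    # RPE complex: peaked at r0, shoulders falling off, extending down to BM
    in_rpe = (rows >= (r0 - spec.rpe_halfwidth)[None, :]) & (rows <= bm_px[None, :])
    shoulder = spec.rpe_brightness - _RPE_SHOULDER_DROP * np.abs(rows - r0[None, :])
    img[in_rpe] = np.maximum(shoulder, spec.choroid_mean + 50.0)[in_rpe]

    # vessel shadows: multiplicative dips in vertical strips of the choroid
    for _ in range(spec.n_shadows):
        c = int(rng.integers(0, W))
        half = max(1, spec.shadow_width // 2)
        lo, hi = max(0, c - half), min(W, c + half)
        strip = in_choroid[:, lo:hi]
        img[:, lo:hi][strip] *= _SHADOW_FACTOR

    if spec.speckle_sigma > 0:
        img = img + rng.normal(0.0, spec.speckle_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        bm=BoundaryTrace(bm),
        csi=BoundaryTrace(csi),
        rpe=BoundaryTrace(rpe),
    )
    return img, truth


def write_phantom(directory, index: int, img: np.ndarray, truth: GroundTruth) -> None:
    """Write an 8-bit grayscale PNG and a (x, bm_row, csi_row) CSV, 0-based."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode="L").save(directory / f"phantom_{index:03d}.png")
    arr = np.column_stack([np.arange(img.shape[1]), truth.bm.rows, truth.csi.rows])
    np.savetxt(
        directory / f"phantom_{index:03d}_truth.csv",
        arr,
        fmt="%d,%.6f,%.6f",
        header="x,bm_row,csi_row",
        comments="",
    )


def load_truth_csv(path) -> GroundTruth:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return GroundTruth(bm=BoundaryTrace(arr[:, 1]), csi=BoundaryTrace(arr[:, 2]))
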