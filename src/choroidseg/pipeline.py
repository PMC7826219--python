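"""End-to-end segmentation: upper layers -> heat map -> recorrection -> fit.

``segment_image`` chains every stage on one 150x600 B-scan: RPE and BM
detection from image physics, BM-cropping, the CNN heat map, per-column
candidate extraction, RANSAC plus the below-BM shape constraint, the
sparse l2-lq polynomial fit of the CSI, and the minimum-distance thickness
profile.  When ground truth is supplied the evaluation metrics are
attached to the result.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _resize

from . import lqfit, metrics, upper_layers
from .heatmap import DEFAULT_PEAK_THRESHOLD, CandidatePoints, HeatMap, build_heatmap, \
    extract_column_candidates
from .phantom import GroundTruth
from .recorrect import RansacConfig, ransac_filter, shape_constraint_filter
from .trace import BoundaryTrace

log = logging.getLogger(__name__)

WORK_H, WORK_W = 150, 600


@dataclass
class PipelineConfig:
    """Frozen method defaults: lambda=1, q=0.1, xi=0.1; stride-3 inference;
    cubic RANSAC at 5 px; candidate threshold at probability 0.5."""

    lam: float = lqfit.DEFAULT_LAMBDA
    q: float = lqfit.DEFAULT_Q
    xi: float = lqfit.DEFAULT_XI
    degree: int | None = None  # None = extent-based degree rule
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD
    shape_margin: float = 0.0
    ransac: RansacConfig = field(default_factory=RansacConfig)
    seed: int = 0

    def __post_init__(self):
        # the RANSAC stage derives its seed from the pipeline seed
        self.ransac = replace(self.ransac, seed=self.seed)


@dataclass
class SegmentationResult:
    rpe: BoundaryTrace
    bm: BoundaryTrace
    heat: HeatMap
    candidates_raw: CandidatePoints
    candidates_filtered: CandidatePoints
    csi_fit: lqfit.FitResult
    csi: BoundaryTrace
    thickness: metrics.ThicknessProfile
    report: metrics.MetricsReport | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def load_image(path) -> np.ndarray:
    """Load a grayscale image, resizing to 150x600 (bilinear) if needed."""
    img = np.asarray(Image.open(path).convert("L"))
    if img.shape != (WORK_H, WORK_W):
        img = _resize(img.astype(float), (WORK_H, WORK_W), order=1,
                      preserve_range=True, anti_aliasing=False)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def segment_image(
    img: np.ndarray,
    model,
    config: PipelineConfig | None = None,
    truth: GroundTruth | None = None,
    debug_dir=None,
) -> SegmentationResult:
    """Run the full segmentation chain on one image.

    ``model`` is a trained patch classifier (or any patch-probability
    callable).  Deterministic given the model and ``config.seed``.  A
    failing stage raises :class:`StageError` naming the stage; when
    ``debug_dir`` is given every intermediate computed so far is persisted
    there first.
    """
    config = config or PipelineConfig()
    img = np.asarray(img)
    done: dict[str, object] = {}

    def run(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except StageError:
            raise
        except Exception as e:
            if debug_dir is not None:
                _dump_debug(debug_dir, done)
            raise StageError(stage, e) from e
        log.info("stage %-22s %6.2f s", stage, time.perf_counter() - t0)
        done[stage] = out
        return out

    rpe = run("detect_rpe", lambda: upper_layers.detect_rpe(img))
    bm = run("detect_bm", lambda: upper_layers.detect_bm(img, rpe))
    cropped = run("crop_above_bm", lambda: upper_layers.crop_above_bm(img, bm))
    heat = run("build_heatmap", lambda: build_heatmap(cropped, model))
    raw = run("extract_candidates",
              lambda: extract_column_candidates(heat, config.peak_threshold))
    kept = run("ransac_filter", lambda: ransac_filter(raw, config.ransac))
    kept = run("shape_constraint",
               lambda: shape_constraint_filter(kept, bm, config.shape_margin))
    fit = run("fit_l2lq", lambda: lqfit.fit_l2lq(
        kept.x, kept.y, lam=config.lam, q=config.q, xi=config.xi, degree=config.degree))
    csi = fit.trace(img.shape[1])
    thick = run("thickness_profile", lambda: metrics.thickness_profile(csi, bm))

    report = None
    if truth is not None:
        report = run("evaluate", lambda: metrics.evaluate_segmentation(
            bm, csi, truth.bm, truth.csi, H=img.shape[0]))
    if debug_dir is not None:
        _dump_debug(debug_dir, done)
    return SegmentationResult(
        rpe=rpe, bm=bm, heat=heat, candidates_raw=raw, candidates_filtered=kept,
        csi_fit=fit, csi=csi, thickness=thick, report=report,
    )


def _dump_debug(debug_dir, done: dict) -> None:
    d = Path(debug_dir)
    d.mkdir(parents=True, exist_ok=True)
    for stage, obj in done.items():
        if isinstance(obj, BoundaryTrace):
            obj.to_csv(d / f"{stage}.csv")
        elif isinstance(obj, HeatMap):
            obj.to_png(d / f"{stage}.png")
        elif isinstance(obj, CandidatePoints):
            obj.to_csv(d / f"{stage}.csv")
        elif isinstance(obj, lqfit.FitResult):
            obj.to_json(d / f"{stage}.json")
        elif isinstance(obj, metrics.ThicknessProfile):
            np.savetxt(d / f"{stage}.csv", obj.l, fmt="%.4f")
        elif isinstance(obj, np.ndarray) and obj.ndim == 2:
            Image.fromarray(np.clip(obj, 0, 255).astype(np.uint8), mode="L").save(
                d / f"{stage}.png")
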