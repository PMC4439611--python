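"""End-to-end segmentation pipeline.

Fixed stage order: SRAD denoising -> homomorphic bias correction ->
circular-Hough ROI -> segmentation engine (acwe | spf | gmm | fcm) ->
anatomical postprocessing -> Dice evaluation. Stage toggles can skip
preprocessing or postprocessing but never reorder stages. All stages
are deterministic given the configured seeds, so a fixed config yields
bit-identical outputs across runs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .active_contours import AcweParams, SpfParams, acwe_segment, spf_segment
from .clustering import fcm_segment, gmm_segment
from .evaluation import EvalRecord, dice
from .homomorphic import HomomorphicParams, homomorphic_correct
from .hough_roi import CircleROI, detect_humeral_circle
from .io_types import (BinaryMask, Image2D, SegmentationResult, save_boundary_csv,
                       save_image, save_mask, save_overlay)
from .postprocess import extract_boundary, postprocess_mask
from .srad import SradParams, srad

logger = logging.getLogger("boneseg")

METHODS = ("acwe", "spf", "gmm", "fcm")


@dataclass
class PipelineConfig:
    method: str = "acwe"
    srad: SradParams = field(default_factory=SradParams)
    homomorphic: HomomorphicParams = field(default_factory=HomomorphicParams)
    hough_r_min: Optional[int] = None
    hough_r_max: Optional[int] = None
    hough_enlargement: float = 1.2
    acwe: AcweParams = field(default_factory=AcweParams)
    spf: SpfParams = field(default_factory=SpfParams)
    cluster_seed: int = 0
    skip_preprocess: bool = False
    skip_postprocess: bool = False
    element_radius: int = 3
    output_dir: Optional[Path] = None
    save_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "method" in cfg:
            kwargs["method"] = cfg["method"]
        if "srad" in cfg:
            kwargs["srad"] = SradParams(**cfg["srad"])
        if "homomorphic" in cfg:
            kwargs["homomorphic"] = HomomorphicParams(**cfg["homomorphic"])
        if "acwe" in cfg:
            kwargs["acwe"] = AcweParams(**cfg["acwe"])
        if "spf" in cfg:
            kwargs["spf"] = SpfParams(**cfg["spf"])
        for key in ("hough_r_min", "hough_r_max", "hough_enlargement",
                    "cluster_seed", "skip_preprocess", "skip_postprocess",
                    "element_radius", "save_intermediates"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if cfg.get("output_dir"):
            kwargs["output_dir"] = Path(cfg["output_dir"])
        return cls(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _timed(stage: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        logger.info("stage %-12s %.2fs", stage, time.perf_counter() - t0)
        return out
    return wrap


def run_pipeline(image: Image2D, config: PipelineConfig | None = None,
                 truth: Optional[BinaryMask] = None,
                 image_id: str = "image", group: str = "normal",
                 roi: Optional[CircleROI] = None
                 ) -> tuple[SegmentationResult, Optional[EvalRecord]]:
    """Segment one slice; returns the result and, if truth is given, an
    evaluation record with pre- and post-postprocessing Dice."""
    config = config or PipelineConfig()
    outdir = config.output_dir
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    work = image
    detect_input = image
    if not config.skip_preprocess:
        work = _timed("srad")(srad, work, config.srad)
        detect_input = work  # circle detection runs on the denoised slice;
        # the log-domain compression of the homomorphic step would shift
        # Canny's relative thresholds, and Hough needs only edges, not
        # homogeneous intensities
        work = _timed("homomorphic")(homomorphic_correct, work, config.homomorphic)
        if outdir is not None and config.save_intermediates:
            save_image(work, outdir / "preprocessed.png")

    if roi is None:
        roi = _timed("hough")(detect_humeral_circle, detect_input,
                              config.hough_r_min, config.hough_r_max,
                              config.hough_enlargement)

    if config.method == "acwe":
        result = _timed("acwe")(acwe_segment, work, roi, config.acwe)
    elif config.method == "spf":
        result = _timed("spf")(spf_segment, work, roi, config.spf)
    elif config.method == "gmm":
        mask, state = _timed("gmm")(gmm_segment, work, roi, config.cluster_seed)
        result = SegmentationResult(mask=mask, boundary=[], method_name="gmm",
                                    iterations_run=state.n_iters)
    else:
        mask, state = _timed("fcm")(fcm_segment, work, roi, config.cluster_seed)
        result = SegmentationResult(mask=mask, boundary=[], method_name="fcm",
                                    iterations_run=state.n_iters)

    pre_mask = result.mask
    dice_pre = dice(pre_mask, truth) if truth is not None else None

    if not config.skip_postprocess:
        final = _timed("postprocess")(postprocess_mask, pre_mask, roi, work,
                                      config.element_radius)
    else:
        final = pre_mask
    dice_post = dice(final, truth) if truth is not None else None

    boundary = extract_boundary(final) if final.astype_bool().any() else []
    result = SegmentationResult(
        mask=final, boundary=boundary, method_name=result.method_name,
        iterations_run=result.iterations_run, dice=dice_post,
        dice_pre_postprocess=dice_pre,
        circle=(roi.center[0], roi.center[1], roi.radius))

    if outdir is not None:
        save_mask(final, outdir / "mask.png")
        save_overlay(image, boundary, outdir / "overlay.png")
        save_boundary_csv(boundary, outdir / "boundary.csv")
        result.save_json(outdir / "result.json")

    record = None
    if truth is not None:
        record = EvalRecord(image_id=image_id, method=result.method_name,
                            dice_pre=dice_pre, dice_post=dice_post, group=group)
    return result, record
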