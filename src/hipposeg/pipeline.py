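"""End-to-end orchestration: preprocess → atlas ROI → classify → restore.

The stage order is fixed: intensity normalization and isotropic resampling;
affine then non-linear registration of the atlas reference to the subject;
warping of each probabilistic hippocampus map; binarization and dilation;
bounding-box cropping with a safety margin (independently for the left and
right sides); dense network inference inside each crop; thresholding and
mask clamping; and restoration of both binary results into a single
left/right label map on the subject grid.

This module also holds the training orchestration (ROI extraction for a
labelled cohort, blur augmentation, model fitting with validation-based
selection) and the test-retest driver.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import net as net_mod
from .atlas import Atlas, RoiConfig, RoiCrop
from .evaluation import (EvalReport, reports_to_frame, summarize_retest,
                         test_retest_precision)
from .net import NetConfig, TrainConfig, TrainedModel, TrainingCrop
from .volume import (LabelMap, Volume, normalize_intensity, read_labelmap,
                     read_volume, resample_isotropic, resample_labelmap,
                     write_labelmap, LABEL_LEFT, LABEL_RIGHT)

log = logging.getLogger("hipposeg")

SIDE_LABELS = {"left": LABEL_LEFT, "right": LABEL_RIGHT}


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; sub-configs use their own defaults."""

    roi: RoiConfig = field(default_factory=RoiConfig)
    net: NetConfig = field(default_factory=net_mod.scaled_config)
    train: TrainConfig = field(default_factory=TrainConfig)
    target_spacing: float = 1.0
    seed: int = 0


def preprocess(v: Volume, target_spacing: float = 1.0) -> Volume:
    """Standardize intensities over the brain and resample to isotropic mm.

    Statistics come from the smoothed, eroded brain interior so that a scan
    that has been resampled (e.g. a co-registered retest acquisition, whose
    edge voxels are partial-volume mixtures and whose noise is smoothed)
    standardizes identically to the raw scan of the same anatomy.
    """
    from .volume import robust_brain_standardize

    return resample_isotropic(robust_brain_standardize(v), target_spacing, order=3)


def locate_rois(subject: Volume, atlas: Atlas, roi_cfg: RoiConfig,
                return_transform: bool = False):
    """Register the atlas and extract the left and right ROI crops."""
    ref = normalize_intensity(atlas.reference)
    t0 = time.perf_counter()
    affine_t = atlas_mod.register_affine(ref, subject, precise=False)
    t1 = time.perf_counter()
    nonlin_t = atlas_mod.register_nonlinear(ref, subject, affine_t)
    t2 = time.perf_counter()
    log.info("registration: affine %.1fs, non-linear %.1fs", t1 - t0, t2 - t1)
    crops = {}
    for side in ("left", "right"):
        warped = atlas_mod.warp_probability_map(atlas.prob_map(side), nonlin_t, subject)
        dilated = atlas_mod.binarize_and_dilate(warped, roi_cfg)
        crops[side] = atlas_mod.extract_roi(subject, dilated, roi_cfg, side)
    if return_transform:
        return crops, nonlin_t
    return crops


def segment_volume(subject: Volume, atlas: Atlas, model: TrainedModel,
                   roi_cfg: RoiConfig | None = None,
                   preprocessed: bool = False) -> LabelMap:
    """Full two-stage segmentation of one subject volume."""
    roi_cfg = roi_cfg or RoiConfig()
    v = subject if preprocessed else preprocess(subject)
    crops = locate_rois(v, atlas, roi_cfg)
    merged = np.zeros(v.shape, dtype=np.uint8)
    for side in ("left", "right"):
        crop = crops[side]
        t0 = time.perf_counter()
        prob = net_mod.predict_roi(model, crop)
        seg = net_mod.finalize_segmentation(prob, crop)
        log.info("%s inference %.1fs (crop %s)", side, time.perf_counter() - t0,
                 crop.image.shape)
        full = atlas_mod.restore_to_full(seg, crop)
        clash = (merged > 0) & (full > 0)
        if clash.any():  # unreachable with a conforming (disjoint) atlas
            log.warning("left/right overlap at %d voxels; left wins", clash.sum())
            full[clash] = 0
        merged |= full
    return LabelMap(merged, v.affine.copy(), subject.id)


def make_segmenter(atlas: Atlas, model: TrainedModel,
                   roi_cfg: RoiConfig | None = None, preprocessed: bool = False):
    """Bind atlas/model/config into a Volume -> LabelMap callable."""
    def segmenter(v: Volume) -> LabelMap:
        return segment_volume(v, atlas, model, roi_cfg, preprocessed=preprocessed)
    return segmenter


# --------------------------------------------------------------------------
# training orchestration
# --------------------------------------------------------------------------

def build_training_crops(subjects, atlas: Atlas, roi_cfg: RoiConfig | None = None,
                         augment_sigmas=(0.5, 1.0), augment: bool = True,
                         preprocessed: bool = False) -> list[TrainingCrop]:
    """ROI crops plus ground truth for a labelled cohort.

    ``subjects`` is a list of (Volume, LabelMap).  Each subject contributes
    two crops (left, right); with augmentation on, each crop additionally
    appears once per blur sigma with identical truth, so the training set
    grows by a factor of ``1 + len(augment_sigmas)``.
    """
    crops: list[TrainingCrop] = []
    for v, truth in subjects:
        vp = v if preprocessed else preprocess(v)
        rois = locate_rois(vp, atlas, roi_cfg or RoiConfig())
        for side, crop in rois.items():
            label = SIDE_LABELS[side]
            sl = tuple(slice(l, h) for l, h in zip(crop.bbox_lo, crop.bbox_hi))
            t = (truth.data[sl] == label)
            crops.append(TrainingCrop(crop, t))
            if augment:
                for blurred in net_mod.augment_blur(crop.image, augment_sigmas):
                    bcrop = RoiCrop(blurred, crop.dilated_mask.copy(), crop.bbox_lo,
                                    crop.parent_shape, side)
                    crops.append(TrainingCrop(bcrop, t.copy()))
    return crops


def run_train(train_subjects, val_subjects, atlas: Atlas,
              cfg: PipelineConfig | None = None,
              checkpoint_path=None, augment: bool = True) -> TrainedModel:
    """Train a model on labelled subjects with validation-based selection."""
    cfg = cfg or PipelineConfig()
    if not train_subjects or not val_subjects:
        raise ValueError("empty training or validation split")
    log.info("extracting ROIs for %d train / %d val subjects",
             len(train_subjects), len(val_subjects))
    train_crops = build_training_crops(train_subjects, atlas, cfg.roi,
                                       cfg.train.augment_sigmas, augment=augment)
    val_crops = build_training_crops(val_subjects, atlas, cfg.roi, augment=False)
    model = net_mod.build_network(cfg.net, seed=cfg.seed)
    model = net_mod.train(model, train_crops, val_crops, cfg.train)
    if checkpoint_path is not None:
        net_mod.save_checkpoint(model, checkpoint_path)
        log_path = Path(str(checkpoint_path)).with_suffix(".log.csv")
        pd.DataFrame(model.training_log).to_csv(log_path, index=False)
    return model


# --------------------------------------------------------------------------
# directory-level drivers (CLI surface)
# --------------------------------------------------------------------------

def run_segment_dir(input_paths, atlas: Atlas, model: TrainedModel,
                    out_dir, roi_cfg: RoiConfig | None = None) -> dict:
    """Segment a list of NIfTI files; failures are recorded, not fatal."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"written": [], "failed": {}}
    for p in input_paths:
        try:
            v = read_volume(p)
            seg = segment_volume(v, atlas, model, roi_cfg)
            out = out_dir / (Path(p).name.replace(".nii", "_seg.nii"))
            write_labelmap(seg, out)
            summary["written"].append(str(out))
        except Exception as exc:
            log.error("segmentation failed for %s: %s", p, exc)
            summary["failed"][str(p)] = str(exc)
    return summary


def run_retest(pairs, atlas: Atlas, model: TrainedModel,
               out_dir=None, roi_cfg: RoiConfig | None = None,
               preprocessed: bool = False):
    """Test-retest protocol over scan pairs; optional CSV + YAML summary."""
    segmenter = make_segmenter(atlas, model, roi_cfg, preprocessed=preprocessed)
    reports = test_retest_precision(pairs, segmenter)
    summary = summarize_retest(reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        reports_to_frame(reports).to_csv(out_dir / "retest_sessions.csv", index=False)
        with open(out_dir / "retest_summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh)
    return reports, summary


def evaluate_against_truth(seg: LabelMap, truth: LabelMap,
                           subject: str = "", method: str = "hipposeg") -> list[EvalReport]:
    """Per-side Dice and volumes of a segmentation against ground truth."""
    from .evaluation import dice_coefficient, volume_ml

    reports = []
    for side, label in SIDE_LABELS.items():
        m_seg = seg.data == label
        m_tru = truth.data == label
        try:
            d = dice_coefficient(m_seg, m_tru)
        except ValueError:
            d = float("nan")
        reports.append(EvalReport(subject or seg.id, "", side, method, d,
                                  volume_ml(m_seg, seg.spacing),
                                  volume_ml(m_tru, truth.spacing),
                                  abs(volume_ml(m_seg, seg.spacing)
                                      - volume_ml(m_tru, truth.spacing))))
    return reports
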