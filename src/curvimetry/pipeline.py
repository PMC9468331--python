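"""End-to-end orchestration and the evaluation harness.

The full measurement pipeline is localize -> crop -> segment ->
post-process -> estimate.  The localization and segmentation stages are
pluggable: any callable satisfying :class:`Detector` /
:class:`Segmenter` slots in, including trained deep models.  The
repository ships two deterministic stand-ins that make the pipeline
testable end-to-end without trained weights: an oracle detector that
reads the box off a known mask, and an intensity-threshold segmenter.

:class:`TrainConfig` records the training hyperparameters used for the
reference deep models (detector: SGD; segmenter: Adam with early
stopping and plateau LR decay) purely as configuration — no training
happens in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .errors import (
    DegenerateImageError,
    LocalizationFailureError,
    PipelineStageError,
    SplitError,
)
from .estimator import CurvatureEstimate, estimate_curvature
from .phantom import (
    HORIZONTAL_TILT_RANGE,
    PANEL_ANGLES_DEG,
    PhantomSample,
    PhantomSpec,
    generate_phantom,
)
from .postprocess import crop_to_bbox
from .types import BoundingBox, DetectionResult


class Detector(Protocol):
    """Image -> list of scored bounding boxes (class 0 = shaft area)."""

    def __call__(self, image: np.ndarray) -> list[DetectionResult]: ...


class Segmenter(Protocol):
    """Image -> per-pixel foreground probability map of the same shape."""

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class DetectorTrainConfig:
    optimizer: str = "SGD"
    epochs: int = 250
    lr: float = 1e-2
    momentum: float = 0.937
    batch_size: int = 16
    weight_decay: float = 5e-4


@dataclass(frozen=True)
class SegmenterTrainConfig:
    optimizer: str = "Adam"
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    epochs: int = 100
    batch_size: int = 16
    early_stop_patience: int = 15
    lr_factor: float = 0.2
    lr_patience: int = 5


@dataclass(frozen=True)
class CrossValConfig:
    folds: int = 5
    val_fraction: float = 0.2
    augmented_per_fold: int = 3500


@dataclass(frozen=True)
class TrainConfig:
    """Reference training hyperparameters, recorded as configuration."""

    detector: DetectorTrainConfig = field(default_factory=DetectorTrainConfig)
    segmenter: SegmenterTrainConfig = field(default_factory=SegmenterTrainConfig)
    cv: CrossValConfig = field(default_factory=CrossValConfig)


# ---------------------------------------------------------------------------
# stand-in detector / segmenter
# ---------------------------------------------------------------------------


@dataclass
class OracleDetector:
    """Detector stand-in that reports the tight box of a known mask."""

    mask: np.ndarray
    confidence: float = 1.0

    def __call__(self, image: np.ndarray) -> list[DetectionResult]:
        if not self.mask.any():
            return []
        return [
            DetectionResult(
                predicted_box=BoundingBox.from_mask(self.mask),
                confidence=self.confidence,
            )
        ]


def threshold_segmenter(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground probability from intensity distance to the background mode.

    The background level is the modal intensity of the image's border
    frame (after localization cropping the object is interior, so the
    frame shows background even when the object dominates the crop
    area); each pixel's probability is its absolute intensity distance
    to that level, normalized to [0, 1].  Works for either contrast
    polarity.  ``threshold`` is the recommended binarization level for
    the output.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    img = img.astype(float)
    if np.ptp(img) == 0:
        raise DegenerateImageError("constant image: nothing to segment")
    border = np.concatenate(
        [img[0], img[-1], img[1:-1, 0], img[1:-1, -1]]
    )
    hist, edges = np.histogram(border, bins=64, range=(img.min(), img.max()))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    dist = np.abs(img - mode)
    return dist / dist.max()


@dataclass
class ThresholdSegmenter:
    """Callable wrapper around :func:`threshold_segmenter`."""

    threshold: float = 0.5

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return threshold_segmenter(image, self.threshold)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def apply_rigid(
    sample: PhantomSample,
    dx: int = 0,
    dy: int = 0,
    rotation_deg: float = 0.0,
    flip_h: bool = False,
    flip_v: bool = False,
) -> PhantomSample:
    """Apply one rigid op combination jointly to image, mask and box.

    All ops preserve the ground-truth curvature angle; the bounding box
    is recomputed from the transformed mask.
    """
    image = sample.image
    mask = sample.mask
    if rotation_deg != 0.0:
        image = sktransform.rotate(
            image.astype(float), rotation_deg, order=1, mode="edge", preserve_range=True
        ).astype(sample.image.dtype)
        # bilinear + re-threshold keeps the rotated boundary smoother
        # (and the limb axes truer) than nearest-neighbor resampling
        mask = (
            sktransform.rotate(
                mask.astype(float), rotation_deg, order=1, preserve_range=True
            )
            >= 0.5
        )
    if dx or dy:
        image = np.roll(np.roll(image, dy, axis=0), dx, axis=1)
        mask = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
    if flip_h:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if flip_v:
        image = image[::-1].copy()
        mask = mask[::-1].copy()
    return replace(
        sample, image=image, mask=mask, bbox=BoundingBox.from_mask(mask)
    )


def augment(sample: PhantomSample, ops_seed: int) -> PhantomSample:
    """Seeded random translate / rotate / flip combination.

    Translation up to 10% of the image side, rotation uniform in
    +-15 deg, independent coin-flip mirrors.  Rigid ops only, so the
    ground-truth angle is unchanged.
    """
    rng = np.random.default_rng(ops_seed)
    h, w = sample.mask.shape
    max_dx, max_dy = int(0.1 * w), int(0.1 * h)
    return apply_rigid(
        sample,
        dx=int(rng.integers(-max_dx, max_dx + 1)),
        dy=int(rng.integers(-max_dy, max_dy + 1)),
        rotation_deg=float(rng.uniform(-15.0, 15.0)),
        flip_h=bool(rng.integers(0, 2)),
        flip_v=bool(rng.integers(0, 2)),
    )


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold with model-disjoint train/test sides."""

    fold_index: int
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple


def make_folds(
    ids_by_model: dict,
    n_folds: int = 5,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[FoldSplit]:
    """Model-held-out k-fold splits with a validation carve-out.

    Whole models are assigned to test folds (images of one physical
    model never straddle train and test); within each fold the
    validation set is a seeded ``val_fraction`` draw from the
    train-side images.  Every image appears in exactly one test fold.
    """
    models = sorted(ids_by_model)
    if len(models) < n_folds:
        raise SplitError(
            f"{len(models)} models cannot fill {n_folds} model-disjoint folds"
        )
    rng = np.random.default_rng(seed)
    order = [models[i] for i in rng.permutation(len(models))]
    groups: list[list] = [[] for _ in range(n_folds)]
    for i, model in enumerate(order):
        groups[i % n_folds].append(model)
    folds = []
    for k, test_models in enumerate(groups):
        test_ids = [i for m in test_models for i in ids_by_model[m]]
        train_side = [
            i for m in models if m not in test_models for i in ids_by_model[m]
        ]
        n_val = int(round(val_fraction * len(train_side)))
        val_pick = set(
            rng.choice(len(train_side), size=n_val, replace=False).tolist()
        )
        val_ids = [x for i, x in enumerate(train_side) if i in val_pick]
        train_ids = [x for i, x in enumerate(train_side) if i not in val_pick]
        folds.append(
            FoldSplit(
                fold_index=k,
                train_ids=tuple(train_ids),
                val_ids=tuple(val_ids),
                test_ids=tuple(test_ids),
            )
        )
    return folds


# ---------------------------------------------------------------------------
# end-to-end pipeline and experiments
# ---------------------------------------------------------------------------


def run_pipeline(
    image: np.ndarray,
    detector: Detector,
    segmenter: Segmenter,
    crop_margin_fraction: float = 0.05,
    binarize_threshold: float = 0.5,
) -> CurvatureEstimate:
    """localize -> crop -> segment -> post-process -> estimate.

    The highest-confidence detection wins; the crop box is expanded by
    ``crop_margin_fraction`` of its longer side so the Hough stage never
    sees clipped edges.  Downstream failures propagate as
    :class:`PipelineStageError` with the stage name attached.
    """
    detections = detector(image)
    if not detections:
        raise PipelineStageError(
            "localize", LocalizationFailureError("detector returned no box")
        )
    box = max(detections, key=lambda d: d.confidence).predicted_box
    margin = int(round(crop_margin_fraction * max(box.width, box.height)))
    crop = crop_to_bbox(image, box, margin_px=margin)
    try:
        prob = segmenter(crop)
    except DegenerateImageError as e:
        raise PipelineStageError("segment", e) from e
    mask = np.asarray(prob) >= binarize_threshold
    return estimate_curvature(mask)


def tilt_experiment(
    angles_deg=PANEL_ANGLES_DEG,
    tilt_bin_edges_deg=(0.0, 7.0, 15.0, 20.0),
    n_per_cell: int = 5,
    seed: int = 0,
    boundary_noise_sigma_px: float = 1.0,
    estimator: Callable[[np.ndarray], CurvatureEstimate] = estimate_curvature,
) -> pd.DataFrame:
    """Camera-tilt sensitivity study on synthetic phantoms.

    For each (ground-truth angle, vertical-tilt bin) cell, generates
    ``n_per_cell`` phantoms with vertical tilt uniform inside the bin
    and horizontal tilt uniform over its capture range, runs the angle
    estimator, and tabulates per-cell and per-bin MAE.  Returns a tidy
    frame with one row per sample (columns: angle, tilt_bin, vertical
    tilt, estimate, abs_error).
    """
    edges = list(tilt_bin_edges_deg)
    rng = np.random.default_rng(seed)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"<{hi:g}"
        for angle in angles_deg:
            for _ in range(n_per_cell):
                spec = PhantomSpec(
                    curvature_angle_deg=float(angle),
                    horizontal_tilt_deg=float(rng.uniform(*HORIZONTAL_TILT_RANGE)),
                    vertical_tilt_deg=float(rng.uniform(lo, hi)),
                    boundary_noise_sigma_px=boundary_noise_sigma_px,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                )
                sample = generate_phantom(spec)
                est = estimator(sample.mask)
                rows.append(
                    {
                        "angle": float(angle),
                        "tilt_bin": label,
                        "vertical_tilt": spec.vertical_tilt_deg,
                        "estimate": est.angle_deg,
                        "abs_error": abs(est.angle_deg - angle),
                    }
                )
    return pd.DataFrame(rows)


def tilt_bin_mae(table: pd.DataFrame) -> pd.Series:
    """Per-tilt-bin MAE from a :func:`tilt_experiment` table."""
    if table.empty:
        return pd.Series(dtype=float)
    order = sorted(table["tilt_bin"].unique(), key=lambda s: float(s[1:]))
    return table.groupby("tilt_bin")["abs_error"].mean().reindex(order)


def evaluate_panel(
    samples: list[PhantomSample],
    estimator: Callable[[np.ndarray], CurvatureEstimate] = estimate_curvature,
) -> pd.DataFrame:
    """Run the estimator over a phantom panel; one row per sample."""
    rows = []
    for s in samples:
        est = estimator(s.mask)
        rows.append(
            {
                "gt_angle": s.gt_angle_deg,
                "estimate": est.angle_deg,
                "abs_error": abs(est.angle_deg - s.gt_angle_deg),
                "horizontal_tilt": s.spec.horizontal_tilt_deg,
                "vertical_tilt": s.spec.vertical_tilt_deg,
            }
        )
    return pd.DataFrame(rows)
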