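"""BOLD-sensitivity and data-quality metrics.

Residual temporal-SNR maps (task effects regressed out first), ROI
summaries, acquisition-weighted tSNR variants, top-5% t-score averages,
frame-to-frame head-motion metrics and the scaled-variance image-quality
series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ProtocolSpec, ROISet, ValidationError, VolumeImage
from .glm import DesignMatrix
from .synth import MotionTrace

logger = logging.getLogger(__name__)


@dataclass
class MotionMetrics:
    mean_translation_mm: float
    max_translation_mm: float
    n_movements_gt_half_mm: int
    rotation_summary_deg: float


def tsnr_map(image4d: VolumeImage, design: DesignMatrix) -> VolumeImage:
    """Temporal SNR per voxel: mean of the raw series divided by the SD of
    the residuals after regressing out the design (dof = n - rank(X))."""
    if image4d.n_volumes != design.n_volumes:
        raise ValidationError("volume counts differ between image and design")
    shape = image4d.data.shape[:3]
    Y = image4d.data.reshape(-1, design.n_volumes).T.astype(float)
    X = design.X
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = design.n_volumes - int(rank)
    sd = np.sqrt((resid**2).sum(axis=0) / dof)
    mean = Y.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsnr = np.where(sd > 0, mean / sd, np.nan)
    n_degenerate = int(np.sum(sd == 0))
    if n_degenerate:
        logger.warning("tsnr_map: %d voxel(s) with zero residual SD set to NaN",
                       n_degenerate)
    return VolumeImage(tsnr.reshape(shape), image4d.affine, "tsnr")


def roi_summary(map3d: VolumeImage, rois: ROISet) -> dict[str, float]:
    """NaN-aware mean of a 3D map within each named ROI."""
    if map3d.data.shape != rois.labels.shape:
        raise ValidationError("map and ROI grids differ")
    out: dict[str, float] = {}
    for name in rois.names:
        vals = map3d.data[rois.mask(name)]
        if np.isnan(vals).all():
            warnings.warn(f"ROI {name!r} is all-NaN", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(np.nanmean(vals))
    return out


def weighted_tsnr(tsnr: float, protocol: ProtocolSpec,
                  phi: float) -> tuple[float, float, float]:
    """Acquisition-weighted tSNR variants.

    Returns (tSNR / sqrt(TR_volume in s), tSNR / sqrt(N),
    tSNR_s = tSNR * sqrt(N (1 - phi) / (1 + phi))) — the last scales by the
    AR(1) effective number of independent volumes.
    """
    if not abs(phi) < 1:
        raise ValidationError(f"|phi| must be < 1, got {phi}")
    n = protocol.n_volumes
    per_tr = tsnr / np.sqrt(protocol.tr_s)
    per_n = tsnr / np.sqrt(n)
    scaled = tsnr * np.sqrt(n * (1.0 - phi) / (1.0 + phi))
    return float(per_tr), float(per_n), float(scaled)


def top5_tscores(t_map: VolumeImage, rois: ROISet,
                 fraction: float = 0.05) -> dict[str, float]:
    """Mean t-value over the ceil(fraction * |ROI|) largest voxels per ROI."""
    if t_map.data.shape != rois.labels.shape:
        raise ValidationError("map and ROI grids differ")
    out: dict[str, float] = {}
    for name in rois.names:
        vals = t_map.data[rois.mask(name)]
        vals = vals[np.isfinite(vals)]
        k = int(np.ceil(fraction * rois.voxel_count(name)))
        if vals.size == 0 or k == 0:
            warnings.warn(f"ROI {name!r}: empty top-{fraction:.0%} selection",
                          stacklevel=2)
            out[name] = float("nan")
            continue
        k = min(k, vals.size)
        out[name] = float(np.sort(vals)[-k:].mean())
    return out


def motion_metrics(trace: MotionTrace | np.ndarray,
                   threshold_mm: float = 0.5) -> MotionMetrics:
    """Frame-to-frame motion summary.

    Translation displacement per volume transition is the Euclidean norm of
    the difference of the 3 translation parameters; the count records
    transitions above ``threshold_mm``. Rotations are summarized as the mean
    frame-to-frame rotation-vector magnitude in degrees.
    """
    params = trace.params if isinstance(trace, MotionTrace) else np.asarray(trace, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValidationError(f"expected (n, 6) motion parameters, got {params.shape}")
    if params.shape[0] < 2:
        raise ValidationError("need at least 2 volumes")
    d = np.diff(params, axis=0)
    trans = np.linalg.norm(d[:, :3], axis=1)
    rot = np.linalg.norm(d[:, 3:], axis=1)
    return MotionMetrics(
        mean_translation_mm=float(trans.mean()),
        max_translation_mm=float(trans.max()),
        n_movements_gt_half_mm=int(np.sum(trans > threshold_mm)),
        rotation_summary_deg=float(np.degrees(rot.mean())),
    )


def scaled_variance(image4d: VolumeImage) -> tuple[np.ndarray, float]:
    """Scaled variance per consecutive volume pair.

    For each pair, the mean squared intensity difference divided by the
    squared global mean intensity; the subject summary is the mean over
    pairs. Scale-invariant by construction.
    """
    if image4d.n_volumes < 2:
        raise ValidationError("need at least 2 volumes")
    data = image4d.data.astype(float)
    gm = data.mean()
    if gm == 0:
        raise ValidationError("zero global mean intensity")
    diffs = np.diff(data, axis=3)
    series = (diffs**2).mean(axis=(0, 1, 2)) / gm**2
    return series, float(series.mean())
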