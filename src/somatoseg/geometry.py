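"""Somatotopy geometry from statistical maps.

Thresholding of t-maps, centers of mass and activation maxima in world-mm
coordinates, ROI-adjusted activation volumes, ordering checks (is the hand
representation between foot and face; do foot/face sit at the expected end
of the structure-specific gradient), and SVD projection of centers of mass
onto ROI-specific principal axes.

Axis semantics (MNI-like): +X lateral-right, +Y anterior, +Z dorsal;
"more dorsal" means larger Z, "more medial" means smaller |X|. All ordering
checks use strict inequalities — ties fail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ValidationError, VolumeImage

#: expected foot-vs-face gradient per ROI structure: axis code and expected
#: sign of (foot - face). Axis "Z": dorsal-ventral; "Y": posterior-anterior;
#: "|X|": medial-lateral (compared on the absolute lateral coordinate).
DEFAULT_EXPECTATIONS: dict[str, tuple[str, int]] = {
    "M1": ("Z", +1),        # foot dorsal to face
    "SMA": ("Y", -1),       # foot posterior to face
    "putamen": ("Z", +1),   # dorsal-to-ventral gradient
    "pallidum": ("Z", +1),
    "thalamus": ("|X|", -1),  # lateral-to-medial: foot more medial
}

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class GeometrySummary:
    """Tidy per-(ROI, body part, resolution) geometry results plus per-ROI
    principal axes."""

    table: "object"  # pandas DataFrame: roi, body_part, resolution, com/max/volume
    betweenness: "object"  # DataFrame: roi, resolution, x/y/z/any flags
    directions: "object"  # DataFrame: roi, resolution, axis, expected_sign, flag
    principal_axes: dict = field(default_factory=dict)  # roi -> 3x3 orthonormal
    projected_coms: dict = field(default_factory=dict)  # roi -> 9x3


def threshold_tmap(t_map: VolumeImage, dof: int, alpha: float = 0.05) -> VolumeImage:
    """Binary mask of voxels with one-sided p(t; dof) < alpha (activation
    contrasts test positive BOLD responses)."""
    if dof < 1:
        raise ValidationError("dof must be >= 1")
    t_crit = stats.t.ppf(1.0 - alpha, dof)
    mask = np.nan_to_num(t_map.data, nan=-np.inf) > t_crit
    return VolumeImage(mask.astype(np.uint8), t_map.affine, "suprathreshold")


def center_of_mass(mask: VolumeImage, weights: VolumeImage | None = None) -> np.ndarray:
    """World-mm centroid of a binary mask (unweighted by default; pass a
    t-map as ``weights`` for a t-weighted variant)."""
    m = np.asarray(mask.data).astype(bool)
    ijk = np.argwhere(m)
    if ijk.shape[0] == 0:
        warnings.warn("empty mask: center of mass undefined", stacklevel=2)
        return np.full(3, np.nan)
    world = ijk @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    if weights is not None:
        w = np.asarray(weights.data)[m].astype(float)
        if w.sum() <= 0:
            warnings.warn("non-positive weight total; falling back to unweighted",
                          stacklevel=2)
            return world.mean(axis=0)
        return (world * w[:, None]).sum(axis=0) / w.sum()
    return world.mean(axis=0)


def activation_maximum(t_map: VolumeImage, roi_mask: np.ndarray) -> np.ndarray:
    """World coordinate of the largest t-value inside the ROI; ties broken
    by the lowest linear (C-order) voxel index."""
    roi_mask = np.asarray(roi_mask).astype(bool)
    if not roi_mask.any():
        raise ValidationError("empty ROI")
    idx = np.argwhere(roi_mask)  # C-order => first occurrence of max wins
    vals = t_map.data[roi_mask]
    best = idx[int(np.argmax(vals))]
    return best @ t_map.affine[:3, :3].T + t_map.affine[:3, 3]


def adjusted_volume(mask: VolumeImage | np.ndarray, roi_mask: np.ndarray) -> float:
    """Suprathreshold volume inside the ROI divided by the ROI size."""
    m = np.asarray(mask.data if isinstance(mask, VolumeImage) else mask).astype(bool)
    roi = np.asarray(roi_mask).astype(bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("empty ROI")
    return float((m & roi).sum()) / n_roi


def betweenness_check(com_foot: np.ndarray, com_hand: np.ndarray,
                      com_face: np.ndarray) -> dict[str, bool | None]:
    """Is the hand center strictly between foot and face per axis?

    Returns flags for X, Y, Z and their OR under key "any"; NaN coordinates
    yield None (missing)."""
    coms = [np.asarray(c, dtype=float) for c in (com_foot, com_hand, com_face)]
    out: dict[str, bool | None] = {}
    for axis, a in _AXIS_INDEX.items():
        f, h, c = (v[a] for v in coms)
        if np.isnan([f, h, c]).any():
            out[axis] = None
        else:
            out[axis] = bool(min(f, c) < h < max(f, c))
    flags = [v for v in out.values() if v is not None]
    out["any"] = any(flags) if flags else None
    return out


def direction_check(com_foot: np.ndarray, com_face: np.ndarray, roi_structure: str,
                    expectations: dict[str, tuple[str, int]] | None = None) -> bool:
    """Does the foot-face coordinate difference have the expected sign on the
    structure's expected gradient axis? Strict inequality; zero fails."""
    table = expectations if expectations is not None else DEFAULT_EXPECTATIONS
    if roi_structure not in table:
        raise ValidationError(f"no gradient expectation for ROI {roi_structure!r}")
    axis, sign = table[roi_structure]
    foot = np.asarray(com_foot, dtype=float)
    face = np.asarray(com_face, dtype=float)
    if axis == "|X|":
        diff = abs(foot[0]) - abs(face[0])
    else:
        diff = foot[_AXIS_INDEX[axis]] - face[_AXIS_INDEX[axis]]
    if np.isnan(diff):
        return False
    return bool(sign * diff > 0)


def principal_axis_projection(coms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project centers of mass onto ROI-specific principal axes.

    Centers the m x 3 coordinates, takes the SVD of the centered matrix and
    projects onto the right-singular vectors ordered by singular value. Each
    axis is sign-fixed so its largest-magnitude loading is positive. Returns
    (projected m x 3 coordinates, 3 x 3 axes as rows).
    """
    coms = np.asarray(coms, dtype=float)
    if coms.ndim != 2 or coms.shape[1] != 3:
        raise ValidationError("expected an m x 3 coordinate array")
    distinct = np.unique(coms[~np.isnan(coms).any(axis=1)], axis=0)
    if distinct.shape[0] < 2:
        raise ValidationError("need at least 2 distinct points")
    centered = coms - np.nanmean(coms, axis=0)
    _, _, Vt = np.linalg.svd(np.nan_to_num(centered), full_matrices=True)
    for i in range(3):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    return centered @ Vt.T, Vt
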