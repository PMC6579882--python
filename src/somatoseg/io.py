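"""File I/O and spatial smoothing.

NIfTI-1 round trips via nibabel, event tables and motion traces as
plain-text, PCM fits as JSON, run configuration as YAML, and separable
Gaussian smoothing in millimetre units.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .core import ValidationError, VolumeImage
from .pcm import PCMFit
from .synth import EVENT_COLUMNS, MotionTrace

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def write_nifti(image: VolumeImage, path: "str | Path") -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(image.data), image.affine), str(path))
    return path


def read_nifti(path: "str | Path") -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise ValidationError(f"malformed NIfTI at {path}: {exc}") from exc
    return VolumeImage(data, img.affine, space_label=path.stem)


def write_events(events: pd.DataFrame, path: "str | Path") -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS)
    return path


def read_events(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValidationError(f"event table missing columns {sorted(missing)}")
    return df


def write_motion(trace: MotionTrace, path: "str | Path") -> Path:
    path = Path(path)
    np.savetxt(path, trace.params, fmt="%.8f")
    return path


def read_motion(path: "str | Path") -> MotionTrace:
    return MotionTrace(np.loadtxt(path, ndmin=2))


def write_pcm_fit(fit: PCMFit, path: "str | Path") -> Path:
    path = Path(path)
    payload = {
        "roi_name": fit.roi_name,
        "G_hat": fit.G_hat.tolist(),
        "sigma2_hat": fit.sigma2_hat,
        "loglik_trace": np.asarray(fit.loglik_trace).tolist(),
        "n_iter": fit.n_iter,
        "converged": fit.converged,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_pcm_fit(path: "str | Path") -> PCMFit:
    d = json.loads(Path(path).read_text())
    return PCMFit(np.asarray(d["G_hat"]), d["sigma2_hat"],
                  np.asarray(d["loglik_trace"]), d["n_iter"], d["converged"],
                  d.get("roi_name", ""))


def _voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm; reject sheared affines (the separable
    axis-aligned kernel would be wrong there)."""
    A = np.asarray(affine, dtype=float)[:3, :3]
    sizes = np.linalg.norm(A, axis=0)
    off = A - np.diag(np.diag(A))
    if np.abs(off).max() > 1e-6 * sizes.max():
        raise ValidationError("sheared/oblique affine unsupported for smoothing")
    return sizes


def gaussian_smooth(image: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Separable 3D Gaussian smoothing with FWHM given in mm (0 = identity);
    applied volume-wise to 4D images."""
    if fwhm_mm < 0:
        raise ValidationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return VolumeImage(np.array(image.data, copy=True), image.affine,
                           image.space_label)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / _voxel_sizes(image.affine)
    data = np.asarray(image.data, dtype=float)
    if data.ndim == 3:
        out = ndimage.gaussian_filter(data, sigma=sigma_vox)
    else:
        sigma4 = tuple(sigma_vox) + (0.0,)
        out = ndimage.gaussian_filter(data, sigma=sigma4)
    return VolumeImage(out, image.affine, image.space_label)


def save_yaml(obj, path: "str | Path") -> Path:
    path = Path(path)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def load_yaml(path: "str | Path") -> dict:
    return yaml.safe_load(Path(path).read_text())
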