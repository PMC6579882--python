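"""Subject-level general linear model.

Design matrices with canonical-HRF condition regressors, a pooled
preparation-period regressor, six rigid-body motion covariates and an
intercept; ordinary least-squares fitting per voxel; differential contrasts
against the resting baseline with t-maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .core import ProtocolSpec, ValidationError, VolumeImage


def canonical_hrf(dt: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every ``dt`` s.

    Response gamma with shape 6, undershoot gamma with shape 16 weighted 1/6
    (both unit scale), peak near 5 s, scaled to unit peak.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    t = np.arange(0.0, length_s + dt / 2, dt)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """GLM design: columns = condition regressors + nuisance (prep, motion,
    intercept)."""

    X: np.ndarray
    column_names: list[str]
    condition_columns: dict[str, int]
    nuisance_columns: list[int]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


@dataclass
class GLMFit:
    betas: np.ndarray          # k x v
    residuals: np.ndarray      # n_volumes x v
    dof: int
    sigma2_hat: np.ndarray     # per-voxel residual variance (v,)
    design: DesignMatrix
    data_shape: tuple = ()     # spatial shape for map reconstruction
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass
class ContrastResult:
    name: str
    contrast_vector: np.ndarray
    effect_map: VolumeImage
    t_map: VolumeImage


def build_design(events: pd.DataFrame, protocol: ProtocolSpec,
                 motion: "np.ndarray | None" = None, dt: float = 0.1,
                 n_cosine_drift: int = 0) -> DesignMatrix:
    """Design matrix at the volume acquisition times.

    One HRF-convolved boxcar per active condition, one pooled regressor for
    all preparation periods, six motion covariates (if a trace is given),
    optional cosine drift columns, and an intercept. Under the default
    6-condition paradigm with motion this gives k = 14.
    """
    horizon = float((events["onset"] + events["duration"]).max())
    if horizon > protocol.scan_duration_s + 1e-9:
        raise ValidationError("events exceed scan duration")

    hrf = canonical_hrf(dt)
    n_fine = int(np.ceil(protocol.scan_duration_s / dt)) + 1
    t_vol = np.arange(protocol.n_volumes) * protocol.tr_s
    idx = np.minimum((t_vol / dt).round().astype(int), n_fine - 1)

    def convolved(rows: pd.DataFrame) -> np.ndarray:
        box = np.zeros(n_fine)
        for _, ev in rows.iterrows():
            box[int(round(ev.onset / dt)):int(round((ev.onset + ev.duration) / dt))] = 1.0
        return np.convolve(box, hrf)[:n_fine][idx]

    cols, names = [], []
    condition_columns: dict[str, int] = {}
    active = events[events.event_class == "active"]
    for cond in sorted(str(c) for c in active.trial_type.unique()):
        condition_columns[cond] = len(cols)
        names.append(cond)
        cols.append(convolved(active[active.trial_type == cond]))

    nuisance: list[int] = []
    prep = events[events.event_class == "prep"]
    if len(prep):
        nuisance.append(len(cols))
        names.append("prep")
        cols.append(convolved(prep))

    if motion is not None:
        params = motion.params if hasattr(motion, "params") else np.asarray(motion)
        if params.shape != (protocol.n_volumes, 6):
            raise ValidationError(
                f"motion trace shape {params.shape} != ({protocol.n_volumes}, 6)")
        for j, nm in enumerate(["tx", "ty", "tz", "rx", "ry", "rz"]):
            nuisance.append(len(cols))
            names.append(f"motion_{nm}")
            cols.append(params[:, j])

    for j in range(n_cosine_drift):
        nuisance.append(len(cols))
        names.append(f"drift_cos{j + 1}")
        n = protocol.n_volumes
        cols.append(np.cos(np.pi * (j + 1) * (np.arange(n) + 0.5) / n))

    nuisance.append(len(cols))
    names.append("intercept")
    cols.append(np.ones(protocol.n_volumes))

    X = np.column_stack(cols)
    dm = DesignMatrix(X, names, condition_columns, nuisance)
    if dm.rank() < dm.k:
        flat = [names[j] for j in range(X.shape[1])
                if names[j] != "intercept" and np.ptp(X[:, j]) == 0]
        warnings.warn(
            "design matrix is rank deficient"
            + (f"; constant columns collinear with intercept: {flat}" if flat else ""),
            stacklevel=2)
    return dm


def fit_glm(image4d: VolumeImage, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares per voxel."""
    if image4d.n_volumes != design.n_volumes:
        raise ValidationError(
            f"image has {image4d.n_volumes} volumes, design {design.n_volumes}")
    shape = image4d.data.shape[:3]
    Y = image4d.data.reshape(-1, design.n_volumes).T.astype(float)  # n x v
    X = design.X
    betas, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = design.n_volumes - int(rank)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = (resid**2).sum(axis=0) / dof if dof > 0 else np.full(Y.shape[1], np.nan)
    return GLMFit(betas, resid, dof, sigma2, design, shape, image4d.affine)


def differential_contrasts(condition_names: list[str] | tuple[str, ...],
                           design: DesignMatrix) -> list[tuple[str, np.ndarray]]:
    """One contrast per condition against the implicit resting baseline:
    +1 on the condition column, 0 elsewhere. Returns (name, vector) pairs."""
    out = []
    for cond in condition_names:
        if cond not in design.condition_columns:
            raise ValidationError(f"condition {cond!r} not in design")
        c = np.zeros(design.k)
        c[design.condition_columns[cond]] = 1.0
        out.append((cond, c))
    return out


def compute_contrast(fit: GLMFit, contrast: np.ndarray, name: str = "") -> ContrastResult:
    """Effect and t maps for a contrast vector: t = c'b / sqrt(s2 * c'(X'X)^-1 c)."""
    c = np.asarray(contrast, dtype=float)
    X = fit.design.X
    effect = c @ fit.betas
    xtx_inv = np.linalg.pinv(X.T @ X)
    var_factor = float(c @ xtx_inv @ c)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = effect / np.sqrt(fit.sigma2_hat * var_factor)
    shape = fit.data_shape
    return ContrastResult(
        name, c,
        VolumeImage(effect.reshape(shape), fit.affine, "effect"),
        VolumeImage(t.reshape(shape), fit.affine, "t"),
    )
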