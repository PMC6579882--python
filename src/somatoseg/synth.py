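"""Synthetic study generator.

Emulates, at desk scale, the data a visually cued motor block paradigm would
produce under the three acquisition presets: event tables, condition x voxel
activity patterns with a known 9 x 9 pattern covariance, 4D block-design
time series with AR(1) noise at a protocol-specific tSNR, box-shaped ROI
masks with a somatotopic foot/hand/face layout, and head-motion traces.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (
    BODY_PARTS,
    RESOLUTIONS,
    ROI_STRUCTURES,
    SIDES,
    SUBCORTICAL_STRUCTURES,
    FactorialIndex,
    ParadigmSpec,
    ProtocolSpec,
    ROISet,
    ValidationError,
    VolumeImage,
    body_part_and_side,
    contralateral,
)
from .glm import canonical_hrf

EVENT_COLUMNS = ["onset", "duration", "trial_type", "event_class"]

#: default baseline intensity of simulated BOLD series (arbitrary units)
BASELINE = 100.0


@dataclass
class GroundTruth:
    """Programmed truth for one scenario.

    ``G_true`` is the 9 x 9 pattern covariance over the MOVEMENT x RESOLUTION
    cells (resolution-major order); ``amplitudes`` maps ROI structure name to
    peak response amplitude in percent of baseline; ``tsnr_target`` maps
    protocol name to the programmed baseline/noise-SD ratio.
    """

    G_true: np.ndarray
    sigma2_true: float = 0.5
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"M1": 3.0, "SMA": 2.5, "putamen": 1.5,
                                 "pallidum": 1.5, "thalamus": 1.5}
    )
    ar1_phi: float = 0.3
    tsnr_target: dict[str, float] = field(
        default_factory=lambda: {"1.5mm": 20.0, "2mm": 30.0, "3mm": 40.0}
    )
    pattern_scale: float = 1.0  # weight of the random pattern vs the somatotopic slab

    def __post_init__(self) -> None:
        self.G_true = np.asarray(self.G_true, dtype=float)
        _check_psd(self.G_true)
        if not abs(self.ar1_phi) < 1:
            raise ValidationError(f"|ar1_phi| must be < 1, got {self.ar1_phi}")
        if any(t <= 0 for t in self.tsnr_target.values()):
            raise ValidationError("tsnr_target values must be > 0")


@dataclass
class MotionTrace:
    """Per-volume rigid-body position: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValidationError(f"motion trace must be (n_volumes, 6), got {self.params.shape}")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


def _check_psd(G: np.ndarray, tol_scale: float = 1e-8) -> None:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValidationError(f"covariance must be square, got {G.shape}")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValidationError("covariance must be symmetric")
    w = np.linalg.eigvalsh(G)
    floor = -tol_scale * max(np.trace(G), 1.0)
    if w.min() < floor:
        raise ValidationError(f"covariance not PSD: min eigenvalue {w.min():.3e}")


def make_paradigm(spec: ParadigmSpec, seed: int) -> pd.DataFrame:
    """Generate a block event table: rest -> cued preparation -> active block.

    Condition order is a seeded pseudo-random permutation of the
    ``blocks_per_condition`` repetitions of each condition, constrained so no
    condition occurs twice in a row (guards against learning/attention
    confounds collapsing onto one condition).

    Returns a DataFrame with columns onset (s), duration (s), trial_type,
    event_class ('rest' | 'prep' | 'active').
    """
    if spec.n_active_blocks == 0:
        raise ValidationError("paradigm has zero active blocks")
    rng = np.random.default_rng(seed)
    sequence = list(spec.conditions) * spec.blocks_per_condition
    order = _constrained_shuffle(sequence, rng)

    rows = []
    t = 0.0
    for cond in order:
        if spec.rest_duration_s > 0:
            rows.append((t, spec.rest_duration_s, "rest", "rest"))
            t += spec.rest_duration_s
        if spec.prep_duration_s > 0:
            rows.append((t, spec.prep_duration_s, cond, "prep"))
            t += spec.prep_duration_s
        rows.append((t, spec.block_duration_s, cond, "active"))
        t += spec.block_duration_s
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _constrained_shuffle(items: list[str], rng: np.random.Generator,
                         max_tries: int = 200) -> list[str]:
    """Seeded permutation with no identical neighbours (shuffle + local
    repair: an offending element is swapped with a position where neither
    neighbourhood ends up with a repeat)."""
    items = list(items)
    if len(set(items)) == 1:
        return items  # constraint unsatisfiable and irrelevant
    n = len(items)
    for _ in range(max_tries):
        perm = list(rng.permutation(items))
        for _ in range(10 * n):
            dups = [i for i in range(1, n) if perm[i] == perm[i - 1]]
            if not dups:
                return perm
            i = dups[0]
            candidates = [j for j in range(n) if abs(j - i) > 1
                          and perm[j] != perm[i]
                          and (j == 0 or perm[j - 1] != perm[i])
                          and (j == n - 1 or perm[j + 1] != perm[i])
                          and perm[i - 1] != perm[j]
                          and (i == n - 1 or perm[i + 1] != perm[j])]
            if not candidates:
                break  # reshuffle and try again
            j = int(rng.choice(candidates))
            perm[i], perm[j] = perm[j], perm[i]
    raise RuntimeError("could not find a no-repeat ordering")  # pragma: no cover


def simulate_patterns(G_true: np.ndarray, Z: np.ndarray, v: int, sigma2: float,
                      seed: int) -> np.ndarray:
    """Draw ``Y = Z U + E`` with ``U[:, j] ~ N(0, G_true)`` iid over voxels
    and ``E`` iid ``N(0, sigma2)``. Returns the n x v data matrix."""
    if v < 1:
        raise ValidationError("v must be >= 1")
    G_true = np.asarray(G_true, dtype=float)
    Z = np.asarray(Z, dtype=float)
    _check_psd(G_true)
    if Z.shape[1] != G_true.shape[0]:
        raise ValidationError("Z columns must match G_true dimension")
    rng = np.random.default_rng(seed)
    U = sample_patterns(G_true, v, rng)
    E = np.sqrt(sigma2) * rng.standard_normal((Z.shape[0], v))
    return Z @ U + E


def sample_patterns(G: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """p x v matrix whose columns are N(0, G) draws (eigendecomposition root,
    valid for singular G)."""
    w, Q = np.linalg.eigh(np.asarray(G, dtype=float))
    A = Q * np.sqrt(np.clip(w, 0.0, None))
    return A @ rng.standard_normal((G.shape[0], v))


def make_roi_masks(grid_shape: tuple[int, int, int] = (40, 48, 40),
                   affine: np.ndarray | None = None,
                   box_shape: tuple[int, int, int] = (8, 8, 9)) -> ROISet:
    """Ten disjoint axis-aligned box ROIs: 5 structures x 2 hemispheres.

    Structures are stacked along y; hemispheres mirror across the mid-sagittal
    plane ``i = (nx - 1) / 2``. Boxes are axis-aligned so that centers of mass
    are hand-computable in the geometry tests. The z extent of each box is
    meant to be divisible by 3: the somatotopy simulator splits it into
    foot (dorsal) / hand / face (ventral) slabs.
    """
    nx, ny, nz = grid_shape
    bx, by, bz = box_shape
    n_struct = len(ROI_STRUCTURES)
    gap = 1
    if affine is None:
        # 1.5 mm isotropic, origin at grid centre (mid-sagittal plane -> x = 0)
        vox = 1.5
        affine = np.diag([vox, vox, vox, 1.0])
        affine[:3, 3] = -vox * (np.array(grid_shape) - 1) / 2.0

    x_left0 = max(1, nx // 2 - 2 * bx)
    need_y = n_struct * by + (n_struct - 1) * gap
    y0 = (ny - need_y) // 2
    z0 = (nz - bz) // 2
    if (x_left0 + bx > nx // 2 or y0 < 0 or y0 + need_y > ny
            or z0 < 0 or z0 + bz > nz):
        raise ValidationError(f"grid {grid_shape} too small for 10 boxes of {box_shape}")

    labels = np.zeros(grid_shape, dtype=np.int16)
    names: list[str] = []
    label = 0
    for s, struct in enumerate(ROI_STRUCTURES):
        ys = y0 + s * (by + gap)
        for side in ("left", "right"):
            label += 1
            names.append(f"{struct}_{side}")
            if side == "left":
                xs = slice(x_left0, x_left0 + bx)
            else:
                # mirror voxel-exactly across i = (nx-1)/2
                hi = nx - 1 - x_left0
                xs = slice(hi - bx + 1, hi + 1)
            labels[xs, ys:ys + by, z0:z0 + bz] = label
    return ROISet(labels, names, affine)


def body_part_slab(rois: ROISet, roi_name: str, body_part: str) -> np.ndarray:
    """Boolean mask of the body-part slab inside one box ROI.

    The box is split into three equal-depth slabs along z: face (ventral,
    low z), hand (middle), foot (dorsal, high z) — the classical
    dorsal-to-ventral foot/hand/face gradient.
    """
    mask = rois.mask(roi_name)
    kk = np.unique(np.where(mask)[2])
    thirds = np.array_split(kk, 3)  # ventral -> dorsal
    order = {"face": 0, "hand": 1, "foot": 2}
    sel = thirds[order[body_part]]
    out = np.zeros_like(mask)
    out[:, :, sel] = mask[:, :, sel]
    return out


def condition_target_mask(rois: ROISet, condition: str) -> np.ndarray:
    """Voxels responding to a movement condition: the body-part slab of every
    ROI in the contralateral hemisphere."""
    bp, side = body_part_and_side(condition)
    hemi = contralateral(side)
    out = np.zeros(rois.labels.shape, dtype=bool)
    for struct in ROI_STRUCTURES:
        out |= body_part_slab(rois, f"{struct}_{hemi}", bp)
    return out


def scenario_preset(name: str) -> GroundTruth:
    """Programmed ground truths for the two qualitative study outcomes.

    ``cortical_invariant``: between-movement pattern correlation is equally
    low at all three resolutions (segregation does not depend on protocol).

    ``subcortical_protocol_dependent``: between-movement correlation is low
    at 1.5 mm and 3 mm but high at 2 mm, i.e. the intermediate resolution
    yields the *least* segregated somatotopy in deep nuclei.

    G is built from a factor loading matrix (movement factors + resolution
    factors + a common factor + cell-unique factors), hence PSD by
    construction.
    """
    if name == "cortical_invariant":
        within_res_corr = {1.5: 0.10, 2.0: 0.10, 3.0: 0.10}
    elif name == "subcortical_protocol_dependent":
        within_res_corr = {1.5: 0.10, 2.0: 0.50, 3.0: 0.10}
    else:
        raise ValidationError(f"unknown scenario {name!r}")
    G = _factor_covariance(within_res_corr, common_var=0.05, movement_var=0.35)
    amplitudes = {"M1": 3.0, "SMA": 2.5, "putamen": 1.5, "pallidum": 1.5,
                  "thalamus": 1.5}
    return GroundTruth(G_true=G, amplitudes=amplitudes)


def _factor_covariance(within_res_corr: dict[float, float], common_var: float,
                       movement_var: float) -> np.ndarray:
    """9x9 unit-variance covariance with programmed within-resolution
    between-movement correlation per resolution.

    Latent decomposition per cell (movement m, resolution r):
    ``u = a*f_m + b_r*g_r + c*h + d_r*e_cell`` with independent unit-variance
    factors, so corr(same r, different m) = b_r^2 + c^2 and
    corr(same m, different r) = a^2 + c^2.
    """
    cells = FactorialIndex()
    p = cells.p
    res_var = {r: within_res_corr[r] - common_var for r in within_res_corr}
    if any(v < 0 for v in res_var.values()):
        raise ValidationError("within-resolution correlation below common variance")
    n_factors = len(BODY_PARTS) + len(RESOLUTIONS) + 1 + p
    L = np.zeros((p, n_factors))
    for i in range(p):
        mov, res = cells.cell(i)
        uniq = 1.0 - movement_var - common_var - res_var[res]
        if uniq < 0:
            raise ValidationError("factor variances exceed total unit variance")
        L[i, BODY_PARTS.index(mov)] = np.sqrt(movement_var)
        L[i, len(BODY_PARTS) + RESOLUTIONS.index(res)] = np.sqrt(res_var[res])
        L[i, len(BODY_PARTS) + len(RESOLUTIONS)] = np.sqrt(common_var)
        L[i, len(BODY_PARTS) + len(RESOLUTIONS) + 1 + i] = np.sqrt(uniq)
    return L @ L.T


def ar1_noise(shape_t_by_v: tuple[int, int], phi: float, sd: float,
              rng: np.random.Generator, burn_in: int = 50) -> np.ndarray:
    """Stationary AR(1) series per column: lag-1 coefficient ``phi``,
    stationary standard deviation ``sd``."""
    if not abs(phi) < 1:
        raise ValidationError(f"|phi| must be < 1, got {phi}")
    nt, nv = shape_t_by_v
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = innov_sd * rng.standard_normal((nt + burn_in, nv))
    series = lfilter([1.0], [1.0, -phi], eps, axis=0)
    return series[burn_in:]


def simulate_timeseries(protocol: ProtocolSpec, events: pd.DataFrame,
                        rois: ROISet, truth: GroundTruth, seed: int,
                        U: np.ndarray | None = None,
                        ) -> tuple[VolumeImage, MotionTrace]:
    """Simulate a 4D BOLD run for one protocol on the ROI grid.

    Signal model per voxel: ``baseline * (1 + sum_c a_c(voxel) * x_c(t) / 100)``
    where ``x_c`` is the condition boxcar convolved with the canonical HRF
    (unit peak) and ``a_c`` is the percent-signal amplitude: the ROI-structure
    amplitude inside the condition's contralateral body-part slab, modulated
    multiplicatively by the pattern component ``U`` of the cell
    (movement, protocol resolution) when ``U`` is given (9 x total-ROI-voxel
    matrix in the row order of :class:`~somatoseg.core.FactorialIndex` and
    the column order of ``np.where(labels > 0)``).

    Noise: per-voxel AR(1) with stationary SD ``baseline / tsnr_target``.
    Motion: seeded random walk (translations mm, rotations rad).
    """
    horizon = float((events["onset"] + events["duration"]).max())
    if horizon > protocol.scan_duration_s + 1e-9:
        raise ValidationError(
            f"events end at {horizon:.1f}s but scan lasts {protocol.scan_duration_s:.1f}s")

    rng = np.random.default_rng(seed)
    nt = protocol.n_volumes
    shape = rois.labels.shape
    conditions = sorted(events.loc[events.event_class == "active", "trial_type"].unique())
    regressors = _condition_regressors(events, conditions, protocol)

    tsnr = truth.tsnr_target.get(protocol.name)
    if tsnr is None:
        raise ValidationError(f"no tsnr_target for protocol {protocol.name!r}")

    cells = FactorialIndex()
    roi_flat = np.where(rois.labels.ravel() > 0)[0]
    amp = np.zeros((len(conditions),) + shape)
    for ci, cond in enumerate(conditions):
        bp, side = body_part_and_side(cond)
        slab = condition_target_mask(rois, cond)
        # structure-wise amplitude scale over the whole contralateral hemisphere
        scale = np.zeros(shape)
        for struct in ROI_STRUCTURES:
            m = rois.mask(f"{struct}_{contralateral(side)}")
            scale[m] = truth.amplitudes.get(struct, 0.0)
        # response = scale * (slab indicator + pattern component of this cell)
        a = scale * slab
        if U is not None:
            cell = cells.cell_index(bp, protocol.voxel_size_mm)
            mod = np.zeros(shape)
            mod.ravel()[roi_flat] = truth.pattern_scale * U[cell]
            a = a + scale * mod
        amp[ci] = a

    # signal: baseline * (1 + sum_c amp_c/100 * x_c(t))
    data = np.empty(shape + (nt,), dtype=np.float32)
    data[...] = BASELINE
    for ci in range(len(conditions)):
        data += (BASELINE / 100.0) * amp[ci][..., None] * regressors[:, ci]

    sd = BASELINE / tsnr
    if sd > 0:
        noise = ar1_noise((nt, int(np.prod(shape))), truth.ar1_phi, sd, rng)
        data += noise.T.reshape(shape + (nt,)).astype(np.float32)

    motion = _random_walk_motion(nt, rng)
    return VolumeImage(data, rois.affine, space_label="synthetic-bold"), motion


def _condition_regressors(events: pd.DataFrame, conditions: list[str],
                          protocol: ProtocolSpec, dt: float = 0.1) -> np.ndarray:
    """HRF-convolved condition boxcars sampled at volume onsets
    (n_volumes x n_conditions)."""
    hrf = canonical_hrf(dt)
    n_fine = int(np.ceil(protocol.scan_duration_s / dt)) + 1
    out = np.zeros((protocol.n_volumes, len(conditions)))
    t_vol = np.arange(protocol.n_volumes) * protocol.tr_s
    idx = np.minimum((t_vol / dt).round().astype(int), n_fine - 1)
    active = events[events.event_class == "active"]
    for ci, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        for _, ev in active[active.trial_type == cond].iterrows():
            i0 = int(round(ev.onset / dt))
            i1 = int(round((ev.onset + ev.duration) / dt))
            box[i0:i1] = 1.0
        conv = np.convolve(box, hrf)[:n_fine]
        out[:, ci] = conv[idx]
    return out


def _random_walk_motion(nt: int, rng: np.random.Generator,
                        trans_step_mm: float = 0.25,
                        rot_step_rad: float = 5e-5) -> MotionTrace:
    """Seeded random-walk head position. Step SDs are set so frame-to-frame
    displacement norms average ~0.4 mm with occasional excursions past the
    0.5 mm flagging threshold, the regime typical of motor-task fMRI."""
    steps = rng.standard_normal((nt, 6))
    steps[:, :3] *= trans_step_mm
    steps[:, 3:] *= rot_step_rad
    steps[0] = 0.0
    return MotionTrace(np.cumsum(steps, axis=0))


def group_pattern(truth: GroundTruth, rois: ROISet, seed: int) -> np.ndarray:
    """Draw the group-level 9 x v pattern matrix U over all ROI voxels
    (column order = flattened ``labels > 0`` order)."""
    v = int((rois.labels > 0).sum())
    rng = np.random.default_rng(seed)
    return sample_patterns(truth.G_true, v, rng)
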