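"""End-to-end synthetic study.

Simulates the full experiment (subjects x three acquisition protocols on a
common 1.5 mm grid), runs subject-level GLMs, pools betas into the 9-cell
MOVEMENT x RESOLUTION factorial per ROI, fits the pattern component model,
derives IoS similarity reports, BOLD-sensitivity and motion metrics,
somatotopy geometry and the group-level statistics, and writes tidy tables
plus a machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geom
from . import group_stats as gs
from .core import (
    BODY_PARTS,
    CORTICAL_STRUCTURES,
    ROI_STRUCTURES,
    SIDES,
    SUBCORTICAL_STRUCTURES,
    FactorialIndex,
    ParadigmSpec,
    ValidationError,
    VolumeImage,
    contralateral,
    default_protocol_presets,
)
from .glm import build_design, compute_contrast, differential_contrasts, fit_glm
from .io import gaussian_smooth, save_yaml
from .pcm import default_design, fit_per_roi
from .sensitivity import (
    motion_metrics,
    roi_summary,
    scaled_variance,
    top5_tscores,
    tsnr_map,
    weighted_tsnr,
)
from .similarity import similarity_report
from .synth import (
    GroundTruth,
    make_paradigm,
    make_roi_masks,
    sample_patterns,
    scenario_preset,
    simulate_timeseries,
)


@dataclass
class RunConfig:
    """Configuration of one synthetic study run.

    ``scenario`` selects the programmed subcortical ground truth; cortical
    ROIs always follow the resolution-invariant truth, so a single default
    run exercises both halves of the expected outcome. ``smoothing`` is
    "none" or "proportional" (FWHM = ``fwhm_per_voxel`` x voxel size).
    """

    scenario: str = "subcortical_protocol_dependent"
    n_subjects: int = 15
    grid_shape: tuple = (40, 48, 40)
    box_shape: tuple = (8, 8, 9)
    seed: int = 0
    smoothing: str = "none"
    fwhm_per_voxel: float = 1.0
    alpha: float = 0.05
    q_fdr: float = 0.05
    blocks_per_condition: int = 3

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    similarity_pairs: pd.DataFrame
    similarity_tests: pd.DataFrame
    sensitivity: pd.DataFrame
    motion: pd.DataFrame
    scaled_variance_table: pd.DataFrame
    geometry_table: pd.DataFrame
    betweenness: pd.DataFrame
    directions: pd.DataFrame
    pcm_fits: dict
    group: dict
    summary: dict
    geometry: "geom.GeometrySummary | None" = None


def _composite_pattern(rois, truth_cort: GroundTruth, truth_sub: GroundTruth,
                       rng: np.random.Generator) -> np.ndarray:
    """Group-level 9 x v pattern over all ROI voxels: cortical voxels follow
    the cortical covariance, subcortical voxels the scenario covariance."""
    flat_labels = rois.labels.ravel()
    roi_idx = np.where(flat_labels > 0)[0]
    v = roi_idx.size
    U = np.empty((truth_cort.G_true.shape[0], v))
    struct_of_label = {i + 1: name.rsplit("_", 1)[0] for i, name in enumerate(rois.names)}
    labels_at = flat_labels[roi_idx]
    is_cort = np.array([struct_of_label[l] in CORTICAL_STRUCTURES for l in labels_at])
    U[:, is_cort] = sample_patterns(truth_cort.G_true, int(is_cort.sum()), rng)
    U[:, ~is_cort] = sample_patterns(truth_sub.G_true, int((~is_cort).sum()), rng)
    return U


def _lag1_autocorr(resid: np.ndarray) -> float:
    num = (resid[1:] * resid[:-1]).sum()
    den = (resid**2).sum()
    return float(num / den) if den > 0 else 0.0


def run_pipeline(config: RunConfig, out_dir: "str | Path | None" = None) -> PipelineResult:
    """Run the full synthetic study and return (and optionally write) all
    result tables. Deterministic given the config."""
    if config.scenario not in ("cortical_invariant", "subcortical_protocol_dependent"):
        raise ValidationError(f"unknown scenario {config.scenario!r}")
    presets = default_protocol_presets()
    paradigm = ParadigmSpec(blocks_per_condition=config.blocks_per_condition)
    rois = make_roi_masks(config.grid_shape, box_shape=config.box_shape)
    cells = FactorialIndex()

    truth_cort = scenario_preset("cortical_invariant")
    truth_sub = scenario_preset(config.scenario)
    rng = np.random.default_rng(config.seed)
    U = _composite_pattern(rois, truth_cort, truth_sub, rng)
    run_seeds = rng.integers(2**31, size=(config.n_subjects, len(presets), 2))

    flat_labels = rois.labels.ravel()
    roi_idx = np.where(flat_labels > 0)[0]
    roi_masks_flat = {name: flat_labels[roi_idx] == i + 1
                      for i, name in enumerate(rois.names)}

    n_cond = 6
    S = config.n_subjects
    # per (protocol, condition): running sums of subject effect maps at ROI voxels
    eff_sum = {p.name: np.zeros((n_cond, roi_idx.size)) for p in presets}
    eff_sumsq = {p.name: np.zeros((n_cond, roi_idx.size)) for p in presets}
    top5_acc: list[dict] = []
    tsnr_rows: list[dict] = []
    motion_rows: list[dict] = []
    sv_rows: list[dict] = []
    phi_hat: dict[str, list[float]] = {p.name: [] for p in presets}
    cond_names: list[str] = []

    for s in range(S):
        for ip, protocol in enumerate(presets):
            ev_seed, ts_seed = (int(x) for x in run_seeds[s, ip])
            events = make_paradigm(paradigm, seed=ev_seed)
            img, motion = simulate_timeseries(protocol, events, rois, truth_sub,
                                              seed=ts_seed, U=U)
            if config.smoothing == "proportional":
                img = gaussian_smooth(img, config.fwhm_per_voxel * protocol.voxel_size_mm)
            design = build_design(events, protocol, motion)
            fit = fit_glm(img, design)
            cond_names = sorted(design.condition_columns)
            flat_resid_roi = fit.residuals[:, roi_idx]
            phi_hat[protocol.name].append(_lag1_autocorr(flat_resid_roi))

            contrasts = differential_contrasts(cond_names, design)
            for ci, (cname, cvec) in enumerate(contrasts):
                res = compute_contrast(fit, cvec, cname)
                eff_flat = res.effect_map.data.ravel()[roi_idx]
                eff_sum[protocol.name][ci] += eff_flat
                eff_sumsq[protocol.name][ci] += eff_flat**2
                t5 = top5_tscores(res.t_map, rois)
                for roi_name, val in t5.items():
                    top5_acc.append({"subject": s, "protocol": protocol.name,
                                     "roi": roi_name, "condition": cname,
                                     "t_top5": val})

            tmap = tsnr_map(img, design)
            for roi_name, val in roi_summary(tmap, rois).items():
                tsnr_rows.append({"subject": s, "protocol": protocol.name,
                                  "roi": roi_name, "tsnr": val})

            mm = motion_metrics(motion)
            motion_rows.append({"subject": s, "protocol": protocol.name,
                                "mean_translation_mm": mm.mean_translation_mm,
                                "max_translation_mm": mm.max_translation_mm,
                                "n_movements_gt_half_mm": mm.n_movements_gt_half_mm,
                                "rotation_summary_deg": mm.rotation_summary_deg})

            sv_series, sv_mean = scaled_variance(img)
            pair_parts = _pairs_by_body_part(events, protocol, len(sv_series))
            for bp in BODY_PARTS:
                sel = pair_parts == bp
                if sel.any():
                    sv_rows.append({"subject": s, "protocol": protocol.name,
                                    "body_part": bp,
                                    "scaled_variance": float(sv_series[sel].mean())})
            del img, fit

    # ---- group-level betas per ROI -> PCM -> similarity --------------------
    betas: dict[str, np.ndarray] = {}
    for roi_name in rois.names:
        struct, hemi = roi_name.rsplit("_", 1)
        mov_side = contralateral(hemi)
        sel = roi_masks_flat[roi_name]
        Y = np.zeros((cells.p, int(sel.sum())))
        for i in range(cells.p):
            bp, res = cells.cell(i)
            pname = next(p.name for p in presets if p.voxel_size_mm == res)
            ci = cond_names.index(f"{bp}_{mov_side}")
            Y[i] = eff_sum[pname][ci][sel] / S
        betas[roi_name] = Y

    fits = fit_per_roi(betas, default_design(cells.p))
    sim_pairs, sim_tests = [], []
    for roi_name, fit in fits.items():
        rep = similarity_report(fit, cells, n_eff=rois.voxel_count(roi_name),
                                q=config.q_fdr)
        sim_pairs.append(rep.pairs)
        sim_tests.append(rep.tests)
    similarity_pairs = pd.concat(sim_pairs, ignore_index=True)
    similarity_tests = pd.concat(sim_tests, ignore_index=True)

    # ---- sensitivity table -------------------------------------------------
    tsnr_df = pd.DataFrame(tsnr_rows)
    top5_df = pd.DataFrame(top5_acc)
    sens_rows = []
    for protocol in presets:
        phi = float(np.mean(phi_hat[protocol.name]))
        for roi_name in rois.names:
            t_mean = tsnr_df.query("protocol == @protocol.name and roi == @roi_name")["tsnr"].mean()
            per_tr, per_n, scaled = weighted_tsnr(float(t_mean), protocol, phi)
            hemi = roi_name.rsplit("_", 1)[1]
            contra = [f"{bp}_{contralateral(hemi)}" for bp in BODY_PARTS]
            t5 = top5_df.query(
                "protocol == @protocol.name and roi == @roi_name and condition in @contra"
            )["t_top5"].mean()
            sens_rows.append({"roi": roi_name, "protocol": protocol.name,
                              "tsnr_mean": float(t_mean), "tsnr_per_tr": per_tr,
                              "tsnr_per_n": per_n, "tsnr_scaled": scaled,
                              "t_top5_mean": float(t5), "phi_hat": phi})
    sensitivity = pd.DataFrame(sens_rows)
    motion_df = pd.DataFrame(motion_rows)
    sv_df = pd.DataFrame(sv_rows)

    # ---- geometry on group t-maps ------------------------------------------
    geo_rows, bet_rows, dir_rows = [], [], []
    coms_by_roi: dict[str, np.ndarray] = {r: np.full((cells.p, 3), np.nan)
                                          for r in rois.names}
    dof_group = S - 1
    for protocol in presets:
        # group one-sample t over subjects, per condition, at ROI voxels
        mean_eff = eff_sum[protocol.name] / S
        var_eff = (eff_sumsq[protocol.name] - S * mean_eff**2) / (S - 1) if S > 1 else None
        for roi_name in rois.names:
            struct, hemi = roi_name.rsplit("_", 1)
            mov_side = contralateral(hemi)
            roi_mask3d = rois.mask(roi_name)
            for bp in BODY_PARTS:
                ci = cond_names.index(f"{bp}_{mov_side}")
                tflat = np.full(flat_labels.size, np.nan)
                if var_eff is not None:
                    with np.errstate(invalid="ignore", divide="ignore"):
                        tvals = mean_eff[ci] / np.sqrt(var_eff[ci] / S)
                else:
                    tvals = np.sign(mean_eff[ci]) * np.inf
                tflat[roi_idx] = tvals
                t_img = VolumeImage(tflat.reshape(rois.labels.shape), rois.affine, "t")
                supra = geom.threshold_tmap(t_img, dof_group, config.alpha)
                mask_in_roi = (supra.data.astype(bool)) & roi_mask3d
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    com = geom.center_of_mass(
                        VolumeImage(mask_in_roi.astype(np.uint8), rois.affine))
                mx = geom.activation_maximum(t_img, roi_mask3d)
                vol = geom.adjusted_volume(mask_in_roi, roi_mask3d)
                cell = cells.cell_index(bp, protocol.voxel_size_mm)
                coms_by_roi[roi_name][cell] = com
                geo_rows.append({"roi": roi_name, "body_part": bp,
                                 "resolution": protocol.voxel_size_mm,
                                 "com_x": com[0], "com_y": com[1], "com_z": com[2],
                                 "max_x": mx[0], "max_y": mx[1], "max_z": mx[2],
                                 "adjusted_volume": vol})
            by_bp = {bp: coms_by_roi[roi_name][cells.cell_index(bp, protocol.voxel_size_mm)]
                     for bp in BODY_PARTS}
            flags = geom.betweenness_check(by_bp["foot"], by_bp["hand"], by_bp["face"])
            bet_rows.append({"roi": roi_name, "resolution": protocol.voxel_size_mm,
                             **{f"axis_{k}": v for k, v in flags.items()}})
            dir_rows.append({"roi": roi_name, "resolution": protocol.voxel_size_mm,
                             "expected_gradient": geom.DEFAULT_EXPECTATIONS[struct][0],
                             "flag": geom.direction_check(by_bp["foot"], by_bp["face"],
                                                          struct)})
    geometry_table = pd.DataFrame(geo_rows)
    betweenness = pd.DataFrame(bet_rows)
    directions = pd.DataFrame(dir_rows)

    # ---- group statistics ---------------------------------------------------
    group: dict = {}
    res_of = {p.voxel_size_mm: p.name for p in presets}

    # IoS vs tSNR over ROI x resolution (30 rows)
    ios_rows = []
    for roi_name in fits:
        for res in cells.resolutions:
            fam = similarity_pairs.query(
                "roi == @roi_name and family == 'within_resolution'")
            sub = fam[fam["pair"].str.contains(f"@{res:g}\\|")]
            ios_mean = float(sub["ios"].mean())
            t_row = sensitivity[(sensitivity.roi == roi_name)
                                & (sensitivity.protocol == res_of[res])].iloc[0]
            ios_rows.append({"roi": roi_name, "resolution": res, "ios": ios_mean,
                             "tsnr": t_row["tsnr_mean"],
                             "tsnr_per_tr": t_row["tsnr_per_tr"],
                             "tsnr_per_n": t_row["tsnr_per_n"],
                             "tsnr_scaled": t_row["tsnr_scaled"]})
    ios_tsnr = pd.DataFrame(ios_rows)
    group["ios_tsnr_table"] = ios_tsnr
    group["correlation"] = gs.correlate(ios_tsnr["tsnr"], ios_tsnr["ios"])
    group["ancova"] = gs.ancova_ios(ios_tsnr["ios"], ios_tsnr["tsnr"],
                                    ios_tsnr["resolution"])

    # MANOVA on projected centers of mass across ROIs
    proj_rows = []
    axes_by_roi: dict[str, np.ndarray] = {}
    for roi_name, coms in coms_by_roi.items():
        if np.isnan(coms).any():
            continue
        proj, axes = geom.principal_axis_projection(coms)
        axes_by_roi[roi_name] = axes
        for i in range(cells.p):
            bp, res = cells.cell(i)
            proj_rows.append({"roi": roi_name, "body_part": bp, "resolution": res,
                              "p1": proj[i, 0], "p2": proj[i, 1], "p3": proj[i, 2]})
    proj_df = pd.DataFrame(proj_rows)
    group["projected_coms"] = proj_df
    if len(proj_df) >= 18:
        group["manova"] = gs.manova_coords(
            proj_df[["p1", "p2", "p3"]].to_numpy(),
            proj_df["body_part"], proj_df["resolution"])

    # activation volume vs resolution (1-way) and motion metrics (1-way each)
    group["volume_anova"] = gs.anova_oneway_twoway(
        geometry_table["adjusted_volume"],
        {"resolution": geometry_table["resolution"]})
    group["volume_means"] = geometry_table.groupby("resolution")["adjusted_volume"] \
                                          .mean().to_dict()
    group["motion_anovas"] = {
        metric: gs.anova_oneway_twoway(motion_df[metric],
                                       {"protocol": motion_df["protocol"]})
        for metric in ["mean_translation_mm", "max_translation_mm",
                       "n_movements_gt_half_mm", "rotation_summary_deg"]
    }
    if sv_df["body_part"].nunique() > 1:
        group["scaled_variance_anova"] = gs.anova_oneway_twoway(
            sv_df["scaled_variance"],
            {"protocol": sv_df["protocol"], "body_part": sv_df["body_part"]})

    summary = _summarize(config, ios_tsnr, group)
    geo_summary = geom.GeometrySummary(
        table=geometry_table, betweenness=betweenness, directions=directions,
        principal_axes=axes_by_roi,
        projected_coms={r: proj_df[proj_df.roi == r][["p1", "p2", "p3"]].to_numpy()
                        for r in axes_by_roi})
    result = PipelineResult(config, similarity_pairs, similarity_tests, sensitivity,
                            motion_df, sv_df, geometry_table, betweenness, directions,
                            fits, group, summary, geometry=geo_summary)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _pairs_by_body_part(events: pd.DataFrame, protocol, n_pairs: int) -> np.ndarray:
    """Label each consecutive-volume pair with the body part whose active
    block contains the pair midpoint ('' outside active blocks)."""
    mid = (np.arange(n_pairs) + 0.5) * protocol.tr_s
    out = np.array([""] * n_pairs, dtype=object)
    active = events[events.event_class == "active"]
    for _, ev in active.iterrows():
        inside = (mid >= ev.onset) & (mid < ev.onset + ev.duration)
        out[inside] = ev.trial_type.split("_")[0]
    return out


def _cortical_subcortical_ios(ios_tsnr: pd.DataFrame) -> dict:
    out = {}
    for klass, structures in (("cortical", CORTICAL_STRUCTURES),
                              ("subcortical", SUBCORTICAL_STRUCTURES)):
        sel = ios_tsnr[ios_tsnr["roi"].str.rsplit("_", n=1).str[0].isin(structures)]
        out[klass] = sel.groupby("resolution")["ios"].mean().to_dict()
    return out


def _summarize(config: RunConfig, ios_tsnr: pd.DataFrame, group: dict) -> dict:
    by_class = _cortical_subcortical_ios(ios_tsnr)
    sub = by_class["subcortical"]
    cort = by_class["cortical"]
    sub_2mm_excess = sub[2.0] - 0.5 * (sub[1.5] + sub[3.0])
    cort_range = max(cort.values()) - min(cort.values())
    return {
        "config_digest": config.digest(),
        "seed": config.seed,
        "scenario": config.scenario,
        "ios_mean_by_class_resolution": {k: {f"{r:g}": v for r, v in d.items()}
                                         for k, d in by_class.items()},
        "subcortical_2mm_ios_excess": float(sub_2mm_excess),
        "cortical_ios_resolution_range": float(cort_range),
        "flag_subcortical_2mm_least_segregated":
            bool(sub[2.0] > sub[1.5] and sub[2.0] > sub[3.0]),
        "flag_cortical_resolution_invariant": bool(cort_range < 0.1),
        "ios_tsnr_pearson_r": group["correlation"]["pearson_r"],
        "ios_tsnr_spearman_rho": group["correlation"]["spearman_rho"],
        "ancova_model_f": group["ancova"].model_f,
        "ancova_r2": group["ancova"].r_squared,
        "volume_means_by_resolution": {f"{k:g}": float(v)
                                       for k, v in group["volume_means"].items()},
        "manova_pillai_body_part": (
            float(group["manova"].terms.set_index("term").loc["body_part", "pillai"])
            if "manova" in group else None),
    }


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (f"# somatoseg run  config={result.config.digest()}  "
              f"seed={result.config.seed}\n")

    def write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    write(result.similarity_pairs, "similarity_pairs.tsv")
    write(result.similarity_tests, "similarity_tests.tsv")
    write(result.sensitivity, "sensitivity.tsv")
    write(result.motion, "motion.tsv")
    write(result.scaled_variance_table, "scaled_variance.tsv")
    write(result.geometry_table, "geometry.tsv")
    write(result.betweenness, "betweenness.tsv")
    write(result.directions, "directions.tsv")
    write(result.group["ios_tsnr_table"], "ios_tsnr.tsv")
    save_yaml(result.config, out_dir / "config.yaml")
    (out_dir / "summary.json").write_text(json.dumps(result.summary, indent=1,
                                                     default=float))
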