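import numpy as np
import pytest

import somatoseg as ss
from somatoseg.core import ParadigmSpec, ValidationError, VolumeImage
from somatoseg.glm import (
    build_design,
    canonical_hrf,
    compute_contrast,
    differential_contrasts,
    fit_glm,
)
from somatoseg.synth import GroundTruth, MotionTrace, make_paradigm, simulate_timeseries


class TestCanonicalHrf:
    def test_zero_at_origin_and_unit_peak(self):
        h = canonical_hrf(0.1)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_peak_near_five_seconds(self):
        dt = 0.01
        h = canonical_hrf(dt)
        t_peak = np.argmax(h) * dt
        # mode of the gamma(6, 1) response lobe is 5 s; the undershoot
        # subtraction shifts it only slightly
        assert abs(t_peak - 5.0) < 0.5

    def test_positive_integral_with_undershoot(self):
        h = canonical_hrf(0.05)
        assert h.sum() > 0
        assert h.min() < 0  # undershoot lobe exists

    def test_invalid_dt(self):
        with pytest.raises(ValidationError):
            canonical_hrf(0.0)


@pytest.fixture(scope="module")
def run(presets_module, rois_module, paradigm_module):
    """A noiseless simulated run with known percent-signal amplitudes."""
    protocol = presets_module[0]
    truth = GroundTruth(G_true=np.eye(9),
                        amplitudes={"M1": 3.0, "SMA": 2.5, "putamen": 1.5,
                                    "pallidum": 1.5, "thalamus": 1.5},
                        tsnr_target={protocol.name: np.inf}, ar1_phi=0.0)
    ev = make_paradigm(paradigm_module, seed=21)
    img, motion = simulate_timeseries(protocol, ev, rois_module, truth, seed=21)
    design = build_design(ev, protocol, motion)
    return protocol, truth, ev, img, motion, design


@pytest.fixture(scope="module")
def presets_module():
    return ss.default_protocol_presets()


@pytest.fixture(scope="module")
def rois_module():
    from somatoseg.synth import make_roi_masks
    return make_roi_masks(grid_shape=(28, 36, 28), box_shape=(6, 6, 6))


@pytest.fixture(scope="module")
def paradigm_module():
    return ParadigmSpec()


class TestBuildDesign:
    def test_fourteen_columns_under_default_paradigm(self, run):
        *_, design = run
        assert design.k == 14  # 6 conditions + prep + 6 motion + intercept
        assert len(design.condition_columns) == 6
        assert design.column_names.count("intercept") == 1

    def test_zero_motion_flagged_collinear(self, presets_module, paradigm_module):
        protocol = presets_module[0]
        ev = make_paradigm(paradigm_module, seed=0)
        zero_motion = MotionTrace(np.zeros((protocol.n_volumes, 6)))
        with pytest.warns(UserWarning, match="collinear"):
            design = build_design(ev, protocol, zero_motion)
        motion_cols = [j for j, n in enumerate(design.column_names)
                       if n.startswith("motion_")]
        assert np.all(design.X[:, motion_cols] == 0)

    def test_events_beyond_scan_rejected(self, presets_module):
        ev = make_paradigm(ParadigmSpec(blocks_per_condition=10), seed=0)
        with pytest.raises(ValidationError):
            build_design(ev, presets_module[0])

    def test_cosine_drift_columns_optional(self, presets_module, paradigm_module):
        ev = make_paradigm(paradigm_module, seed=0)
        d = build_design(ev, presets_module[0], n_cosine_drift=3)
        assert sum(n.startswith("drift_cos") for n in d.column_names) == 3


class TestFitGlm:
    def test_noiseless_betas_recover_programmed_amplitudes(self, run, rois_module):
        protocol, truth, ev, img, motion, design = run
        fit = fit_glm(img, design)
        # hand_left activates the hand slab of right-hemisphere ROIs
        from somatoseg.synth import body_part_slab
        slab = body_part_slab(rois_module, "M1_right", "hand")
        col = design.condition_columns["hand_left"]
        betas = fit.betas[col].reshape(img.data.shape[:3])[slab]
        expected = 100.0 * truth.amplitudes["M1"] / 100.0  # baseline * pct
        assert np.allclose(betas, expected, rtol=1e-6)

    def test_residual_orthogonality(self, run):
        _, _, _, img, _, design = run
        fit = fit_glm(img, design)
        gram = design.X.T @ fit.residuals
        assert np.abs(gram).max() < 1e-8 * np.abs(img.data).max()

    def test_voxel_permutation_equivariance(self, run):
        _, _, _, img, _, design = run
        fit = fit_glm(img, design)
        n_keep = 50
        flat = img.data.reshape(-1, design.n_volumes)[:n_keep]
        perm = np.random.default_rng(0).permutation(n_keep)
        img_p = VolumeImage(flat[perm].reshape(n_keep, 1, 1, design.n_volumes),
                            np.eye(4))
        fit_p = fit_glm(img_p, design)
        assert np.allclose(fit_p.betas, fit.betas[:, :n_keep][:, perm])

    def test_mismatched_volume_count_rejected(self, run):
        _, _, _, img, _, design = run
        short = VolumeImage(img.data[..., :-5], img.affine)
        with pytest.raises(ValidationError):
            fit_glm(short, design)

    def test_doubling_amplitude_doubles_condition_beta(
            self, presets_module, rois_module, paradigm_module):
        protocol = presets_module[2]
        ev = make_paradigm(paradigm_module, seed=1)
        fits = []
        for scale in (1.0, 2.0):
            truth = GroundTruth(G_true=np.eye(9),
                                amplitudes={"M1": 2.0 * scale},
                                tsnr_target={protocol.name: np.inf}, ar1_phi=0.0)
            img, motion = simulate_timeseries(protocol, ev, rois_module, truth, seed=2)
            design = build_design(ev, protocol, motion)
            fits.append(fit_glm(img, design))
        col = fits[0].design.condition_columns["foot_right"]
        b1, b2 = fits[0].betas[col], fits[1].betas[col]
        active = np.abs(b1) > 1e-6
        assert active.any()
        assert np.allclose(b2[active], 2.0 * b1[active], rtol=1e-6)


class TestContrasts:
    def test_six_differential_contrasts_single_entry(self, run):
        *_, design = run
        specs = differential_contrasts(sorted(design.condition_columns), design)
        assert len(specs) == 6
        for name, c in specs:
            assert np.count_nonzero(c) == 1
            assert c[design.condition_columns[name]] == 1.0

    def test_missing_condition_rejected(self, run):
        *_, design = run
        with pytest.raises(ValidationError):
            differential_contrasts(["tail_left"], design)

    def test_tmap_maximum_inside_stimulated_roi(
            self, presets_module, rois_module, paradigm_module):
        protocol = presets_module[1]
        truth = GroundTruth(G_true=np.eye(9), amplitudes={"putamen": 2.0},
                            tsnr_target={protocol.name: 80.0}, ar1_phi=0.0)
        ev = make_paradigm(paradigm_module, seed=3)
        img, motion = simulate_timeseries(protocol, ev, rois_module, truth, seed=3)
        design = build_design(ev, protocol, motion)
        fit = fit_glm(img, design)
        name, c = differential_contrasts(["face_left"], design)[0]
        res = compute_contrast(fit, c, name)
        from somatoseg.synth import body_part_slab
        target = body_part_slab(rois_module, "putamen_right", "face")
        peak = np.unravel_index(np.nanargmax(res.t_map.data), res.t_map.data.shape)
        assert target[peak]


class TestStatisticalProperties:
    def test_ols_parameter_recovery_unbiased(self, presets_module, rois_module,
                                             paradigm_module):
        """Mean fitted beta over repeated noisy runs stays within 2 SE of truth."""
        protocol = presets_module[2]
        truth = GroundTruth(G_true=np.eye(9), amplitudes={"M1": 2.0},
                            tsnr_target={protocol.name: 30.0}, ar1_phi=0.3)
        ev = make_paradigm(paradigm_module, seed=4)
        design = None
        vals = []
        from somatoseg.synth import body_part_slab
        slab = body_part_slab(rois_module, "M1_left", "hand")
        for seed in range(30):
            img, motion = simulate_timeseries(protocol, ev, rois_module, truth,
                                              seed=100 + seed)
            design = build_design(ev, protocol, motion)
            fit = fit_glm(img, design)
            col = design.condition_columns["hand_right"]
            vals.append(fit.betas[col].reshape(img.data.shape[:3])[slab].mean())
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 2.0) < 2.5 * se + 0.02

    def test_null_tmap_false_positive_rate(self, presets_module, rois_module,
                                           paradigm_module):
        """Pure-noise runs reject at the nominal one-sided alpha = 0.05."""
        from scipy import stats
        protocol = presets_module[2]
        truth = GroundTruth(G_true=np.eye(9), amplitudes={},
                            tsnr_target={protocol.name: 20.0}, ar1_phi=0.0)
        ev = make_paradigm(paradigm_module, seed=5)
        img, motion = simulate_timeseries(protocol, ev, rois_module, truth, seed=6)
        design = build_design(ev, protocol, motion)
        fit = fit_glm(img, design)
        name, c = differential_contrasts(["hand_left"], design)[0]
        res = compute_contrast(fit, c, name)
        t_crit = stats.t.ppf(0.95, fit.dof)
        frac = np.mean(res.t_map.data > t_crit)
        assert frac == pytest.approx(0.05, abs=0.01)
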