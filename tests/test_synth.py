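import numpy as np
import pandas as pd
import pytest

import somatoseg as ss
from somatoseg.core import ParadigmSpec, ValidationError
from somatoseg.glm import build_design, fit_glm
from somatoseg.synth import (
    GroundTruth,
    ar1_noise,
    body_part_slab,
    condition_target_mask,
    make_paradigm,
    make_roi_masks,
    scenario_preset,
    simulate_patterns,
    simulate_timeseries,
)


class TestMakeParadigm:
    def test_default_block_structure(self, paradigm):
        ev = make_paradigm(paradigm, seed=0)
        active = ev[ev.event_class == "active"]
        assert len(active) == 18
        assert active.trial_type.value_counts().eq(3).all()

    def test_rest_blocks_interleave_and_preps_precede(self, paradigm):
        ev = make_paradigm(paradigm, seed=3)
        classes = list(ev.event_class)
        # repeating unit is rest, prep, active
        assert classes == ["rest", "prep", "active"] * 18
        # prep immediately precedes its active block with matching condition
        preps = ev[ev.event_class == "prep"].reset_index(drop=True)
        actives = ev[ev.event_class == "active"].reset_index(drop=True)
        assert (preps.trial_type == actives.trial_type).all()
        assert np.allclose(preps.onset + preps.duration, actives.onset)

    def test_onsets_non_decreasing_no_overlap(self, paradigm):
        ev = make_paradigm(paradigm, seed=5)
        assert (np.diff(ev.onset) >= 0).all()
        ends = ev.onset + ev.duration
        assert (ev.onset.values[1:] >= ends.values[:-1] - 1e-9).all()

    def test_no_condition_repeats_consecutively(self, paradigm):
        for seed in range(10):
            ev = make_paradigm(paradigm, seed=seed)
            seq = list(ev[ev.event_class == "active"].trial_type)
            assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_same_seed_reproduces_table(self, paradigm):
        a = make_paradigm(paradigm, seed=11)
        b = make_paradigm(paradigm, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_session_time_fits_every_preset(self, paradigm, presets):
        ev = make_paradigm(paradigm, seed=2)
        horizon = float((ev.onset + ev.duration).max())
        for p in presets:
            assert horizon <= p.scan_duration_s

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            make_paradigm(ParadigmSpec(blocks_per_condition=0), seed=0)


class TestSimulatePatterns:
    def test_degenerate_zero_model_gives_zero_data(self):
        Y = simulate_patterns(np.zeros((3, 3)), np.eye(3), v=5, sigma2=0.0, seed=0)
        assert np.all(Y == 0)

    def test_second_moment_matches_g_true_at_large_v(self):
        G = scenario_preset("subcortical_protocol_dependent").G_true
        v = 100_000
        Y = simulate_patterns(G, np.eye(9), v=v, sigma2=0.0, seed=42)
        S = Y @ Y.T / v
        # entrywise within 3 Monte-Carlo SEs; var(u_i u_j) = G_ii G_jj + G_ij^2
        se = np.sqrt((np.outer(np.diag(G), np.diag(G)) + G**2) / v)
        assert np.all(np.abs(S - G) < 3.5 * se)

    def test_fixed_seed_bitwise_reproducible(self):
        G = np.eye(4)
        a = simulate_patterns(G, np.eye(4), v=10, sigma2=0.3, seed=9)
        b = simulate_patterns(G, np.eye(4), v=10, sigma2=0.3, seed=9)
        assert np.array_equal(a, b)

    def test_non_psd_covariance_rejected(self):
        G = np.diag([1.0, -0.5])
        with pytest.raises(ValidationError):
            simulate_patterns(G, np.eye(2), v=3, sigma2=0.1, seed=0)


class TestRoiMasks:
    def test_default_grid_ten_disjoint_nonempty_rois(self, rois_default):
        assert len(rois_default.names) == 10
        counts = [rois_default.voxel_count(n) for n in rois_default.names]
        assert all(c >= 27 for c in counts)
        # labels partition: voxel belongs to at most one ROI by construction
        assert rois_default.labels.max() == 10

    def test_hemispheres_mirror_across_midline(self, rois_default):
        labels = rois_default.labels
        nx = labels.shape[0]
        flipped = labels[::-1, :, :]
        for struct in ("M1", "putamen"):
            left = rois_default.mask(f"{struct}_left")
            right = rois_default.mask(f"{struct}_right")
            assert np.array_equal(left[::-1, :, :], right)

    def test_world_midline_symmetry(self, rois_default):
        # mirrored boxes have opposite-sign x centroids in world mm
        from somatoseg.geometry import center_of_mass
        from somatoseg.core import VolumeImage
        aff = rois_default.affine
        l = center_of_mass(VolumeImage(rois_default.mask("SMA_left").astype(np.uint8), aff))
        r = center_of_mass(VolumeImage(rois_default.mask("SMA_right").astype(np.uint8), aff))
        assert l[0] == pytest.approx(-r[0])
        assert l[1:] == pytest.approx(r[1:])

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValidationError):
            make_roi_masks(grid_shape=(10, 10, 10))

    def test_body_part_slabs_partition_roi(self, rois_default):
        roi = "putamen_left"
        total = rois_default.mask(roi)
        slabs = [body_part_slab(rois_default, roi, bp) for bp in ("foot", "hand", "face")]
        assert np.array_equal(np.logical_or.reduce(slabs), total)
        assert sum(s.sum() for s in slabs) == total.sum()
        # foot slab is dorsal (higher z) to face slab
        z_foot = np.where(slabs[0])[2].mean()
        z_face = np.where(slabs[2])[2].mean()
        assert z_foot > z_face

    def test_condition_targets_are_contralateral(self, rois_default):
        m = condition_target_mask(rois_default, "hand_left")
        right_all = np.zeros_like(m)
        for s in ("M1", "SMA", "putamen", "pallidum", "thalamus"):
            right_all |= rois_default.mask(f"{s}_right")
        assert m.sum() > 0
        assert not np.any(m & ~right_all)


class TestScenarioPresets:
    @pytest.mark.parametrize("name", ["cortical_invariant",
                                      "subcortical_protocol_dependent"])
    def test_psd_and_unit_variance(self, name):
        G = scenario_preset(name).G_true
        assert np.linalg.eigvalsh(G).min() >= -1e-10
        assert np.allclose(np.diag(G), 1.0)

    def test_cortical_between_movement_r_constant_across_resolutions(self, cells):
        G = scenario_preset("cortical_invariant").G_true
        rs = {res: [G[i, j] for (i, j) in cells.within_resolution_pairs()
                    if cells.cell(i)[1] == res]
              for res in (1.5, 2.0, 3.0)}
        means = [np.mean(v) for v in rs.values()]
        assert np.ptp(means) < 1e-12

    def test_subcortical_2mm_pairs_more_correlated(self, cells):
        G = scenario_preset("subcortical_protocol_dependent").G_true
        def mean_r(res):
            return np.mean([G[i, j] for (i, j) in cells.within_resolution_pairs()
                            if cells.cell(i)[1] == res])
        assert mean_r(2.0) > mean_r(1.5)
        assert mean_r(2.0) > mean_r(3.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValidationError):
            scenario_preset("nonexistent")


class TestSimulateTimeseries:
    def test_tsnr_recovery_without_task(self, presets, rois_small, paradigm):
        protocol = presets[1]
        truth = GroundTruth(G_true=np.eye(9), amplitudes={},
                            tsnr_target={protocol.name: 20.0}, ar1_phi=0.0)
        ev = make_paradigm(paradigm, seed=0)
        img, _ = simulate_timeseries(protocol, ev, rois_small, truth, seed=4)
        data = img.data.reshape(-1, protocol.n_volumes)
        sel = np.random.default_rng(0).choice(data.shape[0], 600, replace=False)
        tsnr = data[sel].mean(axis=1) / data[sel].std(axis=1, ddof=1)
        assert abs(tsnr.mean() - 20.0) / 20.0 < 0.10

    def test_white_noise_has_no_lag1_autocorrelation(self, presets, rois_small, paradigm):
        protocol = presets[2]
        truth = GroundTruth(G_true=np.eye(9), amplitudes={},
                            tsnr_target={protocol.name: 30.0}, ar1_phi=0.0)
        ev = make_paradigm(paradigm, seed=1)
        img, _ = simulate_timeseries(protocol, ev, rois_small, truth, seed=5)
        x = img.data.reshape(-1, protocol.n_volumes)[:500]
        x = x - x.mean(axis=1, keepdims=True)
        phi = (x[:, 1:] * x[:, :-1]).sum() / (x**2).sum()
        assert abs(phi) < 0.05

    def test_ar1_noise_matches_programmed_phi_and_sd(self, rng):
        x = ar1_noise((4000, 50), phi=0.45, sd=2.0, rng=rng)
        phi_hat = (x[1:] * x[:-1]).sum() / (x**2).sum()
        assert phi_hat == pytest.approx(0.45, abs=0.03)
        assert x.std() == pytest.approx(2.0, rel=0.05)

    def test_noiseless_zero_amplitude_is_constant(self, presets, rois_small, paradigm):
        protocol = presets[0]
        truth = GroundTruth(G_true=np.eye(9), amplitudes={},
                            tsnr_target={protocol.name: np.inf}, ar1_phi=0.0)
        ev = make_paradigm(paradigm, seed=0)
        img, _ = simulate_timeseries(protocol, ev, rois_small, truth, seed=0)
        assert np.ptp(img.data) == 0

    def test_events_beyond_scan_rejected(self, presets, rois_small):
        long_spec = ParadigmSpec(blocks_per_condition=10)
        ev = make_paradigm(long_spec, seed=0)
        truth = GroundTruth(G_true=np.eye(9))
        with pytest.raises(ValidationError):
            simulate_timeseries(presets[0], ev, rois_small, truth, seed=0)

    def test_determinism(self, presets, rois_small, paradigm):
        protocol = presets[0]
        truth = GroundTruth(G_true=np.eye(9))
        ev = make_paradigm(paradigm, seed=0)
        a, ma = simulate_timeseries(protocol, ev, rois_small, truth, seed=8)
        b, mb = simulate_timeseries(protocol, ev, rois_small, truth, seed=8)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ma.params, mb.params)


def test_ground_truth_validation():
    with pytest.raises(ValidationError):
        GroundTruth(G_true=np.eye(9), ar1_phi=1.0)
    with pytest.raises(ValidationError):
        GroundTruth(G_true=np.eye(9), tsnr_target={"1.5mm": -1.0})
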