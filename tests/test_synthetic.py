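import numpy as np
import pytest
import scipy.ndimage
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodist.synthetic import (generate_beta_set, generate_design,
                                 generate_model_features, generate_rts,
                                 generate_volumetric, layer_signal_profile)


class TestDesign:
    @pytest.mark.parametrize(
        "counts,n_scenes,per_super,per_basic",
        [((2, 3, 10), 60, 30, 10), ((1, 1, 1), 1, 1, 1), ((2, 2, 5), 20, 10, 5)],
    )
    def test_nested_counts(self, counts, n_scenes, per_super, per_basic):
        d = generate_design(*counts)
        assert d.n_scenes == n_scenes
        for lvl in d.superordinate_levels:
            assert np.sum(d.superordinate == lvl) == per_super
        for b in d.basic_levels:
            assert np.sum(d.basic_level == b) == per_basic

    def test_scene_ids_contiguous_and_nesting(self):
        d = generate_design(2, 3, 10)
        assert np.array_equal(d.scene_id, np.arange(60))
        # each basic-level label maps to exactly one superordinate
        for b in d.basic_levels:
            assert np.unique(d.superordinate[d.basic_level == b]).size == 1

    @pytest.mark.parametrize("counts", [(0, 3, 10), (2, 0, 10), (2, 3, 0), (-1, 1, 1)])
    def test_nonpositive_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            generate_design(*counts)


class TestBetaSet:
    def test_zero_run_noise_replicates_pattern(self, design_small):
        bs, _ = generate_beta_set(design_small, n_runs=6, n_voxels=10,
                                  run_noise_sd=0.0, seed=0)
        assert np.allclose(bs.values, bs.values[:, :1, :])

    def test_min_runs_enforced(self, design_small):
        with pytest.raises(ValueError, match=">= 5"):
            generate_beta_set(design_small, n_runs=4, n_voxels=10, seed=0)

    def test_seed_determinism(self, design_small):
        a, _ = generate_beta_set(design_small, n_runs=6, n_voxels=12, seed=42)
        b, _ = generate_beta_set(design_small, n_runs=6, n_voxels=12, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_planted_separation_matches_effect(self, design60):
        # closed form: projection of class-mean difference on the boundary
        # axis equals super_effect; run noise averages out over runs/scenes
        seps = []
        for seed in range(30):
            bs, truth = generate_beta_set(design60, n_runs=10, n_voxels=100,
                                          super_effect=1.0, basic_effect=0.0,
                                          exemplar_sd=0.0, run_noise_sd=1.0,
                                          seed=seed)
            signs = np.where(design60.superordinate
                             == design60.superordinate_levels[0], 1.0, -1.0)
            mean_pat = bs.values.mean(axis=1)
            sep = (mean_pat[signs > 0].mean(axis=0)
                   - mean_pat[signs < 0].mean(axis=0)) @ truth.signal_weights
            seps.append(sep)
        # MC error of the mean separation: run noise sd 1, 30*10 averages
        assert abs(np.mean(seps) - 1.0) < 3 * np.std(seps) / np.sqrt(len(seps))
        assert abs(np.mean(seps) - 1.0) < 0.05

    def test_ground_truth_distance_is_projection(self, design_small):
        bs, truth = generate_beta_set(design_small, n_runs=5, n_voxels=20,
                                      run_noise_sd=0.0, seed=3)
        proj = truth.noiseless_pattern @ truth.signal_weights
        assert np.allclose(proj, truth.signed_distance)


class TestRTs:
    def test_noiseless_rts_affine_in_distance(self, design_small):
        _, truth = generate_beta_set(design_small, n_runs=5, n_voxels=10, seed=0,
                                     exemplar_axis_sd=0.3)
        t = generate_rts(truth, design_small, task_sign=-1, rt_noise_sd=0.0,
                         accuracy_rate=1.0, n_subjects=2, subject_sd=0.0, seed=1)
        per_scene = t.groupby("scene_id")["rt"].mean().to_numpy()
        r = np.corrcoef(per_scene, truth.distance)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_slope_decouples_rt(self, design_small):
        _, truth = generate_beta_set(design_small, n_runs=5, n_voxels=10, seed=0,
                                     exemplar_axis_sd=0.3)
        rs = []
        for seed in range(50):
            t = generate_rts(truth, design_small, rt_slope=0.0, n_subjects=2,
                             seed=seed)
            per_scene = t.groupby("scene_id")["rt"].mean().to_numpy()
            rs.append(np.corrcoef(per_scene, truth.distance)[0, 1])
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.02

    def test_correct_trial_rate_binomial(self, design_small):
        _, truth = generate_beta_set(design_small, n_runs=5, n_voxels=10, seed=0)
        counts = []
        for seed in range(30):
            t = generate_rts(truth, design_small, accuracy_rate=0.8,
                             n_trials_per_scene=24, n_subjects=1, seed=seed)
            counts.append(t.groupby("scene_id")["correct"].sum().mean())
        assert np.mean(counts) == pytest.approx(19.2, abs=0.3)

    def test_rts_floored_positive(self, design_small):
        _, truth = generate_beta_set(design_small, n_runs=5, n_voxels=10, seed=0)
        t = generate_rts(truth, design_small, rt_intercept=0.2, rt_noise_sd=1.0,
                         n_subjects=1, seed=0)
        assert (t["rt"] >= 0.15).all()

    def test_preconditions(self, design_small):
        _, truth = generate_beta_set(design_small, n_runs=5, n_voxels=10, seed=0)
        with pytest.raises(ValueError):
            generate_rts(truth, design_small, rt_intercept=0.0)
        with pytest.raises(ValueError):
            generate_rts(truth, design_small, accuracy_rate=0.0)
        with pytest.raises(ValueError):
            generate_rts(truth, design_small, task_sign=2)


class TestModelFeatures:
    def test_profile_unimodal_peak(self):
        p = layer_signal_profile(6, 3)
        assert np.argmax(p) == 2 and p.max() == 1.0
        assert np.all(np.diff(p[:3]) > 0) and np.all(np.diff(p[2:]) < 0)
        assert np.allclose(layer_signal_profile(4, None), 1.0)

    def test_noiseless_features_separable_at_peak(self, design_small):
        from sklearn.svm import SVC
        fs = generate_model_features(design_small, n_layers=4, peak_layer=2,
                                     n_features=20, pool_size=48, noise_sd=0.0,
                                     seed=0)
        levels = fs.pool_design.superordinate_levels
        y = np.where(fs.pool_design.superordinate == levels[0], 1, -1)
        clf = SVC(kernel="linear", C=1.0).fit(fs.pool_features[1], y)
        y_scene = np.where(design_small.superordinate == levels[0], 1, -1)
        assert clf.score(fs.scene_features[1], y_scene) == 1.0

    def test_peak_layer_bounds_checked(self, design_small):
        with pytest.raises(ValueError):
            generate_model_features(design_small, n_layers=4, peak_layer=5)

    def test_scene_signal_length_checked(self, design_small):
        with pytest.raises(ValueError):
            generate_model_features(design_small, scene_signal=np.ones(3))


class TestVolumetric:
    def test_cluster_outside_mask_rejected(self, design_small):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        with pytest.raises(ValueError, match="outside"):
            generate_volumetric(design_small, (6, 6, 6), mask=mask,
                                cluster_spec=[((4, 0, 0), (2, 2, 2))])

    def test_effect_confined_to_planted_cluster(self, design_small):
        vol, truth = generate_volumetric(
            design_small, (6, 6, 6), cluster_spec=[((1, 1, 1), (3, 3, 3))],
            effect_size=2.0, noise_sd=0.0, n_runs=5, seed=0)
        planted = vol.planted_mask[vol.brain_mask]
        outside = vol.betas.values[:, :, ~planted]
        assert np.allclose(outside, 0.0)
        assert np.any(vol.betas.values[:, :, planted] != 0.0)

    def test_two_disjoint_clusters_labelled(self, design_small):
        vol, _ = generate_volumetric(
            design_small, (8, 8, 8),
            cluster_spec=[((0, 0, 0), (2, 2, 2)), ((5, 5, 5), (2, 2, 2))],
            effect_size=1.0, noise_sd=0.0, n_runs=5, seed=0)
        active = np.abs(vol.to_volume(vol.betas.values[0, 0], fill=0.0)) > 0
        _, n = scipy.ndimage.label(active)
        assert n == 2


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_determinism_property(seed):
    d = generate_design(2, 3, 2)
    a, ta = generate_beta_set(d, n_runs=5, n_voxels=6, seed=seed)
    b, tb = generate_beta_set(d, n_runs=5, n_voxels=6, seed=seed)
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(ta.signed_distance, tb.signed_distance)
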