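import numpy as np
import pytest

from neurodist.decoding import (_sample_distractors, decode_basic_level,
                                decode_superordinate, run_roi_decoding,
                                split_and_average)
from neurodist.synthetic import BetaSet, generate_beta_set, generate_design


class TestSplitAndAverage:
    @pytest.mark.parametrize("n_runs,n_train_expected", [(10, 3), (8, 2)])
    def test_pseudo_beta_counts(self, design_small, n_runs, n_train_expected):
        bs, _ = generate_beta_set(design_small, n_runs=n_runs, n_voxels=5, seed=0)
        train_X, train_scene, test_X = split_and_average(
            bs, n_test=4, train_group_size=2, rng=np.random.default_rng(0))
        assert test_X.shape == (design_small.n_scenes, 5)
        assert train_X.shape[0] == design_small.n_scenes * n_train_expected
        counts = np.bincount(train_scene)
        assert np.all(counts == n_train_expected)

    def test_identical_runs_average_to_same_pattern(self, design_small):
        bs, _ = generate_beta_set(design_small, n_runs=6, n_voxels=5,
                                  run_noise_sd=0.0, seed=1)
        train_X, train_scene, test_X = split_and_average(
            bs, rng=np.random.default_rng(0))
        assert np.allclose(test_X, bs.values[:, 0, :])
        assert np.allclose(train_X, bs.values[train_scene, 0, :])

    def test_too_few_runs_errors_with_minimum(self, design_small):
        bs, _ = generate_beta_set(design_small, n_runs=5, n_voxels=5, seed=0)
        with pytest.raises(ValueError, match="at least 6"):
            split_and_average(bs, n_test=4, train_group_size=2)


class TestSuperordinate:
    def test_separable_data_decodes_perfectly(self, separable_betas):
        res = decode_superordinate(separable_betas[0], n_repeats=3, rng=0)
        assert res.accuracy == 1.0

    def test_decision_value_sign_matches_class_side(self):
        # 2-voxel toy: class means at +/-1 on voxel 1, voxel 2 uninformative
        design = generate_design(2, 1, 4)
        signs = np.where(design.superordinate == "man-made", 1.0, -1.0)
        patterns = np.column_stack([signs, np.zeros(8)])
        values = np.repeat(patterns[:, None, :], 6, axis=1)
        values[:, :, 1] += 0.01 * np.random.default_rng(0).standard_normal((8, 6))
        bs = BetaSet(values, design)
        res = decode_superordinate(bs, n_repeats=2, rng=1, standardize=False)
        dv_mean = res.decision_values.mean(axis=1)
        assert np.all(np.sign(dv_mean) == signs)

    def test_accuracy_invariant_to_joint_voxel_permutation(self, separable_betas):
        bs, _ = separable_betas
        perm = np.random.default_rng(3).permutation(bs.n_voxels)
        res_a = decode_superordinate(bs, n_repeats=2, rng=5)
        res_b = decode_superordinate(bs.select_voxels(perm), n_repeats=2, rng=5)
        assert res_a.accuracy == res_b.accuracy
        assert np.allclose(res_a.decision_values, res_b.decision_values)

    def test_unbalanced_design_rejected(self):
        design = generate_design(2, 1, 3)
        sub_scenes = np.arange(5)  # drop one scene: 3 vs 2
        from neurodist.decoding import _subset_design
        bs = BetaSet(np.random.default_rng(0).standard_normal((5, 6, 4)),
                     _subset_design(design, sub_scenes))
        with pytest.raises(ValueError, match="equal scene counts"):
            decode_superordinate(bs, n_repeats=1, rng=0)


class TestBasicLevel:
    def test_separable_data_decodes_every_target(self, separable_betas):
        bs, _ = separable_betas
        for tgt in bs.design.basic_levels:
            res = decode_basic_level(bs, tgt, n_repeats=2, rng=0)
            assert res.accuracy == 1.0

    def test_distractor_sampling_balances_train_set(self, design60):
        rng = np.random.default_rng(0)
        tgt = design60.basic_levels[0]
        d = _sample_distractors(design60, tgt, 10, rng)
        assert d.size == 10
        picked = design60.basic_level[d]
        sup = design60.superordinate_of_basic(tgt)
        assert all(design60.superordinate_of_basic(b) == sup for b in picked)
        _, counts = np.unique(picked, return_counts=True)
        assert np.array_equal(np.sort(counts), [5, 5])

    def test_single_distractor_category_rejected(self):
        design = generate_design(2, 2, 4)
        bs = BetaSet(np.random.default_rng(0).standard_normal((16, 6, 5)), design)
        with pytest.raises(ValueError, match="distractor"):
            decode_basic_level(bs, design.basic_levels[0], n_repeats=1, rng=0)

    def test_target_scenes_recorded_for_distance_extraction(self, separable_betas):
        bs, _ = separable_betas
        tgt = bs.design.basic_levels[2]
        res = decode_basic_level(bs, tgt, n_repeats=2, rng=0)
        expected = np.flatnonzero(bs.design.basic_level == tgt)
        assert np.array_equal(res.extras["target_scenes"], expected)
        assert not np.any(np.isnan(res.decision_values[expected]))


class TestRunROIDecoding:
    def test_identical_data_identical_results_across_rois(self, separable_betas):
        bs, _ = separable_betas
        rois = {"roi": np.ones(bs.n_voxels, dtype=bool)}
        t1 = run_roi_decoding({0: bs}, rois, ("superordinate",), n_repeats=2,
                              master_seed=9)
        t2 = run_roi_decoding({0: bs}, rois, ("superordinate",), n_repeats=2,
                              master_seed=9)
        assert t1.iloc[0]["accuracy"] == t2.iloc[0]["accuracy"]
        assert np.array_equal(t1.iloc[0]["result"].decision_values,
                              t2.iloc[0]["result"].decision_values)

    def test_empty_roi_flagged_missing(self, separable_betas):
        bs, _ = separable_betas
        rois = {"empty": np.zeros(bs.n_voxels, dtype=bool)}
        t = run_roi_decoding({0: bs}, rois, ("superordinate", "basic"),
                             n_repeats=1)
        assert t["missing"].all()
        assert t["accuracy"].isna().all()

    def test_basic_scheme_averages_over_targets(self, separable_betas):
        bs, _ = separable_betas
        rois = {"all": np.ones(bs.n_voxels, dtype=bool)}
        t = run_roi_decoding({0: bs}, rois, ("basic",), n_repeats=1, master_seed=0)
        per_target = t.iloc[0]["result"]
        assert len(per_target) == 6
        assert t.iloc[0]["accuracy"] == pytest.approx(
            np.mean([r.accuracy for r in per_target.values()]))


def test_accuracy_monotone_in_effect_size(design_small):
    """Stronger planted category signal must not reduce expected accuracy."""
    means = []
    for effect in (0.0, 0.8, 2.5):
        accs = []
        for seed in range(15):
            bs, _ = generate_beta_set(design_small, n_runs=8, n_voxels=24,
                                      super_effect=effect, basic_effect=0.0,
                                      exemplar_sd=0.1, run_noise_sd=1.0,
                                      seed=seed)
            accs.append(decode_superordinate(bs, n_repeats=2, rng=seed).accuracy)
        means.append(np.mean(accs))
    assert means[0] < means[1] < means[2]
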