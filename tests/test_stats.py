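import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodist.stats import (bootstrap_peak_ci, cluster_correct, fdr_correct,
                             overlap_percent, sign_permutation_test)


def exact_sign_flip_p(values, tail):
    """Independent oracle: enumerate every sign pattern with itertools."""
    values = np.asarray(values, dtype=float)
    obs = values.mean()
    stats = [np.mean(np.array(s) * values)
             for s in itertools.product([1, -1], repeat=values.size)]
    if tail == "right":
        hits = sum(x >= obs - 1e-12 for x in stats)
    elif tail == "left":
        hits = sum(x <= obs + 1e-12 for x in stats)
    else:
        hits = sum(abs(x) >= abs(obs) - 1e-12 for x in stats)
    return hits / len(stats)


class TestSignPermutation:
    def test_all_positive_triple_exact_eighth(self):
        r = sign_permutation_test(np.array([1.0, 1.0, 1.0]), 0.0, 1000, "right")
        assert r.p == 0.125 and r.exact

    def test_degenerate_all_zero(self):
        r = sign_permutation_test(np.zeros(5), 0.0, 100, "right")
        assert r.p == 1.0

    @pytest.mark.parametrize("tail", ["right", "left", "two-sided"])
    def test_exact_branch_matches_enumeration_oracle(self, tail):
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.standard_normal(7)
            r = sign_permutation_test(v, 0.0, 10_000, tail)
            assert r.exact
            assert r.p == pytest.approx(exact_sign_flip_p(v, tail), abs=1e-12)

    def test_sampled_branch_agrees_with_exact_within_mc_error(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(9) + 0.4
        n_perm = 400  # < 2^9, forces sampling
        exact = exact_sign_flip_p(v, "right")
        r = sign_permutation_test(v, 0.0, n_perm, "right", rng=2)
        assert not r.exact
        tol = 3 * np.sqrt(exact * (1 - exact) / n_perm) + 1 / n_perm
        assert abs(r.p - exact) < tol

    def test_chance_level_centering(self):
        acc = np.array([0.6, 0.7, 0.65, 0.72])
        r = sign_permutation_test(acc, 0.5, 1000, "right")
        assert r.observed == pytest.approx(acc.mean() - 0.5)
        assert r.p == pytest.approx(1 / 16)


class TestFDR:
    def bh_oracle(self, p, q):
        """Brute force: largest rejection count k with p_(k) <= kq/m."""
        p = np.asarray(p)
        m = p.size
        order = np.argsort(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        mask = np.zeros(m, dtype=bool)
        mask[order[:k_star]] = True
        return mask

    def test_spec_examples(self):
        assert fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), 0.05).all()
        assert not fdr_correct(np.ones(6), 0.05).any()
        assert fdr_correct(np.array([0.04]), 0.05).all()

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = rng.integers(1, 12)
            p = rng.random(m) ** 2
            assert np.array_equal(fdr_correct(p, 0.05), self.bh_oracle(p, 0.05))

    def test_empty_input(self):
        assert fdr_correct(np.array([]), 0.05).size == 0


class TestClusterCorrection:
    def test_adjacency_rule_splits_diagonal_components(self):
        # two suprathreshold blobs touching only at a corner; 16 subjects so
        # no sampled sign pattern duplicates the identity (2^16 >> n_perm)
        maps = np.zeros((16, 6, 6, 6))
        maps[:, 1:3, 1:3, 1:3] = 5.0
        maps[:, 3:5, 3:5, 3:5] = 5.0
        maps += 0.01 * np.random.default_rng(0).standard_normal(maps.shape)
        r6 = cluster_correct(maps, 0.0, 0.02, 0.05, 200, adjacency=6, rng=1)
        r26 = cluster_correct(maps, 0.0, 0.02, 0.05, 200, adjacency=26, rng=1)
        # noise voxels may add spurious singletons at this lenient threshold;
        # the blobs themselves must split by faces and merge by corners
        assert (r6.sizes >= 8).sum() == 2
        assert (r26.sizes >= 8).sum() == 1 and r26.sizes.max() >= 16

    def test_no_suprathreshold_voxels_is_valid_empty(self):
        maps = 0.1 * np.random.default_rng(2).standard_normal((6, 5, 5, 5))
        r = cluster_correct(maps, 0.0, 0.001, 0.05, 200, rng=0)
        assert r.sizes.size == 0 and not r.significant_mask.any()

    def test_planted_cluster_recovered(self):
        rng = np.random.default_rng(4)
        maps = 0.2 * rng.standard_normal((10, 10, 10, 10))
        maps[:, 3:6, 3:6, 3:6] += 2.0
        r = cluster_correct(maps, 0.0, 0.01, 0.05, 300, rng=5)
        planted = np.zeros((10, 10, 10), dtype=bool)
        planted[3:6, 3:6, 3:6] = True
        assert (r.significant_mask & planted).sum() > 0

    def test_axis_relabeling_invariance(self):
        # only adjacency matters, not the voxel ordering of the grid
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((8, 5, 6, 7))
        maps[:, 1:3, 2:4, 2:4] += 2.0
        a = cluster_correct(maps, 0.0, 0.02, 0.05, 200, rng=7)
        b = cluster_correct(maps.transpose(0, 3, 2, 1), 0.0, 0.02, 0.05, 200, rng=7)
        assert np.array_equal(np.sort(a.sizes), np.sort(b.sizes))
        assert np.array_equal(np.sort(a.p_values), np.sort(b.p_values))

    def test_two_sided_unions_tails(self):
        rng = np.random.default_rng(8)
        maps = 0.2 * rng.standard_normal((16, 8, 8, 8))
        maps[:, 1:3, 1:3, 1:3] += 2.0
        maps[:, 5:7, 5:7, 5:7] -= 2.0
        r = cluster_correct(maps, 0.0, 0.01, 0.05, 300, rng=9, tail="two-sided")
        assert r.significant_mask[2, 2, 2] and r.significant_mask[5, 5, 5]


class TestBootstrapPeak:
    def test_sharp_peak_degenerate_ci(self):
        v = np.zeros((6, 6))
        v[:, 3] = 1.0  # every subject peaks at layer 4 (1-based)
        assert bootstrap_peak_ci(v, 1000, rng=0) == (4, 4)

    def test_tied_layers_with_noise_cover_both(self):
        rng = np.random.default_rng(1)
        v = np.zeros((12, 5))
        v[:, 1] = 1.0 + 0.3 * rng.standard_normal(12)
        v[:, 2] = 1.0 + 0.3 * rng.standard_normal(12)
        lo, hi = bootstrap_peak_ci(v, 2000, rng=2)
        assert lo <= 2 and hi >= 3


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4), dtype=bool)
        a[:2] = True
        assert overlap_percent(a, a) == (100.0, 100.0)
        assert overlap_percent(a, ~a) == (0.0, 0.0)

    def test_asymmetric_percentages(self):
        a = np.zeros(200, dtype=bool); a[:100] = True
        b = np.zeros(200, dtype=bool); b[90:140] = True
        assert overlap_percent(a, b) == (10.0, 20.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_percent(np.zeros(3, dtype=bool), np.zeros(4, dtype=bool))


@given(st.lists(st.floats(-3, 3), min_size=2, max_size=8))
@settings(max_examples=30, deadline=None)
def test_permutation_p_valid_and_exact_matches_oracle(values):
    v = np.array(values)
    r = sign_permutation_test(v, 0.0, 10_000, "two-sided")
    assert 0 < r.p <= 1
    if r.exact and not np.all(np.abs(v) <= 1e-12):
        assert r.p == pytest.approx(exact_sign_flip_p(v, "two-sided"), abs=1e-9)
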