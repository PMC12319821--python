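"""Calibration and recovery studies on synthetic data.

Each routine simulates a family of datasets under known conditions, runs the
corresponding pipeline stage, and reports a summary quantity: type-I error of
the sign-permutation test under a symmetric null, family-wise error of the
cluster-extent correction under a null volume, chance-level behavior and
effect-size monotonicity of the decoders, noiseless distance-RT recovery,
commonality-identity checks, planted peak-layer recovery, and the joint
reliability ceiling.  Problem sizes are parameters; the defaults are the
reduced scales these checks are routinely run at.
"""

from __future__ import annotations

import numpy as np

from ._rng import derive_seed, substream
from .behavior import (aggregate_rts, correlate_distance_rt, extract_distances,
                       joint_reliability, rt_split_half, split_half_distances)
from .commonality import commonality, layer_profile, model_distances
from .decoding import decode_basic_level, decode_superordinate
from .stats import bootstrap_peak_ci, cluster_correct, sign_permutation_test
from .synthetic import (generate_beta_set, generate_design,
                        generate_model_features, generate_rts)

__all__ = [
    "type1_calibration",
    "fwer_calibration",
    "decoding_null_accuracy",
    "decoding_separable_accuracy",
    "decoding_effect_monotonicity",
    "distance_rt_noiseless",
    "distance_rt_null",
    "independent_predictor_commonality",
    "peak_layer_recovery",
    "peak_ci_coverage",
    "reliability_ceiling_margin",
]


def type1_calibration(n_datasets: int = 1000, n_subjects: int = 20,
                      n_perm: int = 500, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Rejection rate of the one-sided sign-permutation test under a
    symmetric null (standard-normal subject values)."""
    rng = substream(seed, "type1")
    rejections = 0
    for _ in range(n_datasets):
        v = rng.standard_normal(n_subjects)
        r = sign_permutation_test(v, 0.0, n_perm, "right", rng)
        rejections += r.p <= alpha
    return rejections / n_datasets


def fwer_calibration(n_datasets: int = 500, grid: int = 12,
                     n_subjects: int = 10, n_perm: int = 200,
                     voxel_p: float = 0.01, cluster_alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Family-wise error of the cluster-extent correction on null volumes:
    fraction of simulated group datasets with >= 1 significant cluster."""
    rng = substream(seed, "fwer")
    families = 0
    shape = (n_subjects, grid, grid, grid)
    for _ in range(n_datasets):
        maps = rng.standard_normal(shape)
        res = cluster_correct(maps, 0.0, voxel_p, cluster_alpha, n_perm,
                              rng=rng)
        families += res.significant_mask.any()
    return families / n_datasets


def _null_betas(design, seed):
    return generate_beta_set(design, n_runs=8, n_voxels=24, super_effect=0.0,
                             basic_effect=0.0, exemplar_sd=0.0,
                             run_noise_sd=1.0, seed=seed)[0]


def decoding_null_accuracy(n_seeds: int = 100, n_repeats: int = 3,
                           seed: int = 0) -> dict:
    """Mean superordinate and basic-level accuracy on signal-free data,
    with standard errors over simulated datasets."""
    design = generate_design(2, 3, 4)
    sup, bas = [], []
    for i in range(n_seeds):
        bs = _null_betas(design, derive_seed(seed, "null", i))
        rng = substream(seed, "null_decode", i)
        sup.append(decode_superordinate(bs, n_repeats, rng).accuracy)
        bas.append(np.mean([
            decode_basic_level(bs, t, n_repeats, rng).accuracy
            for t in design.basic_levels
        ]))
    return {
        "super_mean": float(np.mean(sup)),
        "super_se": float(np.std(sup, ddof=1) / np.sqrt(n_seeds)),
        "basic_mean": float(np.mean(bas)),
        "basic_se": float(np.std(bas, ddof=1) / np.sqrt(n_seeds)),
    }


def decoding_separable_accuracy(seed: int = 0) -> dict:
    """Accuracy on strongly separable noiseless data (both schemes)."""
    design = generate_design(2, 3, 4)
    bs, _ = generate_beta_set(design, n_runs=8, n_voxels=30, super_effect=4.0,
                              basic_effect=2.0, exemplar_sd=0.05,
                              exemplar_axis_sd=0.2, run_noise_sd=0.0,
                              seed=derive_seed(seed, "sep"))
    rng = substream(seed, "sep_decode")
    sup = decode_superordinate(bs, 3, rng).accuracy
    bas = float(np.mean([decode_basic_level(bs, t, 3, rng).accuracy
                         for t in design.basic_levels]))
    return {"super": sup, "basic": bas}


def decoding_effect_monotonicity(effects=(0.0, 0.8, 2.5), n_seeds: int = 30,
                                 seed: int = 0) -> list[float]:
    """Mean superordinate accuracy across a grid of planted effect sizes."""
    design = generate_design(2, 3, 4)
    means = []
    for effect in effects:
        accs = []
        for i in range(n_seeds):
            bs, _ = generate_beta_set(
                design, n_runs=8, n_voxels=24, super_effect=effect,
                basic_effect=0.0, exemplar_sd=0.1, run_noise_sd=1.0,
                seed=derive_seed(seed, "mono", round(effect * 1000), i))
            accs.append(decode_superordinate(
                bs, 2, substream(seed, "mono_decode", round(effect * 1000), i)
            ).accuracy)
        means.append(float(np.mean(accs)))
    return means


def _noiseless_setup(seed, task_sign):
    design = generate_design(2, 3, 10)
    bs, truth = generate_beta_set(design, n_runs=10, n_voxels=50,
                                  super_effect=2.0, basic_effect=0.0,
                                  exemplar_sd=0.0, exemplar_axis_sd=0.3,
                                  run_noise_sd=0.0,
                                  seed=derive_seed(seed, "nl"))
    rt = generate_rts(truth, design, task_sign=task_sign, rt_noise_sd=0.0,
                      accuracy_rate=1.0, n_subjects=2, subject_sd=0.0,
                      seed=derive_seed(seed, "nl_rt"))
    return design, bs, truth, rt


def distance_rt_noiseless(task_sign: int, n_seeds: int = 10,
                          seed: int = 0) -> float:
    """Group-mean distance-RT correlation in the vanishing-noise limit."""
    rs = []
    for i in range(n_seeds):
        _, bs, _, rt = _noiseless_setup(derive_seed(seed, "nlseed", i),
                                        task_sign)
        res = decode_superordinate(bs, 2, substream(seed, "nl_decode", i))
        d = extract_distances(res)
        y = aggregate_rts(rt, "categorization").to_numpy()
        rs.append(correlate_distance_rt(d, y).r)
    return float(np.mean(rs))


def distance_rt_null(n_seeds: int = 100, seed: int = 0) -> float:
    """Mean distance-RT correlation when RTs are decoupled (slope 0)."""
    design = generate_design(2, 3, 5)
    rs = []
    for i in range(n_seeds):
        bs, truth = generate_beta_set(
            design, n_runs=8, n_voxels=30, super_effect=1.5, basic_effect=0.0,
            exemplar_sd=0.2, exemplar_axis_sd=0.3, run_noise_sd=1.0,
            seed=derive_seed(seed, "null_rt", i))
        rt = generate_rts(truth, design, rt_slope=0.0, n_subjects=4,
                          seed=derive_seed(seed, "null_rt_t", i))
        d = extract_distances(
            decode_superordinate(bs, 2, substream(seed, "null_rt_d", i)))
        y = aggregate_rts(rt, "categorization").to_numpy()
        rs.append(correlate_distance_rt(d, y).r)
    return float(np.mean(rs))


def independent_predictor_commonality(n: int = 10_000, seed: int = 0) -> float:
    """Commonality when B is independent of y and A (population value 0)."""
    rng = substream(seed, "indep")
    a = rng.standard_normal(n)
    y = a + rng.standard_normal(n)
    b = rng.standard_normal(n)
    return commonality(y, a, b).C_AB


def _peak_recovery_dataset(seed, n_subjects=6, n_layers=6, peak_layer=3,
                           n_repeats=5):
    design = generate_design(2, 3, 10)
    beta_sets, truth = [], None
    for subj in range(n_subjects):
        bs, truth = generate_beta_set(
            design, n_runs=8, n_voxels=60, super_effect=1.5, basic_effect=0.0,
            exemplar_sd=0.2, exemplar_axis_sd=0.4, run_noise_sd=1.0,
            seed=derive_seed(seed, "pr_truth"),
            noise_seed=derive_seed(seed, "pr_noise", subj))
        beta_sets.append(bs)
    feats = generate_model_features(
        design, n_layers, peak_layer, n_features=80, pool_size=120,
        noise_sd=0.3, seed=derive_seed(seed, "pr_feat"),
        scene_signal=truth.signed_distance)
    md = model_distances(feats, "superordinate", n_components=50,
                         master_seed=derive_seed(seed, "pr_md"))
    rt = generate_rts(truth, design, task_sign=-1, rt_noise_sd=0.1,
                      n_subjects=8, seed=derive_seed(seed, "pr_rt"))
    y = aggregate_rts(rt, "categorization").to_numpy()
    cmat = np.zeros((n_subjects, n_layers))
    for i, bs in enumerate(beta_sets):
        a = extract_distances(decode_superordinate(
            bs, n_repeats, substream(seed, "pr_decode", i)))
        for layer in range(n_layers):
            cmat[i, layer] = commonality(y, a, md[layer]).C_AB
    return cmat


def peak_layer_recovery(n_seeds: int = 50, peak_layer: int = 3,
                        seed: int = 0) -> float:
    """Fraction of simulated studies whose group commonality profile peaks
    at the planted layer."""
    hits = 0
    for i in range(n_seeds):
        cmat = _peak_recovery_dataset(derive_seed(seed, "pr", i),
                                      peak_layer=peak_layer)
        peak, _, _ = layer_profile(cmat)
        hits += peak == peak_layer
    return hits / n_seeds


def peak_ci_coverage(n_seeds: int = 100, n_boot: int = 1000,
                     true_peak: int = 3, seed: int = 0) -> float:
    """Coverage of the bootstrap peak-layer CI on noisy unimodal subject
    curves with a known peak."""
    layers = np.arange(1, 7)
    base = np.exp(-((layers - true_peak) ** 2) / 2.0)
    covered = 0
    for i in range(n_seeds):
        rng = substream(seed, "cov", i)
        curves = base[None, :] + 0.25 * rng.standard_normal((10, 6))
        lo, hi = bootstrap_peak_ci(curves, n_boot, rng)
        covered += lo <= true_peak <= hi
    return covered / n_seeds


def reliability_ceiling_margin(n_seeds: int = 100, seed: int = 0) -> dict:
    """Mean joint reliability and mean |distance-RT r| over noisy synthetic
    studies; the ceiling property requires the former to exceed the latter
    in expectation."""
    design = generate_design(2, 3, 5)
    joints, rabs = [], []
    for i in range(n_seeds):
        bs, truth = generate_beta_set(
            design, n_runs=8, n_voxels=30, super_effect=1.5, basic_effect=0.0,
            exemplar_sd=0.2, exemplar_axis_sd=0.4, run_noise_sd=1.2,
            seed=derive_seed(seed, "rel", i))
        rt = generate_rts(truth, design, task_sign=-1, rt_noise_sd=0.2,
                          n_subjects=8, seed=derive_seed(seed, "rel_rt", i))
        d = extract_distances(
            decode_superordinate(bs, 3, substream(seed, "rel_d", i)))
        y = aggregate_rts(rt, "categorization").to_numpy()
        r = correlate_distance_rt(d, y).r
        d1, d2 = split_half_distances(bs, "superordinate", n_repeats=3,
                                      rng=substream(seed, "rel_sh", i))
        r_half_rt = rt_split_half(rt, "categorization", n_splits=20,
                                  rng=substream(seed, "rel_rts", i))
        joint = joint_reliability((d1, d2), r_half_rt)
        if joint is None:
            continue
        joints.append(abs(joint))
        rabs.append(abs(r))
    return {"mean_joint": float(np.mean(joints)),
            "mean_abs_r": float(np.mean(rabs)),
            "n_defined": len(joints)}
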