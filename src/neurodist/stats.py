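"""Group-level nonparametric inference.

Sign-permutation tests on chance-centered subject statistics, Benjamini-
Hochberg FDR over small families, cluster-extent correction against a
maximum-cluster-size permutation null for whole-volume maps, bootstrap
confidence intervals for the peak layer of a commonality profile, and
significance-map overlap percentages.

Conventions: p-values include the identity permutation (the +1/+1 rule), so
sampled p >= 1/(1+n_perm) and p is never 0.  When 2^n_subjects <= n_perm the
full sign-flip set is enumerated and the p-value is exact.  Cluster adjacency
defaults to 6-connectivity (faces); 18 and 26 are available.  Two-sided
cluster inference runs the positive and negative tails as separate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationTestResult",
    "ClusterResult",
    "sign_permutation_test",
    "fdr_correct",
    "cluster_correct",
    "bootstrap_peak_ci",
    "overlap_percent",
]

_TIE_EPS = 1e-12


@dataclass
class PermutationTestResult:
    observed: float
    p: float
    n_permutations: int
    tail: str
    exact: bool


@dataclass
class ClusterResult:
    labels: np.ndarray                   # cluster id per voxel (0 = background)
    sizes: np.ndarray                    # size per cluster (1-based ids)
    p_values: np.ndarray                 # cluster p per cluster
    significant_mask: np.ndarray         # boolean grid of significant clusters
    voxel_p: np.ndarray | None = None    # voxelwise permutation p-map
    tail: str = "right"
    extras: dict = field(default_factory=dict)


def _all_sign_patterns(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.int64)
    return 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)


def sign_permutation_test(
    subject_values: np.ndarray,
    chance_level: float = 0.0,
    n_perm: int = 10_000,
    tail: str = "right",
    rng: np.random.Generator | int | None = None,
) -> PermutationTestResult:
    """Group sign-permutation test of the mean against ``chance_level``.

    Values are centered by the chance level, each subject's sign is flipped
    at random, and the observed group mean is ranked in the permutation
    distribution of group means.  ``tail``: "right", "left" or "two-sided".
    """
    v = np.asarray(subject_values, dtype=float) - chance_level
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if tail not in ("right", "left", "two-sided"):
        raise ValueError(f"unknown tail: {tail!r}")
    obs = float(v.mean())
    if np.all(np.abs(v) <= _TIE_EPS):
        return PermutationTestResult(obs, 1.0, n_perm, tail, exact=True)

    if 2**n <= n_perm:
        signs = _all_sign_patterns(n)
        perm = signs @ v / n
        if tail == "right":
            count = np.sum(perm >= obs - _TIE_EPS)
        elif tail == "left":
            count = np.sum(perm <= obs + _TIE_EPS)
        else:
            count = np.sum(np.abs(perm) >= abs(obs) - _TIE_EPS)
        return PermutationTestResult(obs, float(count / 2**n), 2**n, tail, exact=True)

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = signs @ v / n
    if tail == "right":
        count = np.sum(perm >= obs - _TIE_EPS)
    elif tail == "left":
        count = np.sum(perm <= obs + _TIE_EPS)
    else:
        count = np.sum(np.abs(perm) >= abs(obs) - _TIE_EPS)
    p = (1.0 + count) / (1.0 + n_perm)
    return PermutationTestResult(obs, float(p), n_perm, tail, exact=False)


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up (independence variant); returns a boolean
    rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


_STRUCTURES = {
    6: scipy.ndimage.generate_binary_structure(3, 1),
    18: scipy.ndimage.generate_binary_structure(3, 2),
    26: scipy.ndimage.generate_binary_structure(3, 3),
}


def _perm_p_maps(perm_means: np.ndarray) -> np.ndarray:
    """Right-tail permutation p of every permutation's map against the full
    permutation distribution, per voxel: p[j, v] = #{means >= means[j, v]}/P."""
    n_perm = perm_means.shape[0]
    ranks = scipy.stats.rankdata(-perm_means, method="max", axis=0)
    return ranks / n_perm


def cluster_correct(
    subject_stat_maps: np.ndarray,
    chance_level: float = 0.0,
    voxel_p_threshold: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 10_000,
    adjacency: int = 6,
    rng: np.random.Generator | int | None = None,
    tail: str = "right",
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-extent correction of a group map by sign permutation.

    ``subject_stat_maps`` is (n_subjects, nx, ny, nz).  Per permutation the
    same sign flip is applied to a subject's whole map, preserving spatial
    structure.  Voxelwise permutation p-maps are thresholded at
    ``voxel_p_threshold``; suprathreshold voxels are clustered by spatial
    adjacency; each observed cluster's p is the rank of its size in the
    maximum-cluster-size null (identity permutation included); clusters with
    p < ``cluster_alpha`` are significant.

    ``tail="left"`` tests for statistics below chance; "two-sided" runs both
    tails separately and unions the significant masks.
    """
    maps = np.asarray(subject_stat_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("subject_stat_maps must be (n_subjects, nx, ny, nz)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if adjacency not in _STRUCTURES:
        raise ValueError("adjacency must be 6, 18 or 26")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    if tail == "two-sided":
        pos = cluster_correct(maps, chance_level, voxel_p_threshold, cluster_alpha,
                              n_perm, adjacency, rng, "right", mask)
        neg = cluster_correct(maps, chance_level, voxel_p_threshold, cluster_alpha,
                              n_perm, adjacency, rng, "left", mask)
        return ClusterResult(
            labels=pos.labels, sizes=pos.sizes, p_values=pos.p_values,
            significant_mask=pos.significant_mask | neg.significant_mask,
            voxel_p=pos.voxel_p, tail="two-sided",
            extras={"positive": pos, "negative": neg},
        )

    grid = maps.shape[1:]
    n_subj = maps.shape[0]
    centered = maps - chance_level
    if tail == "left":
        centered = -centered
    flat = centered.reshape(n_subj, -1)
    if mask is not None:
        flat = flat * np.asarray(mask, dtype=float).reshape(1, -1)

    signs = np.vstack([np.ones((1, n_subj)),
                       rng.choice([-1.0, 1.0], size=(n_perm - 1, n_subj))])
    perm_means = signs @ flat / n_subj          # (n_perm, n_voxels); row 0 = observed
    p_maps = _perm_p_maps(perm_means)
    supra = p_maps < voxel_p_threshold
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool).reshape(1, -1)

    structure = _STRUCTURES[adjacency]
    max_sizes = np.zeros(n_perm)
    for j in range(n_perm):
        if supra[j].any():
            lab, n_lab = scipy.ndimage.label(supra[j].reshape(grid), structure=structure)
            if n_lab:
                max_sizes[j] = np.bincount(lab.ravel())[1:].max()

    labels, n_clusters = scipy.ndimage.label(supra[0].reshape(grid), structure=structure)
    sizes = (np.bincount(labels.ravel())[1:] if n_clusters
             else np.zeros(0, dtype=int))
    cluster_p = np.array([np.mean(max_sizes >= s) for s in sizes])
    sig_ids = np.flatnonzero(cluster_p < cluster_alpha) + 1
    sig_mask = np.isin(labels, sig_ids)
    return ClusterResult(
        labels=labels, sizes=sizes, p_values=cluster_p,
        significant_mask=sig_mask, voxel_p=p_maps[0].reshape(grid), tail=tail,
        extras={"max_size_null": max_sizes},
    )


def bootstrap_peak_ci(
    subject_by_layer_values: np.ndarray,
    n_boot: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, int]:
    """Bootstrap 95% CI for the peak-layer index (1-based).

    Subjects are resampled with replacement; per sample, the layer with the
    maximal subject-mean value is found (ties -> lowest index); the CI is the
    2.5/97.5 percentile pair of the peak-index distribution, taken outward
    (lower percentile floored, upper ceiled) so the bounds are layer indices.
    """
    v = np.asarray(subject_by_layer_values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need (n_subjects >= 2, n_layers >= 2) values")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_subj = v.shape[0]
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    peaks = np.empty(n_boot, dtype=int)
    chunk = 2000  # bound peak memory at n_boot = 100,000
    for start in range(0, n_boot, chunk):
        sel = v[idx[start:start + chunk]]          # (chunk, n_subj, n_layers)
        peaks[start:start + chunk] = np.argmax(sel.mean(axis=1), axis=1) + 1
    lo = int(np.floor(np.percentile(peaks, 2.5)))
    hi = int(np.ceil(np.percentile(peaks, 97.5)))
    return lo, hi


def overlap_percent(
    sig_mask_a: np.ndarray, sig_mask_b: np.ndarray
) -> tuple[float, float]:
    """Overlap of two significance maps in percent of each map's voxels.

    Returns (100*|A∩B|/|A|, 100*|A∩B|/|B|); a term is 0 when its
    denominator set is empty.
    """
    a = np.asarray(sig_mask_a, dtype=bool)
    b = np.asarray(sig_mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    inter = np.count_nonzero(a & b)
    na, nb = np.count_nonzero(a), np.count_nonzero(b)
    return (100.0 * inter / na if na else 0.0,
            100.0 * inter / nb if nb else 0.0)
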