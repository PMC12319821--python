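"""Model-derived distances and commonality analysis.

Layered model feature matrices (e.g. deep-network activations, or the
synthetic stand-ins) are reduced by PCA fitted on a training image pool and
applied unchanged to the experimental scenes.  Per layer, a linear SVM is
trained on the reduced pool features (man-made/natural or basic-level
one-vs-rest) and the experimental scenes' absolute decision values are the
model distances.

Commonality analysis then partitions the variance of per-scene mean RTs (y)
shared with neural distances (A) and model distances (B):

    C(AB) = R2_y.A + R2_y.B - R2_y.AB

with each R2 from an OLS regression of y on A, B, or both (with intercept,
unadjusted).  R2_y.A serves as the upper limit on the commonality.  Negative
commonalities (suppression) are reported, not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from ._rng import substream
from .synthetic import ModelFeatureSet, StimulusDesign

__all__ = [
    "ReducedFeatures",
    "CommonalityResult",
    "reduce_features",
    "model_distances",
    "commonality",
    "layer_profile",
]


@dataclass
class ReducedFeatures:
    pool: np.ndarray          # (pool_size, n_components)
    scenes: np.ndarray        # (n_scenes, n_components)
    n_components: int
    mean: np.ndarray          # pool centering applied to both matrices
    components: np.ndarray | None  # None when the layer passed through unreduced


@dataclass
class CommonalityResult:
    R2_yA: float
    R2_yB: float
    R2_yAB: float
    C_AB: float
    upper_limit: float        # = R2_yA
    layer: int | None = None
    region: str | None = None
    subject: int | str | None = None
    network: str | None = None


def reduce_features(
    pool_matrix: np.ndarray,
    scene_matrix: np.ndarray,
    n_components: int = 1000,
) -> ReducedFeatures:
    """PCA fitted on the centered pool, applied to pool and scenes alike.

    If the feature dimensionality is already <= ``n_components`` the matrices
    pass through unchanged (beyond nothing: no centering either, matching the
    pass-through convention for low-dimensional layers).  If ``n_components``
    exceeds the achievable rank it is clipped with a warning.
    """
    pool = np.asarray(pool_matrix, dtype=float)
    scenes = np.asarray(scene_matrix, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if pool.shape[0] < 2:
        raise ValueError("pool needs at least 2 images")
    if pool.shape[1] != scenes.shape[1]:
        raise ValueError("pool and scene matrices must share feature dimensionality")

    if pool.shape[1] <= n_components:
        return ReducedFeatures(pool, scenes, pool.shape[1],
                               mean=np.zeros(pool.shape[1]), components=None)

    max_rank = min(pool.shape[0] - 1, pool.shape[1])
    k = n_components
    if k > max_rank:
        warnings.warn(f"n_components={k} exceeds achievable rank {max_rank}; clipped")
        k = max_rank
    pca = PCA(n_components=k, svd_solver="full")
    red_pool = pca.fit_transform(pool)
    red_scenes = pca.transform(scenes)
    return ReducedFeatures(red_pool, red_scenes, k, mean=pca.mean_,
                           components=pca.components_)


def _svm_distances(train_X, train_y, test_X, C: float = 1.0) -> np.ndarray:
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_X, train_y)
    return clf.decision_function(test_X)


def model_distances(
    feature_set: ModelFeatureSet,
    scheme: str = "superordinate",
    n_components: int = 1000,
    n_repeats: int = 100,
    master_seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Per-layer model distance vectors, (n_layers, n_scenes).

    Superordinate: one classifier per layer trained on the whole pool.
    Basic-level: per target category, train on all pool images of the target
    vs half of the randomly sampled images from each distractor category of
    the same superordinate; repeat the distractor sampling ``n_repeats``
    times and average the absolute decision values; concatenate the target
    scenes' distances across the category classifiers.
    """
    design = feature_set.design
    pool_design = feature_set.pool_design
    out = np.zeros((feature_set.n_layers, design.n_scenes))

    for layer in range(feature_set.n_layers):
        red = reduce_features(feature_set.pool_features[layer],
                              feature_set.scene_features[layer], n_components)
        if scheme == "superordinate":
            levels = pool_design.superordinate_levels
            if len(levels) != 2:
                raise ValueError("superordinate scheme needs 2 pool classes")
            y = np.where(pool_design.superordinate == levels[0], 1, -1)
            if np.unique(y).size < 2:
                raise ValueError("a class is absent from the pool")
            dv = _svm_distances(red.pool, y, red.scenes, C)
            out[layer] = np.abs(dv)
        elif scheme == "basic":
            for tgt in design.basic_levels:
                rng = substream(master_seed, "model_basic", layer, tgt)
                tgt_scenes = np.flatnonzero(design.basic_level == tgt)
                pos = np.flatnonzero(pool_design.basic_level == tgt)
                if pos.size == 0:
                    raise ValueError(f"category {tgt!r} absent from the pool")
                sup = design.superordinate_of_basic(tgt)
                siblings = [b for b in pool_design.basic_levels_of(sup) if b != tgt]
                acc = np.zeros(tgt_scenes.size)
                for _ in range(n_repeats):
                    neg = []
                    for b in siblings:
                        cand = np.flatnonzero(pool_design.basic_level == b)
                        neg.append(rng.choice(cand, size=max(1, cand.size // 2),
                                              replace=False))
                    neg = np.concatenate(neg)
                    X = np.vstack([red.pool[pos], red.pool[neg]])
                    y = np.concatenate([np.ones(pos.size), -np.ones(neg.size)])
                    dv = _svm_distances(X, y, red.scenes[tgt_scenes], C)
                    acc += np.abs(dv)
                out[layer, tgt_scenes] = acc / n_repeats
        else:
            raise ValueError(f"unknown scheme: {scheme!r}")
    return out


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Unadjusted R2 of an intercept OLS fit, minimum-norm under collinearity."""
    Xd = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("outcome variable is constant")
    return float(1.0 - np.sum(resid**2) / ss_tot)


def commonality(
    y_rt: np.ndarray,
    a_neural_dist: np.ndarray,
    b_model_dist: np.ndarray,
    **indices,
) -> CommonalityResult:
    """Common variance of RTs explained jointly by neural and model distances."""
    y = np.asarray(y_rt, dtype=float)
    a = np.asarray(a_neural_dist, dtype=float)
    b = np.asarray(b_model_dist, dtype=float)
    if not (y.shape == a.shape == b.shape) or y.ndim != 1:
        raise ValueError("y, A and B must be equal-length vectors")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("predictors must be non-constant")

    r2_a = _r2(y, a[:, None])
    r2_b = _r2(y, b[:, None])
    r2_ab = _r2(y, np.column_stack([a, b]))
    return CommonalityResult(
        R2_yA=r2_a, R2_yB=r2_b, R2_yAB=r2_ab,
        C_AB=r2_a + r2_b - r2_ab, upper_limit=r2_a, **indices,
    )


def layer_profile(
    commonality_results: list[CommonalityResult] | np.ndarray,
) -> tuple[int, np.ndarray, bool]:
    """Peak layer of the group-mean commonality curve.

    Accepts a (n_subjects, n_layers) array or a flat list of
    CommonalityResult carrying ``layer`` (1-based) and ``subject``.  Returns
    (peak_layer, group_curve, tied): the arg-max of the subject-mean C_AB
    per layer (1-based), the group curve, and whether the maximum was tied
    (ties broken toward the lower index).
    """
    if isinstance(commonality_results, np.ndarray):
        curve = np.asarray(commonality_results, dtype=float)
        if curve.ndim == 2:
            curve = curve.mean(axis=0)
    else:
        layers = sorted({r.layer for r in commonality_results})
        if any(l is None for l in layers):
            raise ValueError("results must carry a 1-based layer index")
        curve = np.array([
            np.mean([r.C_AB for r in commonality_results if r.layer == l])
            for l in layers
        ])
    peak = int(np.argmax(curve)) + 1
    tied = bool(np.sum(np.isclose(curve, curve.max(), rtol=0, atol=1e-12)) > 1)
    return peak, curve, tied
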