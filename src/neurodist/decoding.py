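"""Cross-validated linear decoding of scene category with pseudo-beta averaging.

The decoding scheme mirrors standard MVPA practice for condition-rich designs:
for every scene, four run betas are held out and averaged into one test
pseudo-beta; the remaining run betas are randomly grouped in pairs and
averaged into train pseudo-betas.  A soft-margin linear SVM (C = 1) is trained
on the train pseudo-betas and evaluated on the held-out pseudo-betas, and the
whole split/average procedure is repeated (default 100 times) with freshly
shuffled run assignments; accuracies are averaged over repeats.

Two schemes are provided: superordinate (man-made vs natural, all scenes) and
basic-level one-vs-rest decoding (all exemplars of the target category as
positives vs an equal number of exemplars sampled from the distractor
categories of the same superordinate).

Decision values of test pseudo-betas (signed distance to the hyperplane, the
quantity the distance-to-bound analysis consumes) are recorded per scene and
repeat.  Sign convention: positive = first-listed class (man-made for the
superordinate scheme; the target category for basic-level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._rng import substream
from .synthetic import BetaSet, StimulusDesign

__all__ = [
    "DecodingResult",
    "split_and_average",
    "decode_superordinate",
    "decode_basic_level",
    "run_roi_decoding",
]

_STANDARDIZE_EPS = 1e-12


@dataclass
class DecodingResult:
    """Accuracy and per-scene decision values of one decoding scheme."""

    accuracy: float
    decision_values: np.ndarray      # (n_scenes, n_repeats); NaN where a scene
                                     # did not enter a repeat's test set
    n_repeats: int
    scheme: str
    target: str | None = None
    accuracy_targets_only: float | None = None
    positive_class: str | None = None
    extras: dict = field(default_factory=dict)


def split_and_average(
    beta_set: BetaSet,
    n_test: int = 4,
    train_group_size: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One random pseudo-beta split for every scene.

    Per scene: ``n_test`` randomly chosen run betas are averaged into the test
    pseudo-beta; the remaining runs are grouped (in shuffled order) into
    non-overlapping groups of ``train_group_size`` and averaged; leftover runs
    beyond a full group are dropped, keeping pseudo-beta noise homogeneous.

    Returns (train_X, train_scene, test_X): train pseudo-betas stacked over
    scenes with their scene index, and one test pseudo-beta per scene.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_runs = beta_set.n_runs
    minimum = n_test + train_group_size
    if n_runs < minimum:
        raise ValueError(
            f"need at least {minimum} runs (= {n_test} test + one train group "
            f"of {train_group_size}); got {n_runs}"
        )
    n_groups = (n_runs - n_test) // train_group_size

    train_rows, train_scene, test_rows = [], [], []
    for s in range(beta_set.n_scenes):
        order = rng.permutation(n_runs)
        test_rows.append(beta_set.values[s, order[:n_test]].mean(axis=0))
        for g in range(n_groups):
            grp = order[n_test + g * train_group_size: n_test + (g + 1) * train_group_size]
            train_rows.append(beta_set.values[s, grp].mean(axis=0))
            train_scene.append(s)
    return (np.asarray(train_rows), np.asarray(train_scene, dtype=int),
            np.asarray(test_rows))


def _standardize(train_X: np.ndarray, test_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel z-scoring with train-set statistics applied to the test set."""
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd < _STANDARDIZE_EPS, 1.0, sd)
    return (train_X - mu) / sd, (test_X - mu) / sd


def _fit_predict(train_X, train_y, test_X, C: float):
    """Train a linear SVM on +/-1 labels; return (predictions, decision values)."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_X, train_y)
    # classes_ is sorted [-1, +1]; decision_function > 0 <=> predicted +1
    dv = clf.decision_function(test_X)
    return np.where(dv > 0, 1, -1), dv


def decode_superordinate(
    beta_set: BetaSet,
    n_repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    n_test: int = 4,
    train_group_size: int = 2,
    C: float = 1.0,
    standardize: bool = True,
) -> DecodingResult:
    """Superordinate (e.g. man-made vs natural) decoding over all scenes."""
    design = beta_set.design
    levels = design.superordinate_levels
    if len(levels) != 2:
        raise ValueError("superordinate decoding requires exactly 2 levels")
    y_scene = np.where(design.superordinate == levels[0], 1, -1)
    if np.sum(y_scene == 1) != np.sum(y_scene == -1):
        raise ValueError("superordinate classes must have equal scene counts")

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n_scenes = design.n_scenes
    dvs = np.full((n_scenes, n_repeats), np.nan)
    n_correct = 0
    for rep in range(n_repeats):
        train_X, train_scene, test_X = split_and_average(
            beta_set, n_test, train_group_size, rng)
        if standardize:
            train_X, test_X = _standardize(train_X, test_X)
        pred, dv = _fit_predict(train_X, y_scene[train_scene], test_X, C)
        dvs[:, rep] = dv
        n_correct += int(np.sum(pred == y_scene))
    acc = n_correct / (n_scenes * n_repeats)
    return DecodingResult(accuracy=acc, decision_values=dvs, n_repeats=n_repeats,
                          scheme="superordinate", positive_class=levels[0])


def _sample_distractors(
    design: StimulusDesign, target: str, n_targets: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample scene indices from the target's sibling categories, balanced to
    the number of positive examples (as evenly split as possible)."""
    super_of_target = design.superordinate_of_basic(target)
    siblings = [b for b in design.basic_levels_of(super_of_target) if b != target]
    if len(siblings) < 2:
        raise ValueError("basic-level decoding needs >= 2 distractor categories")
    base, extra = divmod(n_targets, len(siblings))
    counts = np.full(len(siblings), base, dtype=int)
    if extra:
        counts[rng.choice(len(siblings), size=extra, replace=False)] += 1
    picked = []
    for b, c in zip(siblings, counts):
        pool = np.flatnonzero(design.basic_level == b)
        if c > pool.size:
            raise ValueError(f"not enough exemplars in distractor category {b!r}")
        picked.append(rng.choice(pool, size=c, replace=False))
    return np.concatenate(picked)


def decode_basic_level(
    beta_set: BetaSet,
    target_category: str,
    n_repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    n_test: int = 4,
    train_group_size: int = 2,
    C: float = 1.0,
    standardize: bool = True,
) -> DecodingResult:
    """One-vs-rest basic-level decoding for one target category.

    Positives: all exemplars of the target category.  Negatives: an equal
    number of exemplars sampled (afresh each repeat) from the sibling
    categories of the same superordinate.  Accuracy is computed on the test
    pseudo-betas of targets plus sampled distractors (default) and, for
    reference, on the targets alone.
    """
    design = beta_set.design
    targets = np.flatnonzero(design.basic_level == target_category)
    if targets.size == 0:
        raise ValueError(f"unknown target category: {target_category!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    dvs = np.full((design.n_scenes, n_repeats), np.nan)
    n_correct = n_total = 0
    n_correct_tgt = 0
    for rep in range(n_repeats):
        distractors = _sample_distractors(design, target_category, targets.size, rng)
        scenes = np.concatenate([targets, distractors])
        y_scene = np.concatenate([np.ones(targets.size, dtype=int),
                                  -np.ones(distractors.size, dtype=int)])
        sub = BetaSet(beta_set.values[scenes], _subset_design(design, scenes))
        train_X, train_scene, test_X = split_and_average(sub, n_test, train_group_size, rng)
        if standardize:
            train_X, test_X = _standardize(train_X, test_X)
        pred, dv = _fit_predict(train_X, y_scene[train_scene], test_X, C)
        dvs[scenes, rep] = dv
        n_correct += int(np.sum(pred == y_scene))
        n_total += y_scene.size
        n_correct_tgt += int(np.sum(pred[: targets.size] == 1))
    return DecodingResult(
        accuracy=n_correct / n_total,
        decision_values=dvs,
        n_repeats=n_repeats,
        scheme="basic",
        target=target_category,
        accuracy_targets_only=n_correct_tgt / (targets.size * n_repeats),
        positive_class=target_category,
        extras={"target_scenes": targets},
    )


def _subset_design(design: StimulusDesign, scenes: np.ndarray) -> StimulusDesign:
    return StimulusDesign(
        scene_id=np.arange(scenes.size),
        superordinate=design.superordinate[scenes],
        basic_level=design.basic_level[scenes],
        exemplar=design.exemplar[scenes],
    )


def run_roi_decoding(
    beta_sets_by_subject: dict,
    roi_masks: dict[str, np.ndarray],
    schemes: tuple[str, ...] = ("superordinate", "basic"),
    n_repeats: int = 100,
    master_seed: int = 0,
    **decode_kw,
) -> pd.DataFrame:
    """Run the decoding schemes for every (subject, ROI); tidy summary output.

    Basic-level accuracies (and distances, downstream) are averaged over the
    target categories.  Each (subject, ROI, scheme[, target]) unit draws its
    own RNG substream from the master seed, so results do not depend on
    iteration order.  Empty ROIs yield a row flagged missing rather than
    being silently skipped.

    Returns a DataFrame with columns subject, roi, scheme, accuracy, missing,
    and a ``result`` column holding the DecodingResult objects (per target
    for the basic scheme, as a dict).
    """
    rows = []
    for subj, beta_set in beta_sets_by_subject.items():
        for roi_name, roi in roi_masks.items():
            roi = np.asarray(roi)
            idx = np.flatnonzero(roi) if roi.dtype == bool else roi
            if idx.size == 0:
                for scheme in schemes:
                    rows.append({"subject": subj, "roi": roi_name, "scheme": scheme,
                                 "accuracy": np.nan, "missing": True, "result": None})
                continue
            sub = beta_set.select_voxels(idx)
            for scheme in schemes:
                if scheme == "superordinate":
                    rng = substream(master_seed, subj, roi_name, "superordinate")
                    res = decode_superordinate(sub, n_repeats, rng, **decode_kw)
                    rows.append({"subject": subj, "roi": roi_name, "scheme": scheme,
                                 "accuracy": res.accuracy, "missing": False,
                                 "result": res})
                elif scheme == "basic":
                    per_target = {}
                    for tgt in sub.design.basic_levels:
                        rng = substream(master_seed, subj, roi_name, "basic", tgt)
                        per_target[tgt] = decode_basic_level(sub, tgt, n_repeats, rng,
                                                             **decode_kw)
                    acc = float(np.mean([r.accuracy for r in per_target.values()]))
                    rows.append({"subject": subj, "roi": roi_name, "scheme": scheme,
                                 "accuracy": acc, "missing": False,
                                 "result": per_target})
                else:
                    raise ValueError(f"unknown scheme: {scheme!r}")
    return pd.DataFrame(rows)
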