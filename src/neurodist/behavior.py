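"""Distance-to-bound vs reaction time: distances, RT aggregation, correlation,
and the joint-reliability noise ceiling.

Distances are the absolute decision values of held-out test patterns,
averaged over resampling repeats (mean of absolutes by default; the
alternative — absolute value of the repeat-averaged decision value — is
available behind a flag).  For basic-level decoding, each scene's distance
comes from the decoder of its own target category; the six 10-scene pieces
are concatenated into one 60-scene vector.

RTs are aggregated in two stages: within subject over correct trials, then
unweighted across subjects — one mean RT per scene and task.

The noise ceiling on the observable distance-RT correlation is the joint
reliability: split-half reliabilities of distances (odd vs even runs) and
RTs (random subject halves), Spearman-Brown corrected, combined as the
square root of their product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .decoding import DecodingResult, decode_superordinate, decode_basic_level
from .synthetic import BetaSet

__all__ = [
    "DistanceRTResult",
    "extract_distances",
    "aggregate_rts",
    "correlate_distance_rt",
    "spearman_brown",
    "joint_reliability",
    "split_half_distances",
    "rt_split_half",
]


@dataclass
class DistanceRTResult:
    r: float
    n_scenes: int
    reliability: float | None = None   # signed for display; None if undefined
    scheme: str | None = None
    source: str | None = None


def extract_distances(
    result: DecodingResult | dict[str, DecodingResult],
    abs_of_mean: bool = False,
) -> np.ndarray:
    """Per-scene hyperplane distances from decoding decision values.

    ``result`` is a single superordinate DecodingResult or, for the basic
    scheme, a dict of per-target results whose target-scene distances are
    concatenated (in scene order) to cover the full design.

    Default: mean over repeats of |decision value|.  ``abs_of_mean`` instead
    takes |mean over repeats| (order of operations matters when decision
    values change sign across repeats).
    """
    if isinstance(result, dict):
        some = next(iter(result.values()))
        n_scenes = some.decision_values.shape[0]
        out = np.full(n_scenes, np.nan)
        for res in result.values():
            if res.target is None:
                raise ValueError("basic-level results must carry their target category")
            design_mask = _target_scene_mask(res, n_scenes)
            vals = _reduce(res.decision_values[design_mask], abs_of_mean)
            out[design_mask] = vals
        if np.any(np.isnan(out)):
            missing = np.flatnonzero(np.isnan(out)).tolist()
            raise ValueError(f"scenes missing from every decoder: {missing}")
        return out
    return _reduce(result.decision_values, abs_of_mean)


def _target_scene_mask(res: DecodingResult, n_scenes: int) -> np.ndarray:
    mask = np.zeros(n_scenes, dtype=bool)
    targets = res.extras.get("target_scenes")
    if targets is None:
        # fall back: target scenes enter every repeat's test set
        targets = np.flatnonzero((~np.isnan(res.decision_values)).all(axis=1))
    mask[np.asarray(targets)] = True
    return mask


def _reduce(dv: np.ndarray, abs_of_mean: bool) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        red = (np.abs(np.nanmean(dv, axis=1)) if abs_of_mean
               else np.nanmean(np.abs(dv), axis=1))
    if np.any(np.isnan(red)):
        missing = np.flatnonzero(np.isnan(red)).tolist()
        raise ValueError(f"scenes missing from all repeats: {missing}")
    return red


def aggregate_rts(trial_rt_table: pd.DataFrame, task: str) -> pd.Series:
    """Two-stage RT mean: within subject over correct trials, then unweighted
    across subjects.  Subjects without a correct trial for a scene are
    omitted from that scene's across-subject mean."""
    t = trial_rt_table[(trial_rt_table["task"] == task) & trial_rt_table["correct"]]
    all_scenes = trial_rt_table.loc[trial_rt_table["task"] == task, "scene_id"].unique()
    if t.empty:
        raise ValueError(f"no correct trials for task {task!r}")
    per_subject = t.groupby(["subject", "scene_id"])["rt"].mean()
    per_scene = per_subject.groupby("scene_id").mean().sort_index()
    dead = sorted(int(s) for s in set(all_scenes) - set(per_scene.index))
    if dead:
        raise ValueError(f"scenes with zero correct trials overall: {dead}")
    per_scene.name = "rt"
    return per_scene


def correlate_distance_rt(
    distances: np.ndarray,
    rt: np.ndarray | pd.Series,
    reliability: float | None = None,
    scheme: str | None = None,
    source: str | None = None,
) -> DistanceRTResult:
    """Pearson correlation of per-scene distances with per-scene mean RTs."""
    d = np.asarray(distances, dtype=float)
    r_vec = np.asarray(rt, dtype=float)
    if d.shape != r_vec.shape:
        raise ValueError("distances and RTs must be matched per scene")
    if d.size < 3:
        raise ValueError("need at least 3 scenes")
    if np.ptp(d) == 0 or np.ptp(r_vec) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(scipy.stats.pearsonr(d, r_vec).statistic)
    return DistanceRTResult(r=r, n_scenes=d.size, reliability=reliability,
                            scheme=scheme, source=source)


def spearman_brown(r_half: float) -> float:
    """Prophecy formula: reliability of the full-length measure from a
    split-half correlation."""
    return 2.0 * r_half / (1.0 + r_half)


def joint_reliability(
    distance_halves: tuple[np.ndarray, np.ndarray],
    rt_halves: tuple[np.ndarray, np.ndarray] | float,
    observed_r: float | None = None,
) -> float | None:
    """Noise ceiling for the distance-RT correlation.

    Split-half correlations of each measure are Spearman-Brown corrected and
    combined as sqrt(r_full_dist * r_full_rt).  ``rt_halves`` may be a pair
    of half-sample RT vectors or a pre-averaged split-half correlation (e.g.
    the mean over many random subject splits).  A negative product under the
    square root makes the ceiling undefined: None is returned (reported as
    missing, not propagated as NaN).  When the associated observed
    distance-RT correlation is negative, the returned value is sign-inverted
    for display alongside the (negative) correlation.
    """
    d1, d2 = (np.asarray(h, dtype=float) for h in distance_halves)
    r_half_d = float(scipy.stats.pearsonr(d1, d2).statistic)
    if isinstance(rt_halves, tuple):
        r1, r2 = (np.asarray(h, dtype=float) for h in rt_halves)
        r_half_rt = float(scipy.stats.pearsonr(r1, r2).statistic)
    else:
        r_half_rt = float(rt_halves)
    prod = spearman_brown(r_half_d) * spearman_brown(r_half_rt)
    if prod < 0:
        return None
    joint = float(np.sqrt(prod))
    if observed_r is not None and observed_r < 0:
        joint = -joint
    return joint


def split_half_distances(
    beta_set: BetaSet,
    scheme: str = "superordinate",
    n_repeats: int = 20,
    rng: np.random.Generator | int | None = None,
    n_test: int = 2,
    train_group_size: int = 2,
    **decode_kw,
) -> tuple[np.ndarray, np.ndarray]:
    """Distances computed separately from odd and even runs.

    Each half has about half the runs, so a reduced split (default 2 test
    betas, train groups of 2) is used within the halves.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    halves = []
    for parity in (0, 1):
        sub = beta_set.select_runs(np.arange(parity, beta_set.n_runs, 2))
        if scheme == "superordinate":
            res = decode_superordinate(sub, n_repeats, rng, n_test=n_test,
                                       train_group_size=train_group_size, **decode_kw)
            halves.append(extract_distances(res))
        elif scheme == "basic":
            per_target = {
                tgt: decode_basic_level(sub, tgt, n_repeats, rng, n_test=n_test,
                                        train_group_size=train_group_size, **decode_kw)
                for tgt in sub.design.basic_levels
            }
            halves.append(extract_distances(per_target))
        else:
            raise ValueError(f"unknown scheme: {scheme!r}")
    return halves[0], halves[1]


def rt_split_half(
    trial_rt_table: pd.DataFrame,
    task: str,
    n_splits: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean split-half correlation of per-scene RTs over random subject halves."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = trial_rt_table[(trial_rt_table["task"] == task) & trial_rt_table["correct"]]
    per_subject = (t.groupby(["subject", "scene_id"])["rt"].mean()
                    .unstack("scene_id"))  # subjects x scenes
    subjects = per_subject.index.to_numpy()
    if subjects.size < 2:
        raise ValueError("need >= 2 subjects for a split-half")
    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(subjects.size)
        half = subjects.size // 2
        a = per_subject.iloc[perm[:half]].mean(axis=0)
        b = per_subject.iloc[perm[half:]].mean(axis=0)
        rs.append(scipy.stats.pearsonr(a, b).statistic)
    return float(np.mean(rs))
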