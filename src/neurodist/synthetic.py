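"""Synthetic data with known ground truth for the distance-to-bound pipeline.

The generators emulate the structure of a scene-categorization fMRI study:
a nested stimulus design (superordinate x basic-level x exemplar), per-run
GLM beta patterns with controllable category signal, trial-level reaction
times driven by the true distance to the optimal category boundary, layered
model feature matrices with a unimodal complexity profile, and masked 3-D
volumes with planted effect clusters.

The generative model for beta patterns is linear-Gaussian with nested
category effects, so a linear hyperplane is Bayes-optimal and the "true"
boundary distance of a scene is well defined: the signed projection of its
noiseless pattern onto the unit superordinate axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "StimulusDesign",
    "GroundTruth",
    "BetaSet",
    "ModelFeatureSet",
    "VolumetricDataset",
    "generate_design",
    "generate_beta_set",
    "generate_rts",
    "generate_model_features",
    "generate_volumetric",
]

RT_FLOOR = 0.15  # seconds; truncation floor preserving seed determinism


@dataclass(frozen=True)
class StimulusDesign:
    """Nested scene design: superordinate x basic-level x exemplar."""

    scene_id: np.ndarray          # (n_scenes,) int, contiguous from 0
    superordinate: np.ndarray     # (n_scenes,) str
    basic_level: np.ndarray       # (n_scenes,) str
    exemplar: np.ndarray          # (n_scenes,) int within basic-level category

    @property
    def n_scenes(self) -> int:
        return self.scene_id.size

    @property
    def superordinate_levels(self) -> list[str]:
        # first-occurrence order, not alphabetical: the first-listed level is
        # the positive class of the superordinate decoder
        return list(dict.fromkeys(self.superordinate.tolist()))

    @property
    def basic_levels(self) -> list[str]:
        return list(dict.fromkeys(self.basic_level.tolist()))

    def basic_levels_of(self, superordinate: str) -> list[str]:
        keep = self.superordinate == superordinate
        return list(dict.fromkeys(self.basic_level[keep].tolist()))

    def superordinate_of_basic(self, basic: str) -> str:
        idx = np.flatnonzero(self.basic_level == basic)
        if idx.size == 0:
            raise ValueError(f"unknown basic-level category: {basic!r}")
        return str(self.superordinate[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scene_id": self.scene_id,
                "superordinate": self.superordinate,
                "basic_level": self.basic_level,
                "exemplar": self.exemplar,
            }
        )


@dataclass
class GroundTruth:
    """Planted truth stored alongside every generated dataset."""

    signed_distance: np.ndarray           # (n_scenes,) signed distance to optimal boundary
    noiseless_pattern: np.ndarray | None  # (n_scenes, n_voxels)
    signal_weights: np.ndarray | None     # unit superordinate axis in voxel space
    planted_voxels: np.ndarray | None = None   # flat masked-voxel indices (volumetric)
    rt_slope: float | None = None
    rt_intercept: float | None = None
    noise: dict = field(default_factory=dict)

    @property
    def distance(self) -> np.ndarray:
        """Unsigned true distance to the boundary."""
        return np.abs(self.signed_distance)


@dataclass
class BetaSet:
    """Per-scene, per-run GLM parameter estimates.

    ``values`` is (n_scenes, n_runs, n_voxels); voxel order is the canonical
    pattern order used by every downstream stage.
    """

    values: np.ndarray
    design: StimulusDesign
    mask: np.ndarray | None = None  # voxel validity flags, (n_voxels,)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be (n_scenes, n_runs, n_voxels)")
        if v.shape[0] != self.design.n_scenes:
            raise ValueError("first axis must match the design's scene count")
        if self.mask is None:
            self.mask = np.ones(v.shape[2], dtype=bool)
        if not np.all(np.isfinite(v[:, :, self.mask])):
            raise ValueError("non-finite beta values inside mask")
        self.values = v

    @property
    def n_scenes(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def select_voxels(self, voxel_idx: np.ndarray) -> "BetaSet":
        """Restrict to a voxel subset (ROI or searchlight neighborhood)."""
        voxel_idx = np.asarray(voxel_idx)
        if voxel_idx.dtype == bool:
            voxel_idx = np.flatnonzero(voxel_idx)
        return BetaSet(self.values[:, :, voxel_idx], self.design,
                       mask=np.ones(voxel_idx.size, dtype=bool))

    def select_runs(self, run_idx: np.ndarray) -> "BetaSet":
        return BetaSet(self.values[:, np.asarray(run_idx), :], self.design, mask=self.mask)


@dataclass
class ModelFeatureSet:
    """Layered feature matrices for a training pool and the experimental scenes."""

    pool_features: list[np.ndarray]    # per layer: (pool_size, n_features)
    scene_features: list[np.ndarray]   # per layer: (n_scenes, n_features)
    pool_design: StimulusDesign
    design: StimulusDesign
    layer_signal: np.ndarray           # per-layer planted signal strength

    @property
    def n_layers(self) -> int:
        return len(self.pool_features)


@dataclass
class VolumetricDataset:
    """BetaSet whose voxels carry 3-D grid coordinates."""

    betas: BetaSet
    grid_shape: tuple[int, int, int]
    brain_mask: np.ndarray             # boolean 3-D grid
    voxel_coords: np.ndarray           # (n_voxels, 3) int grid coords, masked order
    planted_mask: np.ndarray | None = None  # boolean 3-D grid of planted clusters

    def __post_init__(self) -> None:
        if self.voxel_coords.shape[0] != self.betas.n_voxels:
            raise ValueError("one grid coordinate per masked voxel required")

    def to_volume(self, voxel_values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-voxel values back onto the 3-D grid."""
        vol = np.full(self.grid_shape, fill, dtype=float)
        vol[tuple(self.voxel_coords.T)] = voxel_values
        return vol


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_design(
    n_superordinate: int = 2,
    n_basic_per_super: int = 3,
    n_exemplars: int = 10,
    superordinate_names: list[str] | None = None,
) -> StimulusDesign:
    """Build a fully crossed nested design.

    The default (2, 3, 10) yields 60 scenes: man-made/natural, three
    basic-level categories each, ten exemplars per category.
    """
    for name, v in [("n_superordinate", n_superordinate),
                    ("n_basic_per_super", n_basic_per_super),
                    ("n_exemplars", n_exemplars)]:
        if int(v) < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")

    if superordinate_names is None:
        base = ["man-made", "natural"]
        superordinate_names = [base[i] if i < 2 else f"super{i}" for i in range(n_superordinate)]
    if len(superordinate_names) != n_superordinate:
        raise ValueError("superordinate_names length mismatch")

    sup, bas, exe = [], [], []
    for s in range(n_superordinate):
        for b in range(n_basic_per_super):
            for e in range(n_exemplars):
                sup.append(superordinate_names[s])
                bas.append(f"{superordinate_names[s]}/basic{b}")
                exe.append(e)
    n = len(sup)
    return StimulusDesign(
        scene_id=np.arange(n),
        superordinate=np.array(sup),
        basic_level=np.array(bas),
        exemplar=np.array(exe),
    )


def _super_signs(design: StimulusDesign) -> np.ndarray:
    """+1 for the first-listed superordinate level, -1 otherwise."""
    if len(design.superordinate_levels) != 2:
        raise ValueError("superordinate signs require exactly 2 levels")
    pos = design.superordinate_levels[0]
    return np.where(design.superordinate == pos, 1.0, -1.0)


def generate_beta_set(
    design: StimulusDesign,
    n_runs: int = 10,
    n_voxels: int = 100,
    super_effect: float = 1.0,
    basic_effect: float = 0.5,
    exemplar_sd: float = 0.5,
    run_noise_sd: float = 1.0,
    exemplar_axis_sd: float = 0.0,
    seed: int = 0,
    noise_seed: int | None = None,
) -> tuple[BetaSet, GroundTruth]:
    """Generate per-run beta patterns with nested category structure.

    Voxel pattern of scene s in run r:

        beta[s, r] = (super_effect / 2) * sign(s) * u_super
                     + basic_effect * u_basic[b(s)]
                     + e_s + eps[s, r]

    with u_super a fixed random unit axis, u_basic per-category unit axes,
    e_s ~ N(0, exemplar_sd^2 I) a fixed per-scene exemplar component and
    eps i.i.d. N(0, run_noise_sd^2) per run.  The true signed boundary
    distance is the projection of the noiseless pattern onto u_super
    (optimal under isotropic noise).

    ``exemplar_sd`` controls isotropic per-scene scatter; ``exemplar_axis_sd``
    adds scatter specifically along the boundary axis.  Only the axis
    component moves a scene's true distance; the isotropic part mostly
    perturbs the pattern orthogonally and thus acts as structured noise for
    the distance-RT relation.  In the vanishing-noise limit (run noise and
    isotropic scatter -> 0, axis scatter > 0) the decoded distances become
    exactly affine in the true distances.

    ``noise_seed`` decouples the run noise from the scene-level structure:
    datasets sharing ``seed`` but differing in ``noise_seed`` emulate
    multiple subjects measuring the same underlying scene representation.
    """
    if n_runs < 5:
        raise ValueError(
            "n_runs must be >= 5: the default split scheme needs >= 4 test "
            "betas plus >= 1 train beta per scene"
        )
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    for name, v in [("super_effect", super_effect), ("basic_effect", basic_effect),
                    ("exemplar_sd", exemplar_sd), ("run_noise_sd", run_noise_sd),
                    ("exemplar_axis_sd", exemplar_axis_sd)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")

    rng = substream(seed, "betas")
    signs = _super_signs(design)

    u_super = rng.standard_normal(n_voxels)
    u_super /= np.linalg.norm(u_super)

    basics = design.basic_levels
    u_basic = {}
    for b in basics:
        v = rng.standard_normal(n_voxels)
        v -= (v @ u_super) * u_super  # keep basic axes orthogonal to the boundary axis
        u_basic[b] = v / np.linalg.norm(v)

    exemplar = exemplar_sd * rng.standard_normal((design.n_scenes, n_voxels))
    if exemplar_axis_sd > 0:
        # antithetic across the two superordinate classes: the realized scene
        # set stays symmetric under reflection about the planted boundary, so
        # the boundary at 0 is exactly optimal for the finite sample and the
        # stored ground-truth distances are exact, not just population-level
        half = design.n_scenes // 2
        z = rng.standard_normal(half)
        offsets = np.empty(design.n_scenes)
        offsets[signs > 0] = z[: np.sum(signs > 0)]
        offsets[signs < 0] = -z[: np.sum(signs < 0)]
        exemplar += exemplar_axis_sd * offsets[:, None] * u_super[None, :]

    noiseless = (
        0.5 * super_effect * signs[:, None] * u_super[None, :]
        + basic_effect * np.stack([u_basic[b] for b in design.basic_level])
        + exemplar
    )
    noise_rng = (rng if noise_seed is None
                 else substream(noise_seed, "beta_noise"))
    noise = run_noise_sd * noise_rng.standard_normal((design.n_scenes, n_runs, n_voxels))
    values = noiseless[:, None, :] + noise

    truth = GroundTruth(
        signed_distance=noiseless @ u_super,
        noiseless_pattern=noiseless,
        signal_weights=u_super,
        noise={"exemplar_sd": exemplar_sd, "run_noise_sd": run_noise_sd,
               "exemplar_axis_sd": exemplar_axis_sd,
               "super_effect": super_effect, "basic_effect": basic_effect},
    )
    return BetaSet(values, design), truth


def generate_rts(
    ground_truth: GroundTruth,
    design: StimulusDesign,
    task_sign: int = -1,
    rt_intercept: float = 0.7,
    rt_slope: float = 0.15,
    rt_noise_sd: float = 0.15,
    n_trials_per_scene: int = 24,
    accuracy_rate: float = 0.8,
    n_subjects: int = 30,
    subject_sd: float = 0.05,
    task: str = "categorization",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate trial-level RTs as a noisy affine function of true distance.

        rt = intercept + subject offset + task_sign * slope * distance + noise

    truncated at 0.15 s.  task_sign = -1 gives the categorization regime
    (far from the boundary -> fast); +1 the interference regime (far from
    the boundary -> slow).  Each trial is flagged correct with probability
    ``accuracy_rate``.
    """
    if rt_intercept <= 0:
        raise ValueError("rt_intercept must be > 0")
    if not (0 < accuracy_rate <= 1):
        raise ValueError("accuracy_rate must be in (0, 1]")
    if task_sign not in (-1, 1):
        raise ValueError("task_sign must be -1 or +1")

    dist = ground_truth.distance
    frames = []
    for subj in range(n_subjects):
        rng = substream(seed, "rts", subj)
        offset = subject_sd * rng.standard_normal()
        mu = rt_intercept + offset + task_sign * rt_slope * dist
        rt = mu[:, None] + rt_noise_sd * rng.standard_normal((design.n_scenes, n_trials_per_scene))
        rt = np.maximum(rt, RT_FLOOR)
        correct = rng.random((design.n_scenes, n_trials_per_scene)) < accuracy_rate
        frames.append(pd.DataFrame({
            "subject": subj,
            "scene_id": np.repeat(design.scene_id, n_trials_per_scene),
            "task": task,
            "correct": correct.ravel(),
            "rt": rt.ravel(),
        }))
    table = pd.concat(frames, ignore_index=True)
    ground_truth.rt_slope = task_sign * rt_slope
    ground_truth.rt_intercept = rt_intercept
    return table


def layer_signal_profile(n_layers: int, peak_layer: int | None, width: float = 0.8) -> np.ndarray:
    """Unimodal (Gaussian-bump) per-layer signal profile, peak value 1.

    ``peak_layer`` is 1-based; None yields a flat profile.
    """
    if peak_layer is None:
        return np.ones(n_layers)
    if not (1 <= peak_layer <= n_layers):
        raise ValueError("peak_layer must be in [1, n_layers]")
    layers = np.arange(1, n_layers + 1, dtype=float)
    return np.exp(-((layers - peak_layer) ** 2) / (2.0 * width**2))


def generate_model_features(
    design: StimulusDesign,
    n_layers: int = 6,
    peak_layer: int | None = 3,
    n_features: int = 100,
    pool_size: int = 120,
    noise_sd: float = 0.3,
    seed: int = 0,
    scene_signal: np.ndarray | None = None,
    basic_effect: float = 1.0,
    profile_width: float = 0.8,
) -> ModelFeatureSet:
    """Generate layered feature matrices with a unimodal complexity profile.

    The category signal strength across layers follows a Gaussian bump
    peaking at ``peak_layer`` (1-based; None = flat), so linear decodability
    of category from the features is maximal at the peak layer.

    ``scene_signal`` is an optional per-scene signed scalar (typically the
    signed true boundary distance from ``generate_beta_set``) that scales
    each experimental scene's category component; passing it couples the
    model features to the neural/behavioral data at the scene level, which
    is what makes downstream commonality analysis recover the planted peak.
    When None, an independent per-scene scalar is drawn.
    """
    rng = substream(seed, "model_features")
    profile = layer_signal_profile(n_layers, peak_layer, profile_width)

    n_super = len(design.superordinate_levels)
    n_basic = len(design.basic_levels)
    reps = int(np.ceil(pool_size / design.n_scenes))
    pool_order = np.tile(np.arange(design.n_scenes), reps)[:pool_size]
    pool_design = StimulusDesign(
        scene_id=np.arange(pool_size),
        superordinate=design.superordinate[pool_order],
        basic_level=design.basic_level[pool_order],
        exemplar=design.exemplar[pool_order],
    )
    del n_super, n_basic

    if scene_signal is None:
        scene_signal = _super_signs(design) + 0.3 * rng.standard_normal(design.n_scenes)
    scene_signal = np.asarray(scene_signal, dtype=float)
    if scene_signal.shape != (design.n_scenes,):
        raise ValueError("scene_signal must have one value per scene")
    pool_signal = _super_signs(pool_design) + 0.3 * rng.standard_normal(pool_size)

    basics = design.basic_levels
    pool_features, scene_features = [], []
    for layer in range(n_layers):
        d_super = rng.standard_normal(n_features)
        d_super /= np.linalg.norm(d_super)
        d_basic = {}
        for b in basics:
            v = rng.standard_normal(n_features)
            v -= (v @ d_super) * d_super
            d_basic[b] = v / np.linalg.norm(v)
        g = profile[layer]
        pool_b = np.stack([d_basic[b] for b in pool_design.basic_level])
        scene_b = np.stack([d_basic[b] for b in design.basic_level])
        pool = g * (pool_signal[:, None] * d_super[None, :] + basic_effect * pool_b)
        scenes = g * (scene_signal[:, None] * d_super[None, :] + basic_effect * scene_b)
        pool = pool + noise_sd * rng.standard_normal(pool.shape)
        scenes = scenes + noise_sd * rng.standard_normal(scenes.shape)
        pool_features.append(pool)
        scene_features.append(scenes)

    return ModelFeatureSet(pool_features, scene_features, pool_design, design, profile)


def generate_volumetric(
    design: StimulusDesign,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    mask: np.ndarray | None = None,
    cluster_spec: list[tuple[tuple[int, int, int], tuple[int, int, int]]] | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    n_runs: int = 10,
    exemplar_sd: float = 0.3,
    seed: int = 0,
    noise_seed: int | None = None,
) -> tuple[VolumetricDataset, GroundTruth]:
    """Generate a masked volume of beta patterns with planted effect clusters.

    ``cluster_spec`` is a list of (corner, size) axis-aligned boxes in grid
    coordinates; inside them, voxels carry a category signal proportional to
    ``effect_size`` (and hence a distance-RT coupling when RTs are generated
    from the returned ground truth); outside, betas are pure noise.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid_shape:
        raise ValueError("mask shape must equal grid_shape")

    planted = np.zeros(grid_shape, dtype=bool)
    if cluster_spec:
        for corner, size in cluster_spec:
            sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
            box = np.zeros(grid_shape, dtype=bool)
            box[sl] = True
            if np.any(box & ~mask):
                raise ValueError("planted cluster extends outside the brain mask")
            planted |= box

    coords = np.argwhere(mask)
    n_vox = coords.shape[0]
    planted_flat = planted[mask]

    rng = substream(seed, "volumetric")
    signs = _super_signs(design)
    scene_scalar = signs + exemplar_sd * rng.standard_normal(design.n_scenes)

    w = np.zeros(n_vox)
    n_planted = int(planted_flat.sum())
    if n_planted:
        w_in = rng.standard_normal(n_planted)
        w_in /= np.linalg.norm(w_in)
        w[planted_flat] = w_in

    noiseless = effect_size * scene_scalar[:, None] * w[None, :]
    noise_rng = (rng if noise_seed is None
                 else substream(noise_seed, "vol_noise"))
    values = noiseless[:, None, :] + noise_sd * noise_rng.standard_normal(
        (design.n_scenes, n_runs, n_vox)
    )

    betas = BetaSet(values, design)
    vol = VolumetricDataset(betas, grid_shape, mask, coords, planted_mask=planted)
    truth = GroundTruth(
        signed_distance=effect_size * scene_scalar if n_planted else np.zeros(design.n_scenes),
        noiseless_pattern=noiseless,
        signal_weights=w,
        planted_voxels=np.flatnonzero(planted_flat),
        noise={"noise_sd": noise_sd, "effect_size": effect_size,
               "exemplar_sd": exemplar_sd},
    )
    return vol, truth
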