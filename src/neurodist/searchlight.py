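"""Searchlight mapping: apply a per-patch statistic over sphere neighborhoods.

A neighborhood is the Euclidean ball of a given radius around each in-mask
voxel (world-coordinate distance when voxel sizes are supplied, voxel
distance otherwise), intersected with the mask.  Any registered per-patch
statistic — superordinate decoding accuracy, basic-level decoding accuracy,
or the distance-RT correlation — is computed independently per neighborhood
with a per-center RNG substream, so maps are deterministic given the master
seed regardless of execution order, and the value at any center equals the
ROI pipeline run on that neighborhood mask with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._rng import substream
from .behavior import correlate_distance_rt, extract_distances
from .decoding import decode_basic_level, decode_superordinate
from .synthetic import BetaSet, VolumetricDataset

__all__ = [
    "SearchlightIndex",
    "StatMap",
    "build_neighborhoods",
    "searchlight_map",
    "STATISTICS",
]


@dataclass
class SearchlightIndex:
    centers: np.ndarray              # masked-voxel indices of centers
    neighbors: list[np.ndarray]      # per center: sorted masked-voxel indices
    radius: float
    grid_shape: tuple[int, int, int]


@dataclass
class StatMap:
    values: np.ndarray               # per masked voxel
    valid: np.ndarray                # per masked voxel
    name: str
    grid_shape: tuple[int, int, int]
    voxel_coords: np.ndarray

    def to_volume(self, fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.grid_shape, fill)
        ok = self.valid
        vol[tuple(self.voxel_coords[ok].T)] = self.values[ok]
        return vol


def build_neighborhoods(
    mask: np.ndarray,
    radius: float = 4.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SearchlightIndex:
    """Euclidean-ball neighborhoods clipped to the mask.

    ``radius`` and ``voxel_size`` share units (mm when an affine's voxel
    sizes are passed, voxels with the unit default).  Every neighborhood
    contains its center.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("mask is empty")
    if radius <= 0:
        raise ValueError("radius must be > 0")

    vs = np.asarray(voxel_size, dtype=float)
    reach = np.floor(radius / vs).astype(int)
    offs = np.array([
        (i, j, k)
        for i in range(-reach[0], reach[0] + 1)
        for j in range(-reach[1], reach[1] + 1)
        for k in range(-reach[2], reach[2] + 1)
        if np.sqrt(((np.array([i, j, k]) * vs) ** 2).sum()) <= radius + 1e-9
    ])

    coords = np.argwhere(mask)
    flat_index = -np.ones(mask.shape, dtype=int)
    flat_index[tuple(coords.T)] = np.arange(coords.shape[0])

    neighbors = []
    shape = np.array(mask.shape)
    for c in coords:
        pts = c[None, :] + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        idx = flat_index[tuple(pts.T)]
        neighbors.append(np.sort(idx[idx >= 0]))
    return SearchlightIndex(
        centers=np.arange(coords.shape[0]),
        neighbors=neighbors,
        radius=float(radius),
        grid_shape=mask.shape,
    )


# ---------------------------------------------------------------------------
# registered per-patch statistics: fn(beta_subset, rng, **kw) -> float
# ---------------------------------------------------------------------------

def _stat_decode_super(beta_subset: BetaSet, rng, n_repeats=10, **kw) -> float:
    return decode_superordinate(beta_subset, n_repeats, rng, **kw).accuracy


def _stat_decode_basic(beta_subset: BetaSet, rng, n_repeats=10, **kw) -> float:
    accs = [decode_basic_level(beta_subset, tgt, n_repeats, rng, **kw).accuracy
            for tgt in beta_subset.design.basic_levels]
    return float(np.mean(accs))


def _stat_dist_rt(beta_subset: BetaSet, rng, rt=None, n_repeats=10,
                  scheme="superordinate", **kw) -> float:
    if rt is None:
        raise ValueError("the dist-rt statistic needs a per-scene rt vector")
    if scheme == "superordinate":
        res = decode_superordinate(beta_subset, n_repeats, rng, **kw)
        d = extract_distances(res)
    else:
        per = {tgt: decode_basic_level(beta_subset, tgt, n_repeats, rng, **kw)
               for tgt in beta_subset.design.basic_levels}
        d = extract_distances(per)
    return correlate_distance_rt(d, np.asarray(rt)).r


STATISTICS: dict[str, Callable] = {
    "decode-super": _stat_decode_super,
    "decode-basic": _stat_decode_basic,
    "dist-rt": _stat_dist_rt,
}


def searchlight_map(
    dataset: VolumetricDataset,
    index: SearchlightIndex,
    statistic: str | Callable,
    master_seed: int = 0,
    min_voxels: int = 2,
    **stat_kw,
) -> StatMap:
    """Compute ``statistic`` on every searchlight neighborhood.

    Each center draws a substream keyed by (master_seed, "searchlight",
    center), so the map is independent of execution order and identical to
    running the ROI pipeline on the neighborhood mask with the same key.
    Neighborhoods smaller than ``min_voxels`` are flagged invalid.
    """
    if isinstance(statistic, str):
        name = statistic
        try:
            fn = STATISTICS[statistic]
        except KeyError:
            raise ValueError(f"unknown statistic {statistic!r}; "
                             f"registered: {sorted(STATISTICS)}") from None
    else:
        fn, name = statistic, getattr(statistic, "__name__", "custom")

    n_vox = dataset.betas.n_voxels
    values = np.full(n_vox, np.nan)
    valid = np.zeros(n_vox, dtype=bool)
    for center, nbrs in zip(index.centers, index.neighbors):
        if nbrs.size < min_voxels:
            continue
        rng = substream(master_seed, "searchlight", int(center))
        sub = dataset.betas.select_voxels(nbrs)
        values[center] = fn(sub, rng, **stat_kw)
        valid[center] = True
    return StatMap(values=values, valid=valid, name=name,
                   grid_shape=dataset.grid_shape, voxel_coords=dataset.voxel_coords)
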