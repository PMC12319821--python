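"""On-disk interchange: NIfTI volumes with JSON sidecars, TSV tables.

Beta sets are written as one 4-D NIfTI (one 3-D volume per scene x run,
scene-major) plus a JSON sidecar carrying the stimulus design and, for
synthetic data, the ground truth.  Flat (ROI) beta sets use a degenerate
1 x 1 x n_voxels spatial grid.  Trial RT tables are TSV with columns
subject, scene_id, task, correct, rt.  All result tables go through
``write_tsv`` with a fixed float format so equal runs produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import BetaSet, GroundTruth, StimulusDesign, VolumetricDataset

__all__ = [
    "save_beta_set", "load_beta_set",
    "save_volumetric", "load_volumetric",
    "save_rt_table", "load_rt_table",
    "save_mask", "load_mask",
    "write_tsv",
]

FLOAT_FORMAT = "%.10g"


def _design_to_dict(design: StimulusDesign) -> dict:
    return {
        "scene_id": design.scene_id.tolist(),
        "superordinate": design.superordinate.tolist(),
        "basic_level": design.basic_level.tolist(),
        "exemplar": design.exemplar.tolist(),
    }


def _design_from_dict(d: dict) -> StimulusDesign:
    return StimulusDesign(
        scene_id=np.asarray(d["scene_id"], dtype=int),
        superordinate=np.asarray(d["superordinate"]),
        basic_level=np.asarray(d["basic_level"]),
        exemplar=np.asarray(d["exemplar"], dtype=int),
    )


def _truth_to_dict(t: GroundTruth | None) -> dict | None:
    if t is None:
        return None
    return {
        "signed_distance": t.signed_distance.tolist(),
        "signal_weights": None if t.signal_weights is None else t.signal_weights.tolist(),
        "planted_voxels": None if t.planted_voxels is None else t.planted_voxels.tolist(),
        "rt_slope": t.rt_slope,
        "rt_intercept": t.rt_intercept,
        "noise": t.noise,
    }


def _truth_from_dict(d: dict | None) -> GroundTruth | None:
    if d is None:
        return None
    return GroundTruth(
        signed_distance=np.asarray(d["signed_distance"], dtype=float),
        noiseless_pattern=None,
        signal_weights=None if d["signal_weights"] is None
        else np.asarray(d["signal_weights"], dtype=float),
        planted_voxels=None if d["planted_voxels"] is None
        else np.asarray(d["planted_voxels"], dtype=int),
        rt_slope=d.get("rt_slope"),
        rt_intercept=d.get("rt_intercept"),
        noise=d.get("noise", {}),
    )


def save_beta_set(beta_set: BetaSet, path: str | Path,
                  ground_truth: GroundTruth | None = None) -> None:
    """Write a flat beta set as NIfTI (1 x 1 x V x scene*run) + sidecar."""
    path = Path(path)
    s, r, v = beta_set.values.shape
    data = np.moveaxis(beta_set.values.reshape(s * r, v), 0, -1)[None, None]
    nib.save(nib.Nifti1Image(data.astype(np.float64), np.eye(4)), str(path))
    sidecar = {
        "n_scenes": s, "n_runs": r, "n_voxels": v,
        "design": _design_to_dict(beta_set.design),
        "ground_truth": _truth_to_dict(ground_truth),
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def load_beta_set(path: str | Path) -> tuple[BetaSet, GroundTruth | None]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    img = np.asarray(nib.load(str(path)).dataobj)
    s, r, v = sidecar["n_scenes"], sidecar["n_runs"], sidecar["n_voxels"]
    values = np.moveaxis(img[0, 0], -1, 0).reshape(s, r, v)
    return (BetaSet(values, _design_from_dict(sidecar["design"])),
            _truth_from_dict(sidecar["ground_truth"]))


def save_volumetric(dataset: VolumetricDataset, path: str | Path,
                    ground_truth: GroundTruth | None = None) -> None:
    """Write a volumetric beta set (nx x ny x nz x scene*run) + mask + sidecar."""
    path = Path(path)
    s, r, v = dataset.betas.values.shape
    grid = dataset.grid_shape
    data = np.zeros(grid + (s * r,))
    flat = dataset.betas.values.reshape(s * r, v)
    data[tuple(dataset.voxel_coords.T)] = np.moveaxis(flat, 0, -1)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    stem = path.with_suffix("").with_suffix("")
    nib.save(nib.Nifti1Image(dataset.brain_mask.astype(np.uint8), np.eye(4)),
             str(stem) + "_mask.nii")
    sidecar = {
        "n_scenes": s, "n_runs": r,
        "design": _design_to_dict(dataset.betas.design),
        "ground_truth": _truth_to_dict(ground_truth),
        "planted_mask": None if dataset.planted_mask is None
        else dataset.planted_mask.astype(int).tolist(),
    }
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def load_volumetric(path: str | Path) -> tuple[VolumetricDataset, GroundTruth | None]:
    path = Path(path)
    stem = path.with_suffix("").with_suffix("")
    sidecar = json.loads(Path(str(stem) + ".json").read_text())
    img = np.asarray(nib.load(str(path)).dataobj)
    mask = np.asarray(nib.load(str(stem) + "_mask.nii").dataobj).astype(bool)
    coords = np.argwhere(mask)
    s, r = sidecar["n_scenes"], sidecar["n_runs"]
    flat = img[tuple(coords.T)]                      # (v, s*r)
    values = np.moveaxis(flat, -1, 0).reshape(s, r, coords.shape[0])
    planted = (None if sidecar["planted_mask"] is None
               else np.asarray(sidecar["planted_mask"], dtype=bool))
    betas = BetaSet(values, _design_from_dict(sidecar["design"]))
    return (VolumetricDataset(betas, img.shape[:3], mask, coords, planted),
            _truth_from_dict(sidecar["ground_truth"]))


def save_rt_table(table: pd.DataFrame, path: str | Path) -> None:
    write_tsv(table[["subject", "scene_id", "task", "correct", "rt"]], path)


def load_rt_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    t["correct"] = t["correct"].astype(bool)
    return t


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), np.eye(4)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV: fixed float format, LF line endings, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")
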