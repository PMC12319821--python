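"""First-level GLM estimation with per-voxel HRF selection, and ROI definition.

Scene regressors are boxcars at the event onsets/durations, convolved with a
hemodynamic response function at a micro-time resolution of TR/16 and sampled
at scan times.  The GLM is refit once per member of an HRF kernel library and,
per voxel, the betas from the member with the minimum mean squared residual
are retained (ties broken toward the lowest library index).  ROIs are defined
as the overlap of an atlas mask with a suprathreshold localizer t-map, with
voxels shared between ROIs excluded from all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

__all__ = [
    "HRFLibrary",
    "GLMFit",
    "double_gamma_hrf",
    "default_hrf_library",
    "build_design_matrix",
    "fit_glm",
    "select_hrf",
    "define_rois",
]

MICROTIME_FACTOR = 16  # micro-time bins per TR for convolution


@dataclass(frozen=True)
class HRFLibrary:
    """Ordered set of HRF kernels sharing sampling rate and length."""

    kernels: np.ndarray  # (n_hrfs, n_timepoints)
    dt: float            # sampling interval in seconds

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=float)
        if k.ndim != 2 or k.shape[0] < 1:
            raise ValueError("kernels must be a non-empty (n_hrfs, n_timepoints) array")
        if not np.all(np.isfinite(k)):
            raise ValueError("HRF kernels must be finite")

    def __len__(self) -> int:
        return self.kernels.shape[0]


@dataclass
class GLMFit:
    """Least-squares GLM estimates per voxel."""

    betas: np.ndarray           # (n_regressors, n_voxels)
    residual_mean: np.ndarray   # (n_voxels,) mean squared residual
    hrf_index: np.ndarray | None = None  # chosen library index per voxel
    regressor_names: list[str] | None = None


def double_gamma_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
    u_dispersion: float = 1.0,
    duration: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at interval ``dt``, peak-normalized."""
    t = np.arange(0, duration, dt)
    peak = scipy.stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    under = scipy.stats.gamma.pdf(t, undershoot_delay / u_dispersion, scale=u_dispersion)
    h = peak - undershoot_ratio * under
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def default_hrf_library(tr: float, n_delays: int = 10) -> HRFLibrary:
    """Parametric double-gamma family: 20 kernels varying peak delay 4-8 s
    and undershoot ratio, sampled at the micro-time resolution TR/16."""
    dt = tr / MICROTIME_FACTOR
    kernels = [
        double_gamma_hrf(dt, peak_delay=d, undershoot_ratio=r)
        for r in (1.0 / 6.0, 1.0 / 3.0)
        for d in np.linspace(4.0, 8.0, n_delays)
    ]
    return HRFLibrary(np.stack(kernels), dt)


def load_hrf_library(path: str, dt: float) -> HRFLibrary:
    """Load user-supplied kernels from a whitespace-delimited text file
    (one kernel per row)."""
    return HRFLibrary(np.atleast_2d(np.loadtxt(path)), dt)


def _as_events(events) -> pd.DataFrame:
    ev = pd.DataFrame(events)
    required = {"onset", "duration", "scene_id"}
    if not required.issubset(ev.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    if np.any(np.diff(ev["onset"].to_numpy()) < 0):
        raise ValueError("event onsets must be non-decreasing")
    if np.any(ev["duration"].to_numpy() <= 0):
        raise ValueError("event durations must be > 0")
    return ev


def build_design_matrix(
    events,
    hrf: np.ndarray,
    tr: float,
    n_scans: int,
    nuisance_regressors: np.ndarray | None = None,
    scene_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build a (scan x regressor) design matrix.

    One column per scene (boxcar convolved with ``hrf`` on a TR/16 micro-time
    grid, sampled at scan times), followed by nuisance columns and a trailing
    intercept.  ``hrf`` must be sampled at dt = tr/16.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    ev = _as_events(events)
    scan_dur = n_scans * tr
    if np.any(ev["onset"].to_numpy() + ev["duration"].to_numpy() > scan_dur + 1e-9):
        raise ValueError("an event extends beyond the scan window")

    dt = tr / MICROTIME_FACTOR
    n_micro = n_scans * MICROTIME_FACTOR
    if scene_ids is None:
        scene_ids = np.unique(ev["scene_id"].to_numpy())
    scan_bins = (np.arange(n_scans) * MICROTIME_FACTOR).astype(int)

    cols, names = [], []
    for sid in scene_ids:
        box = np.zeros(n_micro)
        for _, row in ev[ev["scene_id"] == sid].iterrows():
            i0 = int(np.round(row["onset"] / dt))
            i1 = max(i0 + 1, int(np.round((row["onset"] + row["duration"]) / dt)))
            box[i0:min(i1, n_micro)] = 1.0
        conv = np.convolve(box, hrf)[:n_micro]
        cols.append(conv[scan_bins])
        names.append(f"scene_{sid}")

    X = np.column_stack(cols) if cols else np.empty((n_scans, 0))
    if nuisance_regressors is not None:
        nuis = np.atleast_2d(np.asarray(nuisance_regressors, dtype=float))
        if nuis.shape[0] != n_scans:
            nuis = nuis.T
        if nuis.shape[0] != n_scans:
            raise ValueError("nuisance regressors must have n_scans rows")
        X = np.column_stack([X, nuis])
        names += [f"nuisance_{i}" for i in range(nuis.shape[1])]
    X = np.column_stack([X, np.ones(n_scans)])
    names.append("intercept")
    return X, names


def fit_glm(
    timeseries: np.ndarray,
    design_matrix: np.ndarray,
    regressor_names: list[str] | None = None,
) -> GLMFit:
    """Ordinary least squares fit of ``timeseries`` (scan x voxel) on the design.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    Y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if Y.shape[0] != design_matrix.shape[0]:
        Y = Y.T
    n_scans, n_reg = design_matrix.shape
    if n_scans <= n_reg:
        raise ValueError("need more scans than regressors")

    rank = np.linalg.matrix_rank(design_matrix)
    if rank < n_reg:
        # name columns beyond the rank in a pivoted QR as the collinear set
        _, _, piv = scipy.linalg.qr(design_matrix, pivoting=True)
        bad = sorted(piv[rank:].tolist())
        labels = [regressor_names[i] if regressor_names else str(i) for i in bad]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {labels}")

    betas, _, _, _ = np.linalg.lstsq(design_matrix, Y, rcond=None)
    resid = Y - design_matrix @ betas
    return GLMFit(betas=betas, residual_mean=np.mean(resid**2, axis=0),
                  regressor_names=regressor_names)


def select_hrf(
    timeseries: np.ndarray,
    events,
    hrf_library: HRFLibrary,
    tr: float,
    nuisance_regressors: np.ndarray | None = None,
    scene_ids: np.ndarray | None = None,
) -> GLMFit:
    """Refit the GLM once per library kernel; per voxel, keep the betas from
    the kernel with the minimum mean squared residual (ties -> lowest index)."""
    if len(hrf_library) < 1:
        raise ValueError("HRF library is empty")
    Y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    n_scans = Y.shape[0]

    best = None
    names = None
    for k in range(len(hrf_library)):
        X, names = build_design_matrix(events, hrf_library.kernels[k], tr, n_scans,
                                       nuisance_regressors, scene_ids)
        fit = fit_glm(Y, X, names)
        if best is None:
            best_betas = fit.betas.copy()
            best_resid = fit.residual_mean.copy()
            best_idx = np.zeros(Y.shape[1], dtype=int)
            best = True
        else:
            better = fit.residual_mean < best_resid  # strict: ties keep lower index
            best_betas[:, better] = fit.betas[:, better]
            best_resid[better] = fit.residual_mean[better]
            best_idx[better] = k
    return GLMFit(betas=best_betas, residual_mean=best_resid, hrf_index=best_idx,
                  regressor_names=names)


def define_rois(
    atlas_masks: dict[str, np.ndarray],
    t_maps: dict[str, np.ndarray],
    p_threshold: float = 1e-4,
    df: int | None = None,
) -> dict[str, np.ndarray]:
    """ROI = atlas mask overlap with one-sided suprathreshold localizer t-map.

    Voxels that survive thresholding in more than one ROI are removed from
    all of them, so the returned masks are pairwise disjoint.  An ROI left
    empty after exclusion triggers a warning, not an error.
    """
    if set(atlas_masks) != set(t_maps):
        raise ValueError("atlas_masks and t_maps must share ROI names")
    if df is None or df < 1:
        raise ValueError("df (degrees of freedom of the t-maps) is required")

    rois: dict[str, np.ndarray] = {}
    for name, atlas in atlas_masks.items():
        atlas = np.asarray(atlas, dtype=bool)
        t = np.asarray(t_maps[name], dtype=float)
        if t.shape != atlas.shape:
            raise ValueError(f"t-map and atlas mask shapes differ for {name!r}")
        p = scipy.stats.t.sf(t, df)  # one-sided: directional contrasts
        rois[name] = atlas & (p < p_threshold)

    counts = np.zeros_like(next(iter(rois.values())), dtype=int)
    for m in rois.values():
        counts += m.astype(int)
    shared = counts > 1
    out = {}
    for name, m in rois.items():
        final = m & ~shared
        if not final.any():
            warnings.warn(f"ROI {name!r} is empty after thresholding/exclusion")
        out[name] = final
    return out
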