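"""Neural dimensionality: searchlight-PCA component counts across participants.

For one trial and one local voxel neighbourhood, participants' patterns are
stacked into a participants x voxels matrix; after column centring, the
dimensionality is the smallest number of principal components whose
cumulative explained variance strictly exceeds the criterion. High counts
mean heterogeneous, participant-specific coding; low counts mean a shared
low-dimensional response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .io import ParcellationAtlas, TrialPatternSet
from .stats import bh_fdr, wilcoxon_rank_sum


@dataclass
class DimensionalityMap:
    """Component counts per location and trial (one map per threshold)."""

    values: np.ndarray           # locations x trials (int)
    threshold: float
    location_kind: str           # "voxel" | "parcel"
    location_ids: np.ndarray     # centre voxel index or parcel id
    searchlight_radius: int | None = None
    skipped: list = field(default_factory=list)


@dataclass
class DimensionalityContrast:
    difference: np.ndarray       # mean(weak) - mean(strong) per location
    p_values: np.ndarray
    fdr_mask: np.ndarray
    adjusted_p: np.ndarray
    q: float


def count_components(stack: np.ndarray, thresholds: tuple[float, ...]) -> np.ndarray:
    """Smallest m with cumulative variance ratio > threshold, per threshold.

    ``stack`` is participants x voxels; columns are mean-centred across
    participants before the spectrum is taken, so "variance" refers to
    between-participant variance at each voxel.
    """
    x = np.asarray(stack, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    xc = x - x.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(xc, compute_uv=False)
    var = sv ** 2
    total = var.sum()
    out = np.empty(len(thresholds), dtype=int)
    if total == 0:
        out[:] = 1
        return out
    cum = np.cumsum(var) / total
    for j, t in enumerate(thresholds):
        above = np.nonzero(cum > t + 1e-12)[0]
        out[j] = int(above[0]) + 1 if len(above) else len(cum)
    return out


def _cube_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    return np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)


def searchlight_dimensionality(
    pattern_sets: list[TrialPatternSet],
    atlas: ParcellationAtlas,
    thresholds: tuple[float, ...] = (0.60, 0.75, 0.90),
    radius: int = 2,
    trial_indices: np.ndarray | None = None,
    min_in_mask: float = 0.5,
) -> list[DimensionalityMap]:
    """Cube-searchlight component counts at every in-mask voxel.

    Centres whose cube has fewer than ``min_in_mask`` of its voxels inside
    the mask are skipped and logged. Returns one map per threshold (same
    centre ordering).
    """
    if len(pattern_sets) < 2:
        raise ValueError("need at least 2 participants")
    coords, labels = atlas.voxel_table()
    n_vox = len(labels)
    index_vol = -np.ones(atlas.label_volume.shape, dtype=int)
    index_vol[tuple(coords.T)] = np.arange(n_vox)
    offsets = _cube_offsets(radius)
    cube_size = len(offsets)
    shape = np.array(atlas.label_volume.shape)

    T = pattern_sets[0].patterns.shape[0]
    trial_indices = np.arange(T) if trial_indices is None else np.asarray(trial_indices)
    stack_all = np.stack([ps.patterns for ps in pattern_sets])  # N x T x vox

    centres = []
    neighbourhoods = []
    skipped = []
    for v in range(n_vox):
        pos = coords[v][None, :] + offsets
        inside = np.all((pos >= 0) & (pos < shape[None, :]), axis=1)
        cols = index_vol[tuple(pos[inside].T)]
        cols = cols[cols >= 0]
        if len(cols) < min_in_mask * cube_size:
            skipped.append(int(v))
            continue
        centres.append(v)
        neighbourhoods.append(cols)

    values = np.empty((len(thresholds), len(centres), len(trial_indices)), dtype=int)
    for ci, cols in enumerate(neighbourhoods):
        block = stack_all[:, :, cols]
        for tj, t in enumerate(trial_indices):
            values[:, ci, tj] = count_components(block[:, t, :], thresholds)
    return [
        DimensionalityMap(
            values=values[j], threshold=t, location_kind="voxel",
            location_ids=np.array(centres), searchlight_radius=radius,
            skipped=skipped,
        )
        for j, t in enumerate(thresholds)
    ]


def parcel_dimensionality(
    pattern_sets: list[TrialPatternSet],
    atlas: ParcellationAtlas,
    thresholds: tuple[float, ...] = (0.60, 0.75, 0.90),
    trial_indices: np.ndarray | None = None,
) -> list[DimensionalityMap]:
    """Component counts using each parcel's own voxels as the neighbourhood."""
    if len(pattern_sets) < 2:
        raise ValueError("need at least 2 participants")
    T = pattern_sets[0].patterns.shape[0]
    trial_indices = np.arange(T) if trial_indices is None else np.asarray(trial_indices)
    stack_all = np.stack([ps.patterns for ps in pattern_sets])
    v2p = pattern_sets[0].voxel_to_parcel
    values = np.empty((len(thresholds), atlas.n_parcels, len(trial_indices)), dtype=int)
    for i, pid in enumerate(atlas.parcel_ids):
        cols = np.where(v2p == pid)[0]
        block = stack_all[:, :, cols]
        for tj, t in enumerate(trial_indices):
            values[:, i, tj] = count_components(block[:, t, :], thresholds)
    return [
        DimensionalityMap(
            values=values[j], threshold=t, location_kind="parcel",
            location_ids=atlas.parcel_ids.copy(),
        )
        for j, t in enumerate(thresholds)
    ]


def parcel_aggregate(
    dim_map: DimensionalityMap, atlas: ParcellationAtlas
) -> tuple[np.ndarray, list]:
    """Mean of centre-voxel counts within each parcel (voxel-kind maps)."""
    if dim_map.location_kind != "voxel":
        raise ValueError("parcel_aggregate expects a voxel-kind map")
    coords, labels = atlas.voxel_table()
    centre_parcels = labels[dim_map.location_ids]
    out = np.full((atlas.n_parcels, dim_map.values.shape[1]), np.nan)
    notes = []
    for i, pid in enumerate(atlas.parcel_ids):
        rows = centre_parcels == pid
        if not rows.any():
            notes.append(f"parcel {pid}: no retained searchlight centres")
            continue
        out[i] = dim_map.values[rows].mean(axis=0)
    return out, notes


def sliding_window_profile(
    parcel_dim: np.ndarray,
    word2vec: np.ndarray,
    reference_gradient: np.ndarray,
    window: int = 4,
) -> dict:
    """Window-averaged dimensionality maps correlated with a reference map.

    Trials are ordered by ascending association strength and averaged in
    consecutive non-overlapping windows; each window's mean map is
    correlated (Pearson) with the reference gradient. The trend statistic
    is the correlation of window r values with window-mean word2vec.
    """
    dim = np.asarray(parcel_dim, dtype=float)
    w2v = np.asarray(word2vec, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    T = dim.shape[1]
    if window > T:
        raise ValueError("window exceeds the number of trials")
    order = np.argsort(w2v, kind="stable")
    n_win = T // window
    rs = np.empty(n_win)
    w_means = np.empty(n_win)
    for k in range(n_win):
        idx = order[k * window:(k + 1) * window]
        mean_map = dim[:, idx].mean(axis=1)
        if np.std(mean_map) == 0 or np.std(reference_gradient) == 0:
            rs[k] = np.nan      # flat map in this window; no correlation defined
        else:
            rs[k] = sp_stats.pearsonr(mean_map, reference_gradient).statistic
        w_means[k] = w2v[idx].mean()
    ok = np.isfinite(rs)
    if ok.sum() >= 3 and np.std(rs[ok]) > 0:
        trend = sp_stats.pearsonr(rs[ok], w_means[ok])
        trend_r, trend_p = float(trend.statistic), float(trend.pvalue)
    else:
        trend_r, trend_p = float("nan"), float("nan")
    return {
        "window_r": rs, "window_word2vec": w_means,
        "trend_r": trend_r, "trend_p": trend_p, "window": window,
    }


def dimensionality_contrast(
    parcel_dim: np.ndarray,
    trial_ids: np.ndarray,
    weak_ids: np.ndarray,
    strong_ids: np.ndarray,
    q: float = 0.05,
) -> DimensionalityContrast:
    """Weak-minus-strong dimensionality with Wilcoxon tests and BH-FDR.

    The difference direction follows the convention of subtracting strong
    from weak, so planted extra weak-condition dimensions appear positive.
    """
    weak_ids = np.asarray(weak_ids)
    strong_ids = np.asarray(strong_ids)
    if len(np.intersect1d(weak_ids, strong_ids)):
        raise ValueError("weak and strong trial sets overlap")
    wi = np.where(np.isin(trial_ids, weak_ids))[0]
    si = np.where(np.isin(trial_ids, strong_ids))[0]
    if len(wi) < 2 or len(si) < 2:
        raise ValueError("each condition needs at least 2 trials")
    dim = np.asarray(parcel_dim, dtype=float)
    diff = dim[:, wi].mean(axis=1) - dim[:, si].mean(axis=1)
    p = np.empty(dim.shape[0])
    for loc in range(dim.shape[0]):
        p[loc] = wilcoxon_rank_sum(dim[loc, wi], dim[loc, si]).p
    mask, adjusted = bh_fdr(p, q)
    return DimensionalityContrast(
        difference=diff, p_values=p, fdr_mask=mask, adjusted_p=adjusted, q=q
    )
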