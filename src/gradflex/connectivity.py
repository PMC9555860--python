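"""Informational connectivity: similarity of between-trial similarity.

A parcel's representational geometry is summarised by its between-trial
multivoxel pattern-similarity matrix. Informational connectivity between
two parcels is the correlation of their similarity structures over usable
trial pairs; within-run pairs are excluded so temporal autocorrelation
cannot masquerade as shared geometry. A conventional time-series
correlation matrix is provided as the control measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_CLIP = 1.0 - 1e-6


@dataclass
class TrialSimilarity:
    """Between-trial pattern similarity for one parcel."""

    parcel_id: int
    matrix: np.ndarray        # trials x trials, symmetric, unit diagonal
    valid_mask: np.ndarray    # trials x trials bool; between-run pairs only

    def valid_values(self) -> np.ndarray:
        """Upper-triangle similarity values at valid pairs (fixed order)."""
        iu = np.triu_indices(self.matrix.shape[0], 1)
        keep = self.valid_mask[iu]
        return self.matrix[iu][keep]


@dataclass
class ICMatrix:
    """Parcel-by-parcel informational connectivity."""

    matrix: np.ndarray
    parcel_ids: np.ndarray
    condition_label: str = "all"
    participant_id: str = "group"
    n_valid_pairs: int = 0


def _rankdata_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def trial_similarity(
    patterns: np.ndarray,
    run_labels: np.ndarray,
    parcel_id: int = 0,
    method: str = "pearson",
) -> TrialSimilarity:
    """Correlate every pair of trial patterns across voxels.

    Raises if any trial pattern has zero variance (a correlation would be
    undefined; silent NaNs corrupt everything downstream).
    """
    x = np.asarray(patterns, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 voxels")
    sd = x.std(axis=1)
    tol = 1e-12 * (1.0 + np.abs(x).max())
    if np.any(sd <= tol):
        bad = int(np.where(sd <= tol)[0][0])
        raise ValueError(f"trial {bad} has zero pattern variance")
    if method == "spearman":
        x = _rankdata_rows(x)
    xc = x - x.mean(axis=1, keepdims=True)
    xc /= np.linalg.norm(xc, axis=1, keepdims=True)
    sim = np.clip(xc @ xc.T, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    runs = np.asarray(run_labels)
    valid = runs[:, None] != runs[None, :]
    return TrialSimilarity(parcel_id=parcel_id, matrix=sim, valid_mask=valid)


def ic_matrix(
    similarities: list[TrialSimilarity],
    fisher_z: bool = True,
    condition_label: str = "all",
    participant_id: str = "group",
) -> ICMatrix:
    """Correlate valid-pair similarity vectors between every parcel pair."""
    if not similarities:
        raise ValueError("empty similarity list")
    vecs = np.stack([s.valid_values() for s in similarities])
    n_pairs = vecs.shape[1]
    if n_pairs < 3:
        raise ValueError("fewer than 3 valid trial pairs")
    sd = vecs.std(axis=1)
    tol = 1e-12 * (1.0 + np.abs(vecs).max())
    if np.any(sd <= tol):
        bad = similarities[int(np.where(sd <= tol)[0][0])].parcel_id
        raise ValueError(f"parcel {bad} has a constant similarity vector")
    if fisher_z:
        vecs = np.arctanh(np.clip(vecs, -_CLIP, _CLIP))
    vc = vecs - vecs.mean(axis=1, keepdims=True)
    vc /= np.linalg.norm(vc, axis=1, keepdims=True)
    ic = np.clip(vc @ vc.T, -1.0, 1.0)
    np.fill_diagonal(ic, 1.0)
    return ICMatrix(
        matrix=ic,
        parcel_ids=np.array([s.parcel_id for s in similarities]),
        condition_label=condition_label,
        participant_id=participant_id,
        n_valid_pairs=n_pairs,
    )


def participant_ic(
    pattern_set,
    trial_subset: np.ndarray | None = None,
    fisher_z: bool = True,
    condition_label: str = "all",
    method: str = "pearson",
    parcel_ids: np.ndarray | None = None,
) -> ICMatrix:
    """Informational connectivity for one participant.

    ``trial_subset`` selects trials by id (e.g. one association tercile).
    """
    pats = pattern_set.patterns
    runs = pattern_set.run_labels
    if trial_subset is not None:
        keep = np.isin(pattern_set.trial_ids, trial_subset)
        pats = pats[keep]
        runs = runs[keep]
    if parcel_ids is None:
        parcel_ids = np.unique(pattern_set.voxel_to_parcel)
        parcel_ids = parcel_ids[parcel_ids > 0]
    sims = []
    for pid in parcel_ids:
        cols = pattern_set.voxel_to_parcel == pid
        sims.append(
            trial_similarity(pats[:, cols], runs, parcel_id=int(pid), method=method)
        )
    return ic_matrix(
        sims, fisher_z=fisher_z, condition_label=condition_label,
        participant_id=pattern_set.participant_id,
    )


def group_average(ic_list: list[ICMatrix], fisher_z: bool = True) -> ICMatrix:
    """Element-wise Fisher-z mean of participant matrices, back-transformed."""
    if not ic_list:
        raise ValueError("empty IC list")
    first = ic_list[0]
    mats = np.stack([m.matrix for m in ic_list])
    if fisher_z:
        z = np.arctanh(np.clip(mats, -_CLIP, _CLIP))
        avg = np.tanh(z.mean(axis=0))
    else:
        avg = mats.mean(axis=0)
    np.fill_diagonal(avg, 1.0)
    return ICMatrix(
        matrix=avg,
        parcel_ids=first.parcel_ids,
        condition_label=first.condition_label,
        participant_id="group",
        n_valid_pairs=first.n_valid_pairs,
    )


def timeseries_connectivity(
    mean_series: np.ndarray, parcel_ids: np.ndarray | None = None
) -> ICMatrix:
    """Pearson correlation of parcel-mean series: the conventional control."""
    x = np.asarray(mean_series, dtype=float)   # parcels x timepoints
    sd = x.std(axis=1)
    tol = 1e-12 * (1.0 + np.abs(x).max())
    if np.any(sd <= tol):
        bad = int(np.where(sd <= tol)[0][0])
        raise ValueError(f"parcel index {bad} has a constant time series")
    xc = x - x.mean(axis=1, keepdims=True)
    xc /= np.linalg.norm(xc, axis=1, keepdims=True)
    fc = np.clip(xc @ xc.T, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    if parcel_ids is None:
        parcel_ids = np.arange(1, x.shape[0] + 1)
    return ICMatrix(
        matrix=fc, parcel_ids=np.asarray(parcel_ids),
        condition_label="timeseries", participant_id="group",
        n_valid_pairs=x.shape[1],
    )
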