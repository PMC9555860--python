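"""Second-order RSA: aligning inter-participant rating similarity with
inter-participant neural-pattern similarity.

The semantic model correlates participants' trial-rating vectors; the
brain model, at each location, correlates participants' vectorised
trial-pair similarity structures. Their second-order correlation (Fisher
z) per location is the semantic-brain alignment map. Because entries of a
participants x participants similarity matrix are not independent,
per-location significance uses a Mantel-style permutation of participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import TrialSimilarity
from .stats import bh_fdr

_CLIP = 1.0 - 1e-6


@dataclass
class ParticipantSimilarityModel:
    matrix: np.ndarray             # participants x participants
    kind: str                      # "semantic" | "brain"
    location: int | None = None    # parcel id / centre index for brain models

    def lower_triangle(self) -> np.ndarray:
        il = np.tril_indices(self.matrix.shape[0], -1)
        return self.matrix[il]


@dataclass
class AlignmentMap:
    values: np.ndarray             # Fisher-z alignment per location
    location_ids: np.ndarray
    p_values: np.ndarray | None = None
    fdr_mask: np.ndarray | None = None
    degenerate: list = field(default_factory=list)


def _corr_rows(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = int(np.where(norms[:, 0] == 0)[0][0])
        raise ValueError(f"row {bad} is constant; correlation undefined")
    xc = xc / norms
    out = np.clip(xc @ xc.T, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out


def semantic_model(ratings: np.ndarray) -> ParticipantSimilarityModel:
    """Pairwise Pearson correlation of participants' rating vectors."""
    r = np.asarray(ratings, dtype=float)
    if r.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    try:
        m = _corr_rows(r)
    except ValueError as err:
        raise ValueError(f"constant rating vector: participant {err}") from None
    return ParticipantSimilarityModel(matrix=m, kind="semantic")


def brain_model(
    similarities: list[TrialSimilarity], location: int | None = None
) -> ParticipantSimilarityModel:
    """Correlate participants' valid-pair similarity vectors at a location."""
    vecs = np.stack([s.valid_values() for s in similarities])
    if vecs.shape[1] < 3:
        raise ValueError("fewer than 3 valid trial pairs")
    m = _corr_rows(vecs)
    return ParticipantSimilarityModel(matrix=m, kind="brain", location=location)


def second_order_alignment(
    semantic: ParticipantSimilarityModel,
    brain_models: list[ParticipantSimilarityModel],
) -> AlignmentMap:
    """Fisher-z correlation between semantic and brain model lower triangles."""
    sem = semantic.lower_triangle()
    values = np.full(len(brain_models), np.nan)
    degenerate = []
    ids = []
    for j, bm in enumerate(brain_models):
        if bm.matrix.shape != semantic.matrix.shape:
            raise ValueError("participant sets differ between models")
        ids.append(bm.location if bm.location is not None else j)
        vec = bm.lower_triangle()
        if np.std(vec) == 0 or np.std(sem) == 0:
            degenerate.append(ids[-1])
            continue
        r = np.corrcoef(sem, vec)[0, 1]
        values[j] = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return AlignmentMap(
        values=values, location_ids=np.array(ids), degenerate=degenerate
    )


def alignment_significance(
    alignment: AlignmentMap,
    semantic: ParticipantSimilarityModel,
    brain_models: list[ParticipantSimilarityModel],
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int = 0,
) -> AlignmentMap:
    """Mantel permutation p per location plus a BH-FDR mask.

    The semantic model's rows and columns are permuted simultaneously
    (participant relabelling); the same permutation set is used at every
    location, and p = (1 + #{|z_perm| >= |z_obs|}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n_sub = semantic.matrix.shape[0]
    rng = np.random.default_rng(seed)
    il = np.tril_indices(n_sub, -1)

    perms = np.stack([rng.permutation(n_sub) for _ in range(n_perm)])
    sem_perm = np.stack([
        semantic.matrix[np.ix_(p, p)][il] for p in perms
    ])                                               # n_perm x n_pairs
    sp_c = sem_perm - sem_perm.mean(axis=1, keepdims=True)
    sp_norm = np.linalg.norm(sp_c, axis=1, keepdims=True)
    sp_c = sp_c / sp_norm

    p_values = np.full(len(brain_models), np.nan)
    for j, bm in enumerate(brain_models):
        if not np.isfinite(alignment.values[j]):
            continue
        vec = bm.lower_triangle()
        vc = vec - vec.mean()
        vc = vc / np.linalg.norm(vc)
        null_r = sp_c @ vc
        null_z = np.arctanh(np.clip(null_r, -_CLIP, _CLIP))
        obs = alignment.values[j]
        p_values[j] = (1 + int(np.sum(np.abs(null_z) >= abs(obs)))) / (1 + n_perm)
    finite = np.isfinite(p_values)
    mask = np.zeros(len(p_values), dtype=bool)
    if finite.any():
        mask[finite], _ = bh_fdr(p_values[finite], q)
    return AlignmentMap(
        values=alignment.values,
        location_ids=alignment.location_ids,
        p_values=p_values,
        fdr_mask=mask,
        degenerate=alignment.degenerate,
    )


def parcel_brain_models(
    pattern_sets,
    atlas,
    trial_subset: np.ndarray | None = None,
    method: str = "pearson",
) -> list[ParticipantSimilarityModel]:
    """Brain models for every parcel from participants' trial similarities."""
    from .connectivity import trial_similarity

    models = []
    for pid in atlas.parcel_ids:
        sims = []
        for ps in pattern_sets:
            pats = ps.patterns
            runs = ps.run_labels
            if trial_subset is not None:
                keep = np.isin(ps.trial_ids, trial_subset)
                pats, runs = pats[keep], runs[keep]
            cols = ps.voxel_to_parcel == pid
            sims.append(
                trial_similarity(pats[:, cols], runs, parcel_id=int(pid),
                                 method=method)
            )
        models.append(brain_model(sims, location=int(pid)))
    return models
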