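"""Connectivity gradient decomposition and condition comparison.

The pipeline mirrors the standard connectome-gradient recipe: optionally
sparsify each row of the connectivity matrix, build a cosine affinity
between connectivity profiles, and decompose the (column-centred) affinity
with PCA. Scores are deterministic: each component is sign-fixed so its
largest-magnitude entry is positive, and condition gradients are aligned
to a template before any subtraction (PCA alone leaves sign and, for
near-degenerate spectra, order undetermined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes


@dataclass
class GradientSet:
    """Ordered gradient component scores per parcel."""

    scores: np.ndarray          # P x K
    eigenvalues: np.ndarray     # K
    variance_ratio: np.ndarray  # K, non-increasing
    alignment: str = "none"     # "none" | "sign-matched" | "procrustes"
    template_id: str = ""
    condition_label: str = "all"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def principal(self) -> np.ndarray:
        return self.scores[:, 0]


@dataclass
class MapCorrelation:
    r: float
    method: str
    p_parametric: float
    p_spin: float | None = None
    n: int = 0


def sparsify_rows(matrix: np.ndarray, density: float) -> np.ndarray:
    """Keep the largest entries of each row, zero the rest.

    The diagonal is excluded from the ranking and zeroed. Per row,
    ``min(ceil(density * P), P - 1)`` off-diagonal entries survive.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    P = m.shape[0]
    out = m.copy()
    np.fill_diagonal(out, 0.0)
    if density >= 1.0:
        return out
    n_keep = min(int(np.ceil(density * P)), P - 1)
    ranked = out.copy()
    np.fill_diagonal(ranked, -np.inf)     # diagonal never competes
    result = np.zeros_like(out)
    for i in range(P):
        idx = np.argpartition(ranked[i], -n_keep)[-n_keep:]
        result[i, idx] = out[i, idx]
    return result


def cosine_affinity(matrix: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows; diagonal set to 1."""
    m = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        bad = int(np.where(norms == 0)[0][0])
        raise ValueError(f"row {bad} is all zero; cosine undefined")
    mn = m / norms[:, None]
    aff = mn @ mn.T
    np.fill_diagonal(aff, 1.0)
    return aff


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-|value| entry of each component > 0."""
    out = scores.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            out[:, k] = -col
    return out


def decompose_gradients(
    affinity: np.ndarray,
    n_components: int = 10,
    condition_label: str = "all",
) -> GradientSet:
    """PCA of the column-centred affinity matrix.

    Rows are treated as observations (one per parcel); scores are the
    projections onto the principal axes, ordered by explained variance.
    """
    a = np.asarray(affinity, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if np.max(np.abs(a - a.T)) > 1e-8:
        raise ValueError("affinity must be symmetric")
    P = a.shape[0]
    if n_components > P:
        raise ValueError("n_components exceeds matrix size")
    centred = a - a.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = _fix_signs((u * s)[:, :n_components])
    total = float(np.sum(s ** 2))
    eigenvalues = (s[:n_components] ** 2) / max(P - 1, 1)
    variance_ratio = (s[:n_components] ** 2) / total if total > 0 else s[:n_components] * 0
    return GradientSet(
        scores=scores,
        eigenvalues=eigenvalues,
        variance_ratio=variance_ratio,
        condition_label=condition_label,
    )


def gradients_from_connectivity(
    connectivity: np.ndarray,
    n_components: int = 10,
    sparsity_density: float = 1.0,
    condition_label: str = "all",
) -> GradientSet:
    """sparsify -> cosine affinity -> PCA in one call."""
    sparse = sparsify_rows(connectivity, sparsity_density)
    return decompose_gradients(
        cosine_affinity(sparse), n_components, condition_label
    )


def align_gradients(
    gradients: GradientSet,
    template: GradientSet,
    method: str = "sign",
    template_id: str = "template",
) -> GradientSet:
    """Resolve sign (and optionally rotation) indeterminacy to a template.

    ``"sign"`` flips each component so its correlation with the matching
    template component is non-negative. ``"procrustes"`` finds the best
    orthogonal rotation of the score matrix onto the template's.
    """
    if gradients.scores.shape[0] != template.scores.shape[0]:
        raise ValueError("parcel count mismatch between gradients and template")
    K = gradients.n_components
    if template.n_components < K:
        raise ValueError("template has fewer components than input")
    if method == "sign":
        scores = gradients.scores.copy()
        for k in range(K):
            r = np.corrcoef(scores[:, k], template.scores[:, k])[0, 1]
            if r < 0:
                scores[:, k] = -scores[:, k]
        alignment = "sign-matched"
    elif method == "procrustes":
        R, _ = orthogonal_procrustes(gradients.scores, template.scores[:, :K])
        scores = gradients.scores @ R
        alignment = "procrustes"
    else:
        raise ValueError(f"unknown alignment method {method!r}")
    return GradientSet(
        scores=scores,
        eigenvalues=gradients.eigenvalues,
        variance_ratio=gradients.variance_ratio,
        alignment=alignment,
        template_id=template_id,
        condition_label=gradients.condition_label,
    )


def gradient_difference(
    grad_a: GradientSet, grad_b: GradientSet, component: int = 0
) -> np.ndarray:
    """Per-parcel score difference for one component (a minus b).

    Both inputs must have been aligned to the same template; subtracting
    unaligned PCA scores is meaningless under sign indeterminacy.
    """
    for g in (grad_a, grad_b):
        if g.alignment == "none":
            raise ValueError("align both gradient sets to a template first")
    if grad_a.template_id != grad_b.template_id:
        raise ValueError("gradients aligned to different templates")
    return grad_a.scores[:, component] - grad_b.scores[:, component]


def map_correlation(
    map_a: np.ndarray, map_b: np.ndarray, method: str = "pearson"
) -> MapCorrelation:
    """Correlation between two per-parcel maps with a parametric p."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 parcels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance map")
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MapCorrelation(
        r=float(res.statistic), method=method,
        p_parametric=float(res.pvalue), n=len(a),
    )
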