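"""Inference utilities: spin permutation, FDR, rank tests, rm-ANOVA,
network contrasts, and bootstrap mediation.

Spatial maps on a parcellated sphere are spatially autocorrelated, so
map-to-map correlations are tested with spin permutations (random 3-D
rotations of one map's parcel assignment). Exchangeability-based tests
(Wilcoxon, Mantel, bootstrap) are implemented with explicit tie and
permutation-count handling so small samples stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class SpinNull:
    observed_r: float
    null_rs: np.ndarray
    p_spin: float
    seed: int
    n_perm: int


@dataclass
class StatResult:
    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    effect_size: float | None = None
    correction: str = "none"


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    proportion_mediated: float
    n_boot: int
    seed: int
    boot_indirect: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


# ---------------------------------------------------------------------------
# Fisher z
# ---------------------------------------------------------------------------


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1; clip before transforming")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# spin permutation test
# ---------------------------------------------------------------------------


def spin_permutation_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    sphere_coords: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    method: str = "pearson",
) -> SpinNull:
    """Two-tailed spin test of the correlation between two parcel maps.

    ``map_b`` is re-assigned by nearest centroid under ``n_perm`` uniform
    random rotations of the sphere; the two-tailed p compares |r| against
    that rotation null, with the +1 correction so p is never zero.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    coords = np.asarray(sphere_coords, dtype=float)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if np.any(np.abs(np.linalg.norm(coords, axis=1) - 1.0) > 1e-6):
        raise ValueError("sphere coordinates must be unit-norm")

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        return stats.pearsonr(x, y).statistic

    observed = float(corr(a, b))
    rng = np.random.default_rng(seed)
    rotations = Rotation.random(n_perm, random_state=rng)
    tree = cKDTree(coords)
    # rotate per permutation; one batched nearest-centroid query
    all_rotated = np.einsum("nij,pj->npi", rotations.as_matrix(), coords)
    _, idx = tree.query(all_rotated.reshape(-1, 3), k=1)
    idx = idx.reshape(n_perm, -1)
    b_perm = b[idx]                                    # n_perm x P
    if method == "spearman":
        a_use = stats.rankdata(a)
        b_use = stats.rankdata(b_perm, axis=1)
    else:
        a_use, b_use = a, b_perm
    ac = a_use - a_use.mean()
    ac /= np.linalg.norm(ac)
    bc = b_use - b_use.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(bc, axis=1)
    norms[norms == 0] = np.inf
    null_rs = (bc @ ac) / norms
    p = (1 + int(np.sum(np.abs(null_rs) >= abs(observed)))) / (1 + n_perm)
    return SpinNull(
        observed_r=observed, null_rs=null_rs, p_spin=float(p),
        seed=seed, n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all assignments (midranks for ties)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n = len(combined)
    nx = len(x)
    observed = ranks[:nx].sum()
    sums = np.array([
        ranks[list(c)].sum() for c in combinations(range(n), nx)
    ])
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= abs(observed - mean) - 1e-12)
    return float(observed), float(p)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-sided rank-sum test.

    Exact enumeration when the pooled sample is small (n <= 12), normal
    approximation with tie correction otherwise. Identical constant
    samples return p = 1 with a zero effect size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return StatResult("wilcoxon_rank_sum", 0.0, None, 1.0, effect_size=0.0)
    nx, ny = len(x), len(y)
    # rank-biserial effect size from the Mann-Whitney U statistic
    ranks = stats.rankdata(pooled)
    u = ranks[:nx].sum() - nx * (nx + 1) / 2
    rank_biserial = 2 * u / (nx * ny) - 1
    if nx + ny <= 12:
        statistic, p = _exact_rank_sum_p(x, y)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        statistic, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        "wilcoxon_rank_sum", statistic, None, float(min(p, 1.0)),
        effect_size=float(rank_biserial),
    )


# ---------------------------------------------------------------------------
# network contrasts
# ---------------------------------------------------------------------------


def network_contrast(
    parcel_map: np.ndarray,
    atlas,
    comparisons: list[tuple[str, str]] | None = None,
    excluded_networks: tuple[str, ...] = (),
) -> dict:
    """Per-network means +- SE across parcels and Bonferroni pairwise tests."""
    networks = sorted(
        {v for v in atlas.network_labels.values() if v and v != "other"}
        - set(excluded_networks)
    )
    values = {}
    for name in networks:
        idx = atlas.network_members(name)
        if len(idx) >= 2:
            values[name] = np.asarray(parcel_map, dtype=float)[idx]
    if len(values) < 2:
        raise ValueError("need at least two networks with >= 2 parcels")
    if comparisons is None:
        comparisons = list(combinations(sorted(values), 2))
    summary = {
        name: {
            "mean": float(v.mean()),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "n_parcels": int(len(v)),
        }
        for name, v in values.items()
    }
    m = len(comparisons)
    tests = []
    for n1, n2 in comparisons:
        if n1 not in values or n2 not in values:
            raise ValueError(f"unknown network in comparison ({n1}, {n2})")
        v1, v2 = values[n1], values[n2]
        if np.var(v1) == 0 and np.var(v2) == 0 and v1.mean() == v2.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(v1, v2)
        tests.append(
            StatResult(
                f"{n1}_vs_{n2}", float(t),
                float(len(v1) + len(v2) - 2), float(min(1.0, p * m)),
                correction="bonferroni",
            )
        )
    return {"summary": summary, "tests": tests}


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------


def _gg_epsilon(contrast_scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject scores on effect contrasts."""
    if contrast_scores.shape[1] == 1:
        return 1.0
    cov = np.cov(contrast_scores, rowvar=False)
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0, None)
    denom = contrast_scores.shape[1] * np.sum(eig ** 2)
    if denom <= 0:
        return 1.0
    return float(min(1.0, np.sum(eig) ** 2 / denom))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast basis (Helmert, normalised)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
    return c / np.linalg.norm(c, axis=0, keepdims=True)


def rm_anova_2way(values: np.ndarray) -> dict[str, StatResult]:
    """Balanced two-way within-subject ANOVA.

    ``values`` is participants x levels(A) x levels(B), complete. Returns
    main effects and the interaction with Greenhouse-Geisser-corrected
    degrees of freedom and p values, plus partial eta squared.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be participants x A x B")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells in the design")
    n, a, b = y.shape
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    A = y.mean(axis=(0, 2))
    B = y.mean(axis=(0, 1))
    AB = y.mean(axis=0)
    sA = y.mean(axis=2)     # n x a
    sB = y.mean(axis=1)     # n x b

    ss_a = n * b * np.sum((A - grand) ** 2)
    ss_b = n * a * np.sum((B - grand) ** 2)
    ss_ab = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    ss_sa = b * np.sum((sA - subj[:, None] - A[None, :] + grand) ** 2)
    ss_sb = a * np.sum((sB - subj[:, None] - B[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (y - sA[:, :, None] - sB[:, None, :] - AB[None, :, :]
         + subj[:, None, None] + A[None, :, None] + B[None, None, :] - grand) ** 2
    )

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    cells = y.reshape(n, a * b)
    effects = {
        "A": (ss_a, ss_sa, a - 1, np.kron(ca, np.ones((b, 1)) / np.sqrt(b))),
        "B": (ss_b, ss_sb, b - 1, np.kron(np.ones((a, 1)) / np.sqrt(a), cb)),
        "AxB": (ss_ab, ss_sab, (a - 1) * (b - 1), np.kron(ca, cb)),
    }
    total_ss = ss_a + ss_b + ss_ab + ss_sa + ss_sb + ss_sab
    out: dict[str, StatResult] = {}
    for name, (ss_eff, ss_err, df_eff, contrast) in effects.items():
        tiny = 1e-12 * max(total_ss, 1e-300)
        if ss_eff < tiny:
            ss_eff = 0.0
        df_err = df_eff * (n - 1)
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if ss_err > tiny else 0.0
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        eps = _gg_epsilon(cells @ contrast)
        df1, df2 = df_eff * eps, df_err * eps
        p = float(stats.f.sf(f, df1, df2)) if ms_err > 0 else (1.0 if ss_eff == 0 else 0.0)
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = StatResult(
            name=f"rm_anova_{name}", statistic=float(f),
            df=(float(df1), float(df2)), p=p,
            effect_size=float(eta), correction="greenhouse-geisser",
        )
    return out


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _ols_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS for the three mediation regressions (with intercepts)."""
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("zero-variance predictor")
    a = (xc @ mc) / sxx
    c = (xc @ yc) / sxx
    smm = mc @ mc
    sxm = xc @ mc
    det = sxx * smm - sxm ** 2
    if det <= 1e-12 * sxx * smm:
        # perfectly collinear mediator: attribute the shared effect to the
        # mediator path (b from the simple regression of y on m)
        if smm == 0:
            raise ValueError("zero-variance mediator")
        b = (mc @ yc) / smm
        return a, b, c, c - a * b
    c_prime = (smm * (xc @ yc) - sxm * (mc @ yc)) / det
    b = (sxx * (mc @ yc) - sxm * (xc @ yc)) / det
    return a, b, c, c_prime


def mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
) -> MediationResult:
    """Simple mediation with a percentile bootstrap CI for the indirect path.

    Units (here: parcels) are resampled with replacement; paths are
    estimated by OLS with intercepts. ``proportion_mediated = a*b / c``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    a, b, c, c_prime = _ols_paths(x, m, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ab, bb, _, _ = _ols_paths(x[idx], m[idx], y[idx])
            boot[i] = ab * bb
        except ValueError:
            boot[i] = np.nan
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(a * b), ci_low=float(lo), ci_high=float(hi),
        proportion_mediated=float(a * b / c) if c != 0 else float("nan"),
        n_boot=n_boot, seed=seed, boot_indirect=boot,
    )
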