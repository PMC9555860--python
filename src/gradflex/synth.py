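"""Synthetic parcellated multi-participant datasets with planted ground truth.

The generator emulates the structure of a slow event-related semantic
association experiment: ~31 participants view the same 144 word pairs over
3 runs, and every parcel's multivoxel response to each trial is simulated
so that four planted effects are recoverable downstream:

1. A one-dimensional latent gradient ``g*`` governs between-parcel sharing
   of trial-similarity structure. Each parcel mixes a bank of
   gradient-indexed content streams (Gaussian bump profiles along ``g*``)
   with parcel-private content, so nearby parcels share representational
   geometry and distant parcels do not — informational connectivity without
   time-series correlation.
2. The variance share of the gradient streams scales with the trial's
   association strength (``separation_weak`` -> ``separation_strong``), so
   the principal gradient of informational connectivity is expressed more
   strongly for strong associations.
3. Each parcel and condition has a latent rank: the number of
   participant-varying components in its response, which the searchlight
   dimensionality estimator recovers.
4. In designated coupling parcels a pattern component scales with the
   participant's own trial rating, so inter-participant rating similarity
   predicts inter-participant neural similarity (second-order RSA).

All stream content is shared across participants (group-level structure);
rank components and measurement noise are participant-specific.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .io import BehavioralTable, ParcellationAtlas, TrialPatternSet

NETWORK_NAMES = ("semantic-not-control", "SCN", "SCN+MDN", "MDN")


# ---------------------------------------------------------------------------
# spec and planted truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Parameters of a simulated dataset.

    ``separation_strong > separation_weak >= 0`` encodes the directional
    hypothesis that strong associations express the gradient more strongly;
    setting them equal produces a null dataset for calibration. Ranks are
    per-condition latent dimensionalities; the ``n_rank_modulated`` parcels
    highest on ``g*`` get ``rank_weak``/``rank_strong``, everything else
    ``rank_base`` in both conditions.
    """

    n_participants: int = 31
    n_trials: int = 144
    n_runs: int = 3
    n_parcels: int = 100
    voxels_per_parcel: int = 27
    separation_weak: float = 0.2
    separation_strong: float = 0.95
    chevron_separation: float | None = None   # None -> midpoint, both conditions
    n_streams: int = 16
    stream_width: float = 0.35
    gradient_amp: float = 1.2
    component_amp: float = 1.58
    noise_sd: float = 0.17               # searchlight SNR ~10 at baseline rank
    rank_base: int = 3
    rank_weak: int = 6
    rank_strong: int = 2
    n_rank_modulated: int = 10
    coupling_strength: float = 4.0
    n_coupling_parcels: int = 10
    rating_noise_sd: float = 0.8
    word2vec_range: tuple[float, float] = (-0.05, 0.72)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation_strong < self.separation_weak or self.separation_weak < 0:
            raise ValueError("need separation_strong >= separation_weak >= 0")
        if not (0 <= self.separation_strong <= 1):
            raise ValueError("separation values are variance shares in [0, 1]")
        for k in (self.rank_base, self.rank_weak, self.rank_strong):
            if k < 1 or k > self.voxels_per_parcel:
                raise ValueError(
                    f"rank {k} infeasible for {self.voxels_per_parcel} voxels"
                )
        if self.n_trials % self.n_runs:
            raise ValueError("n_trials must divide evenly into runs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["word2vec_range"] = list(self.word2vec_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        kwargs = dict(d)
        if "word2vec_range" in kwargs:
            kwargs["word2vec_range"] = tuple(kwargs["word2vec_range"])
        return cls(**kwargs)


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every simulated dataset."""

    gradient: np.ndarray             # g* per parcel
    modulation_sign: np.ndarray      # expected sign of (strong - weak) gradient diff
    rank_difference: np.ndarray      # weak - strong latent rank per parcel
    coupling_indicator: np.ndarray   # 1 where rating-brain coupling is planted


def planted_gradient(n_parcels: int) -> np.ndarray:
    """The planted axis: polar angle coordinate of the Fibonacci lattice.

    Parcel 1 sits at the north pole (transmodal apex, g* = +1) and the last
    parcel at the south pole (unimodal end, g* = -1).
    """
    i = np.arange(n_parcels)
    return 1.0 - 2.0 * (i + 0.5) / n_parcels


def _rank_maps(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    weak = np.full(spec.n_parcels, spec.rank_base, dtype=int)
    strong = np.full(spec.n_parcels, spec.rank_base, dtype=int)
    mod = np.arange(spec.n_rank_modulated)      # highest-g* parcels
    weak[mod] = spec.rank_weak
    strong[mod] = spec.rank_strong
    return weak, strong


def planted_truth(spec: SyntheticSpec) -> PlantedTruth:
    """Deterministic bookkeeping of planted effects (no noise involved)."""
    g = planted_gradient(spec.n_parcels)
    if spec.separation_strong > spec.separation_weak:
        sign = np.where(g > np.median(g), 1, -1)
    else:
        sign = np.zeros(spec.n_parcels, dtype=int)
    rank_weak, rank_strong = _rank_maps(spec)
    coupling = np.zeros(spec.n_parcels, dtype=int)
    if spec.coupling_strength > 0:
        coupling[: spec.n_coupling_parcels] = 1
    return PlantedTruth(
        gradient=g,
        modulation_sign=sign,
        rank_difference=rank_weak - rank_strong,
        coupling_indicator=coupling,
    )


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points, ordered from north to south pole."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_synthetic_atlas(
    n_parcels: int = 100,
    voxels_per_parcel: int = 27,
    seed: int = 0,
) -> ParcellationAtlas:
    """Cubic parcels tiling a compact grid, with spherical centroids.

    Parcels are cubes of side ``voxels_per_parcel ** (1/3)`` arranged in a
    near-cubic block grid; centroids come from a Fibonacci lattice so spin
    permutation tests are well-posed. Network labels follow the planted
    gradient: the top decile of g* is the semantic-representation analogue,
    followed by SCN, SCN+MDN and MDN analogues in descending g* order.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    side = round(voxels_per_parcel ** (1 / 3))
    if side ** 3 != voxels_per_parcel:
        raise ValueError("voxels_per_parcel must be a cube number (8, 27, 125, ...)")
    nx = int(np.ceil(n_parcels ** (1 / 3)))
    ny = int(np.ceil((n_parcels / nx) ** (1 / 2)))
    nz = int(np.ceil(n_parcels / (nx * ny)))
    volume = np.zeros((nx * side, ny * side, nz * side), dtype=np.int32)
    pid = 1
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if pid > n_parcels:
                    break
                volume[
                    ix * side:(ix + 1) * side,
                    iy * side:(iy + 1) * side,
                    iz * side:(iz + 1) * side,
                ] = pid
                pid += 1
    centroids = fibonacci_sphere(n_parcels)
    g = planted_gradient(n_parcels)
    order = np.argsort(-g)           # already descending, kept explicit
    decile = max(1, n_parcels // 10)
    networks: dict[int, str] = {}
    for rank, idx in enumerate(order):
        band = rank // decile
        if band < len(NETWORK_NAMES):
            networks[int(idx + 1)] = NETWORK_NAMES[band]
        else:
            networks[int(idx + 1)] = "other"
    return ParcellationAtlas(
        label_volume=volume,
        parcel_ids=np.arange(1, n_parcels + 1),
        centroid_sphere_coords=centroids,
        network_labels=networks,
        voxel_size_mm=(3.0, 3.0, 3.0),
    )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    atlas: ParcellationAtlas
    semantic: list[TrialPatternSet]
    chevron: list[TrialPatternSet]
    behavior: BehavioralTable
    truth: PlantedTruth
    spec: SyntheticSpec


def _mixing_profiles(spec: SyntheticSpec, g: np.ndarray) -> np.ndarray:
    centers = np.linspace(-1.0, 1.0, spec.n_streams)
    w = np.exp(-0.5 * ((g[:, None] - centers[None, :]) / spec.stream_width) ** 2)
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def _per_trial_ranks(
    spec: SyntheticSpec, w2v: np.ndarray, splits: dict[str, np.ndarray],
    trial_ids: np.ndarray,
) -> np.ndarray:
    """Trials x parcels latent rank, set by each trial's tercile."""
    rank_weak, rank_strong = _rank_maps(spec)
    rank_mid = np.round((rank_weak + rank_strong) / 2).astype(int)
    lookup = {tid: rank_mid for tid in trial_ids}
    for tid in splits["weak_ids"]:
        lookup[tid] = rank_weak
    for tid in splits["strong_ids"]:
        lookup[tid] = rank_strong
    return np.stack([lookup[tid] for tid in trial_ids])


def _simulate_window(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    share_t: np.ndarray,            # per-trial gradient-stream variance share
    ranks_tp: np.ndarray,           # trials x parcels latent rank
    ratings_z: np.ndarray | None,   # participants x trials (coupling driver)
    coupling: np.ndarray,           # parcel 0/1 indicator
    bases: np.ndarray,              # P x V x V orthogonal per-parcel bases
    mix: np.ndarray,                # P x D stream mixing profiles
) -> np.ndarray:
    """Participants x trials x parcels x voxels pattern tensor."""
    T, P, V = len(share_t), spec.n_parcels, spec.voxels_per_parcel
    stream_content = rng.standard_normal((T, spec.n_streams, V))
    private_content = rng.standard_normal((T, P, V))
    content = (
        np.sqrt(share_t)[:, None, None]
        * np.einsum("pd,tdv->tpv", mix, stream_content)
        + np.sqrt(1.0 - share_t)[:, None, None] * private_content
    )
    kmax = int(ranks_tp.max())
    comp_mask = (
        np.arange(kmax)[None, None, :] < ranks_tp[:, :, None]
    )                                   # T x P x kmax
    N = spec.n_participants
    # Component coefficients are orthonormalised across participants (after
    # demeaning) so the planted spectrum is exactly flat: at zero noise the
    # dimensionality estimator recovers the latent rank analytically.
    raw = rng.standard_normal((T * P, N, kmax))
    raw -= raw.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(raw)
    all_coefs = (q * np.sqrt(N)).reshape(T, P, N, kmax)
    out = np.empty((N, T, P, V))
    for p in range(spec.n_participants):
        coefs = all_coefs[:, :, p, :] * comp_mask
        pre = spec.gradient_amp * content
        pre = pre.copy()
        pre[:, :, :kmax] += spec.component_amp * coefs
        if ratings_z is not None and spec.coupling_strength > 0:
            # rating-scaled component on a fixed direction (basis column V-1)
            drive = spec.coupling_strength * ratings_z[p][:, None] * coupling[None, :]
            pre[:, :, V - 1] += drive
        pats = np.einsum("tpv,pwv->tpw", pre, bases)
        pats += spec.noise_sd * rng.standard_normal((T, P, V))
        out[p] = pats
    return out


def simulate_dataset(
    spec: SyntheticSpec, atlas: ParcellationAtlas | None = None
) -> SimulatedDataset:
    """Simulate semantic- and chevron-window patterns for all participants.

    The same seed always yields byte-identical output. The chevron window
    is generated with a constant gradient share (no association-strength
    modulation), equal ranks, and no rating coupling: it is the built-in
    null condition, as in the task design it emulates.
    """
    from .io import split_by_association

    if atlas is None:
        atlas = make_synthetic_atlas(spec.n_parcels, spec.voxels_per_parcel, spec.seed)
    if atlas.n_parcels != spec.n_parcels:
        raise ValueError("atlas parcel count does not match spec")
    rng = np.random.default_rng(spec.seed)
    g = planted_gradient(spec.n_parcels)
    truth = planted_truth(spec)

    lo, hi = spec.word2vec_range
    w2v = rng.uniform(lo, hi, spec.n_trials)
    trial_ids = np.array([f"trial_{t:03d}" for t in range(spec.n_trials)])
    behavior_df = pd.DataFrame({"trial_id": trial_ids, "word2vec": w2v})
    wn = (w2v - w2v.min()) / (w2v.max() - w2v.min())

    # integer ratings 0-4, monotone in association strength plus noise
    raw = 4.0 * wn[None, :] + spec.rating_noise_sd * rng.standard_normal(
        (spec.n_participants, spec.n_trials)
    )
    ratings = np.clip(np.round(raw), 0, 4).astype(int)
    ratings_df = pd.DataFrame(
        ratings,
        index=[f"sub-{p:02d}" for p in range(spec.n_participants)],
        columns=trial_ids,
    )
    behavior = BehavioralTable(table=behavior_df, ratings=ratings_df)
    splits = split_by_association(behavior)

    run_labels = np.repeat(
        np.arange(spec.n_runs), spec.n_trials // spec.n_runs
    )
    ranks_tp = _per_trial_ranks(spec, w2v, splits, trial_ids)
    mix = _mixing_profiles(spec, g)
    V = spec.voxels_per_parcel
    bases = np.empty((spec.n_parcels, V, V))
    for i in range(spec.n_parcels):
        q, _ = np.linalg.qr(rng.standard_normal((V, V)))
        bases[i] = q

    # raw scaled ratings drive the coupling: the shared monotone-in-strength
    # baseline keeps the pattern-similarity products monotone in rating
    # agreement (a demeaned driver would be sign-folded by the product)
    ratings_z = (ratings - 2.0) / 2.0

    share_semantic = (
        spec.separation_weak + (spec.separation_strong - spec.separation_weak) * wn
    )
    sem = _simulate_window(
        rng, spec, share_semantic, ranks_tp, ratings_z,
        truth.coupling_indicator.astype(float), bases, mix,
    )
    chev_share = (
        spec.chevron_separation
        if spec.chevron_separation is not None
        else 0.5 * (spec.separation_weak + spec.separation_strong)
    )
    chev_ranks = np.full_like(ranks_tp, spec.rank_base)
    chev = _simulate_window(
        rng, spec, np.full(spec.n_trials, chev_share), chev_ranks, None,
        np.zeros(spec.n_parcels), bases, mix,
    )

    coords, labels = atlas.voxel_table()
    n_vox = len(labels)
    col_of = {int(pid): np.where(labels == pid)[0] for pid in atlas.parcel_ids}

    def to_sets(tensor: np.ndarray, window: str) -> list[TrialPatternSet]:
        sets = []
        for p in range(spec.n_participants):
            flat = np.empty((spec.n_trials, n_vox))
            for i, pid in enumerate(atlas.parcel_ids):
                flat[:, col_of[int(pid)]] = tensor[p][:, i, :]
            sets.append(
                TrialPatternSet(
                    participant_id=f"sub-{p:02d}",
                    patterns=flat,
                    run_labels=run_labels,
                    trial_ids=trial_ids,
                    task_window=window,
                    voxel_to_parcel=labels,
                )
            )
        return sets

    return SimulatedDataset(
        atlas=atlas,
        semantic=to_sets(sem, "semantic"),
        chevron=to_sets(chev, "chevron"),
        behavior=behavior,
        truth=truth,
        spec=spec,
    )
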