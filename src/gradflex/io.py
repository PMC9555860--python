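"""Domain types and file I/O for parcellated trial-pattern analysis.

Volumes travel as NIfTI (via nibabel), tables as TSV (via pandas), and every
map writer drops a JSON sidecar recording the config hash and seed, so any
file on disk can be traced back to the run that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ParcellationAtlas:
    """Integer label volume plus per-parcel metadata.

    ``label_volume`` uses 0 for background and labels ``parcel_ids`` for the
    P parcels. ``centroid_sphere_coords`` places each parcel on the unit
    sphere (used by spin permutation tests). ``network_labels`` maps parcel
    id to a functional network name; parcels may be unlabelled.
    """

    label_volume: np.ndarray
    parcel_ids: np.ndarray
    centroid_sphere_coords: np.ndarray
    network_labels: dict[int, str] = field(default_factory=dict)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label volume must be an integer array")
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.centroid_sphere_coords = np.asarray(
            self.centroid_sphere_coords, dtype=float
        )
        present = set(np.unique(self.label_volume)) - {0}
        missing = present - set(self.parcel_ids.tolist())
        if missing:
            raise ValueError(
                f"parcel {sorted(missing)[0]} present in the volume but "
                "missing from the lookup"
            )
        norms = np.linalg.norm(self.centroid_sphere_coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("centroid coordinates must be unit-norm")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def network_members(self, name: str) -> np.ndarray:
        """Indices (into parcel_ids order) of parcels in network ``name``."""
        return np.array(
            [i for i, pid in enumerate(self.parcel_ids)
             if self.network_labels.get(int(pid)) == name],
            dtype=int,
        )

    def voxel_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened in-mask voxel coordinates and their parcel ids.

        Voxel order is C order over the volume, restricted to labelled
        voxels; this is the canonical voxel ordering for TrialPatternSet.
        """
        mask = self.label_volume > 0
        coords = np.argwhere(mask)
        labels = self.label_volume[mask]
        return coords, labels


@dataclass
class TrialPatternSet:
    """One participant's trial-by-voxel activation patterns."""

    participant_id: str
    patterns: np.ndarray            # trials x voxels
    run_labels: np.ndarray          # trials
    trial_ids: np.ndarray           # trials (shared ordering across participants)
    task_window: str                # "semantic" | "chevron"
    voxel_to_parcel: np.ndarray     # voxels -> parcel id

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.run_labels = np.asarray(self.run_labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids)
        self.voxel_to_parcel = np.asarray(self.voxel_to_parcel, dtype=int)
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("trial patterns contain non-finite values")
        if len(np.unique(self.run_labels)) < 2:
            raise ValueError("at least two runs are required")
        if self.patterns.shape[0] != len(self.run_labels):
            raise ValueError("run_labels length must match trial count")
        if self.patterns.shape[1] != len(self.voxel_to_parcel):
            raise ValueError("voxel_to_parcel length must match voxel count")

    def parcel_patterns(self, parcel_id: int) -> np.ndarray:
        """Trials x voxels restricted to one parcel."""
        cols = self.voxel_to_parcel == parcel_id
        return self.patterns[:, cols]


@dataclass
class BehavioralTable:
    """Per-trial stimulus covariates and per-participant responses."""

    table: pd.DataFrame                      # one row per trial
    ratings: pd.DataFrame | None = None      # participants x trials
    link_descriptions: pd.DataFrame | None = None  # participants x trials, str

    def __post_init__(self) -> None:
        required = {"trial_id", "word2vec"}
        if not required <= set(self.table.columns):
            raise ValueError(f"behaviour table needs columns {sorted(required)}")
        if self.table["trial_id"].duplicated().any():
            raise ValueError("duplicate trial ids in behaviour table")

    @property
    def trial_ids(self) -> np.ndarray:
        return self.table["trial_id"].to_numpy()

    @property
    def word2vec(self) -> np.ndarray:
        return self.table["word2vec"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# atlas loading
# ---------------------------------------------------------------------------


def load_atlas(
    label_volume_path: str | Path,
    lookup_path: str | Path,
    centroid_path: str | Path,
) -> ParcellationAtlas:
    """Read an atlas from a NIfTI label volume and two TSV tables.

    ``lookup_path`` must have columns ``parcel_id`` and optionally
    ``network``; ``centroid_path`` must have ``parcel_id, x, y, z`` with
    unit-sphere coordinates. Parcels are ordered by id.
    """
    img = nib.load(str(label_volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if np.max(np.abs(data - rounded)) > 1e-6:
            raise ValueError("label volume is not an integer NIfTI")
        data = rounded.astype(int)
    lookup = pd.read_csv(lookup_path, sep="\t")
    centroids = pd.read_csv(centroid_path, sep="\t")
    for name, df in (("lookup", lookup), ("centroid", centroids)):
        if "parcel_id" not in df.columns:
            raise ValueError(f"{name} table lacks a parcel_id column")
    lookup = lookup.sort_values("parcel_id").reset_index(drop=True)
    centroids = centroids.set_index("parcel_id").loc[lookup["parcel_id"]]
    networks = {}
    if "network" in lookup.columns:
        networks = {
            int(pid): str(net)
            for pid, net in zip(lookup["parcel_id"], lookup["network"])
            if isinstance(net, str) and net and net != "nan"
        }
    zooms = img.header.get_zooms()[:3] if img.header is not None else (3.0, 3.0, 3.0)
    return ParcellationAtlas(
        label_volume=data,
        parcel_ids=lookup["parcel_id"].to_numpy(dtype=int),
        centroid_sphere_coords=centroids[["x", "y", "z"]].to_numpy(dtype=float),
        network_labels=networks,
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=img.affine,
    )


# ---------------------------------------------------------------------------
# trial-pattern extraction
# ---------------------------------------------------------------------------


def extract_trial_patterns(
    time_series: np.ndarray,
    events: pd.DataFrame,
    window_trs: tuple[int, ...],
    voxel_to_parcel: np.ndarray,
    participant_id: str = "sub-00",
    task_window: str = "semantic",
) -> TrialPatternSet:
    """Average each trial's window of volumes into one pattern.

    ``time_series`` is TRs x voxels (already masked to labelled voxels, in
    atlas voxel order). ``events`` needs columns ``trial_id``, ``onset_tr``
    (0-based volume index of trial onset) and ``run``. ``window_trs`` are
    1-based offsets from onset, so offset 1 is the onset volume itself.
    """
    series = np.asarray(time_series, dtype=float)
    window = np.asarray(window_trs, dtype=int)
    if window.min() < 1:
        raise ValueError("window TR offsets are 1-based and must be >= 1")
    onsets = events["onset_tr"].to_numpy(dtype=int)
    bad = onsets + window.max() - 1 >= series.shape[0]
    if bad.any():
        offending = events["trial_id"].to_numpy()[bad].tolist()
        raise ValueError(
            f"window exceeds series length for trials {offending}"
        )
    idx = onsets[:, None] + window[None, :] - 1      # trials x window
    patterns = series[idx].mean(axis=1)
    return TrialPatternSet(
        participant_id=participant_id,
        patterns=patterns,
        run_labels=events["run"].to_numpy(dtype=int),
        trial_ids=events["trial_id"].to_numpy(),
        task_window=task_window,
        voxel_to_parcel=voxel_to_parcel,
    )


# ---------------------------------------------------------------------------
# condition splits and behavioural summaries
# ---------------------------------------------------------------------------


def split_by_association(
    behavior: BehavioralTable, rule: str = "floor"
) -> dict[str, np.ndarray]:
    """Tercile split of trial ids by ascending association strength.

    The extreme sets each hold ``floor(n/3)`` trials; remainder trials go to
    the middle set, keeping the contrasted sets balanced. Ties in word2vec
    are broken by a stable sort on trial id, so the split is deterministic.
    """
    if rule != "floor":
        raise ValueError(f"unknown tercile rule {rule!r}")
    n = len(behavior.table)
    if n < 3:
        raise ValueError("need at least 3 trials for a tercile split")
    order = behavior.table.sort_values(
        ["word2vec", "trial_id"], kind="stable"
    )["trial_id"].to_numpy()
    k = n // 3
    return {
        "weak_ids": order[:k],
        "middle_ids": order[k:n - k],
        "strong_ids": order[n - k:],
    }


def _normalise_category(text: str) -> str:
    import string

    return text.strip().lower().translate(
        str.maketrans("", "", string.punctuation)
    ).strip()


def response_uniqueness(
    link_descriptions: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Count distinct meaning categories per trial and their prevalence.

    ``link_descriptions`` is participants x trials (columns = trial ids) of
    free-text links already coded so that string equality after lowercase /
    punctuation stripping identifies a shared meaning. Returns the per-trial
    unique-meaning count, a long table of (trial, category, proportion), and
    a list of warnings for trials with no responses.
    """
    counts = {}
    rows = []
    notes: list[str] = []
    n_participants = link_descriptions.shape[0]
    for trial in link_descriptions.columns:
        responses = [
            _normalise_category(str(v))
            for v in link_descriptions[trial]
            if isinstance(v, str) and _normalise_category(str(v))
        ]
        if not responses:
            counts[trial] = 0
            notes.append(f"trial {trial}: no responses recorded")
            continue
        categories = pd.Series(responses).value_counts()
        counts[trial] = len(categories)
        for cat, n in categories.items():
            rows.append(
                {"trial_id": trial, "category": cat,
                 "proportion": n / n_participants}
            )
    proportions = pd.DataFrame(rows, columns=["trial_id", "category", "proportion"])
    return pd.Series(counts, name="n_unique_meanings"), proportions, notes


def behavioral_correlations(
    behavior: BehavioralTable, uniqueness: pd.Series | None = None
) -> dict[str, tuple[float, float]]:
    """Pearson correlations of ratings and meaning counts with word2vec."""
    out: dict[str, tuple[float, float]] = {}
    w2v = behavior.word2vec
    if behavior.ratings is not None:
        mean_rating = behavior.ratings[behavior.trial_ids].mean(axis=0).to_numpy()
        for name, v in (("rating", mean_rating),):
            if np.std(v) == 0 or np.std(w2v) == 0:
                raise ValueError(f"zero variance in {name} or word2vec")
        r, p = stats.pearsonr(mean_rating, w2v)
        out["r_rating_w2v"] = (float(r), float(p))
    if uniqueness is not None:
        counts = uniqueness.loc[behavior.trial_ids].to_numpy(dtype=float)
        if np.std(counts) == 0:
            raise ValueError("zero variance in unique-meaning counts")
        r, p = stats.pearsonr(counts, w2v)
        out["r_meanings_w2v"] = (float(r), float(p))
    return out


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def _write_sidecar(path: Path, config_hash: str | None, seed: int | None,
                   extra: dict | None = None) -> None:
    meta = {"config_hash": config_hash, "seed": seed}
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def write_parcel_map(
    path: str | Path,
    parcel_ids: np.ndarray,
    values: np.ndarray,
    config_hash: str | None = None,
    seed: int | None = None,
    value_name: str = "value",
    extra_meta: dict | None = None,
) -> None:
    """Per-parcel map as a two-column TSV plus JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"parcel_id": parcel_ids, value_name: values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    _write_sidecar(path, config_hash, seed, extra_meta)


def read_parcel_map(path: str | Path, value_name: str = "value") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    labels: np.ndarray,
    config_hash: str | None = None,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Square matrix as TSV with labelled header/index plus sidecar."""
    path = Path(path)
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )
    _write_sidecar(path, config_hash, seed, extra_meta)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy()


def write_label_volume(path: str | Path, atlas: ParcellationAtlas) -> None:
    img = nib.Nifti1Image(
        atlas.label_volume.astype(np.int32), atlas.affine
    )
    nib.save(img, str(path))


def write_atlas_tables(
    lookup_path: str | Path, centroid_path: str | Path, atlas: ParcellationAtlas
) -> None:
    pd.DataFrame(
        {
            "parcel_id": atlas.parcel_ids,
            "network": [
                atlas.network_labels.get(int(p), "") for p in atlas.parcel_ids
            ],
        }
    ).to_csv(lookup_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "parcel_id": atlas.parcel_ids,
            "x": atlas.centroid_sphere_coords[:, 0],
            "y": atlas.centroid_sphere_coords[:, 1],
            "z": atlas.centroid_sphere_coords[:, 2],
        }
    ).to_csv(centroid_path, sep="\t", index=False, float_format="%.17g")
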