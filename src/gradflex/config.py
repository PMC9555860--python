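"""Analysis configuration shared across pipeline stages.

The configuration captures every tunable that affects numerical output:
trial-window placement, tercile rule, similarity options, gradient
decomposition options, dimensionality thresholds, permutation/bootstrap
sizes, and the master seed. All outputs written by the pipeline embed a
hash of this object together with the seed so results are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Parameters governing a full analysis run.

    Attributes
    ----------
    tr_seconds:
        Repetition time of the acquisition, in seconds.
    semantic_window_trs:
        1-based TR offsets from trial onset averaged to form the semantic
        task pattern (the window covering the haemodynamic peak of the
        association judgement).
    chevron_window_trs:
        1-based TR offsets for the interleaved baseline (chevron) task.
    tercile_rule:
        How trials are split by association strength. ``"floor"`` puts
        ``floor(n/3)`` trials in each extreme tercile and the remainder in
        the middle, keeping the extreme sets balanced.
    similarity_fisher_z:
        Fisher-z transform trial-pair similarities before correlating
        them across parcels.
    similarity_method:
        ``"pearson"`` (default) or ``"spearman"`` pattern similarity.
    sparsity_density:
        Fraction of entries kept per row of the connectivity matrix before
        the cosine affinity. 1.0 (default) keeps the matrix dense; see the
        methods note for why dense affinity is the default here.
    n_gradients:
        Number of gradient components retained.
    variance_thresholds:
        Cumulative variance criteria for the dimensionality estimator.
    searchlight_radius_voxels:
        Cube searchlight half-width; the cube has edge ``2*r + 1``.
    n_spin / n_boot:
        Spin permutation count and bootstrap sample count.
    fdr_q:
        Benjamini-Hochberg false discovery level.
    seed:
        Master seed; per-stage child seeds are derived from it.
    excluded_networks:
        Network labels dropped from network-level summaries (mirrors
        low-tSNR exclusions in volumetric studies).
    """

    tr_seconds: float = 1.5
    semantic_window_trs: tuple[int, ...] = (4, 5, 6)
    chevron_window_trs: tuple[int, ...] = (9, 10)
    tercile_rule: str = "floor"
    similarity_fisher_z: bool = True
    similarity_method: str = "pearson"
    group_average_fisher_z: bool = True
    sparsity_density: float = 1.0
    n_gradients: int = 10
    variance_thresholds: tuple[float, ...] = (0.60, 0.75, 0.90)
    searchlight_radius_voxels: int = 1
    n_spin: int = 5000
    n_boot: int = 5000
    rsa_n_perm: int = 5000
    fdr_q: float = 0.05
    seed: int = 0
    excluded_networks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.variance_thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"variance threshold {t} outside (0, 1]")
        if self.n_spin < 1 or self.n_boot < 1:
            raise ValueError("n_spin and n_boot must be >= 1")
        if not (0.0 < self.sparsity_density <= 1.0):
            raise ValueError("sparsity_density must be in (0, 1]")
        if self.similarity_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown similarity method {self.similarity_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                value = d[f.name]
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[f.name] = value
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration contents."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
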