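"""Pipeline configuration: every threshold used by the analysis, with the
published defaults, serialisable to/from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mash_clustering import ClusteringConfig
from .quality_control import QualityThresholds


@dataclass
class PipelineConfig:
    """All fixed constants of the workflow in one place.

    Defaults are the reference settings: k-mer size 21 with 1000-hash
    sketches, silhouette cutoff 0.4 at both clustering levels, 95% species
    similarity, 80% knownclusterblast threshold, 0.3 similarity-network
    distance cutoff, minimum of 5 BGCs per profiled family, and quality
    gates at 90% completeness / 5% contamination / 100 contigs / 100 kb N50.
    """

    seed: int = 0
    kmer_size: int = 21
    sketch_size: int = 1000
    silhouette_cutoff: float = 0.4
    k_range: tuple[int, ...] = tuple(range(2, 21))
    max_rounds: int = 10
    n_init: int = 50
    species_similarity: float = 0.95
    kcb_threshold: float = 80.0
    bigscape_cutoff: float = 0.3
    min_bgcs: int = 5
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    max_contigs: int = 100
    min_n50: int = 100_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.kmer_size < 1 or self.kmer_size > 31:
            raise ValueError("kmer_size must lie in [1, 31]")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")
        if not 0 < self.species_similarity < 1:
            raise ValueError("species_similarity must lie in (0, 1)")
        if not 0 <= self.kcb_threshold <= 100:
            raise ValueError("kcb_threshold must lie in [0, 100]")
        if not -1 < self.silhouette_cutoff < 1:
            raise ValueError("silhouette_cutoff must lie in (-1, 1)")

    def clustering(self) -> ClusteringConfig:
        return ClusteringConfig(
            k_range=tuple(self.k_range),
            silhouette_cutoff=self.silhouette_cutoff,
            max_rounds=self.max_rounds,
            random_seed=self.seed,
            n_init=self.n_init,
        )

    def quality(self) -> QualityThresholds:
        return QualityThresholds(
            min_completeness=self.min_completeness,
            max_contamination=self.max_contamination,
            max_contigs=self.max_contigs,
            min_n50=self.min_n50,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)
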