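"""Genome quality triage into HQ / MQ / LQ tiers.

Gates are applied in order: CheckM-style completeness/contamination first
(completeness must exceed 90%, contamination stay below 5%), then assembly
level (complete or chromosome assemblies are HQ), then fragmentation
(more than 100 contigs or N50 under 100 kb is LQ; the rest is MQ).
All thresholds are configurable; boundary semantics are strict
(completeness exactly 90 fails, exactly 100 contigs is still MQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ASSEMBLY_LEVELS = ("complete", "chromosome", "scaffold", "contig")
HQ_LEVELS = ("complete", "chromosome")


@dataclass
class QualityThresholds:
    min_completeness: float = 90.0  # strict: must be > this
    max_contamination: float = 5.0  # strict: must be < this
    max_contigs: int = 100  # strict: > this is LQ
    min_n50: int = 100_000  # strict: < this is LQ


@dataclass
class GenomeRecord:
    genome_id: str
    assembly_level: str
    n_contigs: int
    n50: int
    completeness: float
    contamination: float
    species_label: str = ""
    quality_tier: str = "unset"

    def __post_init__(self) -> None:
        for name in ("assembly_level", "n_contigs", "n50", "completeness", "contamination"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and value != value):
                raise ValueError(f"genome {self.genome_id}: missing metric '{name}'")
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValueError(
                f"genome {self.genome_id}: unknown assembly level '{self.assembly_level}'"
            )
        if not (0 <= self.completeness <= 100 and 0 <= self.contamination <= 100):
            raise ValueError(f"genome {self.genome_id}: percentages must lie in [0, 100]")
        if self.n_contigs < 1:
            raise ValueError(f"genome {self.genome_id}: n_contigs must be >= 1")
        if self.n50 < 0:
            raise ValueError(f"genome {self.genome_id}: n50 must be >= 0")


def classify_quality(
    rec: GenomeRecord, thresholds: QualityThresholds | None = None
) -> str:
    """Return the quality tier ('HQ', 'MQ' or 'LQ') for one genome."""
    t = thresholds or QualityThresholds()
    if rec.completeness <= t.min_completeness or rec.contamination >= t.max_contamination:
        return "LQ"
    if rec.assembly_level in HQ_LEVELS:
        return "HQ"
    if rec.n_contigs > t.max_contigs or rec.n50 < t.min_n50:
        return "LQ"
    return "MQ"


def classify_all(
    records: list[GenomeRecord], thresholds: QualityThresholds | None = None
) -> list[GenomeRecord]:
    for rec in records:
        rec.quality_tier = classify_quality(rec, thresholds)
    return records


def select_analysis_set(records: list[GenomeRecord]) -> list[str]:
    """Ids of HQ/MQ genomes in input order (the analysis set)."""
    return [r.genome_id for r in records if r.quality_tier in ("HQ", "MQ")]


def records_from_frame(meta: pd.DataFrame) -> list[GenomeRecord]:
    required = ["genome_id", "assembly_level", "n_contigs", "n50", "completeness", "contamination"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    records = []
    for _, row in meta.iterrows():
        records.append(
            GenomeRecord(
                genome_id=str(row.genome_id),
                assembly_level=str(row.assembly_level),
                n_contigs=int(row.n_contigs),
                n50=int(row.n50),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                species_label=str(row.get("species_label", "") or ""),
            )
        )
    return records


def tier_counts(records: list[GenomeRecord]) -> dict[str, int]:
    counts = {"HQ": 0, "MQ": 0, "LQ": 0}
    for r in records:
        counts[r.quality_tier] = counts.get(r.quality_tier, 0) + 1
    return counts
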