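"""Synthetic genome populations and BGC inventories with planted structure.

The generator emulates, at desk scale, the statistical structure the
downstream analysis assumes:

* genomes arranged in a three-level hierarchy (primary clusters ->
  secondary subclusters -> near-identical strains) produced by mutating a
  shared root sequence with substitutions only, plus unclusterable
  outlier genomes diverged beyond every cluster;
* per-genome ordered BGC inventories with a universally conserved ordered
  backbone of gene cluster families (GCFs), subcluster-specific variable
  insertions between fixed backbone anchor pairs, and a configurable number
  of known GCFs deliberately split across multiple GCF labels that share a
  single MIBiG accession (the situation the regrouping step repairs).

Divergence parameters are expected *pairwise* substitution fractions at each
level of the hierarchy, so ``divergence_within_secondary`` is roughly the
Mash distance between two strains of the same subcluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Product-class labels used purely as BGC type tags (abundant classes in
#: actinomycete genomes).
BGC_TYPE_CATALOG = (
    "terpene",
    "NI-siderophore",
    "NRPS",
    "T1PKS",
    "RiPP-like",
    "T3PKS",
    "ectoine",
    "butyrolactone",
    "melanin",
    "T2PKS",
)


@dataclass
class SimulationConfig:
    """Knobs of the planted-structure simulation; defaults are the package's
    reference study conditions (see docs/methods.md)."""

    seed: int = 0
    n_primary: int = 3
    n_secondary_per_primary: int = 2
    genomes_per_secondary: int = 8
    n_outliers: int = 3
    genome_length: int = 50_000
    divergence_within_secondary: float = 0.01
    divergence_within_primary: float = 0.04
    divergence_between_primary: float = 0.15
    outlier_divergence: float = 0.30
    backbone_size: int = 7
    n_variable_gcfs: int = 10
    p_insertion: float = 0.5
    n_split_known_gcfs: int = 3
    split_labels_per_gcf: int = 3
    frac_known_variable: float = 0.4
    known_similarity_range: tuple[float, float] = (81.0, 100.0)
    unknown_similarity_range: tuple[float, float] = (0.0, 50.0)

    def __post_init__(self) -> None:
        if not (
            self.divergence_within_secondary
            < self.divergence_within_primary
            < self.divergence_between_primary
        ):
            raise ValueError("divergences must increase strictly across hierarchy levels")
        if not 0.0 <= self.p_insertion <= 1.0:
            raise ValueError("p_insertion must be in [0, 1]")
        if not 0.0 <= self.frac_known_variable <= 1.0:
            raise ValueError("frac_known_variable must be in [0, 1]")
        for name in (
            "n_primary",
            "n_secondary_per_primary",
            "genomes_per_secondary",
            "n_outliers",
            "backbone_size",
            "n_variable_gcfs",
            "n_split_known_gcfs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_genomes(self) -> int:
        return (
            self.n_primary * self.n_secondary_per_primary * self.genomes_per_secondary
            + self.n_outliers
        )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a Binomial(L, rate) number of positions to a different base."""
    out = seq.copy()
    n_sub = rng.binomial(seq.size, rate)
    if n_sub == 0:
        return out
    pos = rng.choice(seq.size, size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genomes(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate the genome population and its truth table.

    Returns ``(sequences, truth)`` where ``sequences`` maps genome_id to a
    DNA string and ``truth`` has columns ``genome_id, primary, secondary,
    is_outlier`` (outliers carry empty labels).
    """
    if config.n_genomes == 0:
        warnings.warn("zero genomes requested; returning empty collection")
        return {}, pd.DataFrame(columns=["genome_id", "primary", "secondary", "is_outlier"])
    rng = np.random.default_rng(config.seed)
    root = rng.integers(0, 4, size=config.genome_length).astype(np.uint8)
    ws, wp, bp = (
        config.divergence_within_secondary,
        config.divergence_within_primary,
        config.divergence_between_primary,
    )
    sequences: dict[str, str] = {}
    rows = []
    for p in range(1, config.n_primary + 1):
        primary_center = _mutate(root, (bp - wp) / 2.0, rng)
        for s in range(1, config.n_secondary_per_primary + 1):
            secondary_center = _mutate(primary_center, (wp - ws) / 2.0, rng)
            for g in range(1, config.genomes_per_secondary + 1):
                gid = f"G_P{p}_S{s}_{g:02d}"
                sequences[gid] = _to_str(_mutate(secondary_center, ws / 2.0, rng))
                rows.append((gid, f"P{p}", f"P{p}_S{s}", False))
    for o in range(1, config.n_outliers + 1):
        gid = f"G_OUT_{o:02d}"
        sequences[gid] = _to_str(_mutate(root, config.outlier_divergence, rng))
        rows.append((gid, "", "", True))
    truth = pd.DataFrame(rows, columns=["genome_id", "primary", "secondary", "is_outlier"])
    return sequences, truth


# ---------------------------------------------------------------------------
# BGC inventories
# ---------------------------------------------------------------------------

_BGC_LEN = 20_000
_BGC_GAP = 5_000


def simulate_bgc_table(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-genome ordered BGC inventories plus a GCF truth table.

    The returned BGC table has the reader schema (bgc_id, genome_id,
    contig_id, start, end, bgc_type, on_contig_edge, gcf_id, mibig_hit,
    kcb_similarity); coordinates are 0-based half-open, non-overlapping and
    ascending per contig.  The GCF truth table records, for every emitted
    GCF label, whether it is known, its MIBiG accession, its role
    (backbone / variable / split / private) and its anchor slot.
    """
    if truth.empty:
        empty = pd.DataFrame(
            columns=[
                "bgc_id",
                "genome_id",
                "contig_id",
                "start",
                "end",
                "bgc_type",
                "on_contig_edge",
                "gcf_id",
                "mibig_hit",
                "kcb_similarity",
            ]
        )
        return empty, pd.DataFrame(columns=["gcf_id", "known", "mibig_hit", "role", "slot"])
    has_insertions = config.n_variable_gcfs > 0 or (
        config.n_split_known_gcfs > 0 and config.p_insertion > 0
    )
    if config.backbone_size < 2 and has_insertions and config.p_insertion > 0:
        raise ValueError("variable insertions need a backbone of >= 2 anchor GCFs")
    rng = np.random.default_rng(config.seed + 1)

    secondary_labels = sorted(set(truth.loc[~truth.is_outlier, "secondary"]))
    primary_of = {s: s.split("_")[0] for s in secondary_labels}
    primaries = sorted(set(primary_of.values()))
    n_slots = max(config.backbone_size - 1, 1)

    gcf_rows = []  # gcf_id, known, mibig_hit, role, slot
    backbone = [f"GCF_BB{i + 1:02d}" for i in range(config.backbone_size)]
    for i, g in enumerate(backbone):
        known = i % 2 == 0  # alternate known/unknown backbone families
        acc = f"BGC{1000 + i:07d}" if known else ""
        gcf_rows.append((g, known, acc, "backbone", -1))

    # variable GCFs: sampled per secondary cluster, never universal within
    # a primary cluster (so the planted backbone is exactly the universal set)
    presence: dict[str, set[str]] = {s: set() for s in secondary_labels}
    variable = [f"GCF_V{i + 1:03d}" for i in range(config.n_variable_gcfs)]
    n_known_var = int(round(config.frac_known_variable * len(variable)))
    known_var = set(rng.choice(variable, size=n_known_var, replace=False)) if variable else set()
    for i, g in enumerate(variable):
        slot = int(rng.integers(0, n_slots))
        carried = {s for s in secondary_labels if rng.random() < config.p_insertion}
        for p in primaries:
            secs_p = [s for s in secondary_labels if primary_of[s] == p]
            if secs_p and all(s in carried for s in secs_p):
                carried.discard(secs_p[int(rng.integers(0, len(secs_p)))])
        for s in carried:
            presence[s].add(g)
        if g in known_var:
            acc = f"BGC{2000 + i:07d}"
            gcf_rows.append((g, True, acc, "variable", slot))
        else:
            # half of the unknowns get a weak MIBiG hit, half none
            acc = f"BGC{3000 + i:07d}" if i % 2 == 0 else ""
            gcf_rows.append((g, False, acc, "variable", slot))

    # split known GCFs: one compound emitted under several GCF labels that
    # share a MIBiG accession, placed in different secondary clusters
    if config.p_insertion > 0 and config.n_split_known_gcfs > 0:
        if len(secondary_labels) < 2:
            warnings.warn("cannot place split GCFs in different secondary clusters")
        # interleave across primaries so a split compound does not become
        # universal within one primary cluster (where >1 primary exists)
        placement_order = sorted(
            secondary_labels, key=lambda s: (s.split("_")[1], primary_of[s])
        )
        secs_of_primary: dict[str, set[str]] = {}
        for s in secondary_labels:
            secs_of_primary.setdefault(primary_of[s], set()).add(s)
        cursor = 0
        for i in range(config.n_split_known_gcfs):
            acc = f"BGC{7000 + i:07d}"
            slot = int(rng.integers(0, n_slots))
            n_labels = min(config.split_labels_per_gcf, max(len(secondary_labels), 1))
            # pick distinct secondaries round-robin; with >1 primary, never
            # cover all secondaries of one primary (keeps the compound out of
            # that primary's universal backbone)
            chosen: list[str] = []
            attempts = 0
            while len(chosen) < n_labels and attempts < 2 * len(placement_order):
                sec = placement_order[cursor % len(placement_order)]
                cursor += 1
                attempts += 1
                if sec in chosen:
                    continue
                would_complete = (
                    {c for c in chosen if primary_of[c] == primary_of[sec]} | {sec}
                ) == secs_of_primary[primary_of[sec]]
                if would_complete and len(primaries) > 1:
                    continue
                chosen.append(sec)
            for j, sec in enumerate(chosen):
                label = f"GCF_SPLIT{i + 1}_{j + 1}"
                presence[sec].add(label)
                gcf_rows.append((label, True, acc, "split", slot))

    gcf_truth = pd.DataFrame(gcf_rows, columns=["gcf_id", "known", "mibig_hit", "role", "slot"])
    slot_of = dict(zip(gcf_truth.gcf_id, gcf_truth.slot))
    acc_of = dict(zip(gcf_truth.gcf_id, gcf_truth.mibig_hit))
    known_of = dict(zip(gcf_truth.gcf_id, gcf_truth.known))
    type_rng = np.random.default_rng(config.seed + 2)
    type_of = {
        g: BGC_TYPE_CATALOG[int(type_rng.integers(0, len(BGC_TYPE_CATALOG)))]
        for g in gcf_truth.gcf_id
    }

    lo_k, hi_k = config.known_similarity_range
    lo_u, hi_u = config.unknown_similarity_range

    bgc_rows = []
    private_rows = []
    for _, rec in truth.iterrows():
        gid = rec.genome_id
        if rec.is_outlier:
            # outliers carry a few private unknown families
            chromosome = []
            for j in range(3):
                label = f"GCF_PRIV_{gid}_{j + 1}"
                private_rows.append((label, False, "", "private", -1))
                type_of[label] = BGC_TYPE_CATALOG[int(type_rng.integers(0, len(BGC_TYPE_CATALOG)))]
                acc_of[label] = ""
                known_of[label] = False
                chromosome.append(label)
        else:
            inserted = presence[rec.secondary]
            by_slot: dict[int, list[str]] = {}
            for g in sorted(inserted):
                by_slot.setdefault(slot_of[g], []).append(g)
            chromosome = []
            for i, bb in enumerate(backbone):
                chromosome.append(bb)
                chromosome.extend(by_slot.get(i, []))
        for pos, g in enumerate(chromosome):
            start = pos * (_BGC_LEN + _BGC_GAP)
            acc = acc_of[g]
            if acc:
                sim = rng.uniform(lo_k, hi_k) if known_of[g] else rng.uniform(lo_u, hi_u)
                sim = round(float(sim), 2)
            else:
                sim = np.nan
            bgc_rows.append(
                (
                    f"{gid}.r{pos + 1:03d}",
                    gid,
                    f"{gid}.chr",
                    start,
                    start + _BGC_LEN,
                    type_of[g],
                    False,
                    g,
                    acc,
                    sim,
                )
            )
    bgc_table = pd.DataFrame(
        bgc_rows,
        columns=[
            "bgc_id",
            "genome_id",
            "contig_id",
            "start",
            "end",
            "bgc_type",
            "on_contig_edge",
            "gcf_id",
            "mibig_hit",
            "kcb_similarity",
        ],
    )
    if private_rows:
        gcf_truth = pd.concat(
            [gcf_truth, pd.DataFrame(private_rows, columns=gcf_truth.columns)],
            ignore_index=True,
        )
    return bgc_table, gcf_truth


def simulate_metadata(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Genome metadata mirroring an assembly-statistics table: all simulated
    genomes are emitted as complete, clean assemblies (quality triage is
    exercised separately with hand-built records)."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for _, rec in truth.iterrows():
        rows.append(
            (
                rec.genome_id,
                "complete",
                1,
                config.genome_length,
                round(float(rng.uniform(95, 100)), 2),
                round(float(rng.uniform(0, 2)), 2),
                "" if rec.is_outlier else f"sp_{rec.secondary}",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "assembly_level",
            "n_contigs",
            "n50",
            "completeness",
            "contamination",
            "species_label",
        ],
    )
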