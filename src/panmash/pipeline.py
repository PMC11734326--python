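"""End-to-end driver: QC -> distances -> two-level clustering -> species ->
GCF regrouping/distribution -> synteny, with every stage's outputs written
to a results directory and a machine-readable summary of the counts.

Inputs are either file paths (metadata TSV, distance matrix TSV or FASTA
directory, BGC table TSV) or, for self-contained runs, a
:class:`~panmash.synthetic_data.SimulationConfig` whose planted population
is generated on the fly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .gcf_regrouping import (
    cluster_distribution,
    flag_known_gcfs,
    regroup,
    regrouped_to_frame,
    rgcf_of_bgc,
    similarity_bands,
)
from .mash_clustering import primary_clusters, rounds_to_frame, secondary_clusters
from .quality_control import classify_all, records_from_frame, select_analysis_set, tier_counts
from .sketch_distance import DistanceMatrix, distance_matrix, sketch
from .species_network import detect_species, merge_species, similarity_graph
from .synthetic_data import SimulationConfig, simulate_bgc_table, simulate_genomes, simulate_metadata
from .synteny_network import build_graph, detect_backbone, order_bgcs

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    summary: dict
    primary_table: pd.DataFrame
    secondary_table: pd.DataFrame
    species_table: pd.DataFrame
    regrouped_table: pd.DataFrame
    abundance_table: pd.DataFrame
    band_counts: pd.DataFrame
    backbones: dict[str, list[str]] = field(default_factory=dict)


def _sketch_all(sequences: dict[str, str], cfg: PipelineConfig) -> DistanceMatrix:
    sketches = [
        sketch(seq, genome_id=g, k=cfg.kmer_size, s=cfg.sketch_size)
        for g, seq in sequences.items()
    ]
    return distance_matrix(sketches)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    metadata: pd.DataFrame | None = None,
    dm: DistanceMatrix | None = None,
    bgc_table: pd.DataFrame | None = None,
    sim: SimulationConfig | None = None,
) -> PipelineResult:
    """Run every stage in order and write all outputs under ``out_dir``.

    Exactly one of ``sim`` or the (metadata, dm/bgc_table) inputs must
    provide the data.  Deterministic given ``cfg.seed`` (the simulation uses
    its own seed).  Any stage failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    summary: dict = {"thresholds": {
        "kmer_size": cfg.kmer_size,
        "sketch_size": cfg.sketch_size,
        "silhouette_cutoff": cfg.silhouette_cutoff,
        "species_similarity": cfg.species_similarity,
        "kcb_threshold": cfg.kcb_threshold,
        "bigscape_cutoff": cfg.bigscape_cutoff,
        "min_bgcs": cfg.min_bgcs,
        "min_completeness": cfg.min_completeness,
        "max_contamination": cfg.max_contamination,
        "max_contigs": cfg.max_contigs,
        "min_n50": cfg.min_n50,
    }}
    logger.info("thresholds in effect: %s", summary["thresholds"])

    stage = "simulate"
    try:
        if sim is not None:
            sequences, truth = simulate_genomes(sim)
            metadata = simulate_metadata(sim, truth)
            bgc_table, _ = simulate_bgc_table(sim, truth)
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        else:
            sequences = None
        if metadata is None:
            raise ValueError("no metadata given and no simulation requested")

        stage = "quality_control"
        records = classify_all(records_from_frame(metadata), cfg.quality())
        analysis_ids = select_analysis_set(records)
        meta_out = metadata.copy()
        meta_out["quality_tier"] = [r.quality_tier for r in records]
        pio.write_genome_metadata(meta_out, out / "genome_metadata.tsv")
        summary["quality"] = tier_counts(records)
        summary["n_genomes_input"] = len(records)
        summary["n_genomes_analysis"] = len(analysis_ids)

        stage = "distances"
        if dm is None:
            if sequences is None:
                raise ValueError("no distance matrix and no sequences to sketch")
            dm = _sketch_all(
                {g: s for g, s in sequences.items() if g in set(analysis_ids)}, cfg
            )
        else:
            keep = [g for g in dm.ids if g in set(analysis_ids)]
            dm = dm.submatrix(keep)
        pio.write_distance_matrix(dm, out / "mash_distances.tsv")

        stage = "primary_clustering"
        ccfg = cfg.clustering()
        primary_table, primary_rounds = primary_clusters(dm, ccfg)
        rounds_to_frame(primary_rounds, dm.ids).to_csv(
            out / "primary_rounds.tsv", sep="\t", index=False
        )
        primary_table.to_csv(out / "primary_clusters.tsv", sep="\t", index=False)
        n_dropped = int((primary_table.primary_label == "Dropped").sum())
        summary["primary"] = {
            "n_clusters": int(primary_table.primary_label.nunique() - (n_dropped > 0)),
            "n_assigned": int(len(primary_table) - n_dropped),
            "n_dropped": n_dropped,
        }

        stage = "secondary_clustering"
        secondary_table, _ = secondary_clusters(dm, primary_table, ccfg)
        secondary_table.to_csv(out / "secondary_clusters.tsv", sep="\t", index=False)
        assigned = secondary_table[secondary_table.secondary_label != "Dropped"]
        summary["secondary"] = {
            "n_clusters": int(assigned.secondary_label.nunique()),
            "n_assigned": int(len(assigned)),
            "n_dropped": int(len(secondary_table) - len(assigned)),
        }

        stage = "species"
        meta_idx = meta_out.set_index("genome_id")
        labeled = {
            g: str(meta_idx.loc[g, "species_label"])
            for g in analysis_ids
            if str(meta_idx.loc[g, "species_label"] or "")
        }
        unlabeled = [g for g in analysis_ids if g not in labeled and g in dm.ids]
        graph = similarity_graph(dm, unlabeled, cfg.species_similarity)
        novel = detect_species(graph, seed=cfg.seed)
        species_table, species_summary = merge_species(labeled, novel)
        species_table.to_csv(out / "species.tsv", sep="\t", index=False)
        pio.write_graphml(graph, out / "species_network.graphml")
        summary["species"] = species_summary

        stage = "gcf_regrouping"
        if bgc_table is None:
            raise ValueError("no BGC table available")
        bgc_table = bgc_table[bgc_table.genome_id.isin(set(analysis_ids))].reset_index(
            drop=True
        )
        flags = flag_known_gcfs(bgc_table, cfg.kcb_threshold)
        regrouped = regroup(bgc_table, flags)
        overall_bands, per_type_bands, n_top_accessions = similarity_bands(bgc_table)
        overall_bands.to_csv(out / "similarity_bands.tsv", sep="\t", index=False)
        per_type_bands.to_csv(out / "similarity_bands_by_type.tsv", sep="\t")
        summary["gcf"] = {
            "n_bgcs": int(len(bgc_table)),
            "n_gcfs": int(flags.shape[0]),
            "n_known_gcfs": int(flags.known.sum()),
            "n_regrouped_known": sum(1 for r in regrouped if r.known),
            "n_regrouped_total": len(regrouped),
            "n_top_band_accessions": n_top_accessions,
        }

        stage = "gcf_distribution"
        cluster_of = dict(zip(primary_table.genome_id, primary_table.primary_label))
        for g in bgc_table.genome_id.unique():
            cluster_of.setdefault(g, "Dropped")
        classes, abundance, overlaps = cluster_distribution(
            regrouped, bgc_table, cluster_of, cfg.min_bgcs
        )
        regrouped_table = regrouped_to_frame(regrouped)
        regrouped_table.to_csv(out / "regrouped_gcfs.tsv", sep="\t", index=False)
        abundance.to_csv(out / "gcf_abundance.tsv", sep="\t", index=False)
        with open(out / "gcf_overlaps.json", "w") as fh:
            json.dump({"|".join(sorted(k)): v for k, v in overlaps.items()}, fh, indent=1)
        summary["distribution"] = {
            str(k): int(v)
            for k, v in classes[classes.distribution_class != "unassigned"]
            .distribution_class.value_counts()
            .items()
        }

        stage = "synteny"
        mapping = rgcf_of_bgc(regrouped)
        backbones: dict[str, list[str]] = {}
        hq_ids = {
            r.genome_id for r in records if r.quality_tier == "HQ"
        }
        for label in sorted(
            set(primary_table.primary_label) - {"Dropped"}
        ):
            members = [
                g
                for g in primary_table.loc[
                    primary_table.primary_label == label, "genome_id"
                ]
                if g in hq_ids
            ]
            if len(members) < 2:
                continue
            ordered = order_bgcs(bgc_table, members, mapping)
            graph = build_graph(ordered)
            pio.write_graphml(graph, out / f"synteny_{label}.graphml")
            pio.write_cytoscape_tables(graph, out / f"synteny_{label}")
            result = detect_backbone(ordered)
            backbones[label] = result.backbone
        summary["synteny"] = {
            label: {"backbone_size": len(b)} for label, b in backbones.items()
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return PipelineResult(
        summary=summary,
        primary_table=primary_table,
        secondary_table=secondary_table,
        species_table=species_table,
        regrouped_table=regrouped_table,
        abundance_table=abundance,
        band_counts=overall_bands,
        backbones=backbones,
    )
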