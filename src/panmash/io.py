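"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are TSV with a header row; distance matrices carry the
genome ids both as the header and as the first column.  BGC coordinates are
normalised to 0-based half-open on read (pass ``one_based=True`` for tables
in 1-based inclusive convention).  FASTA goes through Biopython; graphs are
exported as GraphML plus Cytoscape-friendly node/edge attribute TSVs.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gcf_regrouping import BGC_COLUMNS
from .sketch_distance import DistanceMatrix

METADATA_COLUMNS = [
    "genome_id",
    "assembly_level",
    "n_contigs",
    "n50",
    "completeness",
    "contamination",
    "species_label",
]


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], directory: str | Path) -> list[Path]:
    """One FASTA file per genome (multi-record files are contigs of one genome)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome_id, seq in sequences.items():
        path = directory / f"{genome_id}.fasta"
        SeqIO.write([SeqRecord(Seq(seq), id=genome_id, description="")], path, "fasta")
        paths.append(path)
    return paths


def read_fasta_genome(path: str | Path) -> tuple[str, list[str]]:
    """Read one genome FASTA; returns (genome_id from file stem, contig seqs)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return Path(path).stem, [str(r.seq) for r in records]


# -- distance matrix ---------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="genome_id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    return DistanceMatrix(ids, df.to_numpy(dtype=float))


# -- genome metadata ---------------------------------------------------------

def read_genome_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    missing = [c for c in METADATA_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if "species_label" not in df.columns:
        df["species_label"] = ""
    df["species_label"] = df["species_label"].fillna("")
    return df


def write_genome_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# -- BGC table ---------------------------------------------------------------

def read_bgc_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Validated BGC table; raises with the offending line number.

    Coordinates are normalised to 0-based half-open; ``one_based=True``
    declares the input as 1-based inclusive.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "bgc_id": str,
            "genome_id": str,
            "contig_id": str,
            "bgc_type": str,
            "gcf_id": str,
            "mibig_hit": str,
        },
    )
    missing = [c for c in BGC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing BGC-table columns {missing}")
    df["mibig_hit"] = df["mibig_hit"].fillna("")
    df["on_contig_edge"] = df["on_contig_edge"].astype(bool)
    if one_based:
        df["start"] = df["start"].astype(int) - 1
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    for i, row in enumerate(df.itertuples(), start=2):  # line 1 is the header
        if row.start >= row.end:
            raise ValueError(f"{path}:{i}: start >= end for BGC {row.bgc_id}")
        if not np.isnan(row.kcb_similarity) and not 0 <= row.kcb_similarity <= 100:
            raise ValueError(f"{path}:{i}: kcb_similarity outside [0, 100]")
        has_hit = bool(row.mibig_hit)
        has_sim = not np.isnan(row.kcb_similarity)
        if has_hit != has_sim:
            raise ValueError(
                f"{path}:{i}: kcb_similarity must be present exactly when mibig_hit is"
            )
    if df.bgc_id.duplicated().any():
        dup = df.bgc_id[df.bgc_id.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate bgc_id {dup}")
    return df


def write_bgc_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- networks ----------------------------------------------------------------

def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_cytoscape_tables(G: nx.Graph, prefix: str | Path) -> tuple[Path, Path]:
    """Node and edge attribute TSVs importable into Cytoscape."""
    prefix = Path(prefix)
    nodes = pd.DataFrame(
        [{"id": n, **attrs} for n, attrs in G.nodes(data=True)]
    )
    if G.is_multigraph():
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, "key": k, **attrs}
                for u, v, k, attrs in G.edges(keys=True, data=True)
            ]
        )
    else:
        edges = pd.DataFrame(
            [{"source": u, "target": v, **attrs} for u, v, attrs in G.edges(data=True)]
        )
    node_path = prefix.with_suffix(".nodes.tsv")
    edge_path = prefix.with_suffix(".edges.tsv")
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    rows = [(u, v, d.get("similarity", d.get("weight", 1.0))) for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )
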