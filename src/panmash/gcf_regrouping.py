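"""Known-GCF flagging, regrouping by shared MIBiG hit, and distribution of
gene cluster families across Mash-clusters.

External clustering tools over-split families of homologous BGCs when
boundary regions differ.  When several input GCFs contain BGCs whose
knownclusterblast similarity against the *same* MIBiG reference exceeds 80%
of genes, they very likely encode the same compound; such GCFs are merged
into a single "regrouped" GCF.  Unknown GCFs (no member above the threshold)
pass through one-to-one, untouched.

The regrouped families are then profiled across Mash-clusters: a family with
at least ``min_bgcs`` member BGCs is *common* if present in every cluster,
*unique* if confined to one, and *accessory* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KCB_THRESHOLD = 80.0
MIN_BGCS = 5

#: Fig-1C-style similarity banding: (label, low, high); a score s falls in the
#: band with low < s <= high, except the lowest band which also takes 0 and
#: BGCs without any MIBiG hit.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<50", 0.0, 50.0),
    ("50-80", 50.0, 80.0),
    (">80", 80.0, 100.0),
)

BGC_COLUMNS = [
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


@dataclass
class RegroupedGCF:
    rgcf_id: str
    member_gcf_ids: list[str]
    mibig_accession: str
    known: bool
    member_bgc_ids: list[str] = field(default_factory=list)
    abundance: dict[str, float] = field(default_factory=dict)
    distribution_class: str = "unassigned"


def flag_known_gcfs(bgc_table: pd.DataFrame, threshold: float = KCB_THRESHOLD) -> pd.DataFrame:
    """Per input GCF: is it known, and which MIBiG accession does it get?

    A GCF is known iff at least one member BGC has a knownclusterblast
    similarity strictly above the threshold.  When members hit several
    accessions above threshold, the accession with the most such hits wins;
    ties go to the higher mean similarity, then to the lexicographically
    smallest accession.
    """
    if bgc_table["gcf_id"].isna().any() or (bgc_table["gcf_id"] == "").any():
        raise ValueError("every BGC needs a gcf_id before flagging")
    rows = []
    for gcf_id, group in bgc_table.groupby("gcf_id", sort=True):
        hits = group[
            (group.kcb_similarity.notna())
            & (group.kcb_similarity > threshold)
            & (group.mibig_hit.fillna("") != "")
        ]
        if hits.empty:
            rows.append((gcf_id, False, ""))
            continue
        stats = hits.groupby("mibig_hit")["kcb_similarity"].agg(["count", "mean"])
        best = sorted(
            stats.itertuples(),
            key=lambda t: (-t.count, -t.mean, t.Index),
        )[0]
        rows.append((gcf_id, True, best.Index))
    return pd.DataFrame(rows, columns=["gcf_id", "known", "mibig_accession"])


def regroup(bgc_table: pd.DataFrame, flags: pd.DataFrame | None = None) -> list[RegroupedGCF]:
    """Merge known GCFs sharing an assigned accession; unknowns pass 1:1.

    Every input BGC ends up in exactly one regrouped GCF, and the number of
    regrouped known families never exceeds the number of known input GCFs.
    """
    if flags is None:
        flags = flag_known_gcfs(bgc_table)
    known = dict(zip(flags.gcf_id, flags.known))
    accession = dict(zip(flags.gcf_id, flags.mibig_accession))
    members_by_rgcf: dict[str, list[str]] = {}
    for gcf_id in flags.gcf_id:
        rid = f"RGCF_{accession[gcf_id]}" if known[gcf_id] else f"RGCF_{gcf_id}"
        members_by_rgcf.setdefault(rid, []).append(gcf_id)
    bgcs_by_gcf = bgc_table.groupby("gcf_id")["bgc_id"].apply(list).to_dict()
    out = []
    for rid in sorted(members_by_rgcf):
        gcfs = sorted(members_by_rgcf[rid])
        is_known = known[gcfs[0]]
        out.append(
            RegroupedGCF(
                rgcf_id=rid,
                member_gcf_ids=gcfs,
                mibig_accession=accession[gcfs[0]] if is_known else "",
                known=is_known,
                member_bgc_ids=sorted(b for g in gcfs for b in bgcs_by_gcf.get(g, [])),
            )
        )
    return out


def rgcf_of_bgc(regrouped: list[RegroupedGCF]) -> dict[str, str]:
    return {b: r.rgcf_id for r in regrouped for b in r.member_bgc_ids}


def regrouped_to_frame(regrouped: list[RegroupedGCF]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.rgcf_id,
                ";".join(r.member_gcf_ids),
                r.mibig_accession,
                r.known,
                len(r.member_bgc_ids),
                r.distribution_class,
            )
            for r in regrouped
        ],
        columns=[
            "rgcf_id",
            "member_gcf_ids",
            "mibig_accession",
            "known",
            "n_bgcs",
            "distribution_class",
        ],
    )


def similarity_bands(
    bgc_table: pd.DataFrame,
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Count BGCs per knownclusterblast similarity band.

    Returns (overall band counts, per-type band counts, number of distinct
    MIBiG accessions matched in the top band).  Bands must not overlap;
    missing similarities count toward the lowest band.
    """
    ordered = sorted(bands, key=lambda b: b[1])
    for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(ordered, ordered[1:]):
        if hi_a > lo_b:
            raise ValueError(f"bands '{la}' and '{lb}' overlap")
    sims = bgc_table.kcb_similarity.fillna(0.0)
    labels = []
    lowest = ordered[0][0]
    for s in sims:
        lab = None
        for name, lo, hi in ordered:
            if (lo < s <= hi) or (s == 0.0 and name == lowest):
                lab = name
                break
        labels.append(lab if lab is not None else lowest)
    tagged = bgc_table.assign(band=labels)
    overall = (
        tagged.band.value_counts()
        .reindex([b[0] for b in ordered], fill_value=0)
        .rename_axis("band")
        .reset_index(name="n_bgcs")
    )
    per_type = (
        tagged.groupby(["bgc_type", "band"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[b[0] for b in ordered], fill_value=0)
    )
    top_band = ordered[-1][0]
    top = tagged[(tagged.band == top_band) & (tagged.mibig_hit.fillna("") != "")]
    n_accessions = int(top.mibig_hit.nunique())
    return overall, per_type, n_accessions


def cluster_distribution(
    regrouped: list[RegroupedGCF],
    bgc_table: pd.DataFrame,
    cluster_of: dict[str, str],
    min_bgcs: int = MIN_BGCS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[frozenset, int]]:
    """Classify regrouped GCFs as common / accessory / unique across clusters.

    ``cluster_of`` maps every genome in the table to a Mash-cluster label or
    'Dropped'.  For each regrouped GCF with at least ``min_bgcs`` member
    BGCs, the abundance in a cluster is the fraction of that cluster's
    genomes carrying at least one member BGC.  Families below ``min_bgcs``
    (or present only in dropped genomes) stay 'unassigned'.  Returns the
    class table, the abundance matrix, and UpSet-style overlap counts keyed
    by the set of clusters a family occurs in.
    """
    genomes = bgc_table.genome_id.unique()
    unknown = [g for g in genomes if g not in cluster_of]
    if unknown:
        raise ValueError(f"genomes without a cluster label: {unknown[:5]}")
    clusters = sorted({c for c in cluster_of.values() if c != "Dropped"})
    cluster_sizes = {c: sum(1 for v in cluster_of.values() if v == c) for c in clusters}
    genomes_by_bgc = dict(zip(bgc_table.bgc_id, bgc_table.genome_id))

    abundance_rows = []
    overlap_counts: dict[frozenset, int] = {}
    for r in regrouped:
        carrier_genomes = {genomes_by_bgc[b] for b in r.member_bgc_ids}
        carriers_by_cluster = {c: 0 for c in clusters}
        dropped_carriers = 0
        for g in carrier_genomes:
            c = cluster_of[g]
            if c == "Dropped":
                dropped_carriers += 1
            else:
                carriers_by_cluster[c] += 1
        r.abundance = {
            c: carriers_by_cluster[c] / cluster_sizes[c] if cluster_sizes[c] else 0.0
            for c in clusters
        }
        if len(r.member_bgc_ids) < min_bgcs:
            r.distribution_class = "unassigned"
        else:
            present = frozenset(c for c in clusters if carriers_by_cluster[c] > 0)
            if not present:
                r.distribution_class = "unassigned"
            elif len(present) == len(clusters):
                r.distribution_class = "common"
            elif len(present) == 1:
                r.distribution_class = "unique"
            else:
                r.distribution_class = "accessory"
            if present:
                overlap_counts[present] = overlap_counts.get(present, 0) + 1
        abundance_rows.append(
            [r.rgcf_id, r.distribution_class, dropped_carriers]
            + [r.abundance[c] for c in clusters]
        )
    abundance = pd.DataFrame(
        abundance_rows,
        columns=["rgcf_id", "distribution_class", "n_dropped_carriers"] + clusters,
    )
    classes = abundance[["rgcf_id", "distribution_class", "n_dropped_carriers"]].copy()
    return classes, abundance, overlap_counts
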