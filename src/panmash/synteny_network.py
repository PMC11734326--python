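"""BGC synteny networks: chromosomal ordering, dual-edge graphs, conserved
backbone detection, variable regions and dot plots.

Within a group of closely related genomes, BGCs tend to keep their relative
order along the chromosome; insertions and deletions happen at specific
positions between conserved anchor BGCs.  This module makes that structure
explicit:

* every genome's BGCs are ordered by (contig, start);
* a graph joins BGC nodes with two edge kinds — *similarity* edges (same
  regrouped GCF, or a supplied pairwise-distance list under a cutoff) and
  *adjacency* edges between chromosomal neighbours (never across contigs);
* the *backbone* is the set of GCFs present in (by default) every genome of
  the group whose projected order is the same, up to whole-genome reversal,
  in each genome.  Order conflicts (e.g. a transposed family in one genome)
  are resolved greedily by removing the family involved in the most
  pairwise order conflicts until the remainder is consistent;
* the BGCs lying strictly between two backbone anchors form that genome's
  *variable region* — the hot spots of insertion and deletion;
* dot plots of shared-family occurrences visualise pairwise synteny.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

BIGSCAPE_CUTOFF = 0.3


@dataclass
class OrderedBGC:
    bgc_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    position: int  # 1-based ordinal along the genome
    rgcf_id: str
    bgc_type: str = ""


@dataclass
class BackboneResult:
    backbone: list[str]  # consensus-ordered rgcf ids
    projections: dict[str, list[str]]  # genome -> projected order (as stored)
    orientation: dict[str, str]  # genome -> 'forward' | 'reversed'
    consistent: bool
    removed: list[str] = field(default_factory=list)  # conflict-removed rgcfs
    multicopy: dict[str, list[str]] = field(default_factory=dict)  # genome -> rgcfs seen >1x


def order_bgcs(
    bgc_table: pd.DataFrame,
    genome_ids: list[str] | None = None,
    rgcf_of: dict[str, str] | None = None,
) -> dict[str, list[OrderedBGC]]:
    """Per-genome BGC order by (contig, start), ties by end then bgc_id.

    ``rgcf_of`` maps bgc_id to its regrouped family; without it the input
    gcf_id is used.  Overlapping BGCs on one contig are kept in start order
    with a warning.
    """
    table = bgc_table
    if genome_ids is not None:
        table = table[table.genome_id.isin(set(genome_ids))]
    out: dict[str, list[OrderedBGC]] = {}
    for genome_id, group in table.groupby("genome_id", sort=True):
        ordered = group.sort_values(["contig_id", "start", "end", "bgc_id"])
        prev_contig, prev_end = None, -1
        records = []
        for pos, row in enumerate(ordered.itertuples(), start=1):
            if row.contig_id == prev_contig and row.start < prev_end:
                warnings.warn(
                    f"overlapping BGCs on {genome_id}/{row.contig_id}; kept in start order"
                )
            prev_contig, prev_end = row.contig_id, row.end
            family = rgcf_of[row.bgc_id] if rgcf_of is not None else row.gcf_id
            records.append(
                OrderedBGC(
                    bgc_id=row.bgc_id,
                    genome_id=genome_id,
                    contig_id=row.contig_id,
                    start=int(row.start),
                    end=int(row.end),
                    position=pos,
                    rgcf_id=family,
                    bgc_type=getattr(row, "bgc_type", ""),
                )
            )
        out[genome_id] = records
    return out


def build_graph(
    ordered: dict[str, list[OrderedBGC]],
    distance_list: pd.DataFrame | None = None,
    distance_cutoff: float = BIGSCAPE_CUTOFF,
) -> nx.MultiGraph:
    """Dual-edge synteny graph.

    Similarity edges come either from regrouped-GCF co-membership (default)
    or, if a 3-column (bgc_a, bgc_b, distance) list is given, from pairs
    under the distance cutoff.  Adjacency edges join chromosomal neighbours
    within each contig, forming one simple path per contig.
    """
    G = nx.MultiGraph()
    for genome_id, records in ordered.items():
        for rec in records:
            G.add_node(
                rec.bgc_id,
                genome=genome_id,
                contig=rec.contig_id,
                position=rec.position,
                rgcf_id=rec.rgcf_id,
                bgc_type=rec.bgc_type,
            )
        for a, b in zip(records, records[1:]):
            if a.contig_id == b.contig_id:
                G.add_edge(a.bgc_id, b.bgc_id, key="adjacency", kind="adjacency")
    if distance_list is not None:
        unknown = (set(distance_list.bgc_a) | set(distance_list.bgc_b)) - set(G.nodes)
        if unknown:
            raise ValueError(f"distance list references unknown BGCs: {sorted(unknown)[:5]}")
        for row in distance_list.itertuples():
            if row.distance <= distance_cutoff and row.bgc_a != row.bgc_b:
                G.add_edge(
                    row.bgc_a,
                    row.bgc_b,
                    key="similarity",
                    kind="similarity",
                    weight=1.0 - float(row.distance),
                )
    else:
        by_family: dict[str, list[str]] = {}
        for rec_list in ordered.values():
            for rec in rec_list:
                by_family.setdefault(rec.rgcf_id, []).append(rec.bgc_id)
        for members in by_family.values():
            for a, b in combinations(sorted(members), 2):
                G.add_edge(a, b, key="similarity", kind="similarity", weight=1.0)
    return G


def _project(records: list[OrderedBGC], candidates: set[str]) -> tuple[list[str], list[str]]:
    """First-occurrence projection of a genome's order onto candidate
    families; also returns the families seen more than once."""
    seen: list[str] = []
    counts: dict[str, int] = {}
    for rec in records:
        if rec.rgcf_id in candidates:
            counts[rec.rgcf_id] = counts.get(rec.rgcf_id, 0) + 1
            if counts[rec.rgcf_id] == 1:
                seen.append(rec.rgcf_id)
    multi = sorted(f for f, c in counts.items() if c > 1)
    return seen, multi


def _restricted_equal(projection: list[str], consensus: list[str]) -> bool:
    shared = set(projection) & set(consensus)
    return [f for f in projection if f in shared] == [f for f in consensus if f in shared]


def _orient(projection: list[str], consensus: list[str]) -> tuple[str, list[str]]:
    """Pick the orientation (forward/reversed) agreeing best with consensus."""
    pos = {f: i for i, f in enumerate(consensus)}
    shared = [f for f in projection if f in pos]
    fwd_agree = sum(
        1 for a, b in combinations(shared, 2) if pos[a] < pos[b]
    )
    rev = list(reversed(projection))
    shared_r = [f for f in rev if f in pos]
    rev_agree = sum(1 for a, b in combinations(shared_r, 2) if pos[a] < pos[b])
    if rev_agree > fwd_agree:
        return "reversed", rev
    return "forward", projection


def detect_backbone(
    ordered: dict[str, list[OrderedBGC]],
    min_presence: float = 1.0,
) -> BackboneResult:
    """Find the conserved ordered backbone of a genome group.

    Candidates are families present in at least ``min_presence`` of the
    genomes.  The consensus order is the projection of the reference genome
    (most BGCs; ties by lexicographically smallest genome id).  If any
    genome's projection disagrees with the consensus beyond whole-genome
    reversal, the family involved in the most pairwise order conflicts is
    removed (ties lexicographic) and the check repeats.
    """
    genomes = sorted(ordered)
    if len(genomes) < 2:
        raise ValueError("backbone detection needs at least 2 genomes")
    n = len(genomes)
    presence: dict[str, int] = {}
    for records in ordered.values():
        for f in {rec.rgcf_id for rec in records}:
            presence[f] = presence.get(f, 0) + 1
    candidates = {f for f, c in presence.items() if c / n >= min_presence}
    if not candidates:
        logger.warning("no candidate backbone families at min_presence=%s", min_presence)
        return BackboneResult([], {}, {}, consistent=False)

    reference = min(genomes, key=lambda g: (-len(ordered[g]), g))
    removed: list[str] = []
    multicopy: dict[str, list[str]] = {}
    while True:
        projections: dict[str, list[str]] = {}
        for g in genomes:
            proj, multi = _project(ordered[g], candidates)
            projections[g] = proj
            if multi:
                multicopy[g] = multi
        consensus = projections[reference]
        pos = {f: i for i, f in enumerate(consensus)}
        conflicts: dict[str, int] = {}
        consistent = True
        for g in genomes:
            _, oriented = _orient(projections[g], consensus)
            if _restricted_equal(oriented, consensus):
                continue
            consistent = False
            shared = [f for f in oriented if f in pos]
            for a, b in combinations(shared, 2):
                if pos[a] > pos[b]:
                    conflicts[a] = conflicts.get(a, 0) + 1
                    conflicts[b] = conflicts.get(b, 0) + 1
        if consistent:
            orientation = {
                g: _orient(projections[g], consensus)[0] for g in genomes
            }
            return BackboneResult(
                backbone=consensus,
                projections=projections,
                orientation=orientation,
                consistent=True,
                removed=removed,
                multicopy=multicopy,
            )
        if not conflicts:
            # disagreement without pairwise conflicts (e.g. missing families
            # under min_presence < 1): report as-is, flagged inconsistent
            orientation = {g: _orient(projections[g], consensus)[0] for g in genomes}
            return BackboneResult(
                backbone=consensus,
                projections=projections,
                orientation=orientation,
                consistent=False,
                removed=removed,
                multicopy=multicopy,
            )
        worst = max(conflicts.values())
        victim = min(f for f, c in conflicts.items() if c == worst)
        candidates.discard(victim)
        removed.append(victim)
        if not candidates:
            return BackboneResult([], {}, {}, consistent=False, removed=removed)


def variable_regions(
    ordered: dict[str, list[OrderedBGC]],
    backbone: BackboneResult,
    anchor_a: str,
    anchor_b: str,
) -> dict[str, list[OrderedBGC]]:
    """Per genome, the BGCs strictly between two backbone anchors,
    respecting each genome's orientation."""
    if anchor_a not in backbone.backbone or anchor_b not in backbone.backbone:
        raise ValueError("both anchors must be backbone families")
    ia, ib = backbone.backbone.index(anchor_a), backbone.backbone.index(anchor_b)
    if abs(ia - ib) != 1:
        warnings.warn(
            "anchors are not adjacent in the backbone; the region spans "
            "intermediate backbone families"
        )
    out: dict[str, list[OrderedBGC]] = {}
    for g, records in ordered.items():
        seq = list(records)
        if backbone.orientation.get(g) == "reversed":
            seq = list(reversed(seq))
        idx_a = next((i for i, r in enumerate(seq) if r.rgcf_id == anchor_a), None)
        idx_b = next((i for i, r in enumerate(seq) if r.rgcf_id == anchor_b), None)
        if idx_a is None or idx_b is None:
            out[g] = []
            continue
        lo, hi = sorted((idx_a, idx_b))
        out[g] = seq[lo + 1 : hi]
    return out


def dotplot_points(
    ordered_a: list[OrderedBGC], ordered_b: list[OrderedBGC]
) -> list[tuple[int, int]]:
    """(i, j) ordinal pairs of BGCs sharing a regrouped family."""
    by_family: dict[str, list[int]] = {}
    for rec in ordered_b:
        by_family.setdefault(rec.rgcf_id, []).append(rec.position)
    points = []
    for rec in ordered_a:
        for j in by_family.get(rec.rgcf_id, []):
            points.append((rec.position, j))
    return sorted(points)


def render_dotplot(
    ordered_a: list[OrderedBGC],
    ordered_b: list[OrderedBGC],
    path: str,
    label_a: str = "genome A",
    label_b: str = "genome B",
) -> list[tuple[int, int]]:
    """Scatter the shared-family occurrences and save the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = dotplot_points(ordered_a, ordered_b)
    fig, ax = plt.subplots(figsize=(5, 5))
    if points:
        xs, ys = zip(*points)
        ax.scatter(xs, ys, s=18, color="#1f4e79")
    ax.set_xlabel(f"{label_a} (BGC ordinal)")
    ax.set_ylabel(f"{label_b} (BGC ordinal)")
    ax.set_title("Shared gene-cluster-family occurrences")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return points


def adjacency_edge_count(G: nx.MultiGraph) -> int:
    return sum(1 for _, _, k in G.edges(keys=True) if k == "adjacency")


def similarity_edge_count(G: nx.MultiGraph) -> int:
    return sum(1 for _, _, k in G.edges(keys=True) if k == "similarity")
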