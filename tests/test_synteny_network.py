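"""Chromosomal ordering, dual-edge graph construction, conserved-backbone
detection and variable-region extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panmash.gcf_regrouping import regroup, rgcf_of_bgc
from panmash.synteny_network import (
    adjacency_edge_count,
    build_graph,
    detect_backbone,
    dotplot_points,
    order_bgcs,
    similarity_edge_count,
    variable_regions,
)


def make_table(chromosomes: dict[str, list[str]], spacing: int = 100) -> pd.DataFrame:
    """One single-contig genome per entry; values are ordered family labels."""
    rows = []
    for genome, families in chromosomes.items():
        for i, fam in enumerate(families):
            rows.append(
                dict(
                    bgc_id=f"{genome}.r{i + 1:02d}",
                    genome_id=genome,
                    contig_id=f"{genome}.chr",
                    start=i * spacing,
                    end=i * spacing + 50,
                    bgc_type="terpene",
                    on_contig_edge=False,
                    gcf_id=fam,
                    mibig_hit="",
                    kcb_similarity=np.nan,
                )
            )
    return pd.DataFrame(rows)


def reverse_coordinates(table: pd.DataFrame, genome: str) -> pd.DataFrame:
    """Store one genome's coordinate system 5'->3' flipped."""
    out = table.copy()
    mask = out.genome_id == genome
    top = out.loc[mask, "end"].max()
    start = top - out.loc[mask, "end"]
    end = top - out.loc[mask, "start"]
    out.loc[mask, "start"], out.loc[mask, "end"] = start, end
    return out


BACKBONE = [f"B{i}" for i in range(1, 8)]  # planted 7-family backbone


class TestOrderBgcs:
    def test_positions_follow_start_coordinates(self):
        t = make_table({"g1": ["X", "Y", "Z"]})
        ordered = order_bgcs(t)
        assert [r.rgcf_id for r in ordered["g1"]] == ["X", "Y", "Z"]
        assert [r.position for r in ordered["g1"]] == [1, 2, 3]

    def test_reversing_coordinates_reverses_order(self):
        t = make_table({"g1": ["X", "Y", "Z"]})
        rev = reverse_coordinates(t, "g1")
        ordered = order_bgcs(rev)
        assert [r.rgcf_id for r in ordered["g1"]] == ["Z", "Y", "X"]

    def test_overlapping_bgcs_warn_but_keep_start_order(self):
        t = make_table({"g1": ["X", "Y"]}, spacing=30)  # end=50 > next start=30
        with pytest.warns(UserWarning, match="overlapping"):
            ordered = order_bgcs(t)
        assert [r.rgcf_id for r in ordered["g1"]] == ["X", "Y"]

    def test_generator_order_matches_planted_backbone(self, bgc_tables, truth):
        table, gcf_truth = bgc_tables
        genome = truth.loc[~truth.is_outlier, "genome_id"].iloc[0]
        ordered = order_bgcs(table, [genome])
        families = [r.rgcf_id for r in ordered[genome]]
        backbone = [g for g in families if g.startswith("GCF_BB")]
        assert backbone == sorted(backbone)  # fixed planted order BB01..BB07


class TestBuildGraph:
    def test_single_genome_path_graph(self):
        t = make_table({"g1": ["A", "B", "C", "D"]})
        G = build_graph(order_bgcs(t))
        assert adjacency_edge_count(G) == 3
        assert G.number_of_nodes() == 4

    def test_two_identical_genomes_matched_by_similarity(self):
        t = make_table({"g1": ["A", "B"], "g2": ["A", "B"]})
        G = build_graph(order_bgcs(t))
        assert adjacency_edge_count(G) == 2
        assert similarity_edge_count(G) == 2  # one per shared family pair

    def test_adjacency_never_spans_contigs(self):
        t = make_table({"g1": ["A", "B"]})
        t.loc[1, "contig_id"] = "g1.plasmid"
        G = build_graph(order_bgcs(t))
        assert adjacency_edge_count(G) == 0

    def test_adjacency_count_conservation(self, bgc_tables):
        table, _ = bgc_tables
        ordered = order_bgcs(table)
        G = build_graph(ordered)
        expected = sum(
            max(0, len(records) - 1) for records in ordered.values()
        )  # single contig per genome in the generator
        assert adjacency_edge_count(G) == expected

    def test_unknown_bgc_in_distance_list_rejected(self):
        t = make_table({"g1": ["A", "B"]})
        dist = pd.DataFrame({"bgc_a": ["nope"], "bgc_b": ["g1.r01"], "distance": [0.1]})
        with pytest.raises(ValueError, match="unknown BGCs"):
            build_graph(order_bgcs(t), distance_list=dist)

    def test_distance_list_cutoff_controls_similarity_edges(self):
        t = make_table({"g1": ["A", "B", "C"]})
        dist = pd.DataFrame(
            {
                "bgc_a": ["g1.r01", "g1.r01"],
                "bgc_b": ["g1.r02", "g1.r03"],
                "distance": [0.1, 0.9],
            }
        )
        G = build_graph(order_bgcs(t), distance_list=dist, distance_cutoff=0.3)
        assert similarity_edge_count(G) == 1


class TestDetectBackbone:
    def chromosomes(self, n_genomes=5):
        return {f"g{i}": list(BACKBONE) for i in range(n_genomes)}

    def test_planted_backbone_recovered_consistent(self):
        chroms = self.chromosomes()
        chroms["g1"] = ["B1", "B2", "V1", "B3", "B4", "B5", "B6", "B7"]
        result = detect_backbone(order_bgcs(make_table(chroms)))
        assert result.backbone == BACKBONE
        assert result.consistent and result.removed == []

    def test_reversed_genome_same_backbone_flagged_reversed(self):
        chroms = self.chromosomes()
        t = reverse_coordinates(make_table(chroms), "g2")
        result = detect_backbone(order_bgcs(t))
        assert result.backbone == BACKBONE or result.backbone == BACKBONE[::-1]
        assert result.consistent
        assert result.orientation["g2"] != result.orientation["g1"]

    def test_single_transposition_excludes_moved_family_only(self):
        chroms = self.chromosomes()
        # move B2 to the end in one genome
        chroms["g3"] = ["B1", "B3", "B4", "B5", "B6", "B7", "B2"]
        result = detect_backbone(order_bgcs(make_table(chroms)))
        assert result.removed == ["B2"]
        assert result.backbone == [b for b in BACKBONE if b != "B2"]
        assert result.consistent

    def test_invariant_to_genome_input_order(self):
        chroms = self.chromosomes()
        fwd = detect_backbone(order_bgcs(make_table(chroms)))
        rev_names = dict(reversed(list(chroms.items())))
        bwd = detect_backbone(order_bgcs(make_table(rev_names)))
        assert fwd.backbone == bwd.backbone

    def test_no_universal_family_yields_empty_backbone(self):
        chroms = {"g1": ["A", "B"], "g2": ["C", "D"]}
        result = detect_backbone(order_bgcs(make_table(chroms)))
        assert result.backbone == [] and not result.consistent

    def test_planted_generator_backbone_exact(self, bgc_tables, truth):
        table, gcf_truth = bgc_tables
        regrouped = regroup(table)
        mapping = rgcf_of_bgc(regrouped)
        planted = {
            f"RGCF_{row.mibig_hit}" if row.known else f"RGCF_{row.gcf_id}"
            for row in gcf_truth[gcf_truth.role == "backbone"].itertuples()
        }
        for primary, group in truth[~truth.is_outlier].groupby("primary"):
            ordered = order_bgcs(table, list(group.genome_id), mapping)
            result = detect_backbone(ordered)
            assert set(result.backbone) == planted
            assert result.consistent


class TestVariableRegions:
    def test_no_insertion_gives_empty_region(self):
        chroms = {"g1": list(BACKBONE), "g2": list(BACKBONE)}
        ordered = order_bgcs(make_table(chroms))
        backbone = detect_backbone(ordered)
        regions = variable_regions(ordered, backbone, "B2", "B3")
        assert all(v == [] for v in regions.values())

    def test_planted_insertion_returned_for_carriers_only(self):
        chroms = {
            "a1": ["B1", "B2", "X", "B3", "B4", "B5", "B6", "B7"],
            "a2": ["B1", "B2", "X", "B3", "B4", "B5", "B6", "B7"],
            "b1": list(BACKBONE),
        }
        ordered = order_bgcs(make_table(chroms))
        backbone = detect_backbone(ordered)
        regions = variable_regions(ordered, backbone, "B2", "B3")
        assert [r.rgcf_id for r in regions["a1"]] == ["X"]
        assert [r.rgcf_id for r in regions["a2"]] == ["X"]
        assert regions["b1"] == []

    def test_reversal_stored_genome_same_region_content(self):
        chroms = {
            "a1": ["B1", "B2", "X", "B3", "B4", "B5", "B6", "B7"],
            "a2": ["B1", "B2", "X", "B3", "B4", "B5", "B6", "B7"],
        }
        t = reverse_coordinates(make_table(chroms), "a2")
        ordered = order_bgcs(t)
        backbone = detect_backbone(ordered)
        regions = variable_regions(ordered, backbone, "B2", "B3")
        assert [r.rgcf_id for r in regions["a2"]] == ["X"]

    def test_non_adjacent_anchors_warn_and_span(self):
        chroms = {"g1": list(BACKBONE), "g2": list(BACKBONE)}
        ordered = order_bgcs(make_table(chroms))
        backbone = detect_backbone(ordered)
        with pytest.warns(UserWarning, match="not adjacent"):
            regions = variable_regions(ordered, backbone, "B1", "B4")
        assert [r.rgcf_id for r in regions["g1"]] == ["B2", "B3"]

    def test_anchor_outside_backbone_rejected(self):
        chroms = {"g1": list(BACKBONE), "g2": list(BACKBONE)}
        ordered = order_bgcs(make_table(chroms))
        backbone = detect_backbone(ordered)
        with pytest.raises(ValueError, match="anchors"):
            variable_regions(ordered, backbone, "B1", "NOPE")


class TestDotplot:
    def test_genome_vs_itself_main_diagonal(self):
        ordered = order_bgcs(make_table({"g1": ["A", "B", "C", "D"]}))
        points = dotplot_points(ordered["g1"], ordered["g1"])
        assert points == [(i, i) for i in range(1, 5)]

    def test_genome_vs_reversal_anti_diagonal(self):
        t = make_table({"g1": ["A", "B", "C", "D"], "g2": ["A", "B", "C", "D"]})
        t = reverse_coordinates(t, "g2")
        ordered = order_bgcs(t)
        points = dotplot_points(ordered["g1"], ordered["g2"])
        assert points == [(i, 5 - i) for i in range(1, 5)]

    def test_shared_backbone_only_monotone_points(self):
        chroms = {
            "g1": ["B1", "U1", "B2", "B3", "U2", "B4", "B5", "B6", "B7"],
            "g2": ["B1", "B2", "W1", "B3", "B4", "B5", "W2", "B6", "B7"],
        }
        ordered = order_bgcs(make_table(chroms))
        points = dotplot_points(ordered["g1"], ordered["g2"])
        assert len(points) == len(BACKBONE)
        ys = [j for _, j in points]
        assert ys == sorted(ys)

    def test_render_writes_figure(self, tmp_path):
        from panmash.synteny_network import render_dotplot

        ordered = order_bgcs(make_table({"g1": ["A", "B"], "g2": ["B", "A"]}))
        out = tmp_path / "dot.png"
        points = render_dotplot(ordered["g1"], ordered["g2"], str(out))
        assert out.exists() and len(points) == 2
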