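"""Iterative silhouette-filtered clustering: planted-partition recovery,
filtering invariants and degenerate inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from panmash.mash_clustering import (
    ClusteringConfig,
    choose_k,
    feature_rows,
    final_assignment,
    iterative_cluster,
    hierarchical_order,
    primary_clusters,
    rounds_to_frame,
    secondary_clusters,
)
from panmash.sketch_distance import DistanceMatrix


def block_matrix(sizes, within=0.01, between=0.2, seed=0) -> DistanceMatrix:
    """Planted block-structured distance matrix with small jitter."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    D = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    jitter = rng.uniform(0, within / 5, size=(n, n))
    D = D + (jitter + jitter.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = [f"g{i:03d}" for i in range(n)]
    return DistanceMatrix(ids, np.clip((D + D.T) / 2, 0, 1))


class TestFeatureRows:
    def test_identical_rows_have_zero_correlation_distance(self):
        D = np.array(
            [
                [0.0, 0.0, 0.5, 0.6],
                [0.0, 0.0, 0.5, 0.6],
                [0.5, 0.5, 0.0, 0.3],
                [0.6, 0.6, 0.3, 0.0],
            ]
        )
        _, corr = feature_rows(DistanceMatrix(list("abcd"), D))
        assert corr[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_two_genome_degenerate_rows_warn(self):
        D = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="zero variance"):
            X, corr = feature_rows(DistanceMatrix(["a", "b"], D))
        assert corr[0, 1] == 1.0

    def test_block_structure_reflected_in_correlation_distance(self):
        dm = block_matrix([5, 5], seed=2)
        _, corr = feature_rows(dm)
        within = [corr[i, j] for i in range(5) for j in range(i + 1, 5)]
        between = [corr[i, j] for i in range(5) for j in range(5, 10)]
        assert np.mean(within) < np.mean(between)

    def test_hierarchical_order_groups_blocks(self):
        dm = block_matrix([4, 4], seed=3)
        order = hierarchical_order(dm)
        positions = {g: i for i, g in enumerate(order)}
        first_block = sorted(positions[g] for g in dm.ids[:4])
        assert first_block in ([0, 1, 2, 3], [4, 5, 6, 7])


class TestChooseK:
    def test_three_separated_blocks_pick_three(self):
        dm = block_matrix([8, 8, 8], within=0.01, between=0.2, seed=4)
        X, _ = feature_rows(dm)
        k, labels, inertia, sils = choose_k(X, dm.D, ClusteringConfig(k_range=tuple(range(2, 8))))
        assert k == 3
        assert adjusted_rand_score(np.repeat([0, 1, 2], 8), labels) == 1.0

    def test_degenerate_blob_falls_back_to_smallest_k(self):
        # all-zero distances: silhouettes tie at 0, elbow ties at 0 -> min k
        n = 8
        dm = DistanceMatrix([f"g{i}" for i in range(n)], np.zeros((n, n)))
        X, _ = feature_rows(dm)
        k, _, _, sils = choose_k(X, dm.D, ClusteringConfig(k_range=(2, 3, 4)))
        assert k == 2
        assert all(v == 0.0 for v in sils.values())

    def test_k_range_truncated_with_warning(self):
        dm = block_matrix([3, 3], seed=5)
        X, _ = feature_rows(dm)
        with pytest.warns(UserWarning, match="truncated"):
            k, _, _, _ = choose_k(X, dm.D, ClusteringConfig(k_range=tuple(range(2, 21))))
        assert k <= 5


class TestIterativeCluster:
    def test_outliers_dropped_and_blocks_recovered(self):
        rng = np.random.default_rng(6)
        dm = block_matrix([8, 8, 8], within=0.01, between=0.2, seed=6)
        # append two far outliers
        n = len(dm.ids)
        D = np.full((n + 2, n + 2), 0.9)
        D[:n, :n] = dm.D
        D[n, n] = D[n + 1, n + 1] = 0.0
        D[n, n + 1] = D[n + 1, n] = 0.95
        dm2 = DistanceMatrix(dm.ids + ["out1", "out2"], (D + D.T) / 2)
        rounds = iterative_cluster(dm2, ClusteringConfig(k_range=tuple(range(2, 8))))
        final = final_assignment(rounds)
        dropped = {g for g, lab in final.items() if lab == "Dropped"}
        assert dropped == {"out1", "out2"}
        kept = [g for g in dm.ids]
        ari = adjusted_rand_score(
            np.repeat([0, 1, 2], 8), [final[g] for g in kept]
        )
        assert ari == 1.0

    def test_vacuous_cutoff_one_round_nothing_dropped(self):
        dm = block_matrix([5, 5], seed=7)
        rounds = iterative_cluster(
            dm, ClusteringConfig(k_range=(2, 3), silhouette_cutoff=-0.999)
        )
        assert len(rounds) == 1 and rounds[0].dropped == []

    def test_retained_plus_dropped_partition_input(self):
        dm = block_matrix([6, 6], seed=8)
        rounds = iterative_cluster(dm, ClusteringConfig(k_range=(2, 3, 4)))
        final = final_assignment(rounds)
        assert set(final) == set(dm.ids)

    def test_final_silhouettes_clear_cutoff(self, mash_dm):
        cfg = ClusteringConfig(k_range=tuple(range(2, 9)))
        rounds = iterative_cluster(mash_dm, cfg)
        last = rounds[-1]
        retained = set(last.labels) - set(last.dropped)
        assert all(last.silhouettes[g] >= cfg.silhouette_cutoff for g in retained)

    def test_all_dropped_raises(self):
        # mutually equidistant points: no structure, all silhouettes ~0
        n = 6
        D = np.full((n, n), 0.5)
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix([f"g{i}" for i in range(n)], D)
        with pytest.raises(ValueError, match="no stable clustering"):
            iterative_cluster(dm, ClusteringConfig(k_range=(2, 3), silhouette_cutoff=0.9))

    def test_raising_cutoff_never_retains_more(self):
        dm = block_matrix([8, 8], within=0.02, between=0.15, seed=9)
        retained = []
        for cutoff in (0.1, 0.4, 0.7):
            rounds = iterative_cluster(
                dm, ClusteringConfig(k_range=(2, 3, 4), silhouette_cutoff=cutoff)
            )
            final = final_assignment(rounds)
            retained.append(sum(1 for v in final.values() if v != "Dropped"))
        assert retained[0] >= retained[1] >= retained[2]

    def test_permuting_genome_order_permutes_labels_consistently(self):
        dm = block_matrix([6, 6, 6], seed=10)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dm.ids))
        dm_p = DistanceMatrix(
            [dm.ids[i] for i in perm], dm.D[np.ix_(perm, perm)]
        )
        f1 = final_assignment(iterative_cluster(dm, ClusteringConfig(k_range=(2, 3, 4))))
        f2 = final_assignment(iterative_cluster(dm_p, ClusteringConfig(k_range=(2, 3, 4))))
        ids = dm.ids
        a = [f1[g] for g in ids]
        b = [f2[g] for g in ids]
        assert adjusted_rand_score(
            [str(x) for x in a], [str(x) for x in b]
        ) == 1.0


class TestTwoLevel:
    def test_planted_population_recovered_at_both_levels(self, mash_dm, truth):
        cfg = ClusteringConfig()
        primary_table, rounds = primary_clusters(mash_dm, cfg)
        tr = truth.set_index("genome_id")
        dropped = set(primary_table.loc[primary_table.primary_label == "Dropped", "genome_id"])
        assert dropped == set(truth.loc[truth.is_outlier, "genome_id"])
        kept = primary_table[primary_table.primary_label != "Dropped"]
        assert adjusted_rand_score(
            [tr.loc[g].primary for g in kept.genome_id], kept.primary_label
        ) == 1.0
        secondary_table, _ = secondary_clusters(mash_dm, primary_table, cfg)
        assigned = secondary_table[secondary_table.secondary_label != "Dropped"]
        assert adjusted_rand_score(
            [tr.loc[g].secondary for g in assigned.genome_id], assigned.secondary_label
        ) == 1.0
        assert assigned.secondary_label.str.match(r"M\d+_\d+").all()

    def test_small_primary_cluster_passes_through_unsplit(self):
        dm = block_matrix([2, 8, 8], within=0.01, between=0.2, seed=11)
        primary_table = pd.DataFrame(
            {
                "genome_id": dm.ids,
                "primary_label": ["M3", "M3"] + ["M1"] * 8 + ["M2"] * 8,
                "silhouette": 0.9,
                "dropped_round": np.nan,
            }
        )
        with pytest.warns(UserWarning, match="unsplit"):
            table, _ = secondary_clusters(dm, primary_table, ClusteringConfig(k_range=(2, 3)))
        small = table[table.primary_label == "M3"]
        assert (small.secondary_label == "M3_1").all() and small.unsplit.all()

    def test_rounds_frame_schema(self, mash_dm):
        table, rounds = primary_clusters(mash_dm, ClusteringConfig(k_range=tuple(range(2, 9))))
        frame = rounds_to_frame(rounds, mash_dm.ids)
        assert "final_label" in frame.columns
        assert frame.genome_id.tolist() == mash_dm.ids
        assert {f"cluster_round_{r.round_index}" for r in rounds} <= set(frame.columns)
        # retained + dropped = input, disjoint
        final = frame.final_label
        assert ((final == "Dropped") | final.astype(str).str.isdigit()).all()
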