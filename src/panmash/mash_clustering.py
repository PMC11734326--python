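"""Two-level K-means clustering of a Mash distance matrix with iterative
silhouette-based removal of poorly clustered genomes.

Each genome is represented by its row of the distance matrix.  For every
candidate cluster count k, K-means (many restarts, fixed seed) partitions the
rows; the partition is scored by the average silhouette computed with the
*precomputed Mash distance* as the metric, so the score reflects the genomic
distance being interpreted rather than Euclidean geometry on rows.  The best
k maximises the average silhouette; exact ties fall back to the elbow
criterion (largest second difference of the inertia curve) and then to the
smaller k.

Genomes whose silhouette falls below the cutoff (default 0.4) are removed and
the procedure repeats until every retained genome clears the cutoff.  The
same machinery is applied once more inside every primary cluster to yield
secondary clusters, labelled ``M<i>_<j>``.

A Pearson-correlation distance between matrix rows (1 - r) and a Ward
hierarchical ordering of it are also provided for heatmap display; they play
no role in the assignment itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .sketch_distance import DistanceMatrix

logger = logging.getLogger(__name__)

#: Silhouette averages closer than this are treated as tied and resolved by
#: the elbow rule, then by the smaller k.
_SILHOUETTE_TIE_TOL = 1e-9


@dataclass
class ClusteringConfig:
    """Parameters of the iterative clustering."""

    k_range: tuple[int, ...] = tuple(range(2, 21))
    silhouette_cutoff: float = 0.4
    max_rounds: int = 10
    random_seed: int = 0
    n_init: int = 50

    def __post_init__(self) -> None:
        if not self.k_range:
            raise ValueError("k_range must be non-empty")
        if any(k < 2 for k in self.k_range):
            raise ValueError("cluster counts must be >= 2")
        if not -1.0 < self.silhouette_cutoff < 1.0:
            raise ValueError("silhouette cutoff must lie in (-1, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class ClusterRound:
    """One filtering round: labels (1..k, contiguous) and silhouettes for the
    genomes retained in this round, and the ids dropped at its end."""

    round_index: int
    chosen_k: int
    labels: dict[str, int]
    silhouettes: dict[str, float]
    mean_silhouette: float
    dropped: list[str]
    inertia_curve: dict[int, float] = field(default_factory=dict)
    silhouette_curve: dict[int, float] = field(default_factory=dict)


def feature_rows(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-genome feature vectors (rows of D) and the Pearson-correlation
    distance matrix (1 - r) between those rows.

    Zero-variance rows have no defined correlation; their off-diagonal
    correlation distance is set to 1 with a warning.
    """
    X = dm.D.copy()
    n = X.shape[0]
    std = X.std(axis=1)
    degenerate = std == 0
    corr_dist = np.ones((n, n))
    np.fill_diagonal(corr_dist, 0.0)
    ok = ~degenerate
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genome rows have zero variance; "
            "their correlation distance is defined as 1"
        )
    if ok.sum() >= 2:
        r = np.corrcoef(X[ok])
        sub = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(sub, 0.0)
        corr_dist[np.ix_(ok, ok)] = sub
    return X, corr_dist


def hierarchical_order(dm: DistanceMatrix) -> list[str]:
    """Ward leaf ordering of genomes on the correlation distance of rows
    (display ordering for heatmaps/dendrograms)."""
    _, corr_dist = feature_rows(dm)
    corr_dist = (corr_dist + corr_dist.T) / 2.0
    np.fill_diagonal(corr_dist, 0.0)
    Z = linkage(squareform(corr_dist, checks=False), method="ward")
    return [dm.ids[i] for i in leaves_list(Z)]


def _silhouettes(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouettes on a precomputed distance matrix; degenerate
    inputs (all-zero distances) score 0."""
    if np.all(D[np.triu_indices_from(D, k=1)] == 0):
        return np.zeros(D.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sil = silhouette_samples(D, labels, metric="precomputed")
    return np.nan_to_num(sil, nan=0.0)


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k, ordered by decreasing size then first member."""
    sizes = {}
    first = {}
    for i, lab in enumerate(labels):
        sizes[lab] = sizes.get(lab, 0) + 1
        first.setdefault(lab, i)
    order = sorted(sizes, key=lambda lab: (-sizes[lab], first[lab]))
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([mapping[lab] for lab in labels])


def choose_k(
    features: np.ndarray,
    D: np.ndarray,
    config: ClusteringConfig,
) -> tuple[int, np.ndarray, dict[int, float], dict[int, float]]:
    """Pick the cluster count maximising average silhouette.

    Returns ``(k_star, labels_at_k_star, inertia_curve, silhouette_curve)``.
    Candidate counts above n - 1 are truncated with a warning.
    """
    n = features.shape[0]
    ks = sorted({k for k in config.k_range if k <= n - 1})
    if len(ks) < len(set(config.k_range)):
        warnings.warn(f"k_range truncated to {ks} for n={n}")
    if not ks:
        raise ValueError(f"no feasible cluster count for n={n}")
    inertia: dict[int, float] = {}
    sil_curve: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(
            n_clusters=k,
            n_init=config.n_init,
            random_state=config.random_seed,
        ).fit(features)
        labels_by_k[k] = km.labels_
        inertia[k] = float(km.inertia_)
        sil_curve[k] = float(np.mean(_silhouettes(D, km.labels_)))
    best = max(sil_curve.values())
    tied = [k for k in ks if best - sil_curve[k] <= _SILHOUETTE_TIE_TOL]
    if len(tied) > 1:
        # elbow on the inertia curve: largest second difference, then smaller k
        second_diff = {}
        for k in tied:
            if k - 1 in inertia and k + 1 in inertia:
                second_diff[k] = inertia[k - 1] - 2 * inertia[k] + inertia[k + 1]
            else:
                second_diff[k] = 0.0  # boundary k: neutral elbow evidence
        best_sd = max(second_diff.values())
        tied = [k for k in tied if second_diff[k] >= best_sd - _SILHOUETTE_TIE_TOL]
        k_star = min(tied)
    else:
        k_star = tied[0]
    return k_star, labels_by_k[k_star], inertia, sil_curve


def iterative_cluster(
    dm: DistanceMatrix, config: ClusteringConfig | None = None
) -> list[ClusterRound]:
    """Cluster, drop genomes below the silhouette cutoff, repeat.

    The final round is the assignment: every genome retained there has a
    silhouette at or above the cutoff.  Raises if every genome would be
    dropped.
    """
    config = config or ClusteringConfig()
    if len(dm.ids) < 3:
        raise ValueError("iterative clustering needs at least 3 genomes")
    retained = list(dm.ids)
    rounds: list[ClusterRound] = []
    for round_index in range(1, config.max_rounds + 1):
        sub = dm.submatrix(retained)
        features, _ = feature_rows(sub)
        k_star, raw_labels, inertia, sil_curve = choose_k(features, sub.D, config)
        labels = _contiguous(raw_labels)
        sil = _silhouettes(sub.D, labels)
        drop_mask = sil < config.silhouette_cutoff
        dropped = [g for g, d in zip(retained, drop_mask) if d]
        keep = [g for g, d in zip(retained, drop_mask) if not d]
        rounds.append(
            ClusterRound(
                round_index=round_index,
                chosen_k=k_star,
                labels={g: int(lab) for g, lab in zip(retained, labels)},
                silhouettes={g: float(x) for g, x in zip(retained, sil)},
                mean_silhouette=float(np.mean(sil)),
                dropped=dropped,
                inertia_curve=inertia,
                silhouette_curve=sil_curve,
            )
        )
        if not keep:
            raise ValueError("no stable clustering at this cutoff: all genomes dropped")
        if not dropped:
            return rounds
        if len(keep) < 3:
            logger.warning(
                "fewer than 3 genomes retained after round %d; stopping with last stable round",
                round_index,
            )
            return rounds
        retained = keep
    logger.warning("max_rounds reached before silhouette filtering converged")
    return rounds


def final_assignment(rounds: list[ClusterRound]) -> dict[str, int | str]:
    """Genome -> final cluster label (int) or 'Dropped'."""
    last = rounds[-1]
    out: dict[str, int | str] = {}
    for r in rounds:
        for g in r.dropped:
            out[g] = "Dropped"
    for g, lab in last.labels.items():
        if g not in out:
            out[g] = lab
    return out


def rounds_to_frame(rounds: list[ClusterRound], all_ids: list[str]) -> pd.DataFrame:
    """Per-round assignment table (one row per genome, one label and one
    silhouette column per round, plus the final label)."""
    data: dict[str, list] = {"genome_id": list(all_ids)}
    dropped_at: dict[str, int] = {}
    for r in rounds:
        labels_col = []
        sil_col = []
        for g in all_ids:
            if g in dropped_at and dropped_at[g] < r.round_index:
                labels_col.append("Dropped")
                sil_col.append(np.nan)
            elif g in r.labels:
                labels_col.append("Dropped" if g in r.dropped else r.labels[g])
                sil_col.append(r.silhouettes[g])
            else:
                labels_col.append("Dropped")
                sil_col.append(np.nan)
        for g in r.dropped:
            dropped_at[g] = r.round_index
        data[f"cluster_round_{r.round_index}"] = labels_col
        data[f"silhouette_round_{r.round_index}"] = sil_col
    final = final_assignment(rounds)
    data["final_label"] = [final.get(g, "Dropped") for g in all_ids]
    return pd.DataFrame(data)


def primary_clusters(
    dm: DistanceMatrix, config: ClusteringConfig | None = None
) -> tuple[pd.DataFrame, list[ClusterRound]]:
    """Primary Mash-clusters with 'M<i>' labels.

    Returns a table (genome_id, primary_label, silhouette) where dropped
    genomes carry 'Dropped' and the round of removal, plus the raw rounds.
    """
    rounds = iterative_cluster(dm, config)
    final = final_assignment(rounds)
    dropped_round = {}
    for r in rounds:
        for g in r.dropped:
            dropped_round[g] = r.round_index
    last = rounds[-1]
    rows = []
    for g in dm.ids:
        lab = final[g]
        if lab == "Dropped":
            rows.append((g, "Dropped", np.nan, dropped_round[g]))
        else:
            rows.append((g, f"M{lab}", last.silhouettes[g], np.nan))
    table = pd.DataFrame(
        rows, columns=["genome_id", "primary_label", "silhouette", "dropped_round"]
    )
    return table, rounds


def secondary_clusters(
    dm: DistanceMatrix,
    primary_table: pd.DataFrame,
    config: ClusteringConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[ClusterRound]]]:
    """Re-cluster each primary cluster independently; labels 'M<i>_<j>'.

    Primary clusters too small to split (fewer than 3 genomes) or with no
    silhouette-stable substructure pass through unsplit as 'M<i>_1'.
    """
    config = config or ClusteringConfig()
    rows = []
    all_rounds: dict[str, list[ClusterRound]] = {}
    assigned = primary_table[primary_table.primary_label != "Dropped"]
    for primary_label, group in assigned.groupby("primary_label", sort=True):
        ids = list(group.genome_id)
        if len(ids) < 3:
            warnings.warn(
                f"primary cluster {primary_label} has {len(ids)} genomes; passed through unsplit"
            )
            for g in ids:
                rows.append((g, primary_label, f"{primary_label}_1", np.nan, True))
            continue
        sub = dm.submatrix(ids)
        try:
            rounds = iterative_cluster(sub, config)
        except ValueError as err:
            logger.warning("primary cluster %s: %s; reported unsplit", primary_label, err)
            for g in ids:
                rows.append((g, primary_label, f"{primary_label}_1", np.nan, True))
            continue
        all_rounds[str(primary_label)] = rounds
        final = final_assignment(rounds)
        last = rounds[-1]
        for g in ids:
            lab = final[g]
            if lab == "Dropped":
                rows.append((g, primary_label, "Dropped", np.nan, False))
            else:
                rows.append(
                    (g, primary_label, f"{primary_label}_{lab}", last.silhouettes[g], False)
                )
    table = pd.DataFrame(
        rows,
        columns=["genome_id", "primary_label", "secondary_label", "silhouette", "unsplit"],
    )
    return table, all_rounds
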