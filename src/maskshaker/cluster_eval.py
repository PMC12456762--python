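"""k-Means and Leiden clustering plus ARI-based consistency scoring.

Cluster assignments of ground-truth and perturbed feature tables are
compared with the Adjusted Rand Index. Because both algorithms are
initialization-sensitive, each table is clustered several times with
distinct seeds and the best-matching pair of runs is reported, so the
remaining disagreement is attributable to the perturbation rather than to
unlucky initializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
from scipy.special import comb
from sklearn.cluster import KMeans

from .errors import ValidationError
from .features import FeatureTable
from .neighborhood import KNNGraph, knn_graph


@dataclass
class Clustering:
    cell_ids: np.ndarray
    labels: np.ndarray
    algorithm: str
    params: dict
    seed: int

    def __post_init__(self):
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("labels must cover all listed cells")


def kmeans_cluster(ft: FeatureTable, k: int, seed: int = 0) -> Clustering:
    """Lloyd k-means (k-means++ init, single seeded start) on the marker
    columns."""
    n = len(ft)
    if k > n:
        raise ValidationError(f"k={k} exceeds number of cells {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                tol=1e-4, random_state=seed)
    labels = km.fit_predict(ft.marker_matrix())
    return Clustering(ft.cell_ids.copy(), labels, "kmeans", {"k": k}, seed)


def leiden_cluster(g: KNNGraph, resolution: float = 1.0, seed: int = 0) -> Clustering:
    """Leiden community detection on the symmetrized (edge-union),
    unweighted kNN graph, modularity objective."""
    n = len(g.cell_ids)
    if n == 0:
        raise ValidationError("empty graph")
    pos = {int(c): i for i, c in enumerate(g.cell_ids)}
    edges = set()
    for cid, nbrs in zip(g.cell_ids.tolist(), g.neighbors.tolist()):
        i = pos[cid]
        for nb in nbrs:
            j = pos[nb]
            edges.add((min(i, j), max(i, j)))
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return Clustering(
        g.cell_ids.copy(),
        np.asarray(part.membership),
        "leiden",
        {"knn": g.k, "resolution": resolution},
        seed,
    )


def adjusted_rand_index(a: Clustering, b: Clustering) -> float:
    """Chance-corrected agreement of two partitions of the same cells.

    Computed from the contingency table:
    (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) and
    max = [sum_i C(a_i,2) + sum_j C(b_j,2)] / 2.
    """
    ia = np.argsort(a.cell_ids, kind="stable")
    ib = np.argsort(b.cell_ids, kind="stable")
    if not np.array_equal(a.cell_ids[ia], b.cell_ids[ib]):
        raise ValidationError("clusterings cover different cell ID sets")
    la = a.labels[ia]
    lb = b.labels[ib]
    n = la.size
    _, la_codes = np.unique(la, return_inverse=True)
    _, lb_codes = np.unique(lb, return_inverse=True)
    nb = lb_codes.max() + 1
    contingency = np.bincount(la_codes * nb + lb_codes, minlength=(la_codes.max() + 1) * nb)
    sum_ij = comb(contingency, 2).sum()
    sum_a = comb(np.bincount(la_codes), 2).sum()
    sum_b = comb(np.bincount(lb_codes), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # both partitions trivial (all-one-cluster or all-singletons)
        return 1.0 if np.array_equal(la_codes, lb_codes) else 0.0
    return float((sum_ij - expected) / (maximum - expected))


def cluster_runs(
    ft: FeatureTable,
    algorithm: str = "kmeans",
    n_seeds: int = 5,
    seed: int = 0,
    **params,
) -> list[Clustering]:
    """One clustering per seed in ``seed .. seed+n_seeds-1``.

    ``params``: ``k`` for k-means; ``knn`` (and optional ``resolution``)
    for Leiden.
    """
    if algorithm == "kmeans":
        return [kmeans_cluster(ft, params["k"], seed=seed + s) for s in range(n_seeds)]
    if algorithm == "leiden":
        g = knn_graph(ft, params["knn"])
        res = params.get("resolution", 1.0)
        return [leiden_cluster(g, resolution=res, seed=seed + s) for s in range(n_seeds)]
    raise ValidationError(f"unknown algorithm {algorithm!r}")


def max_pairwise_ari(runs_a: list[Clustering], runs_b: list[Clustering]) -> float:
    """Most similar pair of cluster assignments across two run sets."""
    return max(adjusted_rand_index(ca, cb) for ca in runs_a for cb in runs_b)


def best_match_ari(
    ft_gt: FeatureTable,
    ft_pert: FeatureTable,
    algorithm: str = "kmeans",
    n_seeds: int = 5,
    seed: int = 0,
    **params,
) -> float:
    """Max ARI over all pairs of seeded runs on ground-truth vs perturbed
    features, restricted to common cell IDs."""
    common = np.intersect1d(ft_gt.cell_ids, ft_pert.cell_ids)
    if common.size == 0:
        raise ValidationError("no common cell IDs")
    runs_gt = cluster_runs(ft_gt.subset(common), algorithm, n_seeds, seed, **params)
    runs_pert = cluster_runs(ft_pert.subset(common), algorithm, n_seeds, seed, **params)
    return max_pairwise_ari(runs_gt, runs_pert)
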