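"""Exact kNN graphs in expression space and neighborhood-preservation scores.

Neighborhoods are computed by brute force (full pairwise Euclidean
distances) rather than any approximate index, so the scores carry no
indexing noise. Distance ties are broken by ascending cell ID, which makes
the graph — and every score derived from it — exactly reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FeatureTable

_CHUNK = 1024  # rows of the distance matrix computed at a time


@dataclass
class KNNGraph:
    """For each cell (ordered by ``cell_ids``), its k nearest neighbor IDs."""

    cell_ids: np.ndarray  # (n,)
    neighbors: np.ndarray  # (n, k) of cell IDs
    k: int
    metric: str = "euclidean"

    def neighbor_sets(self) -> dict[int, set[int]]:
        return {
            int(cid): set(row.tolist())
            for cid, row in zip(self.cell_ids, self.neighbors)
        }


def knn_graph(ft: FeatureTable, k: int) -> KNNGraph:
    """Exact Euclidean k-nearest-neighbor graph on the marker columns."""
    n = len(ft)
    if n < k + 1:
        raise ValidationError(f"need at least k+1={k + 1} cells, got {n}")
    order = np.argsort(ft.cell_ids, kind="stable")
    ids = ft.cell_ids[order]
    x = ft.marker_matrix()[order]
    sq = np.einsum("ij,ij->i", x, x)
    neighbors = np.empty((n, k), dtype=np.int64)
    rank = np.arange(n)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (x[start:stop] @ x.T)
        np.maximum(d2, 0.0, out=d2)
        # sort by distance, then by position (== ascending cell ID) on ties
        idx = np.lexsort((np.broadcast_to(rank, d2.shape), d2), axis=1)
        for i, row in enumerate(idx):
            row = row[row != start + i][:k]  # self excluded by position
            neighbors[start + i] = ids[row]
    return KNNGraph(ids, neighbors, k)


def jknn(g_gt: KNNGraph, g_pert: KNNGraph) -> pd.Series:
    """Per-cell Jaccard similarity of neighbor sets between two graphs.

    Evaluated over the cells present in both graphs, with each neighbor set
    restricted to those common cells first (a neighbor that does not exist
    in the other dataset cannot be preserved).
    """
    if g_gt.k != g_pert.k:
        raise ValidationError(f"k mismatch: {g_gt.k} vs {g_pert.k}")
    common = set(g_gt.cell_ids.tolist()) & set(g_pert.cell_ids.tolist())
    sets_gt = g_gt.neighbor_sets()
    sets_pert = g_pert.neighbor_sets()
    out = {}
    for cid in sorted(common):
        a = sets_gt[cid] & common
        b = sets_pert[cid] & common
        union = len(a | b)
        out[cid] = len(a & b) / union if union else 1.0
    return pd.Series(out, dtype=float)


def knn_accuracy(g_pert: KNNGraph, labels: pd.Series | dict) -> float:
    """Fraction of cells whose label matches the majority label of their
    neighborhood in the perturbed graph; majority ties break lexicographically."""
    lut = dict(pd.Series(labels).items())
    missing = [c for c in g_pert.cell_ids.tolist() if c not in lut]
    if missing:
        raise ValidationError(f"{len(missing)} graph cells lack labels")
    hits = 0
    for cid, nbrs in zip(g_pert.cell_ids.tolist(), g_pert.neighbors.tolist()):
        counts = Counter(lut[n] for n in nbrs)
        top = max(counts.values())
        majority = min(lbl for lbl, c in counts.items() if c == top)
        hits += majority == lut[cid]
    return hits / len(g_pert.cell_ids)
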