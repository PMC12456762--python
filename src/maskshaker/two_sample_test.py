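"""Classifier two-sample test between original and perturbed feature tables.

A gradient-boosted tree classifier tries to tell which table each cell came
from under stratified cross-validation. Held-out accuracy near 0.5 means
the perturbation left the marker distribution statistically indistinguishable
from the original; accuracy near 1.0 flags a clear distributional shift.
Tables of unequal size are seeded-downsampled to balance, so 0.5 is the
exact chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedGroupKFold

from .errors import ValidationError
from .features import FeatureTable


@dataclass
class C2STResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    n_per_class: int
    classifier: str
    seed: int


def c2st(
    ft_a: FeatureTable,
    ft_b: FeatureTable,
    seed: int = 0,
    n_folds: int = 5,
    common_ids_only: bool = False,
) -> C2STResult:
    """Cross-validated two-sample test on the marker columns of two tables."""
    if ft_a.markers != ft_b.markers:
        raise ValidationError("tables must share marker columns")
    if common_ids_only:
        common = np.intersect1d(ft_a.cell_ids, ft_b.cell_ids)
        ft_a, ft_b = ft_a.subset(common), ft_b.subset(common)
    # canonical row order (by cell ID) so results don't depend on how the
    # tables were assembled
    oa = np.argsort(ft_a.cell_ids, kind="stable")
    ob = np.argsort(ft_b.cell_ids, kind="stable")
    xa, ids_a = ft_a.marker_matrix()[oa], ft_a.cell_ids[oa]
    xb, ids_b = ft_b.marker_matrix()[ob], ft_b.cell_ids[ob]
    n = min(len(xa), len(xb))
    if n < 2 * n_folds:
        raise ValidationError(f"need >= {2 * n_folds} rows per class, got {n}")
    rng = np.random.default_rng(seed)
    if len(xa) > n:
        keep = np.sort(rng.choice(len(xa), n, replace=False))
        xa, ids_a = xa[keep], ids_a[keep]
    if len(xb) > n:
        keep = np.sort(rng.choice(len(xb), n, replace=False))
        xb, ids_b = xb[keep], ids_b[keep]
    x = np.vstack([xa, xb])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    # the two versions of one cell are dependent samples: folds are grouped
    # by cell ID so a cell never sits in train with one label and in test
    # with the other
    groups = np.concatenate([ids_a, ids_b])

    clf = LGBMClassifier(
        random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
        force_row_wise=True,
    )
    folds = []
    skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y, groups=groups):
        clf.fit(x[train], y[train])
        folds.append(float(np.mean(clf.predict(x[test]) == y[test])))
    return C2STResult(folds, float(np.mean(folds)), n, "lightgbm", seed)
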