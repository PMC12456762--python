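"""Hierarchical GMM-based phenotyping and phenotype-error metrics.

Marker positivity is decided per marker by a three-component 1-D Gaussian
mixture: the two lower-mean components model background/low expression, the
highest-mean component models genuinely positive cells, which suppresses
false-positive gating from the heavy upper tail of the negative population.
Positivity calls are combined by descending a gating tree — a rooted
hierarchy in which each node adds marker requirements to its parent's — and
a cell is assigned the deepest node whose requirements it satisfies.

Disagreement between two phenotype assignments is quantified three ways:
balanced accuracy (macro-averaged recall), row-normalized confusion
percentages, and the Wu-Palmer tree distance, which grades how severe a
mislabel is (0 = same node, 1 = wrong lineage altogether).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.mixture import GaussianMixture

from .errors import ValidationError
from .features import FeatureTable, log1p_transform

UNASSIGNED = "unassigned"
ROOT = "root"


@dataclass
class GatingTree:
    """Rooted phenotype hierarchy; each node carries cumulative marker
    requirements (marker name -> required positivity)."""

    parents: dict[str, str | None]  # node -> parent (root -> None)
    requirements: dict[str, dict[str, bool]]  # node -> {marker: wanted positivity}

    def __post_init__(self):
        if ROOT not in self.parents or self.parents[ROOT] is not None:
            raise ValidationError("tree must contain a parentless 'root' node")
        for node, parent in self.parents.items():
            if node == ROOT:
                continue
            if parent not in self.parents:
                raise ValidationError(f"node {node!r} has unknown parent {parent!r}")
            preq = self.requirements.get(parent, {})
            req = self.requirements.get(node, {})
            for marker, pol in preq.items():
                if req.get(marker) != pol:
                    raise ValidationError(
                        f"node {node!r} must inherit requirement {marker}={pol} "
                        f"from parent {parent!r}"
                    )

    @property
    def nodes(self) -> list[str]:
        return list(self.parents)

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parents.items() if p == node)

    def leaves(self) -> list[str]:
        return sorted(n for n in self.parents if not self.children(n) and n != ROOT)

    def depth(self, node: str) -> int:
        if node not in self.parents:
            raise KeyError(f"node {node!r} not in tree")
        d = 0
        while self.parents[node] is not None:
            node = self.parents[node]
            d += 1
        return d

    def ancestors(self, node: str) -> list[str]:
        """Path from ``node`` up to and including the root."""
        out = [node]
        while self.parents[out[-1]] is not None:
            out.append(self.parents[out[-1]])
        return out

    def lca(self, x: str, y: str) -> str:
        ax = self.ancestors(x)
        ay = set(self.ancestors(y))
        for node in ax:
            if node in ay:
                return node
        return ROOT

    def markers(self) -> list[str]:
        """All markers referenced by any node."""
        out: set[str] = set()
        for req in self.requirements.values():
            out.update(req)
        return sorted(out)

    def positive_markers(self, node: str) -> set[str]:
        return {m for m, pol in self.requirements.get(node, {}).items() if pol}

    @classmethod
    def from_yaml(cls, path) -> "GatingTree":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        parents, requirements = {ROOT: None}, {ROOT: {}}
        for node in data["nodes"]:
            name = node["name"]
            parents[name] = node.get("parent", ROOT)
            requirements[name] = {
                m: str(v) in ("+", "True", "true", "1")
                for m, v in (node.get("requires") or {}).items()
            }
        return cls(parents, requirements)

    def to_yaml(self, path) -> None:
        nodes = [
            {
                "name": n,
                "parent": p,
                "requires": {m: "+" if v else "-" for m, v in self.requirements[n].items()},
            }
            for n, p in self.parents.items()
            if n != ROOT
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"nodes": nodes}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# GMM gating


@dataclass
class MarkerGate:
    """Three 1-D Gaussian components for one marker, sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray


@dataclass
class GateModel:
    gates: dict[str, MarkerGate] = field(default_factory=dict)
    seed: int = 0
    preprocessing: str = "log1p"


def fit_marker_gmm(values: np.ndarray, seed: int = 0) -> MarkerGate:
    """EM-fit a 3-component Gaussian mixture to one marker's per-cell values."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 30:
        raise ValidationError(f"need >= 30 cells to fit a gate, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("marker values must be finite")
    if np.ptp(values) == 0:
        raise ValidationError("constant marker column; gate is undefined")
    gm = GaussianMixture(n_components=3, covariance_type="full",
                         n_init=3, random_state=seed)
    gm.fit(values[:, None])
    order = np.argsort(gm.means_.ravel())
    return MarkerGate(
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
    )


def gate_positive(gate: MarkerGate, values: np.ndarray) -> np.ndarray:
    """Positive iff the most probable component is the highest-mean one."""
    values = np.asarray(values, dtype=float).ravel()
    log_like = (
        -0.5 * ((values[:, None] - gate.means[None, :]) / gate.sds[None, :]) ** 2
        - np.log(gate.sds[None, :])
        + np.log(gate.weights[None, :])
    )
    return log_like.argmax(axis=1) == len(gate.means) - 1


def fit_gate_model(ft: FeatureTable, tree: GatingTree, seed: int = 0,
                   stabilize: bool = True) -> GateModel:
    """Fit one marker gate per tree-referenced marker (log1p-stabilized by
    default)."""
    table = ft
    if stabilize and ft.preprocessing == "raw":
        table = log1p_transform(ft)
    model = GateModel(seed=seed, preprocessing=table.preprocessing)
    for marker in tree.markers():
        if marker not in table.markers:
            raise ValidationError(f"tree marker {marker!r} absent from feature table")
        model.gates[marker] = fit_marker_gmm(
            table.data[marker].to_numpy(), seed=seed
        )
    return model


def assign_phenotypes(ft: FeatureTable, tree: GatingTree,
                      gates: GateModel) -> pd.Series:
    """Descend the gating tree per cell to the deepest satisfiable node.

    At each node the cell moves to the unique child whose requirements its
    gate statuses satisfy; with no satisfiable child it stays put, with
    several the descent also stops (granularity-conservative). Cells
    stopping at the root are 'unassigned'.
    """
    table = ft
    if gates.preprocessing == "log1p" and ft.preprocessing == "raw":
        table = log1p_transform(ft)
    missing = [m for m in tree.markers() if m not in table.markers]
    if missing:
        raise ValidationError(f"tree markers absent from table: {missing}")
    positive = {
        m: gate_positive(gates.gates[m], table.data[m].to_numpy())
        for m in tree.markers()
    }
    n = len(table)
    assignment = np.full(n, ROOT, dtype=object)
    active = {ROOT: np.arange(n)}
    while active:
        nxt: dict[str, np.ndarray] = {}
        for node, idx in active.items():
            kids = tree.children(node)
            if not kids:
                continue
            sat = np.zeros((len(kids), idx.size), dtype=bool)
            for ki, kid in enumerate(kids):
                ok = np.ones(idx.size, dtype=bool)
                for marker, pol in tree.requirements[kid].items():
                    ok &= positive[marker][idx] == pol
                sat[ki] = ok
            unique = sat.sum(axis=0) == 1
            for ki, kid in enumerate(kids):
                moved = idx[sat[ki] & unique]
                if moved.size:
                    assignment[moved] = kid
                    nxt[kid] = moved
        active = nxt
    out = pd.Series(assignment, index=table.data.index, name="phenotype")
    return out.replace({ROOT: UNASSIGNED})


# ---------------------------------------------------------------------------
# Phenotype-error metrics


def wu_palmer_distance(tree: GatingTree, x: str, y: str) -> float:
    """1 - 2N / (N_x + N_y): 0 for identical nodes, 1 when the only common
    ancestor is the root (lineage change)."""
    for node in (x, y):
        if node not in tree.parents:
            raise KeyError(f"node {node!r} not in tree")
        if node == ROOT:
            raise ValidationError("Wu-Palmer distance is undefined for the root")
    nx, ny = tree.depth(x), tree.depth(y)
    n = tree.depth(tree.lca(x, y))
    return 1.0 - 2.0 * n / (nx + ny)


def balanced_accuracy(y_true, y_pred) -> float:
    """Macro-average of per-class recall over the classes present in
    ``y_true`` (equals (sensitivity + specificity)/2 for two classes)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValidationError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    recalls = []
    for cls in np.unique(y_true):
        sel = y_true == cls
        recalls.append(np.mean(y_pred[sel] == cls))
    if len(recalls) < 2:
        raise ValidationError("need >= 2 classes in y_true")
    return float(np.mean(recalls))


def confusion_percentages(y_true, y_pred, class_order: list[str]) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent (rows sum to 100)."""
    y_true = pd.Series(list(y_true))
    y_pred = pd.Series(list(y_pred))
    mat = pd.DataFrame(0.0, index=class_order, columns=class_order)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    sums = mat.sum(axis=1)
    nonzero = sums > 0
    mat.loc[nonzero] = 100.0 * mat.loc[nonzero].div(sums[nonzero], axis=0)
    return mat


def phenotype_error_breakdown(tree: GatingTree, y_true, y_pred) -> dict[str, float]:
    """Fractions of cells per agreement category.

    Mismatches split into: lineage change (Wu-Palmer distance 1), granularity
    change (one label an ancestor of the other — includes gains/losses of
    assignment, with 'unassigned' acting as the root), and subtype change
    (everything else).
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    n = len(y_true)
    if n == 0:
        raise ValidationError("empty input")
    counts = {"correct": 0, "subtype": 0, "granularity": 0, "lineage": 0}
    for t, p in zip(y_true, y_pred):
        if t == p:
            counts["correct"] += 1
            continue
        if t == UNASSIGNED or p == UNASSIGNED:
            counts["granularity"] += 1
            continue
        if tree.lca(t, p) == ROOT:
            counts["lineage"] += 1
        elif tree.lca(t, p) in (t, p):
            counts["granularity"] += 1
        else:
            counts["subtype"] += 1
    return {k: v / n for k, v in counts.items()}
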