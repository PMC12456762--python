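"""Orchestration of the full in-silico perturbation study.

For every perturbation level (a named target F1) the runner calibrates
transform intervals, generates replicate perturbed masks with derived
seeds, applies quality control, and evaluates the whole metric battery
against the ground truth: segmentation score, realism diagnostics,
neighborhood preservation, clustering consistency, and phenotyping
agreement. Cell-wise metrics are computed on the intersection of cell IDs
surviving across all replicates of a level. Per-level summaries use the
median and the (unscaled) median absolute deviation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cluster_eval import cluster_runs, max_pairwise_ari
from .errors import ValidationError
from .features import FeatureTable, drop_nucleus, extract_features, log1p_transform
from .io_core import LabelMask, MultichannelImage, StudyConfig
from .neighborhood import jknn, knn_accuracy, knn_graph
from .perturb import common_cell_ids, perturb_mask, qc_filter
from .phenotype import (
    UNASSIGNED,
    GatingTree,
    assign_phenotypes,
    balanced_accuracy,
    fit_gate_model,
    phenotype_error_breakdown,
    wu_palmer_distance,
)
from .segscore import (
    area_ratio_stats,
    calibrate_levels,
    correlation_mae,
    expression_residuals,
    f1_score,
    match_cells,
)
from .two_sample_test import c2st

ALL_METRIC_GROUPS = ("realism", "c2st", "jknn", "ari", "phenotype")


def median_mad(values) -> tuple[float, float]:
    """Median and unscaled median absolute deviation."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValidationError("median_mad of empty input")
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def replicate_seed(master_seed: int, level_index: int, replicate: int) -> int:
    """Stable per-replicate seed; adding replicates never changes existing
    ones."""
    ss = np.random.SeedSequence([master_seed, level_index, replicate])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class StudyReport:
    config: StudyConfig
    calibration: dict  # level -> {"params": ..., "achieved_f1": ...}
    per_run: pd.DataFrame  # columns: level, replicate, metric, value
    aggregates: pd.DataFrame  # columns: level, metric, median, mad

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "calibration": {str(k): v for k, v in self.calibration.items()},
            "per_run": self.per_run.to_dict(orient="records"),
            "aggregates": self.aggregates.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def metric_by_level(self, metric: str) -> pd.Series:
        """Median of one metric per level, ordered as configured."""
        sub = self.aggregates[self.aggregates.metric == metric]
        return sub.set_index("level")["median"].reindex(self.config.levels)


@dataclass
class _LevelRun:
    replicate: int
    seed: int
    mask: LabelMask
    f1: float
    ft_raw: FeatureTable
    ft_log: FeatureTable


def _phenotype_metrics(tree, pheno_gt, pheno_pert) -> dict[str, float]:
    aligned = pd.DataFrame({"t": pheno_gt, "p": pheno_pert}).dropna()
    assigned = aligned[(aligned.t != UNASSIGNED) & (aligned.p != UNASSIGNED)]
    out = {"unassigned_fraction": 1.0 - len(assigned) / len(aligned)}
    out["balanced_accuracy"] = balanced_accuracy(assigned.t, assigned.p)
    breakdown = phenotype_error_breakdown(tree, aligned.t, aligned.p)
    out.update({f"frac_{k}": v for k, v in breakdown.items()})
    dwp = [
        wu_palmer_distance(tree, t, p)
        for t, p in zip(assigned.t, assigned.p)
    ]
    out["mean_wu_palmer"] = float(np.mean(dwp))
    return out


def run_study(
    cfg: StudyConfig,
    image: MultichannelImage,
    mask: LabelMask,
    tree: GatingTree | None = None,
    metric_groups=ALL_METRIC_GROUPS,
    calibration_grid=None,
    precalibrated: dict | None = None,
) -> StudyReport:
    """Execute levels x replicates and collect the full metric battery.

    ``precalibrated`` may supply {level: CalibrationResult} from an earlier
    :func:`maskshaker.segscore.calibrate_levels` call to skip calibration.
    """
    if tree is None:
        from .synthetic_tissue import default_gating_tree

        tree = default_gating_tree()

    ft_gt_all = extract_features(image, mask)
    ft_gt = drop_nucleus(ft_gt_all, image.nucleus_channel)
    ft_gt_log = log1p_transform(ft_gt)
    gates_gt = fit_gate_model(ft_gt, tree, seed=cfg.master_seed)
    pheno_gt = assign_phenotypes(ft_gt, tree, gates_gt)

    if precalibrated is not None:
        missing = [lv for lv in cfg.levels if lv not in precalibrated]
        if missing:
            raise ValidationError(f"precalibrated params missing for levels {missing}")
        calib = precalibrated
    else:
        calib = calibrate_levels(
            mask,
            cfg.levels,
            grid=calibration_grid,
            replicates=cfg.calibration_replicates,
            area_tolerance=cfg.area_tolerance,
            seed=cfg.master_seed,
        )

    rows: list[dict] = []

    def record(level, rep, metric, value):
        rows.append(
            {"level": level, "replicate": rep, "metric": metric, "value": float(value)}
        )

    for li, level in enumerate(cfg.levels):
        params = calib[level].params
        runs: list[_LevelRun] = []
        for rep in range(cfg.replicates):
            seed = replicate_seed(cfg.master_seed, li, rep)
            pert = perturb_mask(mask, params.with_seed(seed))
            pert = qc_filter(
                pert,
                image,
                min_area=cfg.qc_min_area,
                max_area_factor=cfg.qc_max_area_factor,
            )
            score = f1_score(match_cells(mask, pert))
            ft_raw = drop_nucleus(extract_features(image, pert), image.nucleus_channel)
            runs.append(
                _LevelRun(rep, seed, pert, score.f1, ft_raw, log1p_transform(ft_raw))
            )
        common = sorted(
            common_cell_ids([mask] + [r.mask for r in runs])
        )
        gt_sub = {"raw": ft_gt.subset(common), "log1p": ft_gt_log.subset(common)}
        graphs_gt = {
            k: knn_graph(gt_sub["log1p"], k)
            for k in cfg.knn_sizes
            if "jknn" in metric_groups
        }
        labels_common = pheno_gt.loc[common]
        # fixed seed set for the multi-seed best-match protocol: the same
        # five clusterings of the ground truth serve every replicate
        gt_cluster_runs: dict[tuple, list] = {}
        if "ari" in metric_groups:
            for preproc in cfg.preprocessing:
                for k in cfg.kmeans_range:
                    gt_cluster_runs[("kmeans", k, preproc)] = cluster_runs(
                        gt_sub[preproc], "kmeans", seed=cfg.master_seed, k=k
                    )
                for k in cfg.leiden_knn:
                    gt_cluster_runs[("leiden", k, preproc)] = cluster_runs(
                        gt_sub[preproc], "leiden", seed=cfg.master_seed, knn=k
                    )

        for run in runs:
            record(level, run.replicate, "f1", run.f1)
            if "realism" in metric_groups:
                record(level, run.replicate, "median_area_ratio",
                       area_ratio_stats(mask, run.mask)[0])
                res = expression_residuals(ft_gt, run.ft_raw)
                record(level, run.replicate, "residual_median",
                       float(np.median(res.to_numpy())))
                record(level, run.replicate, "correlation_mae",
                       correlation_mae(ft_gt, run.ft_raw))
            if "c2st" in metric_groups:
                record(level, run.replicate, "c2st_accuracy",
                       c2st(ft_gt, run.ft_raw, seed=run.seed).mean_accuracy)
            sub = {"raw": run.ft_raw.subset(common), "log1p": run.ft_log.subset(common)}
            if "jknn" in metric_groups:
                for k in cfg.knn_sizes:
                    g_pert = knn_graph(sub["log1p"], k)
                    record(level, run.replicate, f"jknn_median_k{k}",
                           float(jknn(graphs_gt[k], g_pert).median()))
                    record(level, run.replicate, f"knn_accuracy_k{k}",
                           knn_accuracy(g_pert, labels_common))
            if "ari" in metric_groups:
                for preproc in cfg.preprocessing:
                    for k in cfg.kmeans_range:
                        pert_runs = cluster_runs(
                            sub[preproc], "kmeans", seed=cfg.master_seed, k=k
                        )
                        record(level, run.replicate, f"ari_kmeans_k{k}_{preproc}",
                               max_pairwise_ari(gt_cluster_runs[("kmeans", k, preproc)],
                                                pert_runs))
                    for k in cfg.leiden_knn:
                        pert_runs = cluster_runs(
                            sub[preproc], "leiden", seed=cfg.master_seed, knn=k
                        )
                        record(level, run.replicate, f"ari_leiden_knn{k}_{preproc}",
                               max_pairwise_ari(gt_cluster_runs[("leiden", k, preproc)],
                                                pert_runs))
            if "phenotype" in metric_groups:
                gates = fit_gate_model(run.ft_raw, tree, seed=cfg.master_seed)
                pheno = assign_phenotypes(run.ft_raw, tree, gates)
                metrics = _phenotype_metrics(
                    tree, labels_common, pheno.reindex(common)
                )
                for name, value in metrics.items():
                    record(level, run.replicate, name, value)

    per_run = pd.DataFrame(rows)
    agg_rows = []
    for (level, metric), grp in per_run.groupby(["level", "metric"], sort=False):
        med, mad = median_mad(grp["value"])
        agg_rows.append({"level": level, "metric": metric, "median": med, "mad": mad})
    aggregates = pd.DataFrame(agg_rows)
    calibration = {
        level: {
            "params": res.params.to_dict(),
            "achieved_f1": res.achieved_f1,
            "median_area_ratio": res.median_area_ratio,
        }
        for level, res in calib.items()
    }
    return StudyReport(cfg, calibration, per_run, aggregates)
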