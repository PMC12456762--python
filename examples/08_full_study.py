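"""Run the complete in-silico study on a small tissue and print the report.

For each perturbation level the runner calibrates transform intervals,
perturbs the mask with replicate seeds, applies quality control, and
evaluates segmentation score, realism, neighborhood preservation,
clustering consistency, and phenotyping agreement. Takes a few minutes.
"""

from maskshaker import StudyConfig, TissueSpec, generate_tissue
from maskshaker.study import run_study

image, mask, _ = generate_tissue(TissueSpec(shape=(420, 420), n_cells=600, seed=1))

cfg = StudyConfig(
    levels=[100.0, 90.0, 70.0],
    replicates=3,
    master_seed=0,
    knn_sizes=[15],
    kmeans_range=[6],
    leiden_knn=[15],
    preprocessing=["raw", "log1p"],
)
report = run_study(cfg, image, mask)

print("calibrated levels:")
for level, info in report.calibration.items():
    print(f"  target {level}: achieved F1 {info['achieved_f1']:.2f}, "
          f"translate +/-{info['params']['translate_frac'][1]:.3f}")

print("\nmedian +/- MAD per level:")
for metric in ("f1", "median_area_ratio", "c2st_accuracy", "jknn_median_k15",
               "ari_kmeans_k6_raw", "ari_leiden_knn15_raw", "balanced_accuracy"):
    sub = report.aggregates[report.aggregates.metric == metric]
    cells = "  ".join(
        f"{row.level:5.0f}: {row['median']:.3f}+/-{row['mad']:.3f}"
        for _, row in sub.iterrows()
    )
    print(f"  {metric:22s} {cells}")
# Reading the table: F1 medians sit on their calibrated targets and the
# median area ratio stays near 1 (shape change, not size change), while the
# downstream metrics (JKNN, ARI where not saturated, balanced accuracy)
# degrade as the level drops from 100 to 70. The c2st accuracy climbs with
# perturbation strength here because flat-textured synthetic cells make
# background dilution easy for a classifier to spot; see docs/methods.md.
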