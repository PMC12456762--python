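# maskshaker

Calibrated perturbation of cell segmentation masks, and quantification of
how segmentation errors propagate through downstream analysis of highly
multiplexed tissue imaging data.

Every single-cell quantity derived from a multiplexed image — expression
profiles, neighborhood graphs, clusters, phenotypes — is computed inside
segmentation boundaries that are never exactly right. `maskshaker` turns
segmentation error into a controlled variable: starting from a
ground-truth label mask it applies per-cell affine perturbations
(translation, rotation, scaling, shearing, then binary opening and a
one-pixel separation border) whose strength is *calibrated* to hit a named
IoU-F1 level — 100 (error-free by the matching rule), 90, 80, or 70 — and
then measures the damage downstream:

* **F1** — IoU-matched instance score: a cell is correct if its perturbed
  mask overlaps the original with IoU ≥ 0.5; F1 = 2·tp/(2·tp+fp+fn),
  reported in percent.
* **Realism** — expression residuals, median per-cell area ratio,
  correlation-matrix MAE, and a classifier two-sample test between
  original and perturbed feature tables.
* **JKNN** — per-cell Jaccard overlap |X∩X̃|/|X∪X̃| of exact k-nearest-
  neighbor sets in expression space, plus kNN phenotype accuracy.
* **ARI** — Adjusted Rand Index between k-means/Leiden clusterings of
  original and perturbed features, best match over five seeded runs each.
* **Phenotyping** — three-component GMM marker gating descended over a
  phenotype tree; agreement scored by balanced accuracy, confusion
  percentages, Wu–Palmer tree distance d = 1 − 2N/(N_X+N_Y), and an error
  breakdown into subtype / granularity / lineage changes.

A synthetic-tissue generator (dense non-overlapping elliptical cells,
phenotypes drawn from a configurable gating tree, log-normal high/low
marker intensities, nucleus channel, pixel noise) provides ground truth
with known phenotypes, so the whole framework is testable without any
external dataset. See `docs/methods.md` for the model, assumptions, and
what the synthetic data does and does not emulate.

## Worked example

```python
from maskshaker import (
    TissueSpec, generate_tissue, calibrate_levels, perturb_mask,
    match_cells, f1_score, extract_features, drop_nucleus, log1p_transform,
    knn_graph, jknn, NUCLEUS_CHANNEL,
)

# ground truth with known phenotypes
image, mask, phenotypes = generate_tissue(
    TissueSpec(shape=(420, 420), n_cells=600, seed=1))

# calibrate to named F1 levels, then perturb with a fresh seed
calib = calibrate_levels(mask, [100.0, 90.0, 70.0], seed=2)
pert = perturb_mask(mask, calib[90.0].params.with_seed(123))
print(f1_score(match_cells(mask, pert)).f1)      # 89.5

# neighborhood preservation at the 90 level
ft_gt = log1p_transform(drop_nucleus(extract_features(image, mask), NUCLEUS_CHANNEL))
ft_pt = log1p_transform(drop_nucleus(extract_features(image, pert), NUCLEUS_CHANNEL))
ids = ft_gt.data.index.intersection(ft_pt.data.index)
j = jknn(knn_graph(ft_gt.subset(ids), 15), knn_graph(ft_pt.subset(ids), 15))
print(round(j.median(), 3))                      # 0.667
```

The first number is the achieved F1 of the calibrated 90-level
perturbation on an unseen seed — within two points of its target. The
second says that for the median cell only about two thirds of its 15
nearest expression-space neighbors survive a perturbation that the
segmentation metric itself grades as 90% correct: neighborhood structure
degrades much faster than the F1 suggests.

The `examples/` directory walks through each capability (tissue
generation, perturbation and scoring, calibration, neighborhood
preservation, clustering stability, phenotyping, the two-sample test, and
the full study runner); each script prints the numbers it computes and a
note on how to read them. A thin CLI mirrors the main entry points:
`maskshaker simulate|perturb|calibrate|score|evaluate|report`.

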