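"""How much of each cell's expression-space neighborhood survives perturbation.

JKNN is the per-cell Jaccard overlap between a cell's k nearest neighbors
computed on ground-truth features and on perturbed features; kNN accuracy
asks the weaker question of whether the majority phenotype of the perturbed
neighborhood still matches the cell's own label.
"""

import numpy as np

from maskshaker import (
    NUCLEUS_CHANNEL,
    PerturbationParams,
    TissueSpec,
    drop_nucleus,
    extract_features,
    generate_tissue,
    jknn,
    knn_accuracy,
    knn_graph,
    log1p_transform,
    perturb_mask,
)

image, mask, phenotypes = generate_tissue(TissueSpec(shape=(360, 360), n_cells=400, seed=42))
pert = perturb_mask(mask, PerturbationParams(
    translate_frac=(-0.22, 0.22), rotate_deg=(-10, 10), scale=(0.92, 1.08),
    shear_deg=(-10, 10), seed=7,
))

ft_gt = log1p_transform(drop_nucleus(extract_features(image, mask), NUCLEUS_CHANNEL))
ft_pt = log1p_transform(drop_nucleus(extract_features(image, pert), NUCLEUS_CHANNEL))
common = np.intersect1d(ft_gt.cell_ids, ft_pt.cell_ids)
ft_gt, ft_pt = ft_gt.subset(common), ft_pt.subset(common)

for k in (15, 50):
    g_gt = knn_graph(ft_gt, k)
    g_pt = knn_graph(ft_pt, k)
    j = jknn(g_gt, g_pt)
    acc = knn_accuracy(g_pt, phenotypes.loc[common])
    print(f"k={k:3d}: median JKNN = {j.median():.3f}, kNN accuracy = {acc:.3f}")
# Even at a near-perfect F1 the neighbor sets only partially overlap —
# larger neighborhoods are better preserved — while the majority phenotype
# of a neighborhood is far more robust and stays near the ceiling.
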