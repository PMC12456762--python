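# Methods

## The problem

In highly multiplexed tissue imaging (CODEX and related cyclic
immunofluorescence), every downstream quantity — per-cell expression
profiles, neighborhood graphs, clusters, phenotypes — is computed from a
cell segmentation mask. Segmentation is never perfect, but analysis
pipelines treat it as if it were. `maskshaker` makes segmentation error a
controlled experimental variable: it perturbs a ground-truth label mask to
a chosen quality level and measures how far each downstream result drifts.

## Perturbation model

Each cell is perturbed independently. Its binary patch is extracted from
the mask, zero-padded, and transformed by a random affine map composed as
scale → shear → rotate → translate about the patch center, with one
parameter per sub-transform drawn uniformly from a configured interval
(translation is expressed as a fraction of the cell's bounding box, so a
given setting displaces small and large cells by the same relative
amount). Nearest-neighbor resampling keeps the patch binary; binary opening
then removes the thin spurs that shearing and rotation create. The
structuring element is the radius-r Chebyshev ball — a (2r+1)×(2r+1)
square — chosen so that opening is idempotent on rectangular bodies and
only removes protrusions thinner than the element; default r = 1.

Patches are written back in ascending cell-ID order, later cells
overwriting earlier ones where transforms collide (the mechanism by which
merge-like errors arise). Finally a one-pixel background border between
all cells is enforced: for every pair of 8-adjacent distinct labels, one
cell of the pair is chosen at random and its pixels bordering the other
are cleared, iterated to convergence. Iteration (rather than a single
pass) is what guarantees the invariant that no two labels are 8-adjacent
in any output mask.

Randomness is structured for reproducibility: each cell draws from a
sub-stream seeded by (master seed, cell ID), so a cell's transform is
independent of how many other cells exist; the separation pass has its own
stream. Two runs with the same seed are bit-identical.

Quality control after perturbation removes cells that are implausible as
segmentation outputs: area below 10 px, mean nucleus intensity below 10%
of the nucleus channel's 99th percentile (empty masks), or area above 5×
the median (merged masks). All three thresholds are configurable; the
defaults are our choices, stated here because no canonical values exist.

## Scoring and calibration

Segmentation quality is the standard IoU-matched F1: a ground-truth cell
is a true positive when a predicted cell overlaps it with IoU ≥ 0.5 (at
that threshold and with disjoint masks the match is necessarily
one-to-one); unmatched predicted cells are false positives, unmatched
ground-truth cells false negatives; F1 = 2tp/(2tp+fp+fn), reported on a
0–100 scale so perturbation levels can be named by their target F1
(100 = weakest, 70 = strongest).

Calibration finds transform intervals achieving a target F1 by sweeping a
grid of three crossed magnitude ladders (translation fraction, scale
half-width, rotation/shear bound). The translation ladder is coarse below
the IoU-0.5 transition and steps by 0.0075 across it, because the F1
response is flat until typical displacements approach half a cell radius
and then drops by several points per 0.01 of translation fraction. Within
a ladder, evaluation stops once achieved F1 falls 5 points below the
smallest target (the response is monotone, so larger magnitudes cannot
recover). Candidates whose mean median-area-ratio leaves 1 ± 0.1 are
discarded — the perturbation must reshape cells, not resize them. Each
candidate is scored as the mean F1 over seeded replicates (default 3).
Ties go to the stronger perturbation so that even the F1 = 100 level is a
genuine perturbation; for that error-free level the winner must
additionally keep every cell's IoU ≥ 0.6 across calibration replicates,
a margin above the 0.5 matching rule that makes the level reproduce
F1 = 100 exactly on fresh seeds.

## Downstream metrics

* **Features**: per-cell arithmetic mean intensity per channel, plus area
  and centroid. The mean makes a conservation identity
  (Σ area·mean = total labeled intensity) exact, which the tests use.
  Variance stabilization is log(1+x); the nucleus channel is dropped
  before any expression analysis.
* **Neighborhood preservation (JKNN)**: exact brute-force Euclidean kNN
  graphs (ties broken by ascending cell ID, self excluded); per cell, the
  Jaccard overlap of its neighbor sets in ground-truth vs perturbed
  feature space, evaluated on the cells present in both tables with
  neighbor sets restricted to those cells. kNN accuracy asks instead
  whether the majority phenotype of the perturbed neighborhood matches the
  cell's own label (majority ties break lexicographically).
* **Clustering consistency**: k-means (k-means++, single seeded start) and
  Leiden on the unweighted, edge-union-symmetrized kNN graph
  (modularity/RBConfiguration, resolution 1.0). Both are
  initialization-sensitive, so each table is clustered five times with a
  fixed seed set and the best-matching pair of runs is compared with the
  Adjusted Rand Index, computed from the contingency table in-package
  (and cross-checked against scikit-learn in the tests). Fixing the seed
  set per level lets the five ground-truth clusterings be shared across
  replicates and keeps initialization noise out of level comparisons.
* **Phenotyping**: per marker, a three-component 1-D Gaussian mixture on
  log1p values; the two lower-mean components absorb background and low
  expression, and only cells whose most probable component is the
  highest-mean one are called positive — a deliberately conservative gate.
  Cells descend a gating tree (each node's marker requirements extend its
  parent's) to the deepest satisfiable node; with no satisfiable child the
  descent stops, with several it also stops (granularity-conservative);
  cells stopping at the root are "unassigned". Gates are refit on each
  dataset, as a practitioner would process each segmentation output
  independently; passing a ground-truth `GateModel` reproduces the
  fit-once alternative. Agreement is scored by balanced accuracy
  (macro-averaged recall; unassigned cells excluded and reported as a
  separate fraction), row-normalized confusion percentages, and the
  Wu–Palmer tree distance 1 − 2N/(N_X+N_Y) with root depth 0, so identical
  nodes score 0 and cross-lineage errors score exactly 1. The error
  breakdown classifies each mismatch as lineage change (distance 1),
  granularity change (one label an ancestor of the other; "unassigned"
  acts as the root), or subtype change (everything else).
* **Classifier two-sample test**: a LightGBM classifier under 5-fold
  cross-validation distinguishes the two tables' marker rows; tables of
  unequal size are seeded-downsampled so 0.5 is the exact chance level.
  Folds are grouped by cell ID: the two versions of one cell are dependent
  samples, and letting them straddle a fold boundary produces duplicate
  leakage that inverts the chance level on identical tables (memorized
  train labels are exactly wrong in test). With grouping, identical tables
  score exactly 0.5.

## The synthetic tissue

The generator emulates the statistical structure the evaluation needs,
without claiming visual realism: jittered, randomly oriented ellipses
(radius 4.5–8 px; immune cells scaled by 0.7, mirroring the small immune
compartment where segmentation errors bite hardest) placed by
dart-throwing with a one-pixel halo, so generated masks satisfy the
perturbation engine's separation precondition by construction. Phenotypes
are drawn per cell from a two-lineage, three-level gating tree (Immune →
T cell → CD4/CD8/Treg, Immune → Macrophage; Parenchymal → Hepatocyte,
LSEC) with liver-like prevalences. Marker intensities are drawn per cell:
LogNormal(ln 50, 0.25) for markers the phenotype requires positive,
LogNormal(ln 2, 0.6) otherwise, plus relative Gaussian pixel noise
(default 10%); the nucleus channel is positive in every cell. The wide
low/narrow high structure makes the three-component gate assign two
components to background, and the separation is large enough that gating
noise-free generated data recovers the planted phenotypes for 100% of
cells — the closed-loop property the phenotyping tests rely on.

What the generator does **not** emulate — and hence what passing tests do
and do not show: cells are flat-textured (constant base intensity plus
noise), there is no autofluorescence, spillover, spatial correlation
between phenotypes, or marginal-expression population. Three consequences
observed in the study runner: (1) phenotype corruption under perturbation
is far rarer than on real tissue, because almost no cell sits near a gate
boundary — balanced accuracy stays near 0.999 where the real-data figure
is below 0.8; the machinery is validated by the closed loop and by
monotone degradation, not by reproducing real effect sizes. (2) The
two-sample test detects calibrated perturbations above chance level,
because mixing flat cell interiors with zero background shifts means in a
learnable way; on real, textured data the same perturbations are nearly
chance-level. (3) Clustering at the true population count (k = 6) is
almost perfectly stable; instability concentrates at larger k where
clusters split noise, which is also where level-to-level comparisons stop
being informative at n ≈ 1000.

## The study runner

`run_study` executes levels × replicates: calibrate (or accept
precalibrated parameters), perturb with replicate seeds derived as
hash(master seed, level index, replicate) — so adding replicates never
changes existing ones — apply QC, score, extract features (raw and log1p,
nucleus dropped), and evaluate the metric battery. Cell-wise metrics
(JKNN, kNN accuracy, phenotype comparisons) use the intersection of cell
IDs surviving every replicate of a level; dataset-level metrics (c2st,
clustering) use each run's QC-passing table restricted to common IDs where
a paired comparison requires it. Per-level summaries are the median and
the unscaled median absolute deviation. Reports are byte-identical across
reruns with the same configuration and seed.

## Problem sizes and numerical choices

Default test/acceptance tissue: 1,000 cells on 520×520 px; the trend
analysis uses 10 replicates per level at levels 100/90/80/70; calibration
uses 3 replicate seeds per grid candidate. These sizes were chosen so the
full study remains a desk-scale computation while leaving every trend
statistically resolvable. k-means converges at relative tolerance 1e-4 or
300 iterations; GMM fits use 3 EM initializations with a fixed seed;
distance ties in kNN graphs and majority ties in kNN accuracy have
deterministic tie-breaks so that oracle comparisons are exact. Degenerate
inputs are defined rather than accidental: IoU of two empty sets is 0, an
empty mask yields an empty feature table, a constant marker column is a
gating error, and a mask with no cells cannot be scored.

## Known limitations

Cells are convex-ish ellipses; real cell shapes (and hence the geometry of
overwrite collisions) are more varied. Merge/split errors arise only as
side-effects of overwriting, never as explicit events. The gating tree is
a configurable stand-in with canonical marker logic, not a reproduction of
any published panel's strategy. Effect sizes on synthetic data understate
real-data effect sizes for phenotyping (see above); trends and invariants,
not magnitudes, are the transferable results.
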