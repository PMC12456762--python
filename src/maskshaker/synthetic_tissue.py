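"""Synthetic multiplexed tissue with known cell masks and phenotypes.

The generator emulates the structure the evaluation relies on: densely
packed, non-overlapping cell masks (jittered, randomly oriented ellipses
placed by dart-throwing, each kept at least one pixel away from every
neighbor), a phenotype drawn per cell from a gating tree, per-cell marker
intensities drawn from a high log-normal component for markers the
phenotype requires positive and a low component otherwise, a nucleus
channel positive inside every cell, and multiplicative pixel noise.

Immune cells are drawn smaller than parenchymal cells — in real tissue the
small immune compartment is where segmentation errors bite hardest, and the
size contrast preserves that behavior here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon

from .errors import GenerationError, ValidationError
from .io_core import LabelMask, MultichannelImage
from .phenotype import ROOT, GatingTree

NUCLEUS_CHANNEL = "HOECHST"

_N_BOUNDARY_POINTS = 28


def default_gating_tree() -> GatingTree:
    """Fixed 3-level liver-like hierarchy used throughout the package.

    Two lineages under the root — Immune (CD45+) and Parenchymal (CD45-,
    ECAD+) — with T cells and macrophages under Immune, CD4/CD8/Treg under
    T cell, and hepatocytes and LSECs under Parenchymal. Requirements are
    cumulative and mutually exclusive among siblings, so every leaf is
    reachable by exactly one requirement-consistent path.
    """
    parents = {
        ROOT: None,
        "Immune": ROOT,
        "Parenchymal": ROOT,
        "T cell": "Immune",
        "Macrophage": "Immune",
        "CD4 T": "T cell",
        "CD8 T": "T cell",
        "Treg": "T cell",
        "Hepatocyte": "Parenchymal",
        "LSEC": "Parenchymal",
    }
    requirements = {
        ROOT: {},
        "Immune": {"CD45": True},
        "Parenchymal": {"CD45": False, "ECAD": True},
        "T cell": {"CD45": True, "CD3": True},
        "Macrophage": {"CD45": True, "CD3": False, "CD68": True},
        "CD4 T": {"CD45": True, "CD3": True, "CD4": True, "CD8": False, "FOXP3": False},
        "CD8 T": {"CD45": True, "CD3": True, "CD8": True, "CD4": False},
        "Treg": {"CD45": True, "CD3": True, "CD4": True, "FOXP3": True, "CD8": False},
        "Hepatocyte": {"CD45": False, "ECAD": True, "ALB": True, "CD31": False},
        "LSEC": {"CD45": False, "ECAD": True, "CD31": True, "ALB": False},
    }
    return GatingTree(parents, requirements)


DEFAULT_PREVALENCES = {
    "CD4 T": 0.15,
    "CD8 T": 0.12,
    "Treg": 0.05,
    "Macrophage": 0.13,
    "Hepatocyte": 0.40,
    "LSEC": 0.15,
}


@dataclass
class TissueSpec:
    """Parameters of one synthetic tissue.

    Intensity components are (log-mean, log-sd) of log-normal draws per cell
    per marker; ``noise_scale`` is the per-pixel Gaussian noise sd relative
    to the cell's base intensity (0 = noise-free).
    """

    shape: tuple[int, int] = (560, 560)
    n_cells: int = 1000
    radius_range: tuple[float, float] = (4.5, 8.0)
    immune_radius_factor: float = 0.7
    tree: GatingTree | None = None
    prevalences: dict[str, float] | None = None
    positive_lognormal: tuple[float, float] = (math.log(50.0), 0.25)
    negative_lognormal: tuple[float, float] = (math.log(2.0), 0.6)
    noise_scale: float = 0.1
    nucleus_level: float = 40.0
    boundary_jitter: float = 0.08
    max_attempts: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValidationError("radius range must be positive with lo <= hi")
        if 2 * self.radius_range[1] >= min(self.shape):
            raise ValidationError("cells do not fit the image")
        prev = self.prevalences or DEFAULT_PREVALENCES
        if abs(sum(prev.values()) - 1.0) > 1e-8:
            raise ValidationError("phenotype prevalences must sum to 1")


def _cell_polygon(rng, center, a, b, angle, jitter):
    """Jittered ellipse boundary as (rows, cols) polygon vertices."""
    theta = np.linspace(0, 2 * np.pi, _N_BOUNDARY_POINTS, endpoint=False)
    noise = rng.normal(0.0, 1.0, _N_BOUNDARY_POINTS)
    # circular smoothing so the jitter stays low-frequency
    noise = 0.25 * np.roll(noise, 1) + 0.5 * noise + 0.25 * np.roll(noise, -1)
    radial = 1.0 + jitter * noise
    br = a * np.cos(theta) * radial
    bc = b * np.sin(theta) * radial
    rows = center[0] + br * math.cos(angle) - bc * math.sin(angle)
    cols = center[1] + br * math.sin(angle) + bc * math.cos(angle)
    return rows, cols


def _is_immune(tree: GatingTree, phenotype: str) -> bool:
    return "Immune" in tree.ancestors(phenotype)


def generate_tissue(spec: TissueSpec):
    """Generate (MultichannelImage, LabelMask, phenotype Series).

    Deterministic given ``spec.seed``. Raises ``GenerationError`` (carrying
    the achieved count) when the requested cell count cannot be placed at
    the requested density.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree or default_gating_tree()
    prevalences = spec.prevalences or DEFAULT_PREVALENCES
    names = sorted(prevalences)
    probs = np.array([prevalences[n] for n in names])
    phenotypes = rng.choice(names, size=spec.n_cells, p=probs)

    h, w = spec.shape
    mask = np.zeros((h, w), dtype=np.int32)
    forbidden = np.zeros((h, w), dtype=bool)
    cell_pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for i in range(spec.n_cells):
        cell_id = i + 1
        factor = spec.immune_radius_factor if _is_immune(tree, phenotypes[i]) else 1.0
        placed = False
        for _ in range(spec.max_attempts):
            a = factor * rng.uniform(*spec.radius_range)
            b = a * rng.uniform(0.65, 1.0)
            angle = rng.uniform(0, np.pi)
            margin = a * (1 + spec.boundary_jitter) + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            rows, cols = _cell_polygon(rng, center, a, b, angle, spec.boundary_jitter)
            rr, cc = polygon(rows, cols, shape=(h, w))
            if rr.size < 5 or forbidden[rr, cc].any():
                continue
            mask[rr, cc] = cell_id
            cell_pixels[cell_id] = (rr, cc)
            # block the cell plus a one-pixel halo for future placements
            r0, r1 = max(0, rr.min() - 1), min(h, rr.max() + 2)
            c0, c1 = max(0, cc.min() - 1), min(w, cc.max() + 2)
            local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            local[rr - r0, cc - c0] = True
            forbidden[r0:r1, c0:c1] |= ndimage.binary_dilation(
                local, structure=np.ones((3, 3), dtype=bool)
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could only place {i} of {spec.n_cells} cells at this density",
                achieved_count=i,
            )

    markers = tree.markers()
    channels = markers + [NUCLEUS_CHANNEL]
    image = np.zeros((len(channels), h, w), dtype=np.float32)
    mu_hi, sd_hi = spec.positive_lognormal
    mu_lo, sd_lo = spec.negative_lognormal
    log_nuc = math.log(spec.nucleus_level)
    for cell_id, (rr, cc) in cell_pixels.items():
        positive = tree.positive_markers(phenotypes[cell_id - 1])
        for ci, marker in enumerate(channels):
            if marker == NUCLEUS_CHANNEL:
                base = rng.lognormal(log_nuc, 0.2)
            elif marker in positive:
                base = rng.lognormal(mu_hi, sd_hi)
            else:
                base = rng.lognormal(mu_lo, sd_lo)
            values = np.full(rr.size, base)
            if spec.noise_scale > 0:
                values = values + rng.normal(0, spec.noise_scale * base, rr.size)
            image[ci, rr, cc] = np.maximum(values, 0.0)

    labels = pd.Series(
        phenotypes,
        index=pd.Index(np.arange(1, spec.n_cells + 1, dtype=np.int64), name="cell_id"),
        name="phenotype",
    )
    mc = MultichannelImage(image, channels, NUCLEUS_CHANNEL)
    return mc, LabelMask(mask), labels
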