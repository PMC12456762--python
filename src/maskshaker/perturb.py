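"""Per-cell affine perturbation of label masks.

Each cell is processed independently: its binary patch is extracted and
zero-padded, a random affine transform (scale -> shear -> rotate ->
translate, parameters drawn uniformly from configured intervals) is applied
with nearest-neighbor interpolation, the result is smoothed by binary
opening, and the nonzero pixels are written back into the output mask,
overwriting anything a previously processed cell left there. Finally a
one-pixel separation border between all cells is enforced by removing
boundary pixels from one randomly chosen cell of every touching pair.

Randomness is reproducible: each cell draws from a sub-stream derived from
``(seed, cell_id)``, so a cell's transform does not depend on how many other
cells exist; the separation pass uses its own ``(seed,)``-derived stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io_core import LabelMask, MultichannelImage

_EIGHT_NEIGHBORHOOD = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_SEPARATION_STREAM = 0x5E9A  # fixed tag so the separation RNG differs from cell streams


@dataclass
class PerturbationParams:
    """Intervals for the four affine sub-transforms plus opening settings.

    ``translate_frac`` is expressed as a fraction of the cell's bounding-box
    size along each axis; rotation and shear are degrees; ``scale`` is a
    multiplicative factor interval. One value per sub-transform (per axis
    for translation) is drawn uniformly from its interval for every cell.
    """

    translate_frac: tuple[float, float] = (0.0, 0.0)
    rotate_deg: tuple[float, float] = (0.0, 0.0)
    scale: tuple[float, float] = (1.0, 1.0)
    shear_deg: tuple[float, float] = (0.0, 0.0)
    opening_radius: int = 1
    pad: int | None = None  # None: auto per cell, large enough that no transform clips
    seed: int = 0

    def __post_init__(self):
        for name in ("translate_frac", "rotate_deg", "scale", "shear_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} interval has lo > hi: ({lo}, {hi})")
        if self.scale[0] <= 0:
            raise ValidationError("scale interval must be within (0, inf)")
        if self.opening_radius < 0:
            raise ValidationError("opening_radius must be >= 0")

    def with_seed(self, seed: int) -> "PerturbationParams":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "translate_frac": list(self.translate_frac),
            "rotate_deg": list(self.rotate_deg),
            "scale": list(self.scale),
            "shear_deg": list(self.shear_deg),
            "opening_radius": self.opening_radius,
            "pad": self.pad,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationParams":
        kw = dict(d)
        for name in ("translate_frac", "rotate_deg", "scale", "shear_deg"):
            if name in kw:
                kw[name] = tuple(kw[name])
        return cls(**kw)


@dataclass
class CellPatch:
    """Binary sub-array holding one cell, with its offset into the full mask.

    The offset may be negative or extend past the image when a border cell
    is padded; write-back clips to image bounds.
    """

    pixels: np.ndarray  # bool
    offset: tuple[int, int]
    cell_id: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def extract_cell_patch(mask: LabelMask, cell_id: int, pad: int = 0) -> CellPatch:
    """Cut out one cell as a zero-padded binary patch."""
    rows, cols = np.nonzero(mask.pixels == cell_id)
    if rows.size == 0:
        raise KeyError(f"cell_id {cell_id} not present in mask")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    patch = np.zeros((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), dtype=bool)
    patch[pad : pad + (r1 - r0), pad : pad + (c1 - c0)] = (
        mask.pixels[r0:r1, c0:c1] == cell_id
    )
    return CellPatch(patch, (r0 - pad, c0 - pad), cell_id)


def _affine_matrix(
    center: tuple[float, float],
    translate_px: tuple[float, float],
    rotate_deg: float,
    scale: float,
    shear_deg: float,
) -> np.ndarray:
    """Forward 3x3 homogeneous matrix: scale -> shear -> rotate -> translate,
    composed about ``center`` in (row, col) coordinates."""
    cr, cc = center
    to_origin = np.array([[1, 0, -cr], [0, 1, -cc], [0, 0, 1]], dtype=float)
    back = np.array([[1, 0, cr], [0, 1, cc], [0, 0, 1]], dtype=float)
    s = np.diag([scale, scale, 1.0])
    sh = math.tan(math.radians(shear_deg))
    shear = np.array([[1, sh, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    a = math.radians(rotate_deg)
    rot = np.array(
        [[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]],
        dtype=float,
    )
    tr, tc = translate_px
    trans = np.array([[1, 0, tr], [0, 1, tc], [0, 0, 1]], dtype=float)
    return trans @ back @ rot @ shear @ s @ to_origin


def apply_affine_patch(
    patch: CellPatch, params: PerturbationParams, rng: np.random.Generator
) -> CellPatch:
    """Apply one randomly drawn affine transform to a binary cell patch.

    The translation fraction is measured against the cell's tight bounding
    box, so equally strong settings displace small and large cells by the
    same fraction of their size. Nearest-neighbor resampling keeps the patch
    binary; the frame (and offset) are unchanged.
    """
    if not patch.pixels.any():
        raise ValidationError("cannot transform an empty patch")
    rows, cols = np.nonzero(patch.pixels)
    bbox = (rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)

    t_frac_r = rng.uniform(*params.translate_frac)
    t_frac_c = rng.uniform(*params.translate_frac)
    rot = rng.uniform(*params.rotate_deg)
    scale = rng.uniform(*params.scale)
    shear = rng.uniform(*params.shear_deg)

    center = ((patch.shape[0] - 1) / 2.0, (patch.shape[1] - 1) / 2.0)
    fwd = _affine_matrix(
        center, (t_frac_r * bbox[0], t_frac_c * bbox[1]), rot, scale, shear
    )
    inv = np.linalg.inv(fwd)
    out = ndimage.affine_transform(
        patch.pixels.astype(np.uint8),
        inv[:2, :2],
        offset=inv[:2, 2],
        output_shape=patch.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return CellPatch(out.astype(bool), patch.offset, patch.cell_id)


def binary_opening(patch: CellPatch, radius: int) -> CellPatch:
    """Morphological opening (erosion then dilation) of a binary cell patch.

    The structuring element is the radius-``radius`` Chebyshev ball (a
    (2r+1) x (2r+1) square), which removes protrusions thinner than the
    element while leaving rectangular bodies invariant; radius 0 is the
    identity.
    """
    if radius < 0:
        raise ValidationError("opening radius must be >= 0")
    if radius == 0:
        return patch
    element = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    out = ndimage.binary_opening(patch.pixels, structure=element)
    return CellPatch(out, patch.offset, patch.cell_id)


def _paste_patch(output: np.ndarray, patch: CellPatch) -> None:
    """Write a patch's nonzero pixels into the output, overwriting, clipped
    to image bounds."""
    h, w = output.shape
    r0, c0 = patch.offset
    pr, pc = patch.shape
    tr0, tr1 = max(0, r0), min(h, r0 + pr)
    tc0, tc1 = max(0, c0), min(w, c0 + pc)
    if tr0 >= tr1 or tc0 >= tc1:
        return
    sub = patch.pixels[tr0 - r0 : tr1 - r0, tc0 - c0 : tc1 - c0]
    view = output[tr0:tr1, tc0:tc1]
    view[sub] = patch.cell_id


def _adjacent_pairs(arr: np.ndarray) -> np.ndarray:
    """Unordered pairs (a < b) of distinct nonzero labels with 8-adjacent
    pixels."""
    pairs = set()
    for dr, dc in _EIGHT_NEIGHBORHOOD[:4]:  # half the offsets find every pair
        a, b = _shifted_views(arr, dr, dc)
        touch = (a > 0) & (b > 0) & (a != b)
        if touch.any():
            pa, pb = a[touch], b[touch]
            lo, hi = np.minimum(pa, pb), np.maximum(pa, pb)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)


def _shifted_views(arr: np.ndarray, dr: int, dc: int):
    """Views a, b such that a[i] and b[i] are (dr, dc)-neighboring pixels."""
    h, w = arr.shape
    a = arr[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    b = arr[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
    return a, b


def enforce_separation(mask: LabelMask, rng: np.random.Generator) -> LabelMask:
    """Guarantee a one-pixel background border between all cell masks.

    For every pair of distinct labels with 8-adjacent pixels, one cell of
    the pair is chosen at random and its pixels bordering the other cell are
    set to background; the scan repeats until no two labels touch.
    """
    arr = mask.pixels.copy()
    while True:
        pairs = _adjacent_pairs(arr)
        if pairs.size == 0:
            return LabelMask(arr)
        # victim[i]: which of pairs[i] loses its border pixels
        picks = rng.integers(0, 2, size=len(pairs))
        victim = pairs[np.arange(len(pairs)), picks]
        partner = pairs[np.arange(len(pairs)), 1 - picks]
        key = arr.max() + 1
        codes = set((victim.astype(np.int64) * key + partner).tolist())
        remove = np.zeros_like(arr, dtype=bool)
        for dr, dc in _EIGHT_NEIGHBORHOOD:
            a, b = _shifted_views(arr, dr, dc)
            touch = (a > 0) & (b > 0) & (a != b)
            if not touch.any():
                continue
            code = a.astype(np.int64) * key + b
            hit = touch & np.isin(code, list(codes))
            rm_view = remove[
                max(0, -dr) : arr.shape[0] - max(0, dr),
                max(0, -dc) : arr.shape[1] - max(0, dc),
            ]
            rm_view |= hit
        arr[remove] = 0


def _auto_pad(bbox: tuple[int, int], params: PerturbationParams) -> int:
    """Padding that keeps any admissible transform inside the patch frame."""
    longest = max(bbox)
    max_scale = params.scale[1]
    max_translate = max(abs(params.translate_frac[0]), abs(params.translate_frac[1]))
    growth = math.ceil(0.5 * longest * max(max_scale * 1.5 - 1.0, 0.5))
    return growth + math.ceil(max_translate * longest) + params.opening_radius + 1


def perturb_mask(mask: LabelMask, params: PerturbationParams) -> LabelMask:
    """Perturb every cell of a label mask independently (the core procedure).

    Cells are processed in ascending ID order; later cells overwrite earlier
    ones where transforms collide, after which the one-pixel separation
    border is enforced. Cells whose mask ends up empty are absent from the
    output. Deterministic given ``params.seed``.
    """
    output = np.zeros_like(mask.pixels)
    slices = ndimage.find_objects(mask.pixels)
    for cell_id in mask.labels():
        sl = slices[cell_id - 1] if cell_id - 1 < len(slices) else None
        if sl is None:
            continue
        bbox = (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        pad = params.pad if params.pad is not None else _auto_pad(bbox, params)
        patch = CellPatch(
            np.pad(mask.pixels[sl] == cell_id, pad),
            (sl[0].start - pad, sl[1].start - pad),
            int(cell_id),
        )
        rng = np.random.default_rng([params.seed, int(cell_id)])
        patch = apply_affine_patch(patch, params, rng)
        patch = binary_opening(patch, params.opening_radius)
        _paste_patch(output, patch)
    sep_rng = np.random.default_rng([params.seed, _SEPARATION_STREAM])
    return enforce_separation(LabelMask(output), sep_rng)


def qc_filter(
    mask: LabelMask,
    image: MultichannelImage,
    min_area: int = 10,
    min_nucleus_mean: float | None = None,
    max_area_factor: float = 5.0,
) -> LabelMask:
    """Remove implausible cells: too small, nucleus-free, or merged.

    ``min_nucleus_mean`` defaults to 10% of the nucleus channel's 99th
    percentile. Cells larger than ``max_area_factor`` times the median area
    are treated as incorrect merges and dropped.
    """
    if image.spatial_shape != mask.shape:
        raise ValidationError("mask/image shape mismatch")
    labels = mask.labels()
    if labels.size == 0:
        return mask.copy()
    nucleus = image.channel(image.nucleus_channel).astype(float)
    if min_nucleus_mean is None:
        min_nucleus_mean = 0.1 * float(np.percentile(nucleus, 99))
    areas = ndimage.sum_labels(np.ones(mask.shape), labels=mask.pixels, index=labels)
    nuc_mean = ndimage.mean(nucleus, labels=mask.pixels, index=labels)
    keep = (
        (areas >= min_area)
        & (nuc_mean >= min_nucleus_mean)
        & (areas <= max_area_factor * np.median(areas))
    )
    out = mask.pixels.copy()
    drop = labels[~keep]
    if drop.size:
        out[np.isin(out, drop)] = 0
    return LabelMask(out)


def common_cell_ids(masks: list[LabelMask]) -> set[int]:
    """IDs present in every mask of the list."""
    if not masks:
        raise ValidationError("need at least one mask")
    common = set(masks[0].labels().tolist())
    for m in masks[1:]:
        common &= set(m.labels().tolist())
    return common
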