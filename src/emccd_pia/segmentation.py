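"""Heuristic segmentation of a binarized image with region p-values.

Misclassified pixels in a probabilistically thresholded image have only
short-range spatial correlation, so false regions are small.  The
cleaning step exploits this with a single parameter, the allowed gap
length: region sizes of each color are sorted, the walk along the sorted
unique sizes stops at the first gap larger than the allowed gap, and
every region at or below the stopping size (the noise cluster) is
flipped.  Surviving white regions are scored with a p-value p_seg for
their summed counts arising from pure background — a quality control
that makes no assumption about object geometry or topology (holes in
ring-shaped objects stay background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .noise_model import NoiseModel, region_sum_pvalue

__all__ = [
    "Region",
    "SegmentationResult",
    "label_components",
    "gap_size_threshold",
    "clean_mask",
    "score_regions",
]

FLIP_ALL = math.inf  # sentinel cut: no qualifying gap, flip every region

#: Complementary connectivity pair: 8-connected white objects,
#: 4-connected black background (avoids topological paradoxes).
WHITE_CONNECTIVITY = 2
BLACK_CONNECTIVITY = 1


@dataclass(frozen=True)
class Region:
    """One connected component of a single color."""

    label: int
    color: str  # "white" or "black"
    coords: np.ndarray  # (n, 2) pixel coordinates
    sum_counts: int | None = None
    p_seg: float | None = None

    @property
    def size(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.coords.mean(axis=0))


@dataclass(frozen=True)
class SegmentationResult:
    """Cleaned mask, surviving labeled regions and the size cuts used."""

    mask: np.ndarray  # cleaned boolean mask (True = white)
    regions: tuple[Region, ...]  # surviving white regions
    w_white: float
    w_black: float
    allowed_gap_length: int

    def labels(self) -> np.ndarray:
        out = np.zeros(self.mask.shape, dtype=np.int32)
        for region in self.regions:
            out[region.coords[:, 0], region.coords[:, 1]] = region.label
        return out


def label_components(
    mask: np.ndarray,
    color: str = "white",
    connectivity: int | None = None,
    image: np.ndarray | None = None,
) -> list[Region]:
    """Connected components of one color, in row-major first-pixel order.

    Default connectivity is 8 (skimage connectivity=2) for white and 4
    for black.  When ``image`` is given each region records its summed
    counts.
    """
    mask = np.asarray(mask, dtype=bool)
    if color == "white":
        target = mask
        conn = WHITE_CONNECTIVITY if connectivity is None else connectivity
    elif color == "black":
        target = ~mask
        conn = BLACK_CONNECTIVITY if connectivity is None else connectivity
    else:
        raise ValueError(f"color must be 'white' or 'black', got {color!r}")
    labeled = measure.label(target, connectivity=conn)
    regions = []
    for props in measure.regionprops(labeled):
        coords = props.coords
        total = None
        if image is not None:
            total = int(np.asarray(image)[coords[:, 0], coords[:, 1]].sum())
        regions.append(
            Region(label=props.label, color=color, coords=coords, sum_counts=total)
        )
    # deterministic label order: row-major position of each first pixel
    width = mask.shape[1]
    regions.sort(key=lambda reg: int((reg.coords[:, 0] * width + reg.coords[:, 1]).min()))
    return [replace(reg, label=i + 1) for i, reg in enumerate(regions)]


def gap_size_threshold(sizes, allowed_gap_length: int = 1) -> float:
    """Size cut from the sorted-size gap rule.

    Walk the ascending unique region sizes and stop at the first gap to
    the next size exceeding ``allowed_gap_length``; the size where the
    walk stops is the cut (regions of size <= cut are noise).  When no
    such gap exists, return :data:`FLIP_ALL`: no region is trusted.
    """
    unique_sizes = np.unique(np.asarray(list(sizes), dtype=np.int64))
    if len(unique_sizes) == 0:
        raise ValueError("empty size list")
    for current, nxt in zip(unique_sizes[:-1], unique_sizes[1:]):
        if nxt - current > allowed_gap_length:
            return float(current)
    return FLIP_ALL


def clean_mask(
    mask: np.ndarray,
    image: np.ndarray | None = None,
    allowed_gap_length: int = 1,
) -> SegmentationResult:
    """Flip noise-sized regions of both colors and relabel.

    Both size cuts are computed from the input mask and the flips are
    applied simultaneously in a single pass (no iteration).  The
    no-qualifying-gap outcome is color-asymmetric: for white it means no
    region is distinguishable from noise and every object is dropped,
    while for black (the background color) it means no speck population
    is separable from the background itself, so nothing is flipped —
    flipping all black would invert a perfectly clean mask.
    """
    mask = np.asarray(mask, dtype=bool)
    whites = label_components(mask, "white")
    blacks = label_components(mask, "black")
    w_white = gap_size_threshold([r.size for r in whites], allowed_gap_length) if whites else 0.0
    w_black = gap_size_threshold([r.size for r in blacks], allowed_gap_length) if blacks else 0.0
    cleaned = mask.copy()
    for region in whites:
        if region.size <= w_white:
            cleaned[region.coords[:, 0], region.coords[:, 1]] = False
    if not math.isinf(w_black):
        for region in blacks:
            if region.size <= w_black:
                cleaned[region.coords[:, 0], region.coords[:, 1]] = True
    surviving = label_components(cleaned, "white", image=image)
    return SegmentationResult(
        mask=cleaned,
        regions=tuple(surviving),
        w_white=w_white,
        w_black=w_black,
        allowed_gap_length=allowed_gap_length,
    )


def score_regions(
    result: SegmentationResult,
    image: np.ndarray,
    model: NoiseModel,
) -> SegmentationResult:
    """Attach a background p-value p_seg to every surviving white region.

    p_seg is the probability that a region's summed image counts (or
    more) arise from as many iid background pixels under ``model``; true
    signal regions should score far below any reasonable level.
    """
    image = np.asarray(image)
    scored = []
    for region in result.regions:
        total = int(image[region.coords[:, 0], region.coords[:, 1]].sum())
        p_seg = region_sum_pvalue(total, region.size, model)
        scored.append(replace(region, sum_counts=total, p_seg=p_seg))
    return replace(result, regions=tuple(scored))
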