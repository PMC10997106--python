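"""Image I/O, tiling and end-to-end pipeline orchestration.

The full pipeline mirrors the analysis order: per 64x64 tile, estimate
the background rate (truncated MLE + chi-square scan), convert the
requested false-positive probability into a count threshold, binarize
and book-keep a priori rates; then stitch the per-tile masks, run the
gap-rule segmentation on the stitched mask and score surviving regions
against their local background model.  Tiling exists because real
illumination is only locally uniform; on a tile the constant-background
assumption holds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .background_fit import BackgroundFit, BackgroundFitError, SortedCounts, fit_background
from .noise_model import ChipParams, NoiseModel, build_distribution
from .segmentation import SegmentationResult, clean_mask
from .thresholding import ThresholdReport, apriori_rates, binarize, threshold_from_pvalue

__all__ = [
    "Tile",
    "TileGrid",
    "PipelineConfig",
    "PipelineResult",
    "read_image",
    "write_image",
    "tile_image",
    "run_pipeline",
]

#: Edge tiles narrower than this many pixels merge into their neighbor.
MIN_EDGE_TILE = 16


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG, bit-exact, as int64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(
            f"unsupported image layout {arr.shape}; expected single-frame grayscale"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"unsupported dtype {arr.dtype}: images must carry integer counts"
        )
    return arr.astype(np.int64)


def write_image(path, image: np.ndarray) -> None:
    """Write an integer image as 16-bit TIFF (or PNG by extension)."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image.astype(np.uint8))


@dataclass(frozen=True)
class Tile:
    """One tile of the grid; ``row``/``col`` labels start at 1."""

    row: int
    col: int
    row_slice: tuple[int, int]
    col_slice: tuple[int, int]

    def view(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_slice[0] : self.row_slice[1], self.col_slice[0] : self.col_slice[1]]

    @property
    def n_pixels(self) -> int:
        return (self.row_slice[1] - self.row_slice[0]) * (
            self.col_slice[1] - self.col_slice[0]
        )


@dataclass(frozen=True)
class TileGrid:
    shape: tuple[int, int]
    tile_size: int
    tiles: tuple[Tile, ...]

    @property
    def n_rows(self) -> int:
        return max(t.row for t in self.tiles)

    @property
    def n_cols(self) -> int:
        return max(t.col for t in self.tiles)


def _edges(length: int, tile_size: int) -> list[tuple[int, int]]:
    if length <= tile_size:
        return [(0, length)]
    starts = list(range(0, length, tile_size))
    edges = [(s, min(s + tile_size, length)) for s in starts]
    if edges[-1][1] - edges[-1][0] < MIN_EDGE_TILE and len(edges) > 1:
        last = edges.pop()
        prev = edges.pop()
        edges.append((prev[0], last[1]))
    return edges


def tile_image(image: np.ndarray, tile_size: int = 64) -> TileGrid:
    """Cover the image exactly with row-major tiles.

    Edge tiles keep the remainder unless it is narrower than
    ``MIN_EDGE_TILE`` pixels, in which case it merges into its neighbor.
    """
    h, w = np.asarray(image).shape
    row_edges = _edges(h, tile_size)
    col_edges = _edges(w, tile_size)
    tiles = [
        Tile(row=i + 1, col=j + 1, row_slice=rs, col_slice=cs)
        for i, rs in enumerate(row_edges)
        for j, cs in enumerate(col_edges)
    ]
    return TileGrid(shape=(h, w), tile_size=tile_size, tiles=tuple(tiles))


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs, defaulting to the standard analysis settings."""

    p_gof: float = 0.01
    p_binarize: float = 0.01
    tile_size: int = 64
    allowed_gap_length: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("p_gof", "p_binarize"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class TileResult:
    tile: Tile
    background: BackgroundFit | None
    report: ThresholdReport | None
    fallback_from: tuple[int, int] | None = None

    @property
    def passed(self) -> bool:
        return self.background is not None


@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline produced for one image."""

    config: PipelineConfig
    chip: ChipParams
    grid: TileGrid
    tile_results: tuple[TileResult, ...]
    mask: np.ndarray
    segmentation: SegmentationResult
    aggregate_rates: dict
    n_failed_tiles: int

    def to_report(self) -> dict:
        tiles = []
        for tr in self.tile_results:
            entry = {
                "row": tr.tile.row,
                "col": tr.tile.col,
                "passed": tr.passed,
            }
            if tr.background is not None:
                entry["lambda_bg"] = tr.background.lam_bg
                entry["n_icr_bg"] = tr.background.n_icr_bg
            if tr.report is not None:
                entry["threshold"] = tr.report.to_dict()
            if tr.fallback_from is not None:
                entry["fallback_from"] = list(tr.fallback_from)
            tiles.append(entry)
        return {
            "config": self.config.to_dict(),
            "chip": self.chip.to_dict(),
            "image_shape": list(self.grid.shape),
            "tile_size": self.grid.tile_size,
            "tiles": tiles,
            "aggregate_rates": dict(self.aggregate_rates),
            "n_failed_tiles": self.n_failed_tiles,
            "segmentation": {
                "w_white": _json_size(self.segmentation.w_white),
                "w_black": _json_size(self.segmentation.w_black),
                "allowed_gap_length": self.segmentation.allowed_gap_length,
                "regions": [
                    {
                        "label": r.label,
                        "size": r.size,
                        "centroid": list(r.centroid),
                        "sum_counts": r.sum_counts,
                        "p_seg": r.p_seg,
                    }
                    for r in self.segmentation.regions
                ],
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_report(), indent=2, sort_keys=True)


def _json_size(value: float):
    return None if math.isinf(value) else value


def run_pipeline(
    image, chip: ChipParams, config: PipelineConfig | None = None
) -> PipelineResult:
    """Background fit, thresholding and segmentation, tile by tile.

    ``image`` is an integer array or a path readable by
    :func:`read_image`.  Tiles where no truncation point passes the
    goodness-of-fit test are flagged and excluded from rate
    aggregation; their pixels are binarized with the threshold of the
    nearest passing tile.
    """
    if config is None:
        config = PipelineConfig()
    if not isinstance(image, np.ndarray):
        image = read_image(image)
    image = np.asarray(image).astype(np.int64)
    grid = tile_image(image, config.tile_size)

    fits: dict[tuple[int, int], BackgroundFit] = {}
    raw: list[tuple[Tile, BackgroundFit | None]] = []
    for tile in grid.tiles:
        counts = SortedCounts.from_image(tile.view(image), min_pixels=MIN_EDGE_TILE**2)
        try:
            fit = fit_background(counts, chip, p_gof=config.p_gof)
            fits[(tile.row, tile.col)] = fit
        except (BackgroundFitError, ValueError):
            fit = None
        raw.append((tile, fit))
    if not fits:
        raise BackgroundFitError("no tile passed the goodness-of-fit scan")

    mask = np.zeros(image.shape, dtype=bool)
    tile_results: list[TileResult] = []
    models: dict[tuple[int, int], NoiseModel] = {}
    thresholds: dict[tuple[int, int], int] = {}
    for tile, fit in raw:
        fallback_from = None
        if fit is None:
            key = min(
                fits,
                key=lambda rc: (rc[0] - tile.row) ** 2 + (rc[1] - tile.col) ** 2,
            )
            source_fit = fits[key]
            fallback_from = key
        else:
            source_fit = fit
        model = NoiseModel(chip=chip, lam=source_fit.lam_bg)
        dist = build_distribution(model, tail_mass=min(1e-9, config.p_binarize * 1e-3))
        n_thresh, _ = threshold_from_pvalue(config.p_binarize, model, dist=dist)
        counts = SortedCounts.from_image(tile.view(image), min_pixels=MIN_EDGE_TILE**2)
        report = None
        if fit is not None:
            try:
                report = apriori_rates(
                    counts,
                    model,
                    n_icr_thresh=n_thresh,
                    n_icr_bg=fit.n_icr_bg,
                    p_binarize=config.p_binarize,
                    dist=dist,
                )
            except ValueError:
                report = None
        tile_mask = binarize(tile.view(image), n_thresh)
        mask[tile.row_slice[0] : tile.row_slice[1], tile.col_slice[0] : tile.col_slice[1]] = (
            tile_mask.white
        )
        key = (tile.row, tile.col)
        models[key] = model
        thresholds[key] = n_thresh
        tile_results.append(
            TileResult(tile=tile, background=fit, report=report, fallback_from=fallback_from)
        )

    aggregate = _aggregate_rates(tile_results)
    segmentation = _segment(image, mask, grid, models, config)
    return PipelineResult(
        config=config,
        chip=chip,
        grid=grid,
        tile_results=tuple(tile_results),
        mask=mask,
        segmentation=segmentation,
        aggregate_rates=aggregate,
        n_failed_tiles=sum(1 for tr in tile_results if not tr.passed),
    )


def _aggregate_rates(tile_results) -> dict:
    """Pixel-count-weighted mean a priori rates over passing tiles."""
    weights = []
    rates = []
    for tr in tile_results:
        if tr.report is None:
            continue
        weights.append(tr.tile.n_pixels)
        rates.append(tr.report.rates)
    if not weights:
        return {}
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    return {
        name: float(sum(w * r[name] for w, r in zip(weights, rates)))
        for name in ("FPR", "FNR", "ACC", "FDR", "FOR")
    }


def _segment(image, mask, grid, models, config) -> SegmentationResult:
    """Clean the stitched mask and score regions with their local model."""
    result = clean_mask(mask, image=image, allowed_gap_length=config.allowed_gap_length)
    if not result.regions:
        return result
    # per-pixel tile membership for area-weighted lambda_bg per region
    tile_of = np.empty(mask.shape, dtype=np.int32)
    keys = []
    for i, tile in enumerate(grid.tiles):
        tile_of[
            tile.row_slice[0] : tile.row_slice[1], tile.col_slice[0] : tile.col_slice[1]
        ] = i
        keys.append((tile.row, tile.col))
    from dataclasses import replace as _replace

    from .noise_model import region_sum_pvalue

    scored = []
    for region in result.regions:
        tiles_hit = tile_of[region.coords[:, 0], region.coords[:, 1]]
        lam = float(
            np.mean([models[keys[t]].lam for t in tiles_hit])
        )  # area-weighted across spanned tiles
        chip = next(iter(models.values())).chip
        model = NoiseModel(chip=chip, lam=lam)
        total = int(image[region.coords[:, 0], region.coords[:, 1]].sum())
        p_seg = region_sum_pvalue(total, region.size, model)
        scored.append(_replace(region, sum_counts=total, p_seg=p_seg))
    return _replace(result, regions=tuple(scored))
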