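"""Camera parameter estimation from calibration stacks (photon transfer).

Mean-variance relations of the EMCCD count distribution:

    gain off:  S^2 = (1/f)   * xbar - Delta/f      + r^2 + 1/12
    gain on:   S^2 = (2g/f)  * xbar - 2 g Delta/f  + r^2 + 1/12

Fitting straight lines ``y = k x + C`` to per-pixel (mean, variance)
scatter in both gain modes therefore yields

    f = 1 / k_nogain,             g = k_gain * f / 2,
    Delta = f (C_nogain - C_gain) / (2 g - 1),
    r^2 = C_nogain - 1/12 + Delta / f.

Uncertainty is quantified by refitting on random 1000-pixel subsamples
and reporting per-parameter medians and interquartile ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .noise_model import ChipParams

__all__ = [
    "PixelStats",
    "MVLineFit",
    "ChipEstimate",
    "CalibrationError",
    "pixel_stats",
    "fit_mv_line",
    "chip_from_fits",
    "subsample_uncertainty",
    "calibrate_chip",
]


class CalibrationError(RuntimeError):
    """Calibration data inconsistent with the camera model."""


@dataclass(frozen=True)
class PixelStats:
    """Per-pixel sample mean and unbiased variance over a frame stack."""

    mean: np.ndarray
    variance: np.ndarray
    pixel_index: np.ndarray

    def __len__(self) -> int:
        return len(self.mean)


@dataclass(frozen=True)
class MVLineFit:
    """Ordinary least-squares line through a mean-variance scatter."""

    slope: float
    intercept: float
    n_points_used: int
    trim_fractions: tuple[float, float]


@dataclass(frozen=True)
class ChipEstimate:
    """Chip parameters with subsampling medians and interquartile ranges."""

    params: ChipParams
    median: dict
    iqr: dict  # parameter -> (q25, q75)
    n_reps: int


def pixel_stats(stack: np.ndarray) -> PixelStats:
    """Per-pixel mean and unbiased (n-1) variance of an image stack.

    ``stack`` has shape (n_frames, H, W) or (n_frames, n_pixels).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 2 or stack.shape[0] < 2:
        raise ValueError("stack needs at least 2 frames with constant geometry")
    flat = stack.reshape(stack.shape[0], -1)
    return PixelStats(
        mean=flat.mean(axis=0),
        variance=flat.var(axis=0, ddof=1),
        pixel_index=np.arange(flat.shape[1]),
    )


def _trim_experiment(
    stats: PixelStats, trim_low: float, trim_high: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the trim_low/trim_high mean quantiles of one experiment.

    Trimming on the regressor (the pixel mean) removes outlier pixels
    without biasing the least-squares line; trimming on the variance
    would select on the response and systematically pull the line down.
    """
    x = stats.mean
    keep = np.ones(len(x), dtype=bool)
    if trim_low > 0:
        keep &= x >= np.quantile(x, trim_low)
    if trim_high > 0:
        keep &= x <= np.quantile(x, 1.0 - trim_high)
    return x[keep], stats.variance[keep]


def fit_mv_line(
    points,
    trim_low: float = 0.01,
    trim_high: float = 0.01,
) -> MVLineFit:
    """OLS fit of variance on mean, pooled over experiments after trimming.

    Parameters
    ----------
    points
        A single :class:`PixelStats` or a list of them (one per
        illumination level); trimming is applied per experiment, the fit
        pools all surviving pixels.
    trim_low, trim_high
        Variance-quantile fractions removed from each experiment to
        suppress outlier pixels (default 1% each side).
    """
    if isinstance(points, PixelStats):
        points = [points]
    xs, ys = [], []
    for stats in points:
        x, y = _trim_experiment(stats, trim_low, trim_high)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 10:
        raise CalibrationError(f"only {len(x)} points after trimming; need >= 10")
    if np.ptp(x) < 1e-12:
        raise CalibrationError("degenerate mean spread; cannot fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    return MVLineFit(
        slope=float(slope),
        intercept=float(intercept),
        n_points_used=len(x),
        trim_fractions=(trim_low, trim_high),
    )


def chip_from_fits(fit_nogain: MVLineFit, fit_gain: MVLineFit) -> ChipParams:
    """Invert the two mean-variance lines into the four chip constants."""
    if fit_nogain.slope <= 0 or fit_gain.slope <= 0:
        raise CalibrationError("mean-variance slopes must be positive")
    f = 1.0 / fit_nogain.slope
    g = fit_gain.slope * f / 2.0
    if 2.0 * g - 1.0 <= 0:
        raise CalibrationError(f"2g - 1 = {2 * g - 1:.3f} <= 0: inconsistent fits")
    delta = f * (fit_nogain.intercept - fit_gain.intercept) / (2.0 * g - 1.0)
    r_squared = fit_nogain.intercept - 1.0 / 12.0 + delta / f
    if r_squared < 0:
        raise CalibrationError(f"implied r^2 = {r_squared:.4f} < 0: inconsistent fits")
    return ChipParams(g=g, f=f, r=float(np.sqrt(r_squared)), delta=delta, gain_on=True)


def _fit_chip(points_nogain, points_gain, trim_low, trim_high) -> ChipParams:
    fit_ng = fit_mv_line(points_nogain, trim_low, trim_high)
    fit_g = fit_mv_line(points_gain, trim_low, trim_high)
    return chip_from_fits(fit_ng, fit_g)


def subsample_uncertainty(
    points_nogain,
    points_gain,
    subset_size: int = 1000,
    n_reps: int = 200,
    trim_low: float = 0.01,
    trim_high: float = 0.01,
    seed=None,
) -> ChipEstimate:
    """Random-subsampling uncertainty of the chip parameters.

    Repeats the full two-line fit on random ``subset_size``-pixel subsets
    (without replacement within a repetition) and reports per-parameter
    medians and interquartile ranges.
    """
    if isinstance(points_nogain, PixelStats):
        points_nogain = [points_nogain]
    if isinstance(points_gain, PixelStats):
        points_gain = [points_gain]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_pixels = min(min(len(s) for s in points_nogain), min(len(s) for s in points_gain))
    if n_pixels < subset_size:
        warnings.warn(
            f"only {n_pixels} pixels < subset_size={subset_size}; "
            "reporting a single full fit",
            stacklevel=2,
        )
        chip = _fit_chip(points_nogain, points_gain, trim_low, trim_high)
        med = chip.to_dict()
        return ChipEstimate(
            params=chip,
            median={k: med[k] for k in ("g", "f", "r", "delta")},
            iqr={k: (med[k], med[k]) for k in ("g", "f", "r", "delta")},
            n_reps=1,
        )

    estimates = {k: [] for k in ("g", "f", "r", "delta")}
    for _ in range(n_reps):
        idx = rng.choice(n_pixels, size=subset_size, replace=False)
        sub_ng = [
            PixelStats(s.mean[idx], s.variance[idx], s.pixel_index[idx])
            for s in points_nogain
        ]
        sub_g = [
            PixelStats(s.mean[idx], s.variance[idx], s.pixel_index[idx])
            for s in points_gain
        ]
        try:
            chip = _fit_chip(sub_ng, sub_g, trim_low, trim_high)
        except CalibrationError:
            continue
        for k, v in zip(("g", "f", "r", "delta"), (chip.g, chip.f, chip.r, chip.delta)):
            estimates[k].append(v)
    if not estimates["f"]:
        raise CalibrationError("every subsample fit failed")
    median = {k: float(np.median(v)) for k, v in estimates.items()}
    iqr = {
        k: (float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)))
        for k, v in estimates.items()
    }
    params = ChipParams(
        g=median["g"], f=median["f"], r=median["r"], delta=median["delta"], gain_on=True
    )
    return ChipEstimate(params=params, median=median, iqr=iqr, n_reps=len(estimates["f"]))


def calibrate_chip(
    stacks_nogain,
    stacks_gain,
    trim_low: float = 0.01,
    trim_high: float = 0.01,
    subset_size: int = 1000,
    n_reps: int = 200,
    seed=None,
    exclude_levels: tuple[int, ...] = (),
) -> ChipEstimate:
    """Full calibration from raw stacks to a ChipEstimate.

    ``stacks_nogain`` and ``stacks_gain`` are sequences of
    (n_frames, H, W) arrays, one per illumination level.
    ``exclude_levels`` drops dataset-specific outlier levels by index
    (applies to both modes; default none).
    """
    points_ng = [
        pixel_stats(s) for i, s in enumerate(stacks_nogain) if i not in exclude_levels
    ]
    points_g = [
        pixel_stats(s) for i, s in enumerate(stacks_gain) if i not in exclude_levels
    ]
    full = _fit_chip(points_ng, points_g, trim_low, trim_high)
    est = subsample_uncertainty(
        points_ng,
        points_g,
        subset_size=subset_size,
        n_reps=n_reps,
        trim_low=trim_low,
        trim_high=trim_high,
        seed=seed,
    )
    # keep the pooled full-data fit as the point estimate
    return ChipEstimate(params=full, median=est.median, iqr=est.iqr, n_reps=est.n_reps)
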