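"""Probabilistic image thresholding with a priori misclassification rates.

Given the fitted background model theta = {chip, lam_bg}, a requested
tail probability p_binarize is converted into the tightest count
threshold N with P(count > N | background) <= p_binarize.  Counts <= N
are "black", counts > N are "white" (white = positive = signal).

Because the background CDF is known, the pixel population can be split
without ground truth: for thresholds N_j below the trusted truncation
point N_icr_bg, (# pixels <= N_j) = n_bg * cdf(N_j | theta) exactly when
only background contributes, so n_bg is the through-the-origin slope of
that relation.  From n_bg and the black-pixel count, all five confusion
rates (FPR, FNR, ACC, FDR, FOR) are predicted a priori; a +1/+2 Laplace
correction keeps p(black | signal) away from 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background_fit import SortedCounts
from .noise_model import CountDistribution, NoiseModel, build_distribution, invert_cdf

__all__ = [
    "ThresholdReport",
    "BinaryMask",
    "threshold_from_pvalue",
    "binarize",
    "estimate_pixel_split",
    "apriori_rates",
    "otsu_threshold",
    "evaluate_vs_truth",
]

RATE_NAMES = ("FPR", "FNR", "ACC", "FDR", "FOR")


@dataclass(frozen=True)
class BinaryMask:
    """Black/white pixel labels with the threshold that produced them."""

    white: np.ndarray  # True where count > threshold
    n_icr_thresh: int

    @property
    def n_black(self) -> int:
        return int(self.white.size - self.white.sum())


@dataclass(frozen=True)
class ThresholdReport:
    """Threshold, pixel-count bookkeeping and a priori error rates."""

    n_icr_thresh: int
    p_binarize: float
    p_white_given_bg: float
    p_black_given_s: float
    n_bg: int
    n_s: int
    n_black: int
    rates: dict
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "n_icr_thresh": self.n_icr_thresh,
            "p_binarize": self.p_binarize,
            "p_white_given_bg": self.p_white_given_bg,
            "p_black_given_s": self.p_black_given_s,
            "n_bg": self.n_bg,
            "n_s": self.n_s,
            "n_black": self.n_black,
            "rates": dict(self.rates),
            "flags": list(self.flags),
        }


def threshold_from_pvalue(
    p_binarize: float, model: NoiseModel, dist: CountDistribution | None = None
) -> tuple[int, float]:
    """Invert the background CDF into a count threshold.

    Returns ``(n_icr_thresh, p_white_given_bg)`` where the achieved tail
    probability never exceeds the requested ``p_binarize``.
    """
    if dist is None:
        dist = build_distribution(model, tail_mass=min(1e-9, p_binarize * 1e-3))
    n_thresh = invert_cdf(p_binarize, model, dist=dist)
    achieved = float(np.clip(1.0 - dist.cdf(n_thresh), 0.0, 1.0))
    return n_thresh, achieved


def binarize(image: np.ndarray, n_icr_thresh: int) -> BinaryMask:
    """Counts <= threshold turn black; counts above it turn white."""
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        raise ValueError(f"binarize expects an integer image, got dtype {image.dtype}")
    return BinaryMask(white=image > n_icr_thresh, n_icr_thresh=int(n_icr_thresh))


def estimate_pixel_split(
    counts: SortedCounts,
    model: NoiseModel,
    n_icr_bg: int,
    dist: CountDistribution | None = None,
) -> tuple[int, int]:
    """Estimate (n_bg, n_s) from the sub-truncation count ramp.

    For each integer N_j from the distribution support minimum up to
    ``n_icr_bg - 1``, the point (cdf(N_j | theta), # pixels <= N_j) lies
    on a line through the origin with slope n_bg; the slope is fitted by
    least squares and n_s = m - n_bg.
    """
    if dist is None:
        dist = build_distribution(model)
    n_values = np.arange(dist.n_min, int(n_icr_bg))
    if len(n_values) < 3:
        raise ValueError("need at least 3 thresholds below n_icr_bg")
    x = dist.cdf(n_values)
    y = np.searchsorted(counts.values, n_values, side="right").astype(float)
    denom = float(x @ x)
    if denom <= 0:
        raise ValueError("background CDF vanishes below n_icr_bg")
    slope = float(x @ y) / denom
    n_bg = int(np.clip(round(slope), 0, counts.m))
    return n_bg, counts.m - n_bg


def apriori_rates(
    counts: SortedCounts,
    model: NoiseModel,
    n_icr_thresh: int,
    n_icr_bg: int,
    p_binarize: float | None = None,
    dist: CountDistribution | None = None,
) -> ThresholdReport:
    """Predict the five misclassification rates without ground truth.

    Bookkeeping: n(black|bg) = n_bg * cdf(N_thresh); n(black|s) =
    n_black - n(black|bg) (clipped at 0); p(black|s) applies the +1/+2
    Laplace correction.  Rates use white = positive:
    FPR = p(white|bg), FNR = p(black|s),
    ACC = [n_bg (1-FPR) + n_s (1-FNR)] / m,
    FDR = n_bg FPR / [n_bg FPR + n_s (1-FNR)],
    FOR = n_s FNR / [n_s FNR + n_bg (1-FPR)].
    """
    if dist is None:
        dist = build_distribution(model)
    flags: list[str] = []
    m = counts.m
    n_bg, n_s = estimate_pixel_split(counts, model, n_icr_bg, dist=dist)
    cdf_thresh = float(dist.cdf(n_icr_thresh))
    p_white_bg = float(np.clip(1.0 - cdf_thresh, 0.0, 1.0))
    n_black = counts.n_below(int(n_icr_thresh))
    n_black_bg = n_bg * cdf_thresh
    n_black_s = n_black - n_black_bg
    if n_black_s < 0:
        flags.append("n_black_s_clipped")
        n_black_s = 0.0
    if n_black_s > n_s:
        # estimation noise in the pixel split; a probability needs
        # n(black|s) <= n_s
        flags.append("n_black_s_capped")
        n_black_s = float(n_s)
    p_black_s = (n_black_s + 1.0) / (n_s + 2.0)
    fpr = p_white_bg
    fnr = p_black_s
    acc = (n_bg * (1.0 - fpr) + n_s * (1.0 - fnr)) / m
    fdr_den = n_bg * fpr + n_s * (1.0 - fnr)
    if fdr_den > 0:
        fdr = n_bg * fpr / fdr_den
    else:
        fdr = 0.0
        flags.append("fdr_zero_denominator")
    for_den = n_s * fnr + n_bg * (1.0 - fpr)
    if for_den > 0:
        fo_rate = n_s * fnr / for_den
    else:
        fo_rate = 0.0
        flags.append("for_zero_denominator")
    return ThresholdReport(
        n_icr_thresh=int(n_icr_thresh),
        p_binarize=float(p_binarize) if p_binarize is not None else p_white_bg,
        p_white_given_bg=p_white_bg,
        p_black_given_s=p_black_s,
        n_bg=n_bg,
        n_s=n_s,
        n_black=n_black,
        rates={
            "FPR": fpr,
            "FNR": fnr,
            "ACC": float(np.clip(acc, 0.0, 1.0)),
            "FDR": fdr,
            "FOR": fo_rate,
        },
        flags=tuple(flags),
    )


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold by exhaustive scan (baseline, no error control).

    Returns the integer t minimizing the weighted sum of within-class
    variances when pixels <= t are black and pixels > t are white.
    """
    values = np.asarray(image).ravel()
    levels, counts = np.unique(values, return_counts=True)
    if len(levels) < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    levels = levels.astype(float)
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_x = np.cumsum(w * levels)
    cum_x2 = np.cumsum(w * levels**2)
    best_t, best_score = None, np.inf
    for i in range(len(levels) - 1):  # black class = levels[:i+1]
        w0, w1 = cum_w[i], total - cum_w[i]
        m0 = cum_x[i] / w0
        m1 = (cum_x[-1] - cum_x[i]) / w1
        v0 = cum_x2[i] / w0 - m0**2
        v1 = (cum_x2[-1] - cum_x2[i]) / w1 - m1**2
        score = w0 * v0 + w1 * v1
        if score < best_score:
            best_score, best_t = score, levels[i]
    return int(best_t)


def evaluate_vs_truth(mask: BinaryMask | np.ndarray, truth_mask: np.ndarray) -> dict:
    """Observed confusion rates of a binary mask against ground truth.

    White is the positive class and true signal pixels are the positive
    condition.  Empty denominators yield a rate of 0.
    """
    white = mask.white if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if white.shape != truth.shape:
        raise ValueError(f"shape mismatch: mask {white.shape} vs truth {truth.shape}")
    tp = float(np.sum(white & truth))
    fp = float(np.sum(white & ~truth))
    fn = float(np.sum(~white & truth))
    tn = float(np.sum(~white & ~truth))

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    return {
        "FPR": ratio(fp, fp + tn),
        "FNR": ratio(fn, fn + tp),
        "ACC": ratio(tp + tn, tp + tn + fp + fn),
        "FDR": ratio(fp, fp + tp),
        "FOR": ratio(fn, fn + tn),
    }
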