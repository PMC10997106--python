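"""Background rate estimation by truncated MLE with chi-square selection.

An image that contains both background and signal pixels still has a
lower count range dominated by background.  The background Poisson rate
lam_bg is therefore fitted to the counts at or below a truncation point
N, with the likelihood renormalized by cdf(N | theta):

    L(lam) = prod_{n_j <= N} pmf(n_j | theta) / cdf(N | theta).

The fit is repeated over a grid of candidate truncation points (lowest
at the 25% data quantile); each candidate is scored by a chi-square
goodness-of-fit test on five count intervals with near-equal fitted
probability (3 degrees of freedom: 5 bins - 1 - 1 estimated parameter).
The accepted truncation N_icr_bg is the largest candidate whose p-value
reaches the significance level p_gof, and lam_bg is its fitted rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .noise_model import (
    ChipParams,
    NoiseModel,
    cf_emccd,
    default_half_width,
    _OVERSAMPLE,
    _MIN_POINTS,
)

__all__ = [
    "SortedCounts",
    "TruncationScanRecord",
    "BackgroundFit",
    "BackgroundFitError",
    "truncation_grid",
    "truncated_mle",
    "gof_chi2",
    "fit_background",
    "initial_lambda",
]

#: Default ceiling on the number of truncation candidates scanned.
MAX_CANDIDATES = 60

#: Relative tolerance of the scalar likelihood maximization.
MLE_RELATIVE_TOL = 1e-4

#: Formal upper bound of the lambda search, in units of the initializer.
LAMBDA_BOUND_FACTOR = 50.0


class BackgroundFitError(RuntimeError):
    """No truncation point produced an acceptable background fit."""

    def __init__(self, message: str, scan=None):
        super().__init__(message)
        self.scan = scan or []


@dataclass(frozen=True)
class SortedCounts:
    """Ascending integer image counts of one image or tile."""

    values: np.ndarray
    min_pixels: int = 100

    def __post_init__(self):
        values = np.sort(np.asarray(self.values).ravel()).astype(np.int64)
        object.__setattr__(self, "values", values)
        if len(values) < self.min_pixels:
            raise ValueError(
                f"{len(values)} pixels < configured floor of {self.min_pixels}"
            )

    @classmethod
    def from_image(cls, image: np.ndarray, min_pixels: int = 100) -> "SortedCounts":
        return cls(values=np.asarray(image).ravel(), min_pixels=min_pixels)

    @property
    def m(self) -> int:
        return len(self.values)

    def n_below(self, truncation: int) -> int:
        """Number of counts <= truncation."""
        return int(np.searchsorted(self.values, truncation, side="right"))


@dataclass(frozen=True)
class TruncationScanRecord:
    truncation_point: int
    lambda_hat: float
    gof_pvalue: float
    n_below: int
    failed: bool = False


@dataclass(frozen=True)
class BackgroundFit:
    """Accepted background fit plus the full truncation scan."""

    lam_bg: float
    n_icr_bg: int
    scan: tuple[TruncationScanRecord, ...]
    p_gof: float

    def to_dict(self) -> dict:
        return {
            "lambda_bg": self.lam_bg,
            "n_icr_bg": self.n_icr_bg,
            "p_gof": self.p_gof,
            "scan": [
                {
                    "trunc": rec.truncation_point,
                    "lambda": rec.lambda_hat,
                    "p": rec.gof_pvalue,
                    "n_below": rec.n_below,
                    "failed": rec.failed,
                }
                for rec in self.scan
            ],
        }


def initial_lambda(counts: SortedCounts, chip: ChipParams) -> float:
    """Moment-based initializer (median count - Delta) / (g/f), floored."""
    median = float(counts.values[counts.m // 2])
    lam0 = (median - chip.delta) / chip.counts_per_electron
    return max(lam0, 1e-3)


def truncation_grid(
    counts: SortedCounts,
    min_fraction: float = 0.25,
    max_candidates: int = MAX_CANDIDATES,
) -> np.ndarray:
    """Candidate truncation points from the min_fraction quantile upward.

    Unique observed count values between the ``min_fraction`` data
    quantile and the maximum count, thinned to at most
    ``max_candidates`` evenly in quantile space (endpoints kept).
    """
    values = counts.values
    if values[0] == values[-1]:
        raise ValueError("all counts identical; no truncation grid possible")
    lowest = int(values[int(math.ceil(min_fraction * counts.m)) - 1])
    candidates = np.unique(values[values >= lowest])
    if len(candidates) > max_candidates:
        # pick evenly spaced quantile ranks among the candidate values
        ranks = np.searchsorted(values, candidates, side="right") / counts.m
        targets = np.linspace(ranks[0], ranks[-1], max_candidates)
        idx = np.unique(np.searchsorted(ranks, targets).clip(0, len(candidates) - 1))
        candidates = candidates[idx]
    return candidates.astype(np.int64)


class _PmfEvaluator:
    """Fast repeated PMF evaluation on a fixed integer range.

    The inverse-Fourier phase matrix depends only on the chip, the
    support and the grid — not on lambda — so it is built once per image
    and reused across every likelihood evaluation of the truncation
    scan.  ``lam_max`` bounds the phase rate the grid must resolve.
    """

    def __init__(
        self, chip: ChipParams, n_lo: int, n_hi: int, lam_max: float, lam_cap: float | None = None
    ):
        self.chip = chip
        self.n_lo = int(n_lo)
        self.n_hi = int(n_hi)
        self.lam_max = float(lam_max)
        self._cap = 0.0
        self._rebuild(min(lam_cap if lam_cap is not None else lam_max, lam_max))

    def _rebuild(self, lam_cap: float) -> None:
        """Size the quadrature grid for rates up to ``lam_cap``."""
        chip = self.chip
        half_width = default_half_width(chip)
        center = 0.5 * (self.n_lo + self.n_hi)
        max_offset = 0.5 * (self.n_hi - self.n_lo) + 1.0
        rate = lam_cap * chip.counts_per_electron + max_offset + 2.0
        n_points = max(
            _MIN_POINTS,
            int(math.ceil(2.0 * half_width * rate * _OVERSAMPLE / (2.0 * math.pi))),
        )
        p = np.linspace(-half_width, half_width, n_points)
        weights = np.full(n_points, p[1] - p[0])
        weights[0] *= 0.5
        weights[-1] *= 0.5
        base_model = NoiseModel(chip=chip, lam=0.0)
        self._p = p
        self._static = (
            cf_emccd(p, base_model)
            * np.exp(-1j * p * center)
            * weights
            / (2.0 * math.pi)
        )
        d = np.arange(self.n_lo, self.n_hi + 1) - center
        self._phase = np.exp(np.outer(-1j * d, p))
        self._cap = lam_cap

    def pmf(self, lam: float) -> np.ndarray:
        """PMF on [n_lo, n_hi] at rate lam (tiny ripple clipped to 0)."""
        if lam > self._cap:
            self._rebuild(min(max(lam, 2.0 * self._cap), self.lam_max))
        chip = self.chip
        p = self._p
        if chip.gain_on:
            lam_factor = np.exp(lam * (1.0 / (1.0 - 1j * p * (chip.g / chip.f)) - 1.0))
        else:
            lam_factor = np.exp(lam * (np.exp(1j * p / chip.f) - 1.0))
        vals = (self._phase @ (self._static * lam_factor)).real
        return np.clip(vals, 0.0, None)


def _lower_support_bound(counts: SortedCounts, chip: ChipParams) -> int:
    """Integer below which the background PMF mass is negligible."""
    spread = 10.0 * (chip.r + 1.0)
    return int(math.floor(min(float(counts.values[0]), chip.delta - spread))) - 2


def _negative_log_likelihood(
    lam: float,
    evaluator: _PmfEvaluator,
    unique_vals: np.ndarray,
    multiplicities: np.ndarray,
    truncation: int,
    n_below: int,
) -> float:
    pmf = evaluator.pmf(lam)
    cdf_at_trunc = pmf[: truncation - evaluator.n_lo + 1].sum()
    if cdf_at_trunc <= 0:
        return np.inf
    probs = pmf[unique_vals - evaluator.n_lo]
    if np.any(probs <= 0):
        return np.inf
    return float(n_below * math.log(cdf_at_trunc) - multiplicities @ np.log(probs))


def _maximize_truncated_likelihood(
    evaluator: _PmfEvaluator,
    counts: SortedCounts,
    truncation: int,
    lam_init: float,
) -> float:
    n_below = counts.n_below(truncation)
    below = counts.values[:n_below]
    unique_vals, multiplicities = np.unique(below, return_counts=True)
    args = (evaluator, unique_vals, multiplicities.astype(float), truncation, n_below)
    xatol = max(MLE_RELATIVE_TOL * lam_init, 1e-6)
    upper = min(4.0 * lam_init, evaluator.lam_max)
    while True:
        res = optimize.minimize_scalar(
            _negative_log_likelihood,
            bounds=(1e-3, upper),
            args=args,
            method="bounded",
            options={"xatol": xatol},
        )
        at_ceiling = res.x > 0.99 * upper
        if not at_ceiling or upper >= evaluator.lam_max:
            return float(res.x)
        upper = min(4.0 * upper, evaluator.lam_max)


def truncated_mle(
    counts: SortedCounts,
    truncation: int,
    chip: ChipParams,
    min_fraction: float = 0.25,
) -> float:
    """Maximum-likelihood lam for counts <= ``truncation``.

    Maximizes sum_j [log pmf(n_j | theta) - log cdf(truncation | theta)]
    over lam by bounded derivative-free search on
    [1e-3, 50 * lam_init], starting near the moment initializer
    lam_init = (median count - Delta) / (g/f).
    """
    n_below = counts.n_below(truncation)
    if n_below < min_fraction * counts.m:
        raise ValueError(
            f"only {n_below}/{counts.m} counts at or below truncation {truncation}"
        )
    lam_init = initial_lambda(counts, chip)
    evaluator = _PmfEvaluator(
        chip,
        _lower_support_bound(counts, chip),
        int(counts.values[-1]),
        lam_max=LAMBDA_BOUND_FACTOR * lam_init,
        lam_cap=4.0 * lam_init,
    )
    return _maximize_truncated_likelihood(evaluator, counts, int(truncation), lam_init)


def _quantile_bin_edges(trunc_probs: np.ndarray, n_bins: int) -> list[int] | None:
    """Greedy integer bin edges with near-1/n_bins truncated-PMF mass.

    Returns end indices (inclusive) of each bin into ``trunc_probs``,
    or None when fewer than ``n_bins`` non-degenerate bins fit.
    """
    cum = np.cumsum(trunc_probs)
    total = cum[-1]
    edges: list[int] = []
    prev = -1
    for j in range(1, n_bins):
        target = total * j / n_bins
        idx = int(np.searchsorted(cum, target))
        idx = max(idx, prev + 1)
        if idx >= len(trunc_probs) - (n_bins - j):
            return None
        edges.append(idx)
        prev = idx
    edges.append(len(trunc_probs) - 1)
    return edges


def gof_chi2(
    counts: SortedCounts,
    truncation: int,
    model: NoiseModel,
    n_bins: int = 5,
    evaluator: _PmfEvaluator | None = None,
) -> float:
    """Chi-square goodness-of-fit p-value of a truncated background fit.

    The truncated fitted PMF on [support_min, truncation] is split into
    ``n_bins`` contiguous count intervals of near-equal fitted mass;
    the statistic sum (O - E)^2 / E is referred to a chi-square with
    ``n_bins - 1 - 1`` degrees of freedom (one estimated parameter).

    Returns NaN when no valid binning exists (too few distinct counts).
    """
    truncation = int(truncation)
    n_below = counts.n_below(truncation)
    if n_below < 5 * n_bins:
        raise ValueError(f"{n_below} counts below truncation; need >= {5 * n_bins}")
    if evaluator is None:
        evaluator = _PmfEvaluator(
            model.chip,
            _lower_support_bound(counts, model.chip),
            int(counts.values[-1]),
            lam_max=max(2.0 * model.lam, 1.0),
        )
    pmf = evaluator.pmf(model.lam)
    upto = truncation - evaluator.n_lo + 1
    trunc_probs = pmf[:upto]
    total = trunc_probs.sum()
    if total <= 0:
        return float("nan")
    edges = _quantile_bin_edges(trunc_probs, n_bins)
    if edges is None:
        return float("nan")
    observed_per_count = np.bincount(
        counts.values[:n_below] - evaluator.n_lo, minlength=upto
    ).astype(float)
    start = 0
    stat = 0.0
    for end in edges:
        expected = n_below * trunc_probs[start : end + 1].sum() / total
        observed = observed_per_count[start : end + 1].sum()
        if expected <= 0:
            return float("nan")
        stat += (observed - expected) ** 2 / expected
        start = end + 1
    dof = n_bins - 1 - 1
    return float(stats.chi2.sf(stat, dof))


def fit_background(
    counts: SortedCounts,
    chip: ChipParams,
    p_gof: float = 0.01,
    min_fraction: float = 0.25,
    max_candidates: int = MAX_CANDIDATES,
) -> BackgroundFit:
    """Scan truncation points; accept the largest passing the chi-square test.

    Runs the truncated MLE and the goodness-of-fit test at every
    candidate truncation, returning the accepted fit together with the
    whole scan for diagnostics.  Raises :class:`BackgroundFitError`
    (carrying the scan) when no candidate passes.
    """
    candidates = truncation_grid(counts, min_fraction, max_candidates)
    lam_init = initial_lambda(counts, chip)
    evaluator = _PmfEvaluator(
        chip,
        _lower_support_bound(counts, chip),
        int(counts.values[-1]),
        lam_max=LAMBDA_BOUND_FACTOR * lam_init,
        lam_cap=4.0 * lam_init,
    )
    scan: list[TruncationScanRecord] = []
    for trunc in candidates:
        trunc = int(trunc)
        n_below = counts.n_below(trunc)
        try:
            lam_hat = _maximize_truncated_likelihood(evaluator, counts, trunc, lam_init)
            pval = gof_chi2(
                counts,
                trunc,
                NoiseModel(chip=chip, lam=lam_hat),
                evaluator=evaluator,
            )
            failed = not np.isfinite(pval)
        except (ValueError, RuntimeError):
            lam_hat, pval, failed = float("nan"), float("nan"), True
        scan.append(
            TruncationScanRecord(
                truncation_point=trunc,
                lambda_hat=lam_hat,
                gof_pvalue=0.0 if failed else float(pval),
                n_below=n_below,
                failed=failed,
            )
        )
    passing = [rec for rec in scan if not rec.failed and rec.gof_pvalue >= p_gof]
    if not passing:
        raise BackgroundFitError(
            "no truncation point passed the goodness-of-fit test", scan=scan
        )
    best = max(passing, key=lambda rec: rec.truncation_point)
    return BackgroundFit(
        lam_bg=best.lambda_hat,
        n_icr_bg=best.truncation_point,
        scan=tuple(scan),
        p_gof=p_gof,
    )
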