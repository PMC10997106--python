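"""EMCCD count statistics via the closed-form characteristic function.

The count recorded in one EMCCD pixel is the end of a noise chain: Poisson
photoelectrons with rate ``lam``, stochastic electron multiplication
(Gamma-distributed with mean gain ``g``), analog-to-digital conversion
(division by ``f``), additive Gaussian readout noise (standard deviation
``r``), a constant offset ``delta``, and rounding to the nearest integer.
The characteristic function (CF) of the rounded count has a closed
analytic form; every distribution-level quantity in this module — PMF,
CDF, quantiles, moments, tail probabilities of region sums — is obtained
by numerically inverting that CF.

With the gain stage on the CF is

    phi(p) = exp(-p^2 r^2 / 2 + i p delta)
             * exp(lam * (1 / (1 - i p g / f) - 1))
             * sinc(p / 2),          sinc(x) = sin(x) / x,

and with the gain off the middle factor becomes
``exp(lam * (exp(i p / f) - 1))``.  The ``sinc`` factor is the CF of the
uniform rounding error, so the PMF at integer ``n`` is the plain inverse
Fourier integral ``(1/2pi) \\int exp(-i p n) phi(p) dp``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ChipParams",
    "NoiseModel",
    "TransformGrid",
    "CountDistribution",
    "InversionError",
    "cf_emccd",
    "build_distribution",
    "moments",
    "invert_cdf",
    "region_sum_pvalue",
]

#: Region-sum p-values switch from exact CF-power inversion to the
#: continuity-corrected normal approximation above this many pixels.
EXACT_REGION_SUM_MAX_PIXELS = 64

#: |CF| at the integration cutoff when the readout noise sets the decay.
_CUTOFF_TOL = 1e-12

#: Half-width fallback when r = 0 and the Gaussian envelope is absent.
_FALLBACK_HALF_WIDTH = 64.0 * math.pi

#: Quadrature points per oscillation period of the integrand.
_OVERSAMPLE = 8.0

_MIN_POINTS = 4096


class InversionError(RuntimeError):
    """CF inversion failed to capture the required probability mass."""


@dataclass(frozen=True)
class ChipParams:
    """The four camera constants of an EMCCD chip.

    Parameters
    ----------
    g
        Electron-multiplication gain: mean electrons out per input
        electron (dimensionless).  Ignored when ``gain_on`` is False.
    f
        Analog-to-digital conversion factor, electrons per image count.
    r
        Readout noise standard deviation, in image counts.
    delta
        Camera offset added to every count so counts stay positive.
    gain_on
        Whether the electron-multiplication register is active.
    """

    g: float
    f: float
    r: float
    delta: float
    gain_on: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f) and self.f > 0):
            raise ValueError(f"f must be positive and finite, got {self.f}")
        if not (math.isfinite(self.r) and self.r >= 0):
            raise ValueError(f"r must be non-negative and finite, got {self.r}")
        if not math.isfinite(self.delta):
            raise ValueError(f"delta must be finite, got {self.delta}")
        if self.gain_on and not (math.isfinite(self.g) and self.g > 0):
            raise ValueError(f"g must be positive when gain is on, got {self.g}")

    @property
    def counts_per_electron(self) -> float:
        """Mean image counts contributed per input electron (g/f or 1/f)."""
        return self.g / self.f if self.gain_on else 1.0 / self.f

    def with_gain(self, gain_on: bool) -> "ChipParams":
        return dataclasses.replace(self, gain_on=gain_on)

    def to_dict(self) -> dict:
        return {
            "g": self.g,
            "f": self.f,
            "r": self.r,
            "delta": self.delta,
            "gain_on": self.gain_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChipParams":
        return cls(
            g=float(d.get("g", 1.0)),
            f=float(d["f"]),
            r=float(d["r"]),
            delta=float(d["delta"]),
            gain_on=bool(d.get("gain_on", True)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ChipParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class NoiseModel:
    """A chip plus an illumination rate: the full parameter set theta.

    ``lam`` is the Poisson parameter — expected photoelectrons per pixel
    per exposure (quantum efficiency folded in, spurious charge
    neglected, so lam is the single illumination parameter).
    """

    chip: ChipParams
    lam: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lam) and self.lam >= 0):
            raise ValueError(f"lam must be non-negative and finite, got {self.lam}")

    def to_dict(self) -> dict:
        d = self.chip.to_dict()
        d["lambda"] = self.lam
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(chip=ChipParams.from_dict(d), lam=float(d["lambda"]))


@dataclass(frozen=True)
class TransformGrid:
    """Symmetric Fourier-variable grid used for the inverse transform."""

    p_values: np.ndarray
    half_width: float
    n_points: int

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.n_points < 2**10:
            raise ValueError("n_points must be at least 2^10")

    @property
    def spacing(self) -> float:
        return 2.0 * self.half_width / (self.n_points - 1)


def default_half_width(chip: ChipParams, tol: float = _CUTOFF_TOL) -> float:
    """Integration cutoff P such that |CF(P)| < tol.

    The Gaussian readout factor exp(-p^2 r^2 / 2) dominates the decay
    whenever r > 0.  With r = 0 the CF only decays like ~exp(-lam)/p
    through the sinc factor, so we fall back to a fixed 64*pi.
    """
    if chip.r > 0:
        return math.sqrt(2.0 * math.log(1.0 / tol)) / chip.r
    return _FALLBACK_HALF_WIDTH


def make_grid(
    chip: ChipParams,
    lam: float,
    max_offset: float,
    oversample: float = _OVERSAMPLE,
    min_points: int = _MIN_POINTS,
) -> TransformGrid:
    """Grid sized for integrands ``exp(-i p d) * phi(p) * exp(-i p center)``.

    ``max_offset`` bounds |d| = |n - center|.  The phase rate of the
    centered integrand is at most roughly ``lam * counts_per_electron +
    |d| + 1`` anywhere on the real line, and the grid provides
    ``oversample`` points per oscillation period.
    """
    half_width = default_half_width(chip)
    rate = lam * chip.counts_per_electron + max_offset + 2.0
    n_points = int(math.ceil(2.0 * half_width * rate * oversample / (2.0 * math.pi)))
    n_points = max(min_points, n_points)
    p = np.linspace(-half_width, half_width, n_points)
    return TransformGrid(p_values=p, half_width=half_width, n_points=n_points)


@dataclass(frozen=True)
class CountDistribution:
    """PMF and CDF of the rounded image count on a contiguous support."""

    support: np.ndarray  # integers n_min..n_max
    pmf_values: np.ndarray
    cdf_values: np.ndarray

    @property
    def n_min(self) -> int:
        return int(self.support[0])

    @property
    def n_max(self) -> int:
        return int(self.support[-1])

    def pmf(self, n):
        """PMF at integer count(s) ``n`` (0 outside the support)."""
        arr = np.atleast_1d(np.asarray(n))
        idx = arr - self.n_min
        inside = (idx >= 0) & (idx < len(self.support))
        out = np.zeros(arr.shape, dtype=float)
        out[inside] = self.pmf_values[idx[inside].astype(int)]
        return out if np.ndim(n) else float(out[0])

    def cdf(self, n):
        """P(count <= n); 0 below the support, ~1 above it."""
        arr = np.atleast_1d(np.asarray(n))
        idx = np.clip(arr - self.n_min, -1, len(self.support) - 1).astype(int)
        out = np.where(idx < 0, 0.0, self.cdf_values[np.clip(idx, 0, None)])
        return out if np.ndim(n) else float(out[0])

    def mean(self) -> float:
        return float(np.sum(self.support * self.pmf_values))

    def variance(self) -> float:
        mu = self.mean()
        return float(np.sum((self.support - mu) ** 2 * self.pmf_values))


def _sinc_half(p: np.ndarray) -> np.ndarray:
    # sin(p/2)/(p/2) with the removable singularity at 0; np.sinc is
    # the normalized sinc sin(pi x)/(pi x).
    return np.sinc(p / (2.0 * np.pi))


def cf_emccd(p, model: NoiseModel):
    """Characteristic function of the rounded EMCCD image count.

    Parameters
    ----------
    p
        Fourier variable (radians per image count), scalar or array.
    model
        Camera constants plus the Poisson rate lam.

    Returns
    -------
    Complex value(s) of the CF at ``p``.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("transform variable p must be finite")
    chip = model.chip
    readout = np.exp(-0.5 * p**2 * chip.r**2 + 1j * p * chip.delta)
    if chip.gain_on:
        amplified = np.exp(model.lam * (1.0 / (1.0 - 1j * p * (chip.g / chip.f)) - 1.0))
    else:
        amplified = np.exp(model.lam * (np.exp(1j * p / chip.f) - 1.0))
    out = readout * amplified * _sinc_half(p)
    return out if out.ndim else complex(out)


def moments(model: NoiseModel) -> tuple[float, float]:
    """Closed-form (mean, variance) of the rounded image count.

    Gain on:  mean = lam*g/f + delta,  var = 2*lam*(g/f)^2 + r^2 + 1/12.
    Gain off: mean = lam/f + delta,    var = lam/f^2 + r^2 + 1/12.
    The 1/12 term is the variance of the uniform rounding error.
    """
    chip = model.chip
    if chip.gain_on:
        mean = model.lam * chip.g / chip.f + chip.delta
        var = 2.0 * model.lam * (chip.g / chip.f) ** 2 + chip.r**2 + 1.0 / 12.0
    else:
        mean = model.lam / chip.f + chip.delta
        var = model.lam / chip.f**2 + chip.r**2 + 1.0 / 12.0
    return mean, var


def _invert_cf_on_integers(
    cf_values: np.ndarray, grid: TransformGrid, n_values: np.ndarray, center: float
) -> np.ndarray:
    """Trapezoidal inverse Fourier transform at the given integers.

    ``cf_values`` are the CF samples on ``grid``; the phase is unwound
    around ``center`` so the residual oscillation rate is |n - center|.
    """
    p = grid.p_values
    base = cf_values * np.exp(-1j * p * center)
    weights = np.full(p.shape, grid.spacing)
    weights[0] *= 0.5
    weights[-1] *= 0.5
    base = base * (weights / (2.0 * math.pi))
    d = np.asarray(n_values, dtype=float) - center
    out = np.empty(len(d), dtype=float)
    # chunk the (|d| x n_points) phase matrix to bound memory
    chunk = max(1, int(5e6 // max(len(p), 1)))
    for i in range(0, len(d), chunk):
        block = np.exp(np.outer(-1j * d[i : i + chunk], p))
        out[i : i + chunk] = (block @ base).real
    return out


def _build_from_cf(
    cf_func,
    mean: float,
    var: float,
    grid: TransformGrid,
    tail_mass: float,
) -> CountDistribution:
    """Invert an arbitrary count CF into a distribution on integers.

    The support starts at mean +/- 6 sd and is extended outward in
    4-sd blocks until the captured mass reaches ``1 - tail_mass`` (hard
    failure below 1 - 1e-4 after maximal extension).
    """
    sd = math.sqrt(max(var, 1.0 / 12.0))
    center = round(mean)
    cf_values = cf_func(grid.p_values)

    lo = math.floor(mean - 6.0 * sd)
    hi = math.ceil(mean + 6.0 * sd)
    block = max(4, math.ceil(4.0 * sd))
    support = np.arange(lo, hi + 1)
    pmf = _invert_cf_on_integers(cf_values, grid, support, center)

    max_halfwidth = 80.0 * sd + 10.0
    for _ in range(64):
        mass = pmf.sum()
        if mass >= 1.0 - tail_mass:
            break
        grew = False
        if pmf[0] > tail_mass / (8.0 * block) and center - lo < max_halfwidth:
            new = np.arange(lo - block, lo)
            pmf = np.concatenate([_invert_cf_on_integers(cf_values, grid, new, center), pmf])
            lo -= block
            grew = True
        if pmf[-1] > tail_mass / (8.0 * block) and hi - center < max_halfwidth:
            new = np.arange(hi + 1, hi + block + 1)
            pmf = np.concatenate([pmf, _invert_cf_on_integers(cf_values, grid, new, center)])
            hi += block
            grew = True
        if not grew:
            break
    if pmf.sum() < 1.0 - 1e-4:
        raise InversionError(
            f"captured mass {pmf.sum():.6f} < 1 - 1e-4 after maximal support extension"
        )

    most_negative = pmf.min()
    if most_negative <= -1e-9:
        raise InversionError(
            f"PMF value {most_negative:.3e} below -1e-9: quadrature grid failure"
        )
    pmf = np.clip(pmf, 0.0, None)
    total = pmf.sum()
    if total > 1.0:
        pmf = pmf / total
    cdf = np.minimum(np.cumsum(pmf), 1.0)
    return CountDistribution(
        support=np.arange(lo, hi + 1), pmf_values=pmf, cdf_values=cdf
    )


def build_distribution(
    model: NoiseModel,
    grid: TransformGrid | None = None,
    tail_mass: float = 1e-9,
) -> CountDistribution:
    """PMF/CDF of the image count for ``model`` by inverse Fourier transform.

    Parameters
    ----------
    model
        Chip constants plus lam.
    grid
        Transform grid; sized automatically when omitted.
    tail_mass
        Target uncaptured probability mass outside the support.
    """
    mean, var = moments(model)
    if grid is None:
        sd = math.sqrt(max(var, 1.0 / 12.0))
        grid = make_grid(model.chip, model.lam, max_offset=80.0 * sd + 10.0)
    return _build_from_cf(lambda p: cf_emccd(p, model), mean, var, grid, tail_mass)


def invert_cdf(
    p_tail: float, model: NoiseModel, dist: CountDistribution | None = None
) -> int:
    """Smallest integer N with P(count > N) <= ``p_tail``.

    Classifying counts above the returned N as signal ("white") gives a
    background false-positive probability of at most ``p_tail``, and no
    smaller threshold achieves that.
    """
    if not (0.0 < p_tail < 1.0):
        raise ValueError(f"p_tail must be in (0, 1), got {p_tail}")
    if dist is None:
        dist = build_distribution(model, tail_mass=min(1e-9, p_tail * 1e-3))
    tail = 1.0 - dist.cdf_values  # tail[i] = P(count > support[i]), decreasing
    idx = np.searchsorted(-tail, -p_tail)  # first index with tail <= p_tail
    if idx >= len(tail):
        idx = len(tail) - 1
    return int(dist.support[idx])


def region_sum_pvalue(
    observed_sum: int,
    k: int,
    model: NoiseModel,
    exact_k_max: int = EXACT_REGION_SUM_MAX_PIXELS,
) -> float:
    """P(sum of k iid background counts >= observed_sum).

    For small regions (k <= ``exact_k_max``) the k-th power of the CF is
    inverted exactly; larger regions use a continuity-corrected normal
    approximation with mean k*mu and variance k*sigma^2.
    """
    if k < 1 or int(k) != k:
        raise ValueError(f"region size k must be a positive integer, got {k}")
    k = int(k)
    observed_sum = int(observed_sum)
    mean, var = moments(model)
    if k == 1:
        dist = build_distribution(model)
        return float(np.clip(1.0 - dist.cdf(observed_sum - 1), 0.0, 1.0))
    z = (observed_sum - 0.5 - k * mean) / math.sqrt(k * var)
    if k <= exact_k_max and abs(z) <= 8.0:
        sd = math.sqrt(k * var)
        # tails beyond ~10 sd carry < 1e-20 mass; no need to resolve them
        max_offset = 12.0 * sd + 10.0
        rate = k * model.lam * model.chip.counts_per_electron + max_offset
        half_width = default_half_width(model.chip)
        n_points = max(
            _MIN_POINTS,
            int(math.ceil(2.0 * half_width * (rate + 2.0) * _OVERSAMPLE / (2.0 * math.pi))),
        )
        grid = TransformGrid(
            p_values=np.linspace(-half_width, half_width, n_points),
            half_width=half_width,
            n_points=n_points,
        )
        dist = _build_from_cf(
            lambda p: cf_emccd(p, model) ** k, k * mean, k * var, grid, 1e-9
        )
        return float(np.clip(1.0 - dist.cdf(observed_sum - 1), 0.0, 1.0))
    # large regions or extreme sums: continuity-corrected normal tail
    return float(stats.norm.sf(z))
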