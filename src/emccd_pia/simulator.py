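"""Forward simulation of the EMCCD noise chain and synthetic scenes.

The simulator draws each pixel through the physical chain — Poisson
photoelectrons, Gamma electron multiplication (when the gain register is
on), Gaussian readout noise around ``n_oe / f + delta``, and rounding to
the nearest integer — and composes full scenes (disk/annulus "beads" on
a uniform Poisson background) and calibration stacks with ground truth.
It doubles as the Monte-Carlo oracle for the characteristic-function
inversion in :mod:`emccd_pia.noise_model`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .noise_model import ChipParams

__all__ = [
    "Disk",
    "Annulus",
    "SceneSpec",
    "GroundTruth",
    "CalibrationStacks",
    "signal_rate_from_snr",
    "snr_from_rates",
    "draw_counts",
    "render_scene",
    "make_calibration_stacks",
    "random_bead_spec",
]


@dataclass(frozen=True)
class Disk:
    """Hard-edged circular signal region (no PSF)."""

    center: tuple[float, float]  # (row, col)
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("disk radius must be positive")

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2

    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class Annulus:
    """Ring-shaped signal region; its hole is true background."""

    center: tuple[float, float]
    r_outer: float
    r_inner: float

    def __post_init__(self):
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError("need 0 < r_inner < r_outer")

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d2 = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
        return (d2 <= self.r_outer**2) & (d2 > self.r_inner**2)

    def area(self) -> float:
        return math.pi * (self.r_outer**2 - self.r_inner**2)


#: Excess noise factor squared of the electron-multiplication register:
#: stochastic amplification doubles the shot-noise variance, which is
#: why the count variance carries the factor 2 in 2*lam*(g/f)^2.
EXCESS_NOISE_FACTOR_SQ = 2.0


def signal_rate_from_snr(snr: float, lam_bg: float, convention: str = "emccd") -> float:
    """Solve the signal Poisson rate lam_sig from an SNR value.

    ``convention="emccd"`` (default) is the mean-to-noise ratio of this
    camera model, SNR = lam_sig / sqrt(F^2 (lam_sig + lam_bg)) with
    excess noise factor F^2 = 2 from the multiplication register;
    ``"shot"`` is the plain shot-noise ratio (F^2 = 1); ``"ratio"`` is
    the literal fraction lam_sig / (lam_sig + lam_bg) (must be < 1).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if convention in ("emccd", "shot"):
        f2 = EXCESS_NOISE_FACTOR_SQ if convention == "emccd" else 1.0
        a = snr**2 * f2  # lam_sig^2 = a (lam_sig + lam_bg)
        return 0.5 * (a + math.sqrt(a**2 + 4.0 * a * lam_bg))
    if convention == "ratio":
        if snr >= 1:
            raise ValueError("ratio-convention snr must be < 1")
        return snr * lam_bg / (1.0 - snr)
    raise ValueError(f"unknown snr convention {convention!r}")


def snr_from_rates(lam_sig: float, lam_bg: float, convention: str = "emccd") -> float:
    if convention in ("emccd", "shot"):
        f2 = EXCESS_NOISE_FACTOR_SQ if convention == "emccd" else 1.0
        return lam_sig / math.sqrt(f2 * (lam_sig + lam_bg))
    if convention == "ratio":
        return lam_sig / (lam_sig + lam_bg)
    raise ValueError(f"unknown snr convention {convention!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic scene: uniform background plus additive signal objects.

    Signal strength may be given directly (``lam_sig``) or through
    ``snr``; inside objects the Poisson rate is lam_bg + lam_sig.
    """

    shape: tuple[int, int]
    objects: tuple = field(default_factory=tuple)
    lam_bg: float = 20.0
    lam_sig: float | None = None
    snr: float | None = None
    snr_convention: str = "emccd"

    def __post_init__(self):
        if self.lam_bg < 0:
            raise ValueError("lam_bg must be non-negative")
        if self.lam_sig is None and self.snr is None and self.objects:
            raise ValueError("give lam_sig or snr when the scene has objects")
        if self.lam_sig is not None and self.lam_sig < 0:
            raise ValueError("lam_sig must be non-negative")

    @property
    def signal_rate(self) -> float:
        if self.lam_sig is not None:
            return self.lam_sig
        if self.snr is not None:
            return signal_rate_from_snr(self.snr, self.lam_bg, self.snr_convention)
        return 0.0

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "lam_bg": self.lam_bg,
            "lam_sig": self.signal_rate,
            "snr": self.snr,
            "snr_convention": self.snr_convention,
            "objects": [
                {"type": type(o).__name__.lower(), **vars(o)} for o in self.objects
            ],
        }


@dataclass(frozen=True)
class GroundTruth:
    """Per-pixel truth of a rendered scene."""

    mask: np.ndarray  # True where signal
    lam_map: np.ndarray  # per-pixel Poisson rate


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_counts(lam, chip: ChipParams, n: int | None = None, seed=None) -> np.ndarray:
    """Draw rounded image counts through the full EMCCD chain.

    Parameters
    ----------
    lam
        Poisson rate, scalar or array (one rate per sample).
    chip
        Camera constants; ``chip.gain_on`` selects the multiplication
        stage.
    n
        Number of samples when ``lam`` is scalar; ignored for arrays.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    rng = _as_rng(seed)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lam must be non-negative")
    if lam.ndim == 0:
        if n is None or n < 1:
            raise ValueError("n >= 1 required for scalar lam")
        lam = np.full(int(n), float(lam))
    n_ie = rng.poisson(lam)
    if chip.gain_on:
        n_oe = np.zeros(n_ie.shape, dtype=float)
        pos = n_ie > 0
        if np.any(pos):
            n_oe[pos] = rng.standard_gamma(n_ie[pos]) * chip.g
    else:
        n_oe = n_ie.astype(float)
    n_ic = n_oe / chip.f + chip.delta
    if chip.r > 0:
        n_ic = n_ic + rng.normal(0.0, chip.r, size=n_ic.shape)
    return _round_half_away(n_ic).astype(np.int64)


def render_scene(spec: SceneSpec, chip: ChipParams, seed=None) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an integer image plus its ground truth.

    Every pixel is drawn independently through :func:`draw_counts` with
    rate lam_bg outside the objects and lam_bg + lam_sig inside their
    union.  Overlapping objects are allowed (the union is signal).
    """
    rng = _as_rng(seed)
    shape = tuple(spec.shape)
    mask = np.zeros(shape, dtype=bool)
    for obj in spec.objects:
        obj_mask = obj.render(shape)
        if not obj_mask.any():
            raise ValueError(f"object {obj} covers zero pixels of the image")
        mask |= obj_mask
    lam_map = np.full(shape, float(spec.lam_bg))
    lam_map[mask] += spec.signal_rate
    image = draw_counts(lam_map.ravel(), chip, seed=rng).reshape(shape)
    return image, GroundTruth(mask=mask, lam_map=lam_map)


@dataclass(frozen=True)
class CalibrationStacks:
    """Per-level frame stacks at constant illumination, both gain modes."""

    lam_levels: tuple[float, ...]
    gain_on: tuple[np.ndarray, ...]  # each (n_frames, H, W)
    gain_off: tuple[np.ndarray, ...]


def make_calibration_stacks(
    chip: ChipParams,
    lam_levels,
    n_frames: int,
    shape: tuple[int, int],
    seed=None,
    lam_profile: np.ndarray | None = None,
) -> CalibrationStacks:
    """Simulate the calibration protocol: static illumination stacks.

    Per illumination level, ``n_frames`` independent frames are drawn at
    constant per-pixel rate (optionally modulated by a smooth spatial
    ``lam_profile`` to mimic immobile beads), once with the gain on and
    once with it off.
    """
    lam_levels = tuple(float(v) for v in lam_levels)
    if not lam_levels:
        raise ValueError("lam_levels must not be empty")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = _as_rng(seed)
    if lam_profile is None:
        profile = np.ones(shape)
    else:
        profile = np.asarray(lam_profile, dtype=float)
        if profile.shape != tuple(shape):
            raise ValueError("lam_profile shape mismatch")
    stacks: dict[bool, list[np.ndarray]] = {True: [], False: []}
    for gain_on in (True, False):
        mode_chip = chip.with_gain(gain_on)
        for lam in lam_levels:
            lam_map = np.broadcast_to(lam * profile, shape)
            frames = np.stack(
                [
                    draw_counts(lam_map.ravel(), mode_chip, seed=rng).reshape(shape)
                    for _ in range(n_frames)
                ]
            )
            stacks[gain_on].append(frames)
    return CalibrationStacks(
        lam_levels=lam_levels,
        gain_on=tuple(stacks[True]),
        gain_off=tuple(stacks[False]),
    )


def random_bead_spec(
    shape: tuple[int, int],
    lam_bg: float,
    snr: float | None = None,
    lam_sig: float | None = None,
    radius: float = 4.0,
    signal_fraction: float | None = None,
    n_beads: int | None = None,
    seed=None,
    snr_convention: str = "emccd",
) -> SceneSpec:
    """Scatter disk beads uniformly at random over the image.

    Either a bead count (``n_beads``) or a target union ``signal_fraction``
    may be given; with a fraction, beads are added until the union of
    disks covers at least that share of pixels.
    """
    if (signal_fraction is None) == (n_beads is None):
        raise ValueError("give exactly one of signal_fraction or n_beads")
    rng = _as_rng(seed)
    h, w = shape
    margin = radius + 1.0
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the bead radius")
    objects: list[Disk] = []
    union = np.zeros(shape, dtype=bool)
    target = None if signal_fraction is None else signal_fraction * h * w
    max_beads = n_beads if n_beads is not None else 100_000
    while len(objects) < max_beads:
        center = (
            float(rng.uniform(margin, h - margin)),
            float(rng.uniform(margin, w - margin)),
        )
        disk = Disk(center=center, radius=radius)
        objects.append(disk)
        if target is not None:
            union |= disk.render(shape)
            if union.sum() >= target:
                break
    return SceneSpec(
        shape=tuple(shape),
        objects=tuple(objects),
        lam_bg=lam_bg,
        lam_sig=lam_sig,
        snr=snr,
        snr_convention=snr_convention,
    )


def write_scene(out_dir, image: np.ndarray, truth: GroundTruth, spec: SceneSpec, seed) -> None:
    """Write a rendered scene as 16-bit TIFF + 8-bit mask + JSON sidecar."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tif", image.astype(np.uint16))
    tifffile.imwrite(out / "truth_mask.tif", truth.mask.astype(np.uint8) * 255)
    sidecar = {"spec": spec.to_dict(), "seed": seed}
    with open(out / "scene.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)
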