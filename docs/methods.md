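# Methods

This note documents the model, the numerical machinery, the synthetic
data conventions and the design decisions behind `emccd_pia`.

## Noise model

A pixel's recorded count arises from a four-stage chain:

1. **Photoelectrons** `n_ie ~ Poisson(λ)`. λ absorbs the quantum
   efficiency and neglects spurious charge; it is the single
   illumination parameter per pixel (dimensionless electrons per
   exposure).
2. **Electron multiplication** (gain on): `n_oe ~ Gamma(shape=n_ie,
   scale=g)` for `n_ie ≥ 1`, `n_oe = 0` otherwise. `g` is the mean
   gain. With gain off, `n_oe = n_ie`.
3. **Readout**: `n_ic ~ Normal(n_oe/f + Δ, r²)` with conversion factor
   `f` (electrons/count), offset `Δ` and readout noise `r` (counts).
4. **Rounding** to the nearest integer (ties away from zero; any tie
   rule is inside the uniform-error model's 1/12 variance).

The characteristic function of the rounded count is closed-form (see
README); the rounding stage enters as a `sinc(p/2)` factor, i.e. the
rounding error is treated as an independent Uniform(−½, ½) variate.
That approximation has a lattice error of order `exp(−2π²r²)`: it is
negligible for `r ≳ 0.8` counts (real EMCCD readout noise is ~1.5) and
the package is not meant for quantization-dominated regimes. The
gain-off CF replaces the Gamma factor by the Poisson CF
`exp(λ(e^{ip/f} − 1))`.

Moments used throughout:

| mode | mean | variance |
|---|---|---|
| gain on  | `λg/f + Δ` | `2λ(g/f)² + r² + 1/12` |
| gain off | `λ/f + Δ`  | `λ/f² + r² + 1/12` |

## CF inversion

`pmf(n) = (1/2π) ∫ e^{−ipn} φ(p) dp`, evaluated by trapezoidal
quadrature on a symmetric grid. Choices:

- **Cutoff**: `P = sqrt(2 ln 10¹²)/r` so `|φ(P)| < 10⁻¹²` via the
  Gaussian readout envelope; with `r = 0` the decay is only `~e^{−λ}/p`
  and a fixed `P = 64π` is used.
- **Sampling**: the phase is unwound around the distribution's center,
  so the residual oscillation rate is bounded by
  `λ·(g/f) + |n − center| + 2`; the grid supplies 8 points per period,
  with a floor of 4096 points. Trapezoidal quadrature of a smooth
  integrand that vanishes at the endpoints is spectrally accurate;
  observed PMF errors are ≲10⁻¹².
- **Support**: mean ± 6 sd, extended in 4-sd blocks until the captured
  mass reaches `1 − tail_mass` (default 10⁻⁹); failure to reach
  `1 − 10⁻⁴` raises. Quadrature ripple more negative than −10⁻⁹ raises
  (grid failure); smaller negatives are clipped and the PMF is
  renormalized only if its sum exceeds 1.
- **CDF convention**: `cdf(n) = P(count ≤ n)` on integers.

Region-sum p-values `P(Σᵢ Xᵢ ≥ s)` invert `φ(p)^k` exactly for regions
of `k ≤ 64` pixels and fall back to a continuity-corrected normal
approximation (mean `kμ`, variance `kσ²`) above that, or whenever the
observed sum is more than 8 sd from the mean (where the exact
quadrature is noise-floor-limited anyway).

## Calibration

Per-pixel sample means and unbiased variances over frame stacks are
pooled across illumination levels, the bottom/top 1% of pixels *by
mean* are trimmed per experiment, and ordinary least squares gives the
two mean–variance lines. Trimming by mean (the regressor) removes
outlier pixels without biasing the fit; trimming by variance would
select on the response and systematically pull the line down — the
effect is small (~0.2% of σ²) but visible in the tightly determined
readout noise. The four parameters follow from

```
f = 1/k_nogain, g = k_gain f/2,
Δ = f (C_nogain − C_gain)/(2g − 1), r² = C_nogain − 1/12 + Δ/f.
```

Uncertainty comes from refitting on random 1000-pixel subsets (200
repetitions, without replacement within a repetition) and reporting
per-parameter medians and interquartile ranges. Two conditions matter
for this to be meaningful and are the defaults in the simulated
studies: the illumination levels span the dynamic range
(λ ∈ {0, 150, 300}; with a narrow span the gain-off mean range is a few
ADU and the slope is ill-conditioned), and the pixel count is large
against the 1000-pixel subsets (96×96; when the subset is a sizable
fraction of the data the subsample spread understates the true sampling
variability by the finite-population factor `N/n − 1`). Per-level
exclusion of outlier illumination points is available as configuration
but off by default.

## Background estimation

Sorted counts below a truncation point `N` follow the truncated model
`pmf(n|θ)/cdf(N|θ)`. The scan:

1. Candidate truncations: unique observed counts from the 25% data
   quantile to the maximum, thinned to ≤ 60 evenly in quantile space
   (endpoints kept) — enough resolution while keeping a 64×64 tile
   around 100 ms.
2. For each candidate, λ is fitted by bounded derivative-free scalar
   maximization on `[10⁻³, 50·λ_init]` with
   `λ_init = (median count − Δ)/(g/f)` and relative tolerance 10⁻⁴.
   The search interval starts at `4·λ_init` and expands by factors of 4
   while the optimum presses against it: the quadrature grid must
   resolve phase rates proportional to the largest λ evaluated, and
   sizing it for the formal bound up front costs ~5× for nothing.
   The inverse-Fourier phase matrix over the data's count range is
   built once per image and reused across all likelihood evaluations.
3. Goodness of fit: the truncated PMF is split into 5 contiguous count
   intervals by greedy accumulation to the 1/5 quantiles (at least one
   integer per bin); `Σ(O−E)²/E` is referred to χ² with
   5 − 1 − 1 = 3 degrees of freedom (one estimated parameter). Under
   the null the resulting p-values are uniform (KS-tested in the
   acceptance suite).
4. The accepted truncation `N_icr_bg` is the *largest* candidate with
   `p ≥ p_GoF = 0.01`; λ_bg is its fitted rate. If none passes, the
   error carries the full scan so callers (the tiled pipeline) can fall
   back.

## Thresholding and a priori rates

`p_binarize` (default 0.01) is inverted through the background CDF to
the smallest `N` with `1 − cdf(N) ≤ p_binarize`; counts `≤ N` are
black, `> N` white (white = positive). The background pixel count is
the through-origin least-squares slope of
`#(counts ≤ N_j)` against `cdf(N_j|θ)` for all integers `N_j` from the
support minimum to `N_icr_bg − 1` (using all of them beats restricting
to low quantiles: the model-CDF error at small `N_j` outweighs the
signal leakage at large `N_j`). Bookkeeping follows
`n(black|bg) = n_bg·cdf(N)`, `n(black|s) = n_black − n(black|bg)`
(clipped to `[0, n_s]`, flagged when clipped), and
`p(black|s) = (n(black|s)+1)/(n_s+2)` with the +1/+2 correction keeping
probabilities off the boundary. Rates: FPR = p(white|bg),
FNR = p(black|s), ACC/FDR/FOR by the standard confusion-matrix
formulas; zero denominators yield 0 with a flag.

**Known limitation.** Signal pixels whose counts fall below `N_icr_bg`
leak into the `n_bg` slope. At low SNR (≲ 3 under the convention below)
with dense signal (15% of pixels) this inflates `n_bg` by several
percent, which deflates the a priori FNR (and hence FOR and 1−ACC) by
up to tens of percent relative; the χ² scan cannot reject the
contaminated truncations because the fitted λ absorbs the smooth shift.
FPR control is unaffected — it depends only on the background CDF — and
the bias vanishes as the signal separates (SNR ≳ 5) or thins out. The
acceptance suite asserts the strict agreement tolerances anyway and
documents where they fail.

The Otsu baseline is an exhaustive scan over distinct counts minimizing
the within-class variance sum; it is included only as the comparison
point without error control.

## Segmentation

White components use 8-connectivity, black components 4-connectivity
(the standard complementary pair). For each color the region sizes are
sorted; the walk along unique sizes stops at the first gap larger than
`allowedGapLength` (default 1) and every region at or below the
stopping size is flipped. Both cuts are computed from the input mask
and applied in one pass. When no qualifying gap exists the outcome is
color-asymmetric: all white regions are dropped (no object is
distinguishable from noise), while black regions are left alone
(flipping the background color wholesale would invert a perfectly
clean mask). Cleaning is deliberately not iterated — the rule is not
idempotent, since removing the noise cluster removes the very gap that
defined it. Surviving white regions get `p_seg`, the probability that
their summed counts arise from as many background pixels; regions
spanning several tiles are scored with the mean λ_bg of the tiles they
touch.

## Tiled pipeline

Images are covered by 64×64 tiles (row/column labels starting at 1;
edge remainders narrower than 16 pixels merge into their neighbor), so
the constant-illumination assumption only has to hold locally. Per
tile: background fit → threshold → binarize → a priori rates. Tiles
failing every goodness-of-fit test are flagged, excluded from the
pixel-count-weighted rate aggregation, and binarized with the threshold
of the nearest passing tile. The report is JSON with sorted keys; the
pipeline is deterministic given its inputs.

## Synthetic data

The simulator emulates the study conditions: uniform Poisson
background (default λ_bg = 20), hard-edged disk "beads" (default
radius 4 px, union coverage ~15% of pixels) or annuli, signal additive
on background, and the full camera chain per pixel. One seeded
generator drives all randomness; identical seeds give identical scenes.

**SNR convention.** Scenes parameterized by SNR use the EMCCD
signal-to-noise ratio `SNR = λ_sig/√(F²(λ_sig+λ_bg))` with excess noise
factor `F² = 2` — exactly the mean-to-standard-deviation ratio implied
by the model's own variance law `2λ(g/f)²`. At λ_bg = 20 this makes
SNR 3 correspond to λ_sig = 30 (a visually obvious but noisy bead).
The plain shot-noise convention (`F² = 1`) and the literal intensity
fraction `λ_sig/(λ_sig+λ_bg)` are available via `snr_convention`.

What the simulator does *not* model: optics (no PSF — bead edges are
hard, so segmentation results on synthetic data bound what blurred real
objects would give), photobleaching or time dependence, per-pixel gain
variation, and non-Poisson signal statistics. Passing tests therefore
validate the statistical machinery, not robustness to optical blur or
gain non-uniformity.

## Problem sizes in the test suite

Simulated studies run at 256×256 scenes (65 536 pixels), 20-scene
replications for rate statements, 500-frame calibration stacks on a
96×96 region, and 1000 replicates for the χ² uniformity check; the
whole suite completes in about two minutes on one CPU. These sizes were
chosen so every asserted statistic has sampling error well below its
tolerance.
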