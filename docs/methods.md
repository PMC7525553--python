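# Methods

## Forward model

The synthetic detector model makes three assumptions: the ground-truth
scattering pattern has circular symmetry with Lorentzian ring profiles;
photon counting is Poisson; and a spurious isotropic background falls off
as 1/q. Concretely, on a high-resolution (HR) grid of pitch `l/f`
(`l` = physical pixel size, `f` = integer enhancement factor),

```
I_GT(ρ) = Σ_rings A · γ² / ((ρ − R)² + γ²)  +  c/ρ        for ρ > r_beamstop
I_GT(ρ) = 0                                                behind the beamstop
```

with ρ the distance from the beam center. The Lorentzian is used
unnormalised (peak value `A` at ρ = R) so quoted amplitudes are directly
peak heights in counts per unit exposure. Ring radii, widths and the
background scale are quoted in *detector pixels* — the natural unit of the
apparatus — and converted to HR pixels internally (`two_ring_pattern`).

The beam PSF is a slit aperture convolved with a Gaussian source; its 1D
profile is the erf-difference closed form of a width-`w` rectangle
convolved with a σ = s Gaussian, and the 2D kernel is the separable
product. A PSF set is built from three square slit sizes `{s, s+1, s+2}`
(in `l/f` units) plus their three rectangular combinations — six distinct
PSFs from three sizes. Kernel flux is proportional to slit area `w_x·w_y`,
normalised so the smallest slit has flux 1: wider slits pass more photons
and yield brighter, more smeared frames.

A detector frame at sub-pixel offset `(dx, dy)` (integers in `[0, f)`)
crops the blurred HR image at that offset and draws
`Poisson(t · box_sum)` per pixel, where `box_sum` aggregates the `f x f`
HR cells under the pixel (photon tallies are additive). An idealised
`aperture="point"` mode instead samples the cell-center value (scaled by
`f²` to preserve flux): a decimating detector with no in-pixel
integration. The distinction matters: the `f x f` box transfer function
has exact nulls at the period-`f` frequencies that a complete sub-pixel
shift grid would otherwise restore, so *fusion alone* can only resolve
structure finer than one pixel under point sampling. The box aperture is
the default everywhere, including the headline benchmark; the point
aperture is used for the pure-SPS resolution demonstrations, matching the
idealised synthetic setup in which sub-pixel sampling alone separates a
2/3-pixel doublet.

All forward and solver convolutions use symmetric (reflective) padding
cropped back to shape: wrap-around would alias rings across detector
edges, while reflection keeps flux nearly conserved for
interior-dominated patterns. Randomness flows from one root
`SeedSequence` per acquisition with per-frame child seeds, so a single
integer reproduces an entire study.

## Registration and fusion (SPS)

Frames within one PSF group are registered to the first frame by
translation-only Lucas–Kanade: images are transformed as `log(1+counts)`
(compressing ring dynamic range so beamstop-edge gradients do not dominate
the normal equations), lightly smoothed (σ = 1 px), and iterated
coarse-to-fine over a 2-level mean-pyramid. Noiseless recovery is exact to
~5e-4 px; at the benchmark SNR errors are a few hundredths of a pixel.
A non-converged frame falls back to its nominal stage position (stage
accuracy is far below one sub-pixel step, so the nominal value is a safe
prior).

Fusion is robust shift-and-add interlacing: each frame's pixels are
placed on the `l/f` lattice at its estimated offset rounded to the
nearest lattice position (estimation keeps full precision; placement is
lattice-quantised, which absorbs sub-step registration noise), coincident
samples are combined by median (robust to hot pixels and cosmic counts),
and unfilled cells are nearest-neighbour filled and flagged. No
deconvolution happens at this stage, keeping SPS and CMD composable. The
fused canvas is displaced by `(f−1)/2` HR cells relative to the scene (a
pixel's value is indexed by its first HR cell); downstream code corrects
the beam center accordingly.

## Multi-PSF deconvolution (CMD)

Given observations `Y_i ≈ s_i (P_i * X)` (scale `s_i` = exposure x flux),
the estimate minimises

```
Σ_i ||Y_i − P_i * X||²_F / (2σ_i²) + ν ||X||²_F .
```

Per-image weights come from a Gaussian profile over relative total
intensity `r_i = I_i / mean(I)` (intensity tracks slit area and hence
SNR), normalised to `Σ w_i = m`, with `σ_i = (2 w_i)^(−1/2)`. The
`balanced` preset centers the profile at 70% of the mean intensity with
width 20% — the profile found optimal experimentally, slightly favouring
the smaller slits — while `tight`/`wide` center it at the smallest/largest
ratio. Since the objective is quadratic, the minimiser is computed in
closed form per spatial frequency,

```
X̂(ω) = [Σ_i conj(P̂_i) Ŷ_i / σ_i²] / [Σ_i |P̂_i|² / σ_i² + 2ν] ,
```

on a reflect-padded domain (padding to twice the support, then cropping).
Observations are divided by `s_i` and by a common order-one scale before
solving — ν is therefore dimensionless, acting on unit-normalised
intensities — and the solution is rescaled after. ν = 0 with spectrally
deficient PSFs triggers a warning and a minimal ridge floor. An L-BFGS
iterative solver on the same (padded, circular) objective is provided and
agrees with the closed form to machine precision when unconstrained; the
"constrained" variant projects onto non-negativity (as a cheap projection
of the closed-form solution by default, or as bound constraints in the
iterative solver). The non-negativity projection materially stabilises
the azimuthal profile of low-ν retrievals and is enabled in the reference
protocol. Anisotropic satellite artifacts of the frequency-domain
solution are a known cosmetic limitation; L1/total-variation alternatives
are deliberately out of scope.

For the combined retrieval the per-PSF fused images enter CMD on the
`l/f` grid with kernels `P_i ⊗ box_f` (beam smear plus pixel
aggregation), so the deconvolution removes both; with point-aperture data
the box factor is omitted. The order is fixed — fusion first,
deconvolution second: blurring physically precedes detector decimation,
and deconvolving first corrupts the sub-pixel translations registration
needs (reversing the order drops the benchmark separation from ≈0.21 to
≈0.02).

Ridge tuning uses a grid search over
`ν ∈ {1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2}` maximising the mean separation
criterion over replicate acquisitions, followed by the one-standard-error
rule familiar from regularisation-path model selection: the largest ν
whose mean is within one SE of the best. Tiny ν occasionally wins on the
mean with enormous run-to-run variance; the 1-SE rule trades a
statistically insignificant amount of metric for a markedly more stable
retrieval.

## Metrics

* `pixel_to_q`: `q = (4π/λ) sin(0.5·atan(ρ·(l/f)/d_s))` with the
  instrument defaults d_s = 117 mm, λ = 1.54 Å, l = 172 µm.
* Azimuthal integration: per-annulus mean and standard deviation, default
  bin width one effective pixel, bins *centered* on integer radii (bin 0
  is the beam-center pixel). The phase matters: with edges on integers, a
  valley at an integer radius straddles a bin containing a peak and a
  marginally resolved doublet binned at half its separation disappears.
* Separation criterion: the two highest local maxima in a user window and
  the minimum between them; `δ = (I_p − I_v)/Δq` with `I_p` the *lower*
  peak and `Δq` the lower-peak-to-valley distance (the text defining δ
  names the lower peak and the valley immediately before "the distance
  between them"; a `dq_mode="peak-peak"` flag provides the alternative
  reading). Peak detection uses a prominence floor of 3x the median
  standard error of the annulus mean (`spread/√n`), the noise scale of
  the profile actually searched — a raw-spread floor would reject real
  doublets on deconvolved images, whose azimuthal per-pixel spread is
  dominated by anisotropic solver artifacts. Merged or noise-level
  doublets therefore score δ = 0 without special-casing.
* Uncertainty: the same experiment repeated (40 by default) with child
  seeds; failed repeats score δ = 0 and are logged. The analytic error
  budget (Δδ_q ∝ Δq/q²; intensity term ∝ I^(−1/2)) is a secondary
  diagnostic only — the repeat std is the operative uncertainty.
* Retrieval error: Frobenius distance after scaling both images to unit
  total (frames at different fluxes must be comparable); when grids
  differ by an integer factor the ground truth is box-summed down,
  matching detector physics.

## Frozen study conditions

The reference benchmark (`srsaxs.study`, `scripts/acceptance.py`) uses:
rings at 30/34 detector px, widths 0.9, amplitudes 1/0.6, background 1,
beamstop 3 px, on a 257² HR grid (f = 3, 85 detector px); six PSFs from
square slit sizes {8, 9, 10} l/f (≈2.7–3.3 detector px, the scale of a
laboratory collimated beam — the equal-budget plain measurement through
the smallest of these leaves the doublet essentially merged, as in the
real instrument), source σ = 1 l/f; per-frame exposure 10 time units
(54 frames, total budget 540 — an intermediate-SNR regime where the
retrieval is stable run to run); balanced weights; non-negativity on;
ν tuned as above; δ window 25–40 detector px. The protocol-comparison and
resolution-trend studies use smaller grids and their own documented
parameters in the tests; ring amplitudes for fixtures whose absolute
scale is not otherwise pinned were chosen once to give realistic detector
counts (tens per pixel) and kept fixed.

Equal-budget protocol allocations for total time `T = 6 f² t`:
plain 1 frame x `6f²t`; SPS `f²` frames x `6t` (smallest PSF);
CMD 6 frames x `f²t` (one per PSF); SrSAXS `6f²` frames x `t`.
Stage-translation overhead is assumed negligible.

## What the synthetic generator does and does not emulate

It reproduces isotropic Bragg-like ring doublets, slit-defined beam
smearing with flux-area coupling, Poisson counting, sub-pixel detector
translation and a smooth 1/q background. It does **not** model
polychromaticity, detector charge-sharing or point-spread, module gaps
beyond generic masks, anisotropic textures, slit scatter, beamstop
scatter or cosmic spikes (the median fusion is nonetheless robust to
isolated hot pixels). Passing tests therefore demonstrate the estimators'
correctness and the protocol trade-offs under these assumptions, not
performance on any particular real instrument; experimentally measured
separation values depend on beam and sample specifics that are not
modelled here.

## Numerical choices and degenerate inputs

Convolution boundary: reflective, everywhere (solver padding to twice the
support). Richardson–Lucy uses circular FFT convolution with a unit-sum
kernel, which makes the multiplicative update conserve total flux exactly
per iteration; default 50 iterations with early stop at relative change
< 1e-5. (From a uniform start the first RL iterate is the correlation
`Pᵀ Y` — broader than the observation; sharpening emerges over
iterations.) The Farsiu-style baseline deconvolves the fused image by
steepest descent on an L2 data term plus bilateral total variation
(window 2, α = 0.7, weight 0.01, step 0.2, 30 iterations — defaults set
on synthetic fixtures to sit in the mild-deblurring regime and recorded
in result metadata); with zero regularisation and a delta PSF it is
stationary at the fused image. Ties in the ν grid search break toward
larger ν. Degenerate fusions (all frames on one lattice position) warn
and return the upsampled single position. Empty windows, all-masked
images, NaNs, negative RL inputs and out-of-range shifts raise.

## Known limitations

* The separation criterion is quantised by the radial bin width; on the
  native grid Δq resolves only to whole pixels.
* The closed-form solver's satellite rings can bias the annulus spread
  upward; the standard-error prominence floor compensates but very weak
  doublets near the beamstop remain hard.
* Best-subset PSF selection is not implemented; PSF subsets are nested in
  size order, which is mildly suboptimal at high SNR.
* Registration assumes pure translation; rotation/affine drift is out of
  scope.
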